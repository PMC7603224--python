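# atg8kit

Quantitative analysis of the human ATG8/LC3 protein family: where an LC3
paralogue sits inside the cell, how much autophagic flux it carries, and how
the six family members relate in sequence.

The package is aimed at cell biologists quantifying nucleocytoplasmic
shuttling of LC3A/LC3B/LC3C (e.g. after SIRT1 inhibition with Ex527 or HDAC
inhibition with TSA) from confocal images and western blots. It bundles four
things:

1. **A synthetic-image generator** producing DAPI / LC3-marker / p62 fields
   of elliptical cells with *exact* per-cell ground truth, so the imaging
   metrics can be validated end to end without real microscope data.
2. **Segmentation + localization metrics.** Per cell, the
   intensity-weighted **nuclear fraction**
   `NF = Σ(I − bg)₊ over nucleus / Σ(I − bg)₊ over cell`
   and the Manders-type **p62 co-localization**
   `M = Σ(I − bg)₊ over (cytosol ∩ p62 puncta) / Σ(I − bg)₊ over cytosol`,
   aggregated image → treatment (the image is the replicate unit).
3. **Densitometry statistics.** Tubulin normalization, control scaling, the
   autophagic-flux statistic
   `Flux = (LC3-II/Tub)₊BafA1 − (LC3-II/Tub)₋BafA1`
   paired by replicate, Kruskal–Wallis group tests with Benjamini–Hochberg
   post-hocs, and two-factor (treatment × protein) ANOVA.
4. **Sequence meta-analysis.** LIR-motif scanning (`[YFW]-X-X-[VIL]`),
   positional amino-acid frequencies per ATG8-specific interactor group,
   Clustal-style conservation classes (`*`, `:`, `.`) on alignments,
   p-distances and a neighbor-joining tree.

## Worked example

Simulate three replicate fields of 20 cells with 35% nuclear marker and 60%
p62 co-localization, then recover those parameters from the noisy images:

```bash
atg8kit recover --seed 0 --n-images 3 --out demo/
```

which prints (numbers from this exact command):

```
nuclear_fraction: target=0.350 measured=0.355 +/- 0.001 (n=3 images)
coloc_fraction: target=0.600 measured=0.598 +/- 0.004 (n=3 images)
```

i.e. both localization metrics are recovered to within ~0.01 of the
generative truth at realistic shot + read noise. `demo/cells.csv` holds the
per-cell measurements and `demo/provenance.json` the full configuration.

The flux statistic on a densitometry CSV (columns `protein, treatment,
bafA1, replicate, band, intensity, tubulin_intensity`):

```bash
atg8kit flux --table bands.csv --out flux.csv
```

Sequence analyses:

```bash
atg8kit lirscan --fasta interactors.fasta --out hits.csv --freqs freqs.csv
atg8kit msastats --msa atg8.aln            # identical/similar column counts
atg8kit njtree --msa atg8_aligned.fasta --out tree.nwk
```

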