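# Methods

## The measurement problem

LC3B shuttles between nucleus and cytosol; deacetylase inhibition traps it
in the nucleus and the question is whether LC3A or LC3C compensates in the
cytosol. Three quantitative readouts carry that analysis: the per-cell
nuclear fraction of an LC3 marker, its co-localization with the autophagy
receptor p62 in cytosolic puncta, and the BafA1-based autophagic-flux
statistic from western-blot densitometry. A fourth, sequence-level strand
asks how similar the six human ATG8 proteins are and whether their
interactors use distinguishable LIR motifs. Real confocal raw data for such
experiments are rarely deposited, so this package validates its image
metrics against a simulator whose ground truth is exact by construction.

## Synthetic fields (`simulate`)

Cells are random ellipses (axis ratio 0.6–1.0, random orientation), placed
by rejection sampling (≤ 1000 attempts per cell) so that they lie fully
inside the field and do not overlap; the nucleus is a concentric ellipse
scaled to a configurable area ratio (default 0.25). p62 puncta are discs
(default radius 3 px, 8 per cell) whose centers are sampled so each disc
fits in the cytosol with a 1-px rim and outside the nucleus.

The marker channel is solved, per cell, from three amplitudes:

* a uniform nuclear level,
* a uniform cytosolic level outside the punctum mask,
* Gaussian spot profiles (σ = punctum radius / 2) inside a random ~70%
  subset of the puncta.

Writing `T_c` for the total cytosolic marker, the inside-puncta mass is set
to `coloc_true · T_c` and the nuclear total to
`nf_true/(1 − nf_true) · T_c`, which makes the two recorded truths exact
pixel-sum identities on the noiseless render (the tests check them to
1e-6; they hold to float rounding). When `nf_true` equals the nuclear
pixel-area share this reduces to a uniform marker across the cell, as it
must. The randomness consumed per cell is independent of the targets, so
changing `nf_true`/`coloc_true` at a fixed seed changes intensities but not
geometry — this is what makes the recovery grid monotone by construction.

Noise follows the standard shot + read model: Poisson on
(signal + background) at `poisson_scale` photons per intensity unit, then
additive Gaussian read noise, then clamping to the unsigned-16-bit range.
Pixel expectation is `noiseless + background`. Defaults (background 20,
read σ 4, 1 photon/unit against a cytosolic mean of 300 counts) give an
SNR typical of well-exposed confocal imaging; the defaults are the study
conditions used throughout the tests.

What the simulator deliberately omits: point-spread blur, 3-D structure,
photobleaching, cell–cell contact, debris, and mitotic/apoptotic
morphologies. Passing the recovery tests therefore shows the *metrics and
their estimators* are unbiased under the stated model, not that any given
real-world acquisition is.

## Segmentation (`segment`)

* **Nuclei**: Gaussian smoothing (σ = 2 px), global Otsu, hole filling,
  minimum area 200 px. Parameter-light and deterministic.
* **Cell bodies**: the nucleus-seeded watershed runs on the smoothed
  marker + p62 sum, masked by a body mask whose threshold is placed halfway
  between the background level and the cytosolic plateau. The plateau is
  estimated from a ring a few pixels inside a provisional mask, on a
  grey-opened copy (flattens puncta) and away from nuclei (whose blur,
  bright or dark, is uninformative about the cytosol); the estimate is
  iterated three times so it converges from a rough start. The half-height
  rule puts the contour on the true edge of a smoothed step regardless of
  absolute intensities — this is what keeps cell masks accurate across the
  whole nuclear-fraction range. A nucleus without detectable cytosol
  collapses to cell = nucleus and is logged.
* **Puncta**: white top-hat with a disc of twice the expected punctum
  radius, then a per-cell threshold at median + 5·MAD of the cytosolic
  top-hat values, restricted to the cytosol.
* **Background** per channel is the median intensity outside all cells and
  is subtracted (floored at zero) before any intensity metric.
* Cells touching the field border are excluded from quantification: their
  truncated cytosol biases the nuclear fraction. This replaces manual
  visual QC with a deterministic rule.

## Localization metrics (`localize`)

Both metrics are intensity-weighted, not object-count based: nuclear LC3
pools are diffuse, and counting puncta would miss them. Restricting the
co-localization denominator to the cytosol prevents nuclear trapping from
mechanically deflating the coefficient. Cells with a zero denominator are
flagged undefined and excluded rather than imputed. Aggregation is
cells → image mean → treatment mean ± SD with the image as the replicate
unit (n = number of images, matching how such experiments are replicated);
the SD of a single image is reported as 0.

Recovery performance under the default noise model, measured by the
acceptance grid (nuclear fraction ∈ {0.1,…,0.9} × co-localization
∈ {0.2, 0.5, 0.8}, 3 fields × 20 cells each): maximum absolute
treatment-mean bias ≈ 0.007 (nuclear fraction) and ≈ 0.016
(co-localization), against tolerances of 0.05 and 0.07.

## Densitometry (`densitometry`)

Band intensities are divided by the lane's tubulin and scaled to the mean
tubulin-normalized ratio of the control rows. "Control" is interpreted as
treatment `Ctrl` without BafA1, per (protein, band); the operation is
idempotent by construction. The flux statistic subtracts the without-BafA1
from the with-BafA1 lipidated ratio *within* a replicate (lanes of one
membrane belong together); unpaired replicates are an error, not a silent
drop. Flux may legitimately be negative.

Group comparison of fluxes uses Kruskal–Wallis (the data are not assumed
normal) with two-sided Mann–Whitney post-hocs against the control,
BH-adjusted as one family per analysis. Normalized intensities use a
two-factor ANOVA (treatment × protein) with Type II sums of squares —
appropriate for mildly unbalanced layouts without a stated
interaction-driven design — and Welch t contrasts against control within
each protein, BH-adjusted, starred at 0.05/0.01/0.001. Degenerate layouts
(zero residual variance) are resolved explicitly: a zero-variance effect
gets F = 0, p = 1; a nonzero effect with zero residual gets F = ∞, p = 0.

Null calibration: with three groups of n = 10 exchangeable values, the
chi-square approximation of Kruskal–Wallis rejects at ≈ 4.2–4.6% for a
nominal 5% over 10,000 simulations. Group size matters here: with n = 3
per group the exact permutation null makes the chi-square test severely
conservative (≈ 1% rejection), which is a property of the test at that
sample size, not of the implementation; the calibration check therefore
uses the moderate-sample regime.

## Sequence analyses (`sequence`, `phylo`)

The LIR scan matches every (overlapping) window of `[YFW]-X-X-[VIL]`;
an unknown residue `X` may occupy the two variable positions but never an
anchor. Positional frequencies are relative occurrences over a group's
matches, with `X` excluded from the position's denominator. Conservation
classes follow the Clustal X convention verbatim (strong groups STA, NEQK,
NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW; weak groups CSA, ATV, SAG, STNK,
STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY); any gap voids a column.
Percent identity uses the full alignment length as denominator, including
gapped columns. Sub-setting an alignment drops columns that become all-gap;
a fresh re-alignment of the subset is the better route when an aligner is
available, and the LC3-only numbers are computed that way.

Distances are protein p-distances (mismatches over mutually gap-free
columns). The tree is plain Saitou–Nei neighbor joining, deterministic
(ties broken toward the lowest active-index pair), with negative branch
estimates clamped to zero and the deficit moved to the sister branch so
the pair's summed length is preserved. On additive matrices NJ is exact;
the tests verify topology recovery on random 4–8-taxon additive trees and
cross-check against an independent library implementation.

**Sequence provenance.** The packaged ATG8 FASTA
(`data/atg8_human_synthetic.fasta`) is a from-memory reconstruction of the
six human ATG8 paralogues plus yeast Atg8, written for this package and
labelled as such in every header — it is *not* a database export, and
single-residue deviations from the canonical Ensembl/UniProt entries are
possible. Alignments of this set (mafft G-INS-i) give 29 identical and 52
similar columns at 19.7% identity for the six human proteins, and 63–64
identical / ~40 similar columns at ~43% identity for the LC3 trio — in
line with, but not digit-exact against, the published values for the
canonical sequences (28/48 at 19%; 63/39 at 43%). Users with the canonical
records should substitute their own FASTA; every function takes arbitrary
records. The demo interactor set (`data/demo_interactors_synthetic.fasta`)
is fully synthetic (seeded random sequences with implanted LIR cores) and
exists only to exercise the scan-and-tabulate machinery.

## Numerical and interface conventions

Coordinates are 0-based row-major; masks are half-open pixel sets; LIR
positions are reported 1-based inclusive in output files. CSV is comma,
UTF-8, header row, `.` decimal. TIFFs are multi-page, uncompressed,
unsigned 16-bit, channel order dapi → marker → p62 with the channel name
in the page description. Every CLI run writes a `provenance.json` (config,
seed, package version) beside its outputs. All stochastic code paths take
explicit seeds; identical config + seed reproduces output bit-for-bit.

## Known limitations

* The simulator's truth depends on its own geometry model; estimator bias
  under real optics (PSF, z-projection) is not measured.
* Per-cell thresholds assume ≥ some dozens of cytosolic pixels; very small
  cells degrade the MAD estimate.
* The NJ implementation is O(n³)–O(n⁴) and intended for tens of taxa, not
  thousands.
* Two-way ANOVA assumes homoscedastic Gaussian residuals; only the
  contrasts use Welch corrections.
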