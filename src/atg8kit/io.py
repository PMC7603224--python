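"""File formats: TIFF fields and labels, CSV tables, FASTA/MSA, Newick, INI.

One fixed CSV dialect (comma, UTF-8, header, '.' decimal) and uncompressed
multi-page 16-bit TIFF keep round trips exact.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import AlignIO, SeqIO

from . import __version__
from .segment import CellSegmentation
from .sequence import Msa, ProteinRecord
from .simulate import GroundTruthRecord, ImageField, SimulationConfig

__all__ = [
    "write_field_tiff", "read_field_tiff",
    "write_ground_truth", "read_ground_truth_csv",
    "write_labels", "read_labels",
    "read_grouped_fasta", "read_msa",
    "write_newick", "read_config", "write_provenance",
    "write_csv", "read_csv",
]


def write_field_tiff(path, field: ImageField) -> None:
    """Multi-page uint16 TIFF, page order dapi -> marker -> p62, channel in tag."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for name in ImageField.CHANNEL_ORDER:
            page = np.clip(np.round(field.channels[name]), 0, 65535).astype(np.uint16)
            tw.write(page, description=name, compression=None)


def read_field_tiff(path, channel_order=None) -> ImageField:
    """Read a 3-page TIFF; channel names from page tags unless overridden."""
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 3:
            raise ValueError(f"{path}: expected 3 pages, found {len(tf.pages)}")
        for i, page in enumerate(tf.pages):
            if channel_order is not None:
                name = channel_order[i]
            else:
                name = (page.description or "").strip()
            if name not in ImageField.CHANNEL_ORDER:
                raise ValueError(
                    f"{path}: page {i} has unknown channel {name!r}; "
                    "pass channel_order=('dapi','marker','p62')")
            channels[name] = page.asarray().astype(float)
    return ImageField(channels)


def write_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, encoding="utf-8")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_labels(path, labels: np.ndarray) -> None:
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels do not fit uint16")
    tifffile.imwrite(path, labels.astype(np.uint16), compression=None)


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_ground_truth(outdir, records: list[GroundTruthRecord]) -> None:
    """truth.csv plus labeled cell/nucleus TIFFs reconstructed from masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"cell_id": r.cell_id, "nf_true": r.nf_true, "coloc_true": r.coloc_true}
            for r in records]
    write_csv(outdir / "truth.csv", pd.DataFrame(rows, columns=["cell_id", "nf_true", "coloc_true"]))
    if records:
        shape = records[0].cell_mask.shape
        cells = np.zeros(shape, dtype=np.uint16)
        nuclei = np.zeros(shape, dtype=np.uint16)
        for r in records:
            cells[r.cell_mask] = r.cell_id
            nuclei[r.nucleus_mask] = r.cell_id
        write_labels(outdir / "cell_labels.tif", cells)
        write_labels(outdir / "nucleus_labels.tif", nuclei)


def read_ground_truth_csv(path) -> pd.DataFrame:
    return read_csv(path)


def write_segmentation(outdir, seg: CellSegmentation) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_labels(outdir / "cell_labels.tif", seg.cell_labels)
    write_labels(outdir / "nucleus_labels.tif", seg.nucleus_labels)
    write_labels(outdir / "punctum_mask.tif", seg.punctum_mask.astype(np.uint16))
    rows = [{"cell_id": cid,
             "cell_area": int((seg.cell_labels == cid).sum()),
             "nucleus_area": int((seg.nucleus_labels == cid).sum())}
            for cid in seg.cell_ids]
    write_csv(outdir / "areas.csv",
              pd.DataFrame(rows, columns=["cell_id", "cell_area", "nucleus_area"]))


def read_grouped_fasta(path) -> list[ProteinRecord]:
    """FASTA with an optional ``group=<ATG8>`` tag on the description line."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        group = None
        for token in rec.description.split():
            if token.startswith("group="):
                group = token.split("=", 1)[1]
        try:
            records.append(ProteinRecord(rec.id, seq, group))
        except ValueError as e:
            raise ValueError(f"{path}: record {rec.id!r}: {e}") from e
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_msa(path) -> Msa:
    """Aligned FASTA or Clustal ``.aln`` (chosen by extension)."""
    path = Path(path)
    fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def align_with_mafft(records, *, accurate: bool = True) -> Msa:
    """Align protein records with an external ``mafft`` (must be on PATH).

    Uses the G-INS-i strategy (global pairwise + iterative refinement) by
    default, appropriate for small sets of globally alignable proteins.
    """
    import subprocess
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
        tmp = fh.name
    args = ["mafft"] + (["--globalpair", "--maxiterate", "1000"] if accurate else ["--auto"]) + [tmp]
    try:
        proc = subprocess.run(args, capture_output=True, text=True, check=True)
    except FileNotFoundError as e:
        raise RuntimeError("mafft not found on PATH") from e
    except subprocess.CalledProcessError as e:
        raise RuntimeError(f"mafft failed: {e.stderr[-500:]}") from e
    finally:
        Path(tmp).unlink(missing_ok=True)
    import io as _io
    aln = AlignIO.read(_io.StringIO(proc.stdout), "fasta")
    return Msa([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def write_newick(path, tree) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_config(path) -> SimulationConfig:
    """INI-style or flat ``key=value`` simulation config."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.lstrip().startswith("["):
        text = "[simulation]\n" + text
    parser = configparser.ConfigParser()
    parser.read_string(text)
    section = parser[parser.sections()[0]]
    kwargs: dict = {}
    for key, raw in section.items():
        if key in ("field_size", "cell_radius_range"):
            parts = [p for p in raw.replace(",", " ").split() if p]
            conv = int if key == "field_size" else float
            kwargs[key] = tuple(conv(p) for p in parts)
        elif key in ("n_cells", "puncta_per_cell", "seed"):
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    return SimulationConfig(**kwargs)


def write_provenance(outdir, config, seed: int) -> None:
    """Drop a provenance record (config + seed + version) beside outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "atg8kit",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if hasattr(config, "to_dict") else config,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8")
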