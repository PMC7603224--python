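"""Per-cell localization metrics and treatment-level aggregation.

Two intensity-weighted statistics per cell:

* nuclear fraction  NF = sum(marker - bg)+ over nucleus / over whole cell
* p62 co-localization = sum(marker - bg)+ over (cytosol & puncta)
                        / over cytosol   (a Manders-type coefficient)

Both are scale-invariant in the marker channel once the background is
removed.  Aggregation follows the replicate structure of the imaging
experiments: cells are averaged within an image, images within a treatment
(mean +/- SD over image means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import CellSegmentation, border_cell_ids

log = logging.getLogger(__name__)

__all__ = [
    "LocalizationResult",
    "TreatmentSummary",
    "nuclear_fraction",
    "coloc_with_p62",
    "quantify_cells",
    "summarize",
]


@dataclass
class LocalizationResult:
    cell_id: int
    nuclear_fraction: float  # NaN when the whole-cell sum is zero
    coloc_fraction: float    # NaN when the cytosolic sum is zero
    total_marker_intensity: float
    flags: list[str] = field(default_factory=list)


@dataclass
class TreatmentSummary:
    treatment: str
    metric: str
    image_means: dict[str, float]
    mean: float
    sd: float
    n_images: int


def _bg_subtract(marker: np.ndarray, background: float) -> np.ndarray:
    if background < 0:
        raise ValueError("background must be >= 0")
    return np.clip(np.asarray(marker, dtype=float) - background, 0.0, None)


def nuclear_fraction(marker, nucleus_mask, cell_mask, background: float = 0.0) -> float:
    """Share of background-subtracted marker intensity inside the nucleus.

    Returns NaN (undefined) when the whole-cell sum is zero.
    """
    marker = np.asarray(marker)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if marker.shape != nucleus_mask.shape or marker.shape != cell_mask.shape:
        raise ValueError("mask shape mismatch")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask extends outside the cell mask")
    sub = _bg_subtract(marker, background)
    den = sub[cell_mask].sum()
    if den <= 0:
        return float("nan")
    return float(sub[nucleus_mask].sum() / den)


def coloc_with_p62(marker, cytosol_mask, punctum_mask, background: float = 0.0) -> float:
    """Fraction of cytosolic marker intensity inside the p62 punctum mask.

    NaN (undefined) when the cytosolic sum is zero.
    """
    marker = np.asarray(marker)
    cytosol_mask = np.asarray(cytosol_mask, dtype=bool)
    punctum_mask = np.asarray(punctum_mask, dtype=bool)
    if marker.shape != cytosol_mask.shape or marker.shape != punctum_mask.shape:
        raise ValueError("mask shape mismatch")
    if np.any(punctum_mask & ~cytosol_mask):
        raise ValueError("punctum mask extends outside the cytosol")
    sub = _bg_subtract(marker, background)
    den = sub[cytosol_mask].sum()
    if den <= 0:
        return float("nan")
    return float(sub[cytosol_mask & punctum_mask].sum() / den)


def quantify_cells(channels: dict[str, np.ndarray], seg: CellSegmentation,
                   *, exclude_border: bool = True) -> list[LocalizationResult]:
    """Measure NF and p62 co-localization for every segmented cell.

    Cells touching the field border are flagged 'border' and skipped from
    the metrics (their truncated cytosol would bias NF); cells with a zero
    denominator are flagged 'undefined_nf' / 'undefined_coloc'.
    """
    marker = np.asarray(channels["marker"], dtype=float)
    bg = seg.background_estimate.get("marker", 0.0)
    border = border_cell_ids(seg.cell_labels) if exclude_border else set()
    results = []
    for cid in seg.cell_ids:
        cell = seg.cell_labels == cid
        nucleus = seg.nucleus_labels == cid
        flags: list[str] = []
        sub = _bg_subtract(marker, bg)
        total = float(sub[cell].sum())
        if cid in border:
            results.append(LocalizationResult(cid, float("nan"), float("nan"), total, ["border"]))
            continue
        nf = nuclear_fraction(marker, nucleus, cell, bg)
        if np.isnan(nf):
            flags.append("undefined_nf")
        cytosol = cell & ~nucleus
        coloc = coloc_with_p62(marker, cytosol, seg.punctum_mask & cytosol, bg)
        if np.isnan(coloc):
            flags.append("undefined_coloc")
        results.append(LocalizationResult(cid, nf, coloc, total, flags))
    return results


def results_frame(per_image: dict[str, list[LocalizationResult]]) -> pd.DataFrame:
    """Stack per-image result lists into one tidy DataFrame."""
    rows = []
    for image, results in per_image.items():
        for r in results:
            rows.append({
                "image": image, "cell_id": r.cell_id,
                "nuclear_fraction": r.nuclear_fraction,
                "coloc_fraction": r.coloc_fraction,
                "total_marker_intensity": r.total_marker_intensity,
                "flags": ";".join(r.flags),
            })
    return pd.DataFrame(rows)


def summarize(frame: pd.DataFrame, grouping: dict[str, str],
              metric: str = "nuclear_fraction") -> list[TreatmentSummary]:
    """Aggregate per-cell values to image means, then treatment mean +/- SD.

    ``grouping`` maps image id -> treatment label.  The image is the
    replicate unit, so the SD is over image means (sample SD; 0 for a single
    image).  Cells with undefined values are dropped with a logged count.
    """
    missing = set(frame["image"]) - set(grouping)
    if missing:
        raise ValueError(f"images without treatment assignment: {sorted(missing)}")
    out = []
    frame = frame.copy()
    frame["treatment"] = frame["image"].map(grouping)
    for treatment, tdf in frame.groupby("treatment", sort=True):
        image_means: dict[str, float] = {}
        for image, idf in tdf.groupby("image", sort=True):
            vals = idf[metric].dropna()
            n_drop = len(idf) - len(vals)
            if n_drop:
                log.info("%s/%s: dropped %d undefined cells for %s",
                         treatment, image, n_drop, metric)
            if len(vals) == 0:
                continue
            image_means[str(image)] = float(vals.mean())
        if not image_means:
            raise ValueError(f"empty group: no defined {metric} values for {treatment!r}")
        means = np.array(list(image_means.values()))
        sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
        out.append(TreatmentSummary(str(treatment), metric, image_means,
                                    float(means.mean()), sd, len(means)))
    return out
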