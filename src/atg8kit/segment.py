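"""Nucleus / cell / cytosol / p62-punctum segmentation.

Nuclei come from the DAPI channel (Gaussian smoothing, global Otsu, hole
filling, small-object removal); cells from a nucleus-seeded watershed over
the thresholded cell-body mask; p62 puncta from a white top-hat with a
robust per-cell threshold, restricted to the cytosol.  All steps are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg

log = logging.getLogger(__name__)

__all__ = [
    "CellSegmentation",
    "segment_nuclei",
    "segment_cells",
    "segment_puncta",
    "segment_field",
    "border_cell_ids",
]

NUCLEUS_SMOOTH_SIGMA = 2.0
MIN_NUCLEUS_AREA = 200
PUNCTUM_MAD_K = 5.0


@dataclass
class CellSegmentation:
    """Label rasters plus per-channel background estimates.

    Labels are positive integers contiguous from 1; nucleus label *l* lies
    inside cell label *l*.  ``background_estimate[ch]`` is the median
    intensity outside all cell masks.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    punctum_mask: np.ndarray
    bounding_boxes: dict[int, tuple[int, int, int, int]]
    background_estimate: dict[str, float]

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.bounding_boxes)

    def cytosol_mask(self, cell_id: int) -> np.ndarray:
        return (self.cell_labels == cell_id) & (self.nucleus_labels != cell_id)


def _smooth(raster: np.ndarray, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(np.asarray(raster, dtype=float), sigma)


def segment_nuclei(dapi: np.ndarray, *, sigma: float = NUCLEUS_SMOOTH_SIGMA,
                   min_area: int = MIN_NUCLEUS_AREA) -> np.ndarray:
    """Label nuclei in a DAPI raster; blank rasters yield zero labels."""
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("dapi must be a 2D raster")
    if np.any(dapi < 0):
        raise ValueError("dapi must be non-negative")
    sm = _smooth(dapi, sigma)
    if sm.max() == sm.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    mask = sm > filters.threshold_otsu(sm)
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    labels, _ = ndi.label(mask)
    return labels.astype(np.int32)


def _body_mask(sm: np.ndarray, nucleus_mask: np.ndarray | None = None, *,
               spot_flatten_radius: int = 4) -> np.ndarray:
    """Cell-body mask of a smoothed intensity image.

    The threshold is set halfway between the background level and the
    cytosolic plateau so the mask contour lands on the true edge of the
    smoothed intensity step regardless of absolute levels.  The plateau is
    read from a ring a few pixels inside a provisional body on a grey-opened
    copy (which flattens punctum spots); pixels near nuclei are excluded
    from the ring because nuclear signal, bright or void, says nothing
    about the cytosolic plateau.
    """
    if sm.max() == sm.min():
        return np.zeros(sm.shape, dtype=bool)
    near_nucleus = (ndi.binary_dilation(nucleus_mask, iterations=8)
                    if nucleus_mask is not None and nucleus_mask.any() else
                    np.zeros(sm.shape, dtype=bool))
    # provisional mask: anything above background (median + 3 robust SD);
    # background dominates the field, so the median is a background statistic
    bg0 = np.median(sm)
    sigma0 = 1.4826 * np.median(np.abs(sm - bg0))
    body = sm > bg0 + 3.0 * sigma0 + 1e-9 * (sm.max() - bg0)
    k = 2 * spot_flatten_radius + 1
    opened = ndi.grey_opening(sm, footprint=np.ones((k, k)))
    # iterate the half-height refinement: the plateau is read from a ring a
    # few pixels inside the current body, so a poor starting mask converges
    # onto the true edge within a couple of rounds
    for _ in range(3):
        ring = (ndi.binary_erosion(body, iterations=4)
                & ~ndi.binary_erosion(body, iterations=8)
                & ~near_nucleus)
        outside = ~ndi.binary_dilation(body, iterations=3)
        if not ring.any() or not outside.any():
            break
        plateau = np.median(opened[ring])
        background = np.median(opened[outside])
        if plateau <= background:
            break
        body = sm > 0.5 * (plateau + background)
    return body


def segment_cells(marker: np.ndarray, nucleus_labels: np.ndarray,
                  p62: np.ndarray | None = None, *,
                  sigma: float = NUCLEUS_SMOOTH_SIGMA) -> np.ndarray:
    """Seeded watershed giving one cell region per nucleus.

    The cell-body mask is a half-height threshold of the smoothed marker
    channel (summed with p62 when available — the cytosolic p62 pool
    outlines cells even when the marker is mostly nuclear); see
    :func:`_body_mask`.  Each cell contains its
    nucleus; a nucleus with no surrounding body collapses to cell == nucleus
    and is logged.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape != nucleus_labels.shape:
        raise ValueError("marker and nucleus_labels shapes differ")
    if nucleus_labels.max() == 0:
        return np.zeros_like(nucleus_labels, dtype=np.int32)
    body_signal = marker if p62 is None else marker + np.asarray(p62, dtype=float)
    sm = _smooth(body_signal, sigma)
    body = _body_mask(sm, nucleus_labels > 0)
    body |= nucleus_labels > 0
    cells = skseg.watershed(-sm, markers=nucleus_labels, mask=body)
    for lbl in np.unique(nucleus_labels):
        if lbl == 0:
            continue
        nuc = nucleus_labels == lbl
        if (cells[nuc] != lbl).any():
            cells[nuc] = lbl  # nucleus always belongs to its own cell
        if int((cells == lbl).sum()) <= int(nuc.sum()):
            log.warning("cell %d has no cytosolic body; cell == nucleus", lbl)
    return cells.astype(np.int32)


def segment_puncta(p62: np.ndarray, cell_labels: np.ndarray,
                   nucleus_labels: np.ndarray, *,
                   punctum_radius: float = 3.0,
                   k: float = PUNCTUM_MAD_K) -> np.ndarray:
    """Boolean mask of cytosolic p62 spots.

    White top-hat (disc radius = 2x the expected punctum radius) followed by
    a per-cell threshold at median + k*MAD of the cytosolic top-hat values;
    the mask is restricted to each cell's cytosol.
    """
    p62 = np.asarray(p62, dtype=float)
    if p62.shape != cell_labels.shape or p62.shape != nucleus_labels.shape:
        raise ValueError("raster and label shapes differ")
    tophat = morphology.white_tophat(p62, footprint=morphology.disk(int(round(2 * punctum_radius))))
    out = np.zeros(p62.shape, dtype=bool)
    for lbl in np.unique(cell_labels):
        if lbl == 0:
            continue
        cyt = (cell_labels == lbl) & (nucleus_labels != lbl)
        vals = tophat[cyt]
        if vals.size == 0:
            continue
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        out |= cyt & (tophat > med + k * mad)
    return out


def _relabel_matched(cells: np.ndarray, nuclei: np.ndarray):
    """Renumber so cell i and its nucleus share label i, contiguous from 1."""
    new_cells = np.zeros_like(cells, dtype=np.int32)
    new_nuclei = np.zeros_like(cells, dtype=np.int32)
    boxes: dict[int, tuple[int, int, int, int]] = {}
    nxt = 0
    for lbl in np.unique(cells):
        if lbl == 0:
            continue
        nxt += 1
        m = cells == lbl
        new_cells[m] = nxt
        new_nuclei[m & (nuclei == lbl)] = nxt
        ys, xs = np.nonzero(m)
        boxes[nxt] = (int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    return new_cells, new_nuclei, boxes


def segment_field(channels: dict[str, np.ndarray], *,
                  punctum_radius: float = 3.0) -> CellSegmentation:
    """Full segmentation of a dapi/marker/p62 channel dictionary."""
    nuclei = segment_nuclei(channels["dapi"])
    cells = segment_cells(channels["marker"], nuclei, channels.get("p62"))
    cells, nuclei, boxes = _relabel_matched(cells, nuclei)
    if "p62" in channels:
        puncta = segment_puncta(channels["p62"], cells, nuclei,
                                punctum_radius=punctum_radius)
    else:
        puncta = np.zeros(cells.shape, dtype=bool)
    outside = cells == 0
    background = {
        name: float(np.median(np.asarray(ch, dtype=float)[outside])) if outside.any() else 0.0
        for name, ch in channels.items()
    }
    return CellSegmentation(cells, nuclei, puncta, boxes, background)


def border_cell_ids(cell_labels: np.ndarray) -> set[int]:
    """Labels of cells touching the field border (excluded from metrics)."""
    edge = np.concatenate([
        cell_labels[0, :], cell_labels[-1, :], cell_labels[:, 0], cell_labels[:, -1]
    ])
    return set(int(v) for v in np.unique(edge) if v != 0)
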