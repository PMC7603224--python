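"""Synthetic multi-channel fluorescence fields with exact per-cell ground truth.

Generates DAPI / marker (an LC3) / p62 rasters for populations of
non-overlapping elliptical cells.  Each cell carries two exact truths solved
analytically from pixel sums on the noiseless render:

* ``nf_true`` — the nuclear fraction of the marker's total intensity, and
* ``coloc_true`` — the fraction of the *cytosolic* marker intensity that
  falls inside the p62 punctum mask (a Manders-type quantity).

The marker channel is piecewise constructed per cell: a uniform nuclear
level, a uniform cytosolic level outside puncta, and Gaussian spot profiles
inside a random subset of the p62 puncta, with the three amplitudes solved
so the recorded truths are met exactly (to float rounding) on the noiseless
image.  Shot + read noise is applied separately by :func:`add_noise` and
never alters masks or truth values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SimulationConfig",
    "ImageField",
    "GroundTruthRecord",
    "PlacementError",
    "simulate_field",
    "add_noise",
]

# Noiseless intensity levels (arbitrary densitometric counts, well below the
# 16-bit ceiling even after noise).  They set SNR jointly with the noise
# parameters of SimulationConfig but are not themselves part of the truth
# definitions, which are ratios.
DAPI_LEVEL = 900.0
CYTO_MARKER_MEAN = 300.0
P62_BASE = 60.0
P62_SPOT_AMP = 700.0

#: Fraction of a cell's puncta that receive a co-localized marker spot.
MARKER_SPOT_FRACTION = 0.7

MAX_PLACEMENT_ATTEMPTS = 1000
U16_MAX = 65535.0


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all cells or puncta."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated field.

    ``nf_true`` and ``coloc_true`` are the target nuclear fraction and
    cytosolic p62 co-localization fraction of the marker channel; every
    simulated cell meets them exactly on the noiseless render.
    """

    field_size: tuple[int, int] = (512, 512)
    n_cells: int = 20
    cell_radius_range: tuple[float, float] = (22.0, 32.0)
    nucleus_to_cell_area_ratio: float = 0.25
    nf_true: float = 0.35
    coloc_true: float = 0.60
    puncta_per_cell: int = 8
    puncta_radius: float = 3.0
    background_level: float = 20.0
    gaussian_sigma: float = 4.0
    poisson_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size
        if h <= 0 or w <= 0:
            raise ValueError("field_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if not (0.0 < self.nucleus_to_cell_area_ratio < 1.0):
            raise ValueError("nucleus_to_cell_area_ratio must be in (0, 1)")
        for name in ("nf_true", "coloc_true"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.puncta_per_cell < 0:
            raise ValueError("puncta_per_cell must be >= 0")
        if self.puncta_radius <= 0:
            raise ValueError("puncta_radius must be > 0")
        if self.background_level < 0 or self.gaussian_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.coloc_true > 0 and self.puncta_per_cell == 0:
            raise ValueError("coloc_true > 0 requires puncta_per_cell >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_size"] = list(self.field_size)
        d["cell_radius_range"] = list(self.cell_radius_range)
        return d


@dataclass
class ImageField:
    """Registered multi-channel 2D raster (keys: dapi, marker, p62)."""

    channels: dict[str, np.ndarray]

    CHANNEL_ORDER = ("dapi", "marker", "p62")

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruthRecord:
    """Exact per-cell truth for one simulated cell."""

    cell_id: int
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    nf_true: float
    coloc_true: float  # NaN when the cell has no cytosolic marker signal
    punctum_centers: np.ndarray  # (k, 2) row/col coordinates
    punctum_mask: np.ndarray


def _ellipse_mask(shape, center, semi_axes, theta) -> np.ndarray:
    """Boolean raster of a rotated ellipse; pixel centers, half-open grid."""
    h, w = shape
    cy, cx = center
    a, b = semi_axes
    r = int(math.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses fully inside the field."""
    h, w = cfg.field_size
    placed = []  # (cy, cx, a, b, theta) with a = major semi-axis
    for i in range(cfg.n_cells):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            a = rng.uniform(*cfg.cell_radius_range)
            q = rng.uniform(0.6, 1.0)
            b = a * q
            theta = rng.uniform(0.0, math.pi)
            cy = rng.uniform(a + 1, h - a - 1) if h > 2 * a + 2 else None
            cx = rng.uniform(a + 1, w - a - 1) if w > 2 * a + 2 else None
            if cy is None or cx is None:
                raise PlacementError("field too small for configured cell radii")
            # conservative disjointness via bounding circles
            ok = all(
                math.hypot(cy - py, cx - px) > a + pa + 1.0
                for (py, px, pa, _, _) in placed
            )
            if ok:
                placed.append((cy, cx, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{cfg.n_cells} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts; field too crowded"
            )
    return placed


def _place_puncta(cytosol: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator):
    """Sample punctum centers so each disc fits in the cytosol minus a 1-px rim."""
    if cfg.puncta_per_cell == 0:
        return np.empty((0, 2), dtype=float), np.zeros_like(cytosol)
    dist = ndi.distance_transform_edt(cytosol)
    allowed = np.argwhere(dist > cfg.puncta_radius + 1.0)
    if len(allowed) < cfg.puncta_per_cell:
        raise PlacementError("cytosol too small for configured puncta")
    idx = rng.choice(len(allowed), size=cfg.puncta_per_cell, replace=False)
    centers = allowed[np.sort(idx)].astype(float)
    h, w = cytosol.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pmask = np.zeros_like(cytosol)
    for cy, cx in centers:
        pmask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.puncta_radius**2
    pmask &= cytosol
    return centers, pmask


def _spot_profile(shape, centers, sigma) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape, dtype=float)
    r = int(math.ceil(4 * sigma)) + 1
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] += np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    return out


def simulate_field(cfg: SimulationConfig):
    """Render one noiseless field and its exact ground truth.

    Returns ``(ImageField, [GroundTruthRecord])``.  Identical config (which
    includes the seed) gives bit-identical output.  Apply :func:`add_noise`
    for the shot + read noise model.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.field_size
    dapi = np.zeros(shape, dtype=float)
    marker = np.zeros(shape, dtype=float)
    p62 = np.zeros(shape, dtype=float)
    records: list[GroundTruthRecord] = []

    spot_sigma = cfg.puncta_radius / 2.0
    for cell_id, (cy, cx, a, b, theta) in enumerate(_place_cells(cfg, rng), start=1):
        cell = _ellipse_mask(shape, (cy, cx), (a, b), theta)
        s = math.sqrt(cfg.nucleus_to_cell_area_ratio)
        nucleus = _ellipse_mask(shape, (cy, cx), (a * s, b * s), theta)
        nucleus &= cell
        cytosol = cell & ~nucleus
        centers, pmask = _place_puncta(cytosol, cfg, rng)

        n_nuc = int(nucleus.sum())
        n_cyt = int(cytosol.sum())
        n_pun = int(pmask.sum())
        if n_nuc == 0 or n_cyt == 0:
            raise PlacementError("degenerate cell geometry (empty nucleus or cytosol)")

        # p62: uniform cytosolic pool + bright spots at every punctum
        p62[cytosol] += P62_BASE
        if len(centers):
            spots = _spot_profile(shape, centers, spot_sigma)
            p62[cytosol] += P62_SPOT_AMP * spots[cytosol]

        # marker: solve the three amplitudes for exact truths.
        # Draw the spot-subset randomness unconditionally so the rng stream
        # (hence geometry) is invariant under changes of nf/coloc targets.
        subset_draw = rng.random(len(centers))
        nf, c = cfg.nf_true, cfg.coloc_true
        if nf >= 1.0:
            marker[nucleus] += CYTO_MARKER_MEAN
            t_cyt = 0.0
        else:
            t_cyt = CYTO_MARKER_MEAN * n_cyt  # total cytosolic marker
            # outside-puncta uniform level
            if n_cyt > n_pun:
                marker[cytosol & ~pmask] += (1.0 - c) * t_cyt / (n_cyt - n_pun)
            # inside-puncta spot profile scaled to c * t_cyt
            if c > 0.0:
                chosen = centers[subset_draw < MARKER_SPOT_FRACTION]
                if len(chosen) == 0:
                    chosen = centers[:1]
                prof = _spot_profile(shape, chosen, spot_sigma)
                s0 = prof[pmask].sum()
                inpun = np.zeros(shape)
                inpun[pmask] = c * t_cyt * prof[pmask] / s0
                marker += inpun
            if nf > 0.0:
                marker[nucleus] += nf / (1.0 - nf) * t_cyt / n_nuc

        # record truths from pixel sums over the true masks
        cell_sum = marker[cell].sum()
        nf_rec = marker[nucleus].sum() / cell_sum if cell_sum > 0 else float("nan")
        cyt_sum = marker[cytosol].sum()
        coloc_rec = marker[pmask].sum() / cyt_sum if cyt_sum > 0 else float("nan")
        records.append(
            GroundTruthRecord(
                cell_id=cell_id,
                nucleus_mask=nucleus,
                cell_mask=cell,
                nf_true=float(nf_rec),
                coloc_true=float(coloc_rec),
                punctum_centers=centers,
                punctum_mask=pmask,
            )
        )

        dapi[nucleus] += DAPI_LEVEL

    field = ImageField({"dapi": dapi, "marker": marker, "p62": p62})
    return field, records


def add_noise(field: ImageField, cfg: SimulationConfig) -> ImageField:
    """Apply background + Poisson shot noise + Gaussian read noise.

    Pixel expectation is ``noiseless + background_level``.  ``poisson_scale``
    is the photon count per intensity unit (0 disables shot noise);
    ``gaussian_sigma`` is the read-noise SD in intensity units.  Output is
    clamped to the unsigned 16-bit range.  Deterministic for a fixed config
    seed, with a stream independent of the renderer's.
    """
    if cfg.poisson_scale < 0 or cfg.gaussian_sigma < 0 or cfg.background_level < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng([cfg.seed, 7919])
    out = {}
    for name in ImageField.CHANNEL_ORDER:
        x = field.channels[name] + cfg.background_level
        if cfg.poisson_scale > 0:
            x = rng.poisson(x * cfg.poisson_scale).astype(float) / cfg.poisson_scale
        if cfg.gaussian_sigma > 0:
            x = x + rng.normal(0.0, cfg.gaussian_sigma, size=x.shape)
        out[name] = np.clip(x, 0.0, U16_MAX)
    return ImageField(out)
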