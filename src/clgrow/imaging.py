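"""Top-view canopy image analysis: segmentation, per-plant area, coverage.

Mirrors the daily imaging stage of a plant-phenotyping experiment: an RGB
top-view image of a lettuce tray is segmented into plant/background with
the excess-green index (ExG = 2G - R - B) and an Otsu or fixed threshold;
connected plant regions are assigned to the nearest plant centre of the
known chessboard layout to give per-plant projected leaf area (PLA, cm2);
the plant-pixel fraction of the whole frame is the floor coverage.

Per-plant PLA is only meaningful while neighbouring plants do not touch
(the no-overlap window, roughly 2-13 days after transplant in the emulated
study); once a connected region spans two layout centres an
:class:`OverlapError` is raised instead of silently splitting it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "CanopyImage",
    "CanopyMask",
    "PlantLayout",
    "PlantArea",
    "OverlapError",
    "segment_canopy",
    "per_plant_pla",
    "floor_coverage_series",
    "chessboard_layout",
]


class OverlapError(RuntimeError):
    """Two layout centres claim one connected region (canopy closure)."""


@dataclass(frozen=True)
class CanopyImage:
    """An RGB top-view raster with spatial calibration and time stamp.

    ``pixels`` is an (H, W, 3) uint8/float array; ``cm_per_px`` the edge
    length of one pixel in cm; ``dat`` days after transplant; ``phase``
    the within-day imaging phase (start/midpoint/end of photoperiod).
    """

    pixels: np.ndarray
    cm_per_px: float
    dat: float = 0.0
    phase: str = "midpoint"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) RGB raster")
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be > 0")


@dataclass(frozen=True)
class CanopyMask:
    """Binary plant mask aligned to a :class:`CanopyImage`."""

    mask: np.ndarray
    cm_per_px: float
    dat: float = 0.0
    phase: str = "midpoint"
    threshold: float = float("nan")

    @property
    def coverage_fraction(self) -> float:
        """Plant pixels over total pixels, in [0, 1]."""
        return float(np.count_nonzero(self.mask)) / self.mask.size


@dataclass(frozen=True)
class PlantLayout:
    """Plant-centre positions (cm) of a chessboard planting pattern."""

    centres: tuple[tuple[float, float], ...]
    within_row_spacing: float = 15.6
    row_spacing: float = 11.5
    density: float = 56.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if len(set(self.centres)) != len(self.centres):
            raise ValueError("layout centres must be pairwise distinct")


def chessboard_layout(
    n_rows: int,
    n_cols: int,
    within_row_spacing: float = 15.6,
    row_spacing: float = 11.5,
    density: float = 56.0,
    margin: float | None = None,
) -> PlantLayout:
    """Build a chessboard layout: alternate rows offset by half a spacing.

    Centres are (x, y) in cm with the first row at ``y = margin`` (default
    half the row spacing) and the first column at ``x = margin``.
    """
    if margin is None:
        margin = within_row_spacing / 2.0
    centres = []
    for r in range(n_rows):
        off = (within_row_spacing / 2.0) if r % 2 else 0.0
        for c in range(n_cols):
            centres.append((margin + off + c * within_row_spacing,
                            margin + r * row_spacing))
    return PlantLayout(tuple(centres), within_row_spacing, row_spacing, density)


def excess_green(image: CanopyImage) -> np.ndarray:
    """Excess-green index ExG = 2G - R - B as a float array."""
    px = np.asarray(image.pixels, dtype=float)
    return 2.0 * px[..., 1] - px[..., 0] - px[..., 2]


def segment_canopy(image: CanopyImage, threshold_mode: str = "otsu",
                   fixed_threshold: float = 0.0) -> CanopyMask:
    """Segment plant pixels by thresholding the excess-green index.

    ``threshold_mode='otsu'`` picks the threshold from the ExG histogram;
    on a degenerate single-intensity image it falls back to a fixed
    threshold of 0 with a logged warning.  ``threshold_mode='fixed'`` uses
    ``fixed_threshold`` directly.  Pixels with ExG strictly above the
    threshold are plant.
    """
    exg = excess_green(image)
    if threshold_mode == "otsu":
        if np.ptp(exg) == 0:
            msg = "degenerate single-intensity image: falling back to fixed threshold 0"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            thr = 0.0
        else:
            thr = float(threshold_otsu(exg))
    elif threshold_mode == "fixed":
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    logger.info("segment_canopy: mode=%s threshold=%.3f", threshold_mode, thr)
    return CanopyMask(mask=exg > thr, cm_per_px=image.cm_per_px,
                      dat=image.dat, phase=image.phase, threshold=thr)


@dataclass(frozen=True)
class PlantArea:
    """Projected leaf area of one plant in one mask."""

    plant_id: int
    pla_cm2: float
    touches_border: bool = False


def per_plant_pla(mask: CanopyMask, layout: PlantLayout,
                  cm_per_px: float | None = None) -> list[PlantArea]:
    """Assign connected mask regions to layout centres and measure PLA.

    Each connected component is assigned to the nearest layout centre by
    centroid distance (ties broken by lower plant id).  PLA is the
    component pixel count times ``cm_per_px**2``.  Components touching the
    image border are flagged.  If two components claim the same centre the
    canopy has closed and per-plant PLA is no longer defined:
    :class:`OverlapError`.
    """
    if cm_per_px is None:
        cm_per_px = mask.cm_per_px
    lab = label(mask.mask, connectivity=2)
    regions = regionprops(lab)
    if not regions:
        return []
    centres = np.asarray(layout.centres, dtype=float)  # (x, y) cm
    h, w = mask.mask.shape

    # closure check: a connected region containing two layout centres means
    # neighbouring plants have merged and per-plant PLA is no longer defined
    claimed: dict[int, int] = {}
    for pid, (cx, cy) in enumerate(centres):
        r = int(np.clip(round(cy / cm_per_px), 0, h - 1))
        c = int(np.clip(round(cx / cm_per_px), 0, w - 1))
        comp = int(lab[r, c])
        if comp == 0:
            continue
        if comp in claimed:
            raise OverlapError(
                f"plants {claimed[comp]} and {pid} share one connected region "
                "(post-closure regime; per-plant PLA invalid)"
            )
        claimed[comp] = pid

    # each component goes to the nearest centre by centroid distance (ties
    # to the lower plant id); fragments of one plant accumulate
    area_px: dict[int, float] = {}
    border_flag: dict[int, bool] = {}
    for reg in regions:
        cy, cx = reg.centroid  # row, col in px
        d = np.hypot(centres[:, 0] - cx * cm_per_px,
                     centres[:, 1] - cy * cm_per_px)
        pid = int(np.argmin(d))  # argmin takes the lowest index on ties
        rmin, cmin, rmax, cmax = reg.bbox
        border = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        area_px[pid] = area_px.get(pid, 0.0) + float(reg.area)
        border_flag[pid] = border_flag.get(pid, False) or border
    return [
        PlantArea(plant_id=pid, pla_cm2=area_px[pid] * cm_per_px ** 2,
                  touches_border=border_flag[pid])
        for pid in sorted(area_px)
    ]


def floor_coverage_series(
    masks: list[CanopyMask], aggregate: str | None = None
) -> list[tuple[float, float]]:
    """Coverage percentage per DAT, sorted by DAT.

    Duplicate DAT entries are an error unless ``aggregate='mean'`` is
    requested explicitly (e.g. to average the within-day imaging phases).
    """
    if not masks:
        raise ValueError("at least one mask required")
    dats = [m.dat for m in masks]
    if len(set(dats)) != len(dats):
        if aggregate != "mean":
            raise ValueError(
                "duplicate DAT entries; pass aggregate='mean' to average them"
            )
        by_dat: dict[float, list[float]] = {}
        for m in masks:
            by_dat.setdefault(m.dat, []).append(m.coverage_fraction * 100.0)
        return sorted((d, float(np.mean(v))) for d, v in by_dat.items())
    return sorted((m.dat, m.coverage_fraction * 100.0) for m in masks)
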