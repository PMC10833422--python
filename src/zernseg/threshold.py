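"""Conventional gray-value threshold segmentation — the comparator baseline.

Supports both fixed per-class gray ranges (the printed reference ranges:
background exactly 0, LCN 0.05-0.42, shade-off 0.43-0.53, bone 0.54-0.89)
and automatic multi-level Otsu thresholds.  Because fixed ranges leave
gaps, unassigned voxels fall back to the class with the nearest interval
midpoint so that the classifier is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu

from .errors import ConfigurationError, ContractError, DomainError
from .volumes import CLASSES, GrayVolume, LabelVolume

#: Published reference ranges for normalized gray values.
PAPER_RANGES = {
    "background": (0.0, 0.0),
    "lcn": (0.05, 0.42),
    "shade_off": (0.43, 0.53),
    "bone": (0.54, 0.89),
}

#: Class ordering by increasing gray value, used to label Otsu bins.
_BRIGHTNESS_ORDER = {
    2: ("background", "bone"),
    3: ("background", "lcn", "bone"),
    4: ("background", "lcn", "shade_off", "bone"),
}


@dataclass
class ThresholdRanges:
    """Per-class closed gray intervals ``class -> (lo, hi)`` on [0, 1]."""

    ranges: dict

    def __post_init__(self) -> None:
        items = sorted(self.ranges.items(), key=lambda kv: kv[1][0])
        for name, (lo, hi) in items:
            if name not in CLASSES:
                raise ConfigurationError(f"ranges: unknown class '{name}'")
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"ranges: invalid interval for '{name}': ({lo}, {hi})")
        for (na, (_, hia)), (nb, (lob, _)) in zip(items, items[1:]):
            if lob < hia or (lob == hia and hia > 0):
                raise ConfigurationError(f"ranges: intervals of '{na}' and '{nb}' overlap")

    def midpoints(self) -> dict:
        return {name: 0.5 * (lo + hi) for name, (lo, hi) in self.ranges.items()}


def threshold_segment(vol: GrayVolume, ranges: ThresholdRanges) -> LabelVolume:
    """Assign each voxel the class whose interval contains its gray value.

    Voxels in inter-range gaps (or above the top range) take the class with
    the nearest interval midpoint.
    """
    g = vol.data
    if g.min() < 0.0 or g.max() > 1.0:
        raise ContractError("threshold_segment requires gray values normalized to [0, 1]")
    class_set = tuple(c for c in CLASSES if c in ranges.ranges)
    code = {name: i for i, name in enumerate(class_set)}
    out = np.full(g.shape, 255, dtype=np.uint8)
    for name in class_set:
        lo, hi = ranges.ranges[name]
        hit = (g == lo) if lo == hi else ((g >= lo) & (g <= hi))
        out[hit] = code[name]
    gap = out == 255
    if gap.any():
        mids = ranges.midpoints()
        dist = np.stack([np.abs(g[gap] - mids[name]) for name in class_set])
        out[gap] = dist.argmin(axis=0).astype(np.uint8)
    return LabelVolume(out, class_set, vol.voxel_size_nm)


def otsu_multiclass(vol: GrayVolume, n_classes: int, nbins: int = 64) -> ThresholdRanges:
    """Multi-level Otsu thresholds as per-class ranges.

    Thresholds maximize the between-class variance of the gray histogram;
    the resulting bins are mapped onto classes ordered by brightness
    (background darkest, bone brightest).
    """
    if n_classes not in (2, 3, 4):
        raise ConfigurationError("n_classes: must be 2, 3 or 4")
    g = vol.data
    if np.ptp(g) == 0:
        raise DomainError("otsu_multiclass: constant volume has a degenerate histogram")
    try:
        cuts = threshold_multiotsu(g, classes=n_classes, nbins=nbins)
    except ValueError as exc:  # too few distinct values for the class count
        raise DomainError(f"otsu_multiclass: degenerate histogram ({exc})") from exc
    names = _BRIGHTNESS_ORDER[n_classes]
    lo = 0.0
    ranges = {}
    eps = 1e-9
    for name, hi in zip(names, list(float(c) for c in cuts) + [1.0]):
        ranges[name] = (lo, hi)
        lo = min(hi + eps, 1.0)
    return ThresholdRanges(ranges)
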