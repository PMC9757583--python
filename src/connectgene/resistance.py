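"""Suitability-to-cost transformation and resistance-surface composition.

Habitat suitability s in [0, 1] is mapped to a movement cost through six
anchor points — (0, 100), (0.2, 40), (0.4, 15), (0.6, 5), (0.8, 2), (1, 1) —
with log-linear (piecewise-exponential) interpolation between adjacent
anchors, so cost decreases exponentially within each segment and hits every
anchor exactly.  Major roads are burned in at a fixed cost (default 10,000)
that overrides the suitability-derived cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import Raster

__all__ = ["DEFAULT_ANCHORS", "DEFAULT_ROAD_COST", "ResistanceSurface", "suitability_to_cost", "compose_resistance"]

DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 100.0),
    (0.2, 40.0),
    (0.4, 15.0),
    (0.6, 5.0),
    (0.8, 2.0),
    (1.0, 1.0),
)
DEFAULT_ROAD_COST = 10000.0


@dataclass
class ResistanceSurface:
    """A per-cell movement-cost raster with the road mask that shaped it."""

    cost: Raster
    road_mask: Raster
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    road_cost: float = DEFAULT_ROAD_COST

    @property
    def cell_size(self) -> float:
        return self.cost.cell_size


def suitability_to_cost(
    s,
    anchors: Sequence[tuple[float, float]] = DEFAULT_ANCHORS,
    mode: str = "interpolate",
):
    """Map suitability (scalar, array or Raster) to cost.

    ``mode='interpolate'`` (default) interpolates log-cost linearly between
    anchors; ``mode='bin'`` snaps each value to the cost of the nearest
    anchor.  NaN (nodata) passes through; finite values outside [0, 1] raise.
    """
    if isinstance(s, Raster):
        return s.like(suitability_to_cost(s.values, anchors, mode))
    arr = np.asarray(s, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("suitability must lie within [0, 1]")
    xs = np.array([a[0] for a in anchors])
    cs = np.array([a[1] for a in anchors])
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(cs) >= 0):
        raise ValueError("anchors must be strictly increasing in s and decreasing in cost")
    if mode == "interpolate":
        out = np.exp(np.interp(arr, xs, np.log(cs)))
        # anchors are contractual: snap exact anchor inputs to exact costs,
        # and clip each segment to its anchor bounds so the float jitter of
        # exp(interp(log)) can never break monotonicity
        seg = np.clip(np.searchsorted(xs, np.nan_to_num(arr), side="right") - 1, 0, len(xs) - 2)
        out = np.clip(out, cs[seg + 1], cs[seg])
        for x, c in zip(xs, cs):
            out = np.where(arr == x, c, out)
    elif mode == "bin":
        nearest = np.argmin(np.abs(arr[..., None] - xs), axis=-1)
        out = cs[nearest].astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.where(finite, out, np.nan)
    if np.ndim(s) == 0:
        return float(out)
    return out


def compose_resistance(
    suitability: Raster,
    roads: Raster,
    road_cost: float = DEFAULT_ROAD_COST,
    anchors: Sequence[tuple[float, float]] = DEFAULT_ANCHORS,
    mode: str = "interpolate",
    target_cell_size: float | None = None,
) -> ResistanceSurface:
    """Build the resistance surface: transformed suitability with roads burned in.

    Road cells take ``road_cost`` exactly, regardless of suitability; nodata
    propagates from either input.  If ``target_cell_size`` is given, the
    suitability raster is resampled bilinearly and the road mask by nearest
    neighbor before composition.
    """
    if not suitability.is_aligned(roads):
        raise ValueError("suitability and road rasters are not aligned")
    if road_cost < max(c for _, c in anchors):
        raise ValueError("road_cost must be >= the maximum non-road cost")
    if target_cell_size is not None and not np.isclose(target_cell_size, suitability.cell_size):
        zoom = suitability.cell_size / target_cell_size
        sv = ndimage.zoom(np.nan_to_num(suitability.values), zoom, order=1)
        sv = np.clip(sv, 0.0, 1.0)
        nod = ndimage.zoom(suitability.valid_mask.astype(float), zoom, order=0) < 0.5
        sv[nod] = np.nan
        rv = ndimage.zoom(roads.values, zoom, order=0)
        suitability = Raster(sv, target_cell_size, suitability.xll, suitability.yll)
        roads = Raster(rv, target_cell_size, roads.xll, roads.yll)
    cost = suitability_to_cost(suitability, anchors, mode)
    vals = cost.values.copy()
    on_road = roads.values > 0
    vals[on_road & np.isfinite(vals)] = road_cost
    vals[~roads.valid_mask] = np.nan
    return ResistanceSurface(
        suitability.like(vals), roads.copy(), tuple(tuple(a) for a in anchors), float(road_cost)
    )
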