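"""Window-level read-depth ratio numerics.

Turns two samples' per-window mean depths into a GC-corrected log2-ratio
track, and centers segmental log-ratio distributions on their mode.  The
window read ratio for samples i (numerator) and j (denominator) is

    W = log2( (D_i / D_j) * (T_j / T_i) )

with D the window mean depth and T the sample's total mapped bases, so the
ratio is invariant to sequencing throughput differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .core import GenomicWindows, TargetRegions, WindowDepthTable, WindowTrack

__all__ = [
    "tile_windows",
    "window_log_ratio",
    "gc_correct",
    "center_by_mode",
    "CenteringResult",
]

log = logging.getLogger(__name__)

MIN_REGION_BP = 10


def tile_windows(regions: TargetRegions, width: int = 100) -> GenomicWindows:
    """Tile each merged target region into consecutive ``width``-bp windows.

    A trailing remainder of at least ``width/2`` becomes its own window; a
    shorter remainder is appended to the last full window.  Regions shorter
    than a full window form a single window; regions under 10 bp are skipped
    with a warning.  Windows never span region boundaries.
    """
    if width < 10:
        raise ValueError("window width must be >= 10 bp")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    half = width / 2
    for c, s, e in zip(regions.chrom, regions.start, regions.end):
        length = e - s
        if length < MIN_REGION_BP:
            log.warning("skipping region %s:%d-%d shorter than %d bp", c, s, e, MIN_REGION_BP)
            continue
        n_full = length // width
        if n_full == 0:
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            continue
        rem = length - n_full * width
        bounds = [int(s + k * width) for k in range(n_full + 1)]
        if rem >= half:
            bounds.append(int(e))
        else:
            bounds[-1] = int(e)
        for a, b in zip(bounds[:-1], bounds[1:]):
            chroms.append(c)
            starts.append(a)
            ends.append(b)
    return GenomicWindows(np.array(chroms, dtype=object), starts, ends)


def window_log_ratio(
    numerator: WindowDepthTable,
    denominator: WindowDepthTable,
    min_depth: float = 10.0,
) -> WindowTrack:
    """Per-window log2 depth ratio after total-mapped-base normalization.

    Windows where either sample's mean depth falls below ``min_depth`` are
    dropped from the track (capture dropout, not signal), keeping all values
    finite.
    """
    if not numerator.windows.same_tiling(denominator.windows):
        raise ValueError("window tilings differ between samples")
    keep = (numerator.mean_depth >= min_depth) & (denominator.mean_depth >= min_depth)
    if not keep.any():
        raise ValueError("no usable windows after depth filtering")
    dn = numerator.mean_depth[keep]
    dd = denominator.mean_depth[keep]
    values = np.log2(dn / dd) + np.log2(
        denominator.total_mapped_bases / numerator.total_mapped_bases
    )
    return WindowTrack(numerator.windows.subset(keep), values, "log_ratio")


def gc_correct(
    track: WindowTrack,
    gc: WindowTrack,
    n_bins: int = 50,
    min_bin_windows: int = 20,
) -> WindowTrack:
    """Remove GC-dependent bias by binned-median subtraction.

    Windows are grouped into ``n_bins`` equal-width GC bins over [0, 1] and
    each bin's median log-ratio is subtracted from its members.  Bins with
    fewer than ``min_bin_windows`` windows are pooled and corrected by the
    pooled median (the global median when every bin is sparse), which keeps
    the operation exactly idempotent.
    """
    if not track.windows.same_tiling(gc.windows):
        raise ValueError("gc track windows differ from log-ratio track")
    g = gc.values
    if np.any(g < 0) or np.any(g > 1) or not np.all(np.isfinite(g)):
        raise ValueError("gc fractions must lie in [0, 1]")
    idx = np.minimum((g * n_bins).astype(np.int64), n_bins - 1)
    corrected = track.values.copy()
    counts = np.bincount(idx, minlength=n_bins)
    pooled_mask = np.zeros(len(corrected), dtype=bool)
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        members = idx == b
        if counts[b] >= min_bin_windows:
            corrected[members] -= np.median(corrected[members])
        else:
            pooled_mask |= members
    if pooled_mask.any():
        corrected[pooled_mask] -= np.median(corrected[pooled_mask])
    return WindowTrack(track.windows, corrected, "log_ratio")


@dataclass(frozen=True)
class CenteringResult:
    centered: np.ndarray
    mode_estimate: float


BANDWIDTH_CAP = 0.1  # log2 units; keeps few-segment distributions multimodal


def center_by_mode(
    values,
    weights=None,
    grid_step: float = 0.001,
) -> CenteringResult:
    """Center values on the mode of their (weighted) distribution.

    The mode is the argmax of a Gaussian kernel density (Silverman
    bandwidth, capped at 0.1 log2 units so that a handful of well-separated
    segment states is not oversmoothed into one hump) evaluated on a
    regular grid spanning the data; weights are typically segment window
    counts so long copy-neutral segments dominate.  Density ties resolve
    toward the candidate with smallest absolute value.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("mode centering requires at least 2 values")
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != x.shape:
            raise ValueError("weights shape mismatch")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    else:
        w = None
    if np.ptp(x) == 0:
        mode = float(x[0])
        return CenteringResult(x - mode, mode)
    try:
        kde = gaussian_kde(x, bw_method="silverman", weights=w)
        data_sd = np.sqrt(kde.covariance[0, 0]) / kde.factor
        if data_sd > 0 and kde.factor * data_sd > BANDWIDTH_CAP:
            kde.set_bandwidth(BANDWIDTH_CAP / data_sd)
    except (ValueError, np.linalg.LinAlgError):
        # numerically singular spread: fall back to the heaviest value
        ww = w if w is not None else np.ones_like(x)
        totals: dict[float, float] = {}
        for v, wt in zip(x, ww):
            totals[float(v)] = totals.get(float(v), 0.0) + float(wt)
        best = max(totals.values())
        candidates = sorted(
            (v for v, t in totals.items() if t >= best * (1 - 1e-12)),
            key=lambda v: (abs(v), v),
        )
        mode = candidates[0]
        return CenteringResult(x - mode, mode)
    lo, hi = float(x.min()), float(x.max())
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    density = kde(grid)
    best = density.max()
    candidates = grid[density >= best * (1 - 1e-12)]
    order = np.lexsort((candidates, np.abs(candidates)))
    mode = float(candidates[order[0]])
    return CenteringResult(x - mode, mode)
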