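"""Circular binary segmentation of log-ratio window tracks.

Each chromosome is treated as a circle; the arc (i, j] maximizing the
two-sample t-like statistic between arc and complement is a candidate
split, assessed by permutation.  Splitting recurses until no significant
arc remains, then adjacent segments with near-equal means are merged.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
from numba import njit

from .core import PipelineConfig, Segment, WindowTrack

__all__ = ["max_partition_statistic", "cbs_segment"]

_T_DEGENERATE = 1e30


@njit(cache=True)
def _arc_scan(x):
    """Best circular arc (i, j], i < j, by the two-sample t statistic.

    Returns (i, j, T).  Zero pooled variance with unequal means yields a
    sentinel large T; ties prefer smaller i then smaller j.
    """
    n = x.shape[0]
    s_cum = np.empty(n + 1)
    s_cum[0] = 0.0
    sumsq = 0.0
    for t in range(n):
        s_cum[t + 1] = s_cum[t] + x[t]
        sumsq += x[t] * x[t]
    tot = s_cum[n]
    best_t = -1.0
    bi = 0
    bj = 1
    for k in range(1, n):
        w_in = float(k)
        w_out = float(n - k)
        inv = 1.0 / w_in + 1.0 / w_out
        for i in range(0, n - k + 1):
            s = s_cum[i + k] - s_cum[i]
            m1 = s / w_in
            m0 = (tot - s) / w_out
            ss = sumsq - w_in * m1 * m1 - w_out * m0 * m0
            if ss < 0.0:
                ss = 0.0
            d = m1 - m0
            if d < 0.0:
                d = -d
            if ss <= 1e-13:
                tstat = 0.0 if d <= 1e-12 else _T_DEGENERATE
            else:
                tstat = d / np.sqrt((ss / (n - 2)) * inv)
            j = i + k
            # complementary arcs give mathematically equal T up to rounding,
            # so ties are detected with a relative tolerance
            tol = 1e-9 * (best_t if best_t > 1.0 else 1.0)
            if tstat > best_t + tol:
                best_t = tstat
                bi = i
                bj = j
            elif tstat >= best_t - tol and (i < bi or (i == bi and j < bj)):
                if tstat > best_t:
                    best_t = tstat
                bi = i
                bj = j
    return bi, bj, best_t


@njit(cache=True)
def _perm_exceed(x, t_obs, n_perm, max_exceed, seed):
    """Count permutations whose max arc statistic reaches t_obs.

    Stops early once the count exceeds ``max_exceed`` (the split can no
    longer be significant).  Returns (exceed, permutations run).
    """
    np.random.seed(seed)
    y = x.copy()
    exceed = 0
    done = 0
    for _ in range(n_perm):
        np.random.shuffle(y)
        _, _, t = _arc_scan(y)
        done += 1
        if t >= t_obs:
            exceed += 1
            if exceed > max_exceed:
                break
    return exceed, done


def max_partition_statistic(values) -> tuple[int, int, float]:
    """Arc (i, j] maximizing the circular two-sample t statistic."""
    x = np.ascontiguousarray(values, dtype=np.float64)
    if x.size < 4:
        raise ValueError("max_partition_statistic requires >= 4 values")
    i, j, t = _arc_scan(x)
    return int(i), int(j), float(t)


def _chrom_seed(global_seed: int, chrom: str) -> int:
    return (global_seed * 1000003 + zlib.crc32(chrom.encode())) % (2**31)


def _split_points(
    x: np.ndarray,
    lo: int,
    hi: int,
    cfg: PipelineConfig,
    chrom_seed: int,
    out: list[int],
) -> None:
    n = hi - lo
    if n < 4 or n < 2 * cfg.min_seg_windows:
        return
    i, j, t_obs = _arc_scan(x[lo:hi])
    if t_obs <= 0.0:
        return
    k = j - i
    if k < cfg.min_seg_windows or n - k < cfg.min_seg_windows:
        return
    node_seed = (chrom_seed + 7919 * lo + 104729 * hi) % (2**31)
    max_exceed = int(np.floor(cfg.alpha_split * cfg.n_perm))
    exceed, done = _perm_exceed(
        x[lo:hi].copy(), t_obs, cfg.n_perm, max_exceed, node_seed
    )
    if exceed / done > cfg.alpha_split:
        return
    cuts = sorted({lo + i, lo + j} - {lo, hi})
    for c in cuts:
        out.append(c)
    pieces = [lo] + cuts + [hi]
    for a, b in zip(pieces[:-1], pieces[1:]):
        _split_points(x, a, b, cfg, chrom_seed, out)


def _merge_adjacent(
    bounds: list[int], x: np.ndarray, merge_tol: float
) -> list[int]:
    """Drop interior boundaries between segments with near-equal means."""
    while len(bounds) > 2:
        means = [
            x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])
        ]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        kmin = int(np.argmin(diffs))
        if diffs[kmin] >= merge_tol:
            break
        del bounds[kmin + 1]
    return bounds


def cbs_segment(
    track: WindowTrack,
    alpha_split: float | None = None,
    n_perm: int | None = None,
    min_seg_windows: int | None = None,
    merge_tol: float | None = None,
    seed: int | None = None,
    config: PipelineConfig | None = None,
) -> list[Segment]:
    """Segment a log-ratio track chromosome by chromosome.

    A split is accepted when its permutation p-value is at most
    ``alpha_split`` and both circular pieces hold at least
    ``min_seg_windows`` windows.  Permutations are seeded per chromosome
    from the global seed so runs are reproducible.  Chromosomes with too
    few windows yield a single low-confidence segment.
    """
    cfg = config or PipelineConfig()
    overrides = {
        k: v
        for k, v in {
            "alpha_split": alpha_split,
            "n_perm": n_perm,
            "min_seg_windows": min_seg_windows,
            "merge_tol": merge_tol,
            "seed": seed,
        }.items()
        if v is not None
    }
    if overrides:
        cfg = replace(cfg, **overrides)

    segments: list[Segment] = []
    chroms = track.windows.chromosomes()
    for chrom in chroms:
        mask = track.windows.chrom == chrom
        x = np.ascontiguousarray(track.values[mask], dtype=np.float64)
        starts = track.windows.start[mask]
        ends = track.windows.end[mask]
        n = x.size
        if n < max(4, cfg.min_seg_windows):
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(starts[0]),
                    end=int(ends[-1]),
                    n_windows=n,
                    seg_logratio=float(x.mean()),
                    flags=("low_confidence",),
                )
            )
            continue
        cuts: list[int] = []
        _split_points(x, 0, n, cfg, _chrom_seed(cfg.seed, chrom), cuts)
        bounds = [0] + sorted(set(cuts)) + [n]
        bounds = _merge_adjacent(bounds, x, cfg.merge_tol)
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    n_windows=int(b - a),
                    seg_logratio=float(x[a:b].mean()),
                )
            )
    return segments
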