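"""Noise modeling from pairwise normal-normal comparisons.

All unordered pairs of normal diploid samples are compared as read-depth
ratio tracks.  Per chromosome and per log-ratio sign, the coverage of
10-kb bins by segments at increasing absolute log-ratio thresholds (R_T)
separates diffuse technical noise (complete, random coverage at low R_T)
from focal germline copy-number variants (sparse coverage at high R_T).
The noise threshold R_NT = max(R_TF, R_TE) combines the largest drop in
the fraction of covered bins (R_TF) with the first major loss of coverage
entropy (R_TE).  Per-comparison extremes of sub-threshold segments are fit
with a Generalized Extreme Value distribution via probability-weighted
moments, giving the null against which tumor segments are later scored.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma_fn
from sklearn.base import BaseEstimator

from . import cbs as _cbs
from . import depth_ratio as _dr
from .core import (
    DIRECTIONS,
    NEGATIVE,
    POSITIVE,
    ChromDirectionModel,
    NoiseModel,
    PipelineConfig,
    Segment,
    WindowDepthTable,
    WindowTrack,
    chrom_sort_key,
)

__all__ = [
    "enumerate_pairs",
    "normal_normal_segments",
    "CoverageProfile",
    "ComparisonSegments",
    "coverage_profile",
    "fraction_of_coverage",
    "coverage_entropy",
    "noise_threshold",
    "silhouette_index",
    "collect_extremes",
    "fit_gev_pwm",
    "corroborate_germline",
    "build_noise_model",
    "ExtremeValueNoiseModel",
]

log = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329


def enumerate_pairs(sample_ids) -> list[tuple[str, str]]:
    """All N(N-1)/2 unordered sample pairs, lexicographically ordered."""
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to form pairs")
    return list(itertools.combinations(sorted(ids), 2))


@dataclass
class ComparisonSegments:
    """Mode-centered segments of one unordered sample comparison."""

    pair: tuple[str, str]
    segments: list[Segment]
    mode_estimate: float = 0.0

    def on_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]


def _segment_pair_track(
    numerator: WindowDepthTable,
    denominator: WindowDepthTable,
    config: PipelineConfig,
) -> tuple[list[Segment], float]:
    track = _dr.window_log_ratio(numerator, denominator, min_depth=config.min_depth)
    keep = (numerator.mean_depth >= config.min_depth) & (
        denominator.mean_depth >= config.min_depth
    )
    gc_track = WindowTrack(track.windows, numerator.gc_fraction[keep], "gc")
    corrected = _dr.gc_correct(
        track, gc_track, n_bins=config.gc_bins, min_bin_windows=config.gc_min_bin_windows
    )
    segments = _cbs.cbs_segment(corrected, config=config)
    if len(segments) >= 2:
        values = np.array([s.seg_logratio for s in segments])
        weights = np.array([s.n_windows for s in segments], dtype=float)
        centering = _dr.center_by_mode(values, weights=weights)
        mode = centering.mode_estimate
    else:
        # A single genome-wide segment defines the copy-neutral state.
        mode = segments[0].seg_logratio if segments else 0.0
    return [s.shifted(mode) for s in segments], float(mode)


def normal_normal_segments(
    pair: tuple[str, str],
    tables: dict[str, WindowDepthTable],
    config: PipelineConfig | None = None,
) -> ComparisonSegments:
    """Segment one normal-normal comparison (first id as numerator)."""
    cfg = config or PipelineConfig()
    a, b = pair
    segments, mode = _segment_pair_track(tables[a], tables[b], cfg)
    return ComparisonSegments(pair=(a, b), segments=segments, mode_estimate=mode)


@dataclass
class CoverageProfile:
    """Bin-coverage frequencies by segments at each absolute threshold R_T.

    ``F[g, j]`` counts (comparison, segment) incidences overlapping 10-kb
    bin j with sign matching ``direction`` and |segmental log-ratio| at or
    above grid value g.
    """

    chrom: str
    direction: str
    grid: np.ndarray
    bin_size: int
    n_bins: int
    F: np.ndarray  # shape (len(grid), n_bins), int64
    flags: tuple[str, ...] = ()


def coverage_profile(
    comparisons: list[ComparisonSegments],
    chrom: str,
    direction: str,
    span_end: int,
    bin_size: int = 10_000,
    grid: np.ndarray | None = None,
) -> CoverageProfile:
    """Count per-bin segment coverage across the R_T grid."""
    if not comparisons:
        raise ValueError("at least one comparison required")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if grid is None:
        grid = np.round(np.arange(0, 1.0 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=np.float64)
    n_bins = int(math.ceil(span_end / bin_size))
    if n_bins <= 0:
        raise ValueError("chromosome span yields zero bins")
    F = np.zeros((len(grid), n_bins), dtype=np.int64)
    any_seg = False
    for comp in comparisons:
        for seg in comp.on_chrom(chrom):
            any_seg = True
            lr = seg.seg_logratio
            if direction == POSITIVE and lr <= 0:
                continue
            if direction == NEGATIVE and lr >= 0:
                continue
            g_idx = int(np.searchsorted(grid, abs(lr) + 1e-12, side="right"))
            if g_idx == 0:
                continue
            b0 = max(0, seg.start // bin_size)
            b1 = min(n_bins - 1, (seg.end - 1) // bin_size)
            F[:g_idx, b0 : b1 + 1] += 1
    flags = () if any_seg else ("no_segments",)
    return CoverageProfile(
        chrom=chrom,
        direction=direction,
        grid=grid,
        bin_size=bin_size,
        n_bins=n_bins,
        F=F,
        flags=flags,
    )


def fraction_of_coverage(profile: CoverageProfile) -> np.ndarray:
    """Per R_T, the fraction of bins covered by any qualifying segment."""
    if profile.n_bins == 0:
        raise ValueError("profile has zero bins")
    return (profile.F > 0).mean(axis=1)


def coverage_entropy(profile: CoverageProfile) -> np.ndarray:
    """Shannon entropy (bits) of the normalized per-bin coverage counts."""
    F = profile.F.astype(np.float64)
    totals = F.sum(axis=1)
    out = np.zeros(len(profile.grid))
    for g, tot in enumerate(totals):
        if tot <= 0:
            continue
        p = F[g] / tot
        nz = p > 0
        out[g] = float(-(p[nz] * np.log2(p[nz])).sum())
    return out


def noise_threshold(
    fraction: np.ndarray,
    entropy: np.ndarray,
    grid: np.ndarray,
) -> tuple[float, float, float, tuple[str, ...]]:
    """Locate R_TF, R_TE and R_NT = max(R_TF, R_TE) on the grid.

    R_TF is the grid value with the maximal step drop in coverage fraction
    (ties to the smallest R_T); R_TE is the first grid value whose entropy
    drop reaches half the maximal entropy drop.  Flat diagnostics are
    flagged: both flat pins R_NT at the grid maximum ("no structure"); a
    single flat vector contributes the grid minimum instead.
    """
    fraction = np.minimum.accumulate(np.asarray(fraction, dtype=float))
    entropy = np.asarray(entropy, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not (len(fraction) == len(entropy) == len(grid)):
        raise ValueError("vectors must align with the grid")
    fd = fraction[:-1] - fraction[1:]
    ed = entropy[:-1] - entropy[1:]
    flags: list[str] = []
    flat_f = not (fd > 0).any()
    flat_e = not (ed > 0).any()
    if flat_f and flat_e:
        return (
            float(grid[-1]),
            float(grid[-1]),
            float(grid[-1]),
            ("no_structure",),
        )
    if flat_f:
        r_tf = float(grid[0])
        flags.append("flat_fraction")
    else:
        r_tf = float(grid[1 + int(np.argmax(fd))])
    if flat_e:
        r_te = float(grid[0])
        flags.append("flat_entropy")
    else:
        emax = ed.max()
        k = int(np.argmax(ed >= 0.5 * emax))
        r_te = float(grid[1 + k])
    return r_tf, r_te, max(r_tf, r_te), tuple(flags)


def silhouette_index(profile: CoverageProfile, r_nt: float) -> float | None:
    """Average silhouette of F^RT vectors split at R_NT (Euclidean).

    Points are the per-threshold coverage vectors; the two clusters are
    thresholds below vs at-or-above R_NT.  Singleton clusters and
    zero-distance ties contribute silhouette 0.  Returns None when the
    split leaves one side empty.
    """
    labels = profile.grid >= r_nt
    if labels.all() or (~labels).all():
        return None
    X = profile.F.astype(np.float64)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own_others = own.copy()
        own_others[i] = False
        if not own_others.any():
            scores[i] = 0.0
            continue
        a = D[i, own_others].mean()
        b = D[i, ~own].mean()
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def collect_extremes(
    comparisons: list[ComparisonSegments],
    chrom: str,
    direction: str,
    r_nt: float,
) -> list[float]:
    """Per-comparison extreme sub-threshold segmental log-ratios.

    For each comparison, among that chromosome's segments with matching
    sign and |log-ratio| strictly below R_NT, the maximum (positive
    direction) or minimum (negative direction) is kept; comparisons with
    no qualifying segment contribute nothing.
    """
    out: list[float] = []
    for comp in comparisons:
        vals = []
        for seg in comp.on_chrom(chrom):
            lr = seg.seg_logratio
            if direction == POSITIVE and 0 < lr and abs(lr) < r_nt:
                vals.append(lr)
            elif direction == NEGATIVE and lr < 0 and abs(lr) < r_nt:
                vals.append(lr)
        if vals:
            out.append(max(vals) if direction == POSITIVE else min(vals))
    return out


def fit_gev_pwm(
    extremes,
    direction: str = POSITIVE,
    min_k: int = 15,
) -> tuple[float, float, float]:
    """GEV (xi, mu, sigma) by probability-weighted moments.

    Uses the standard PWM/L-moment estimator from sample order statistics;
    the shape sign follows the block-maxima convention (xi > 0 means a
    heavy upper tail).  Negative-direction extremes (minima) are negated
    before fitting so both directions are block maxima.
    """
    x = np.asarray(extremes, dtype=np.float64)
    if x.size < min_k:
        raise ValueError(
            f"insufficient extremes: {x.size} < {min_k} required for GEV fitting"
        )
    if direction == NEGATIVE:
        x = -x
    if np.ptp(x) == 0:
        raise ValueError("degenerate extremes: all values identical")
    x = np.sort(x)
    n = x.size
    j = np.arange(1, n + 1, dtype=np.float64)
    b0 = x.mean()
    b1 = ((j - 1) / (n - 1) * x).mean()
    b2 = ((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * x).mean()
    denom = 3 * b2 - b0
    if abs(denom) < 1e-300:
        raise ValueError("degenerate probability-weighted moments")
    c = (2 * b1 - b0) / denom - math.log(2) / math.log(3)
    k_hat = 7.8590 * c + 2.9554 * c * c  # Hosking's shape (= -xi)
    if abs(k_hat) < 1e-9:
        sigma = (2 * b1 - b0) / math.log(2)
        mu = b0 - EULER_GAMMA * sigma
        xi = 0.0
    else:
        g = _gamma_fn(1 + k_hat)
        sigma = (2 * b1 - b0) * k_hat / (g * (1 - 2 ** (-k_hat)))
        mu = b0 + sigma * (g - 1) / k_hat
        xi = -k_hat
    if not (sigma > 0 and np.isfinite(sigma)):
        raise ValueError("PWM fit produced non-positive scale")
    return float(xi), float(mu), float(sigma)


def _overlap_weighted_partner(seg: Segment, others: list[Segment]) -> float | None:
    """Reciprocal-overlap-weighted mean log-ratio of overlapping segments."""
    num = 0.0
    den = 0.0
    len_a = seg.end - seg.start
    for o in others:
        ov = min(seg.end, o.end) - max(seg.start, o.start)
        if ov <= 0:
            continue
        len_b = o.end - o.start
        w = (ov / len_a) * (ov / len_b)
        num += w * o.seg_logratio
        den += w
    if den == 0:
        return None
    return num / den


def _pearson(pairs: list[tuple[float, float]]) -> float | None:
    if len(pairs) < 3:
        return None
    arr = np.asarray(pairs)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        return None
    return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])


def corroborate_germline(
    nn_comparisons: list[ComparisonSegments],
    tt_comparisons: list[ComparisonSegments],
    r_nt: dict[tuple[str, str], float],
    seed: int = 17,
) -> dict[str, float | None]:
    """Correlate normal-normal segments with tumor-tumor counterparts.

    Each normal-normal segment, stratified as above or below its
    chromosome/direction noise threshold, is paired with the
    reciprocal-overlap-weighted mean log-ratio of overlapping segments in
    the index-matched tumor-tumor comparison and in a seeded random
    tumor-tumor comparison.  Above-threshold segments tracking their
    matched tumors corroborates a germline (inherited) origin.
    """
    if len(nn_comparisons) != len(tt_comparisons):
        raise ValueError("matched tumor-tumor comparisons must align 1:1")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[tuple[float, float]]] = {
        "above_matched": [],
        "below_matched": [],
        "above_random": [],
        "below_random": [],
    }
    n = len(nn_comparisons)
    for idx, nn in enumerate(nn_comparisons):
        matched = tt_comparisons[idx]
        if n > 1:
            choices = [k for k in range(n) if k != idx]
            random_tt = tt_comparisons[int(rng.choice(choices))]
        else:
            random_tt = matched
        for seg in nn.segments:
            direction = POSITIVE if seg.seg_logratio > 0 else NEGATIVE
            if seg.seg_logratio == 0:
                continue
            thr = r_nt.get((seg.chrom, direction))
            if thr is None:
                continue
            stratum = "above" if abs(seg.seg_logratio) >= thr else "below"
            for label, tt in (("matched", matched), ("random", random_tt)):
                partner = _overlap_weighted_partner(seg, tt.on_chrom(seg.chrom))
                if partner is not None:
                    strata[f"{stratum}_{label}"].append((seg.seg_logratio, partner))
    return {
        "r_above_matched": _pearson(strata["above_matched"]),
        "r_below_matched": _pearson(strata["below_matched"]),
        "r_above_random": _pearson(strata["above_random"]),
        "r_below_random": _pearson(strata["below_random"]),
    }


def _model_chrom_direction(
    comparisons: list[ComparisonSegments],
    chrom: str,
    direction: str,
    span_end: int,
    cfg: PipelineConfig,
) -> ChromDirectionModel:
    grid = np.round(
        np.arange(0, cfg.grid_max + cfg.grid_step / 2, cfg.grid_step), 10
    )
    profile = coverage_profile(
        comparisons, chrom, direction, span_end, bin_size=cfg.bin_size, grid=grid
    )
    frac = fraction_of_coverage(profile)
    ent = coverage_entropy(profile)
    r_tf, r_te, r_nt, thr_flags = noise_threshold(frac, ent, grid)
    sil = silhouette_index(profile, r_nt)
    extremes = collect_extremes(comparisons, chrom, direction, r_nt)
    k = len(extremes)
    flags = list(profile.flags) + list(thr_flags)
    if sil is None:
        flags.append("silhouette_undefined")
    if k >= cfg.min_extremes:
        try:
            xi, mu, sigma = fit_gev_pwm(extremes, direction, min_k=cfg.min_extremes)
            modeled = True
        except ValueError as exc:
            log.warning("%s/%s GEV fit failed: %s", chrom, direction, exc)
            xi = mu = sigma = None
            modeled = False
            flags.append("gev_fit_failed")
    else:
        xi = mu = sigma = None
        modeled = False
        flags.append("unmodeled")
        log.warning(
            "%s/%s unmodeled: K=%d below floor %d", chrom, direction, k, cfg.min_extremes
        )
    return ChromDirectionModel(
        chrom=chrom,
        direction=direction,
        r_tf=r_tf,
        r_te=r_te,
        r_nt=r_nt,
        silhouette=sil,
        k=k,
        xi=xi,
        mu=mu,
        sigma=sigma,
        modeled=modeled,
        flags=tuple(flags),
    )


def build_noise_model(
    normals: list[WindowDepthTable],
    config: PipelineConfig | None = None,
    return_comparisons: bool = False,
):
    """Learn the full noise model from a cohort of normal samples.

    Orchestrates pair enumeration, pairwise segmentation, coverage-profile
    thresholding, silhouette diagnostics and GEV fitting for every
    chromosome and direction.
    """
    cfg = config or PipelineConfig()
    if len(normals) < 15:
        log.warning(
            "only %d normal samples; 15-20 are recommended for reliable GEV fits",
            len(normals),
        )
    tables = {t.sample_id: t for t in normals}
    if len(tables) != len(normals):
        raise ValueError("duplicate sample ids among normals")
    ref = normals[0].windows
    for t in normals[1:]:
        if not t.windows.same_tiling(ref):
            raise ValueError("normal samples do not share one window tiling")
    pairs = enumerate_pairs(list(tables))
    comparisons = [normal_normal_segments(p, tables, cfg) for p in pairs]
    tile_width = int(np.median(ref.lengths())) if len(ref) else cfg.tile_width
    model = NoiseModel(
        tile_width=tile_width,
        grid_step=cfg.grid_step,
        grid_max=cfg.grid_max,
        bin_size=cfg.bin_size,
        seed=cfg.seed,
        n_comparisons=len(comparisons),
    )
    for chrom in sorted(ref.chromosomes(), key=chrom_sort_key):
        span_end = ref.span_end(chrom)
        for direction in DIRECTIONS:
            model.entries[(chrom, direction)] = _model_chrom_direction(
                comparisons, chrom, direction, span_end, cfg
            )
    if return_comparisons:
        return model, comparisons
    return model


class ExtremeValueNoiseModel(BaseEstimator):
    """Estimator learning chromosome-specific noise thresholds and GEV tails.

    Parameters mirror :class:`~evdcnv.core.PipelineConfig`.  ``fit`` takes a
    list of :class:`WindowDepthTable` for normal diploid samples; the fitted
    model is available as ``model_`` (serializable via
    :func:`evdcnv.io_formats.write_model`).
    """

    def __init__(
        self,
        min_depth: float = 10.0,
        gc_bins: int = 50,
        alpha_split: float = 0.01,
        n_perm: int = 1000,
        min_seg_windows: int = 3,
        merge_tol: float = 0.05,
        grid_step: float = 0.05,
        grid_max: float = 1.0,
        bin_size: int = 10_000,
        min_extremes: int = 15,
        seed: int = 17,
    ):
        self.min_depth = min_depth
        self.gc_bins = gc_bins
        self.alpha_split = alpha_split
        self.n_perm = n_perm
        self.min_seg_windows = min_seg_windows
        self.merge_tol = merge_tol
        self.grid_step = grid_step
        self.grid_max = grid_max
        self.bin_size = bin_size
        self.min_extremes = min_extremes
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            min_depth=self.min_depth,
            gc_bins=self.gc_bins,
            alpha_split=self.alpha_split,
            n_perm=self.n_perm,
            min_seg_windows=self.min_seg_windows,
            merge_tol=self.merge_tol,
            grid_step=self.grid_step,
            grid_max=self.grid_max,
            bin_size=self.bin_size,
            min_extremes=self.min_extremes,
            seed=self.seed,
        )

    def fit(self, X: list[WindowDepthTable], y=None) -> "ExtremeValueNoiseModel":
        model, comparisons = build_noise_model(
            list(X), self._config(), return_comparisons=True
        )
        self.model_ = model
        self.comparisons_ = comparisons
        self.n_samples_ = len(X)
        return self
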