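"""Somatic copy-number calling against a learned noise model.

A tumor-normal comparison is segmented exactly like the normal-normal
comparisons (tumor as numerator), mode-centered genome-wide so the
dominant ploidy state sits at zero, and each segment is scored by the
upper-tail probability of the chromosome- and direction-specific GEV
noise model:

    G(y) = exp( -[1 + xi (y - mu)/sigma]^(-1/xi) )

with the Gumbel limit at xi -> 0.  Segments with P <= alpha are called
amplified (positive log-ratio) or deleted (negative log-ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import depth_ratio as _dr
from .core import (
    NEGATIVE,
    POSITIVE,
    NoiseModel,
    PipelineConfig,
    SCNACall,
    Segment,
    TargetRegions,
    WindowDepthTable,
    chrom_sort_key,
)
from .noise_model import ExtremeValueNoiseModel, _segment_pair_track

__all__ = [
    "gev_cdf",
    "segment_pvalue",
    "tumor_normal_segments",
    "call_scnas",
    "pool_normals",
    "evaluate_calls",
    "EvaluationResult",
    "SomaticCNVCaller",
]

log = logging.getLogger(__name__)

_XI_GUMBEL_TOL = 1e-9


def gev_cdf(y: float, xi: float, mu: float, sigma: float) -> float:
    """Generalized Extreme Value CDF with support clamping.

    Outside the distribution's support the CDF is clamped to 0 (below the
    lower bound, xi > 0) or 1 (above the upper bound, xi < 0): tumor
    segments legitimately exceed the noise support, and that is signal,
    not an error.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = (y - mu) / sigma
    if abs(xi) < _XI_GUMBEL_TOL:
        return math.exp(-math.exp(-z))
    t = 1.0 + xi * z
    if t <= 0:
        return 0.0 if xi > 0 else 1.0
    return math.exp(-(t ** (-1.0 / xi)))


def segment_pvalue(segment: Segment, model: NoiseModel) -> float | None:
    """Noise-tail probability of a segment's log-ratio, or None if unmodeled."""
    lr = segment.seg_logratio
    if lr == 0:
        return 1.0
    direction = POSITIVE if lr > 0 else NEGATIVE
    entry = model.get(segment.chrom, direction)
    if entry is None or not entry.modeled:
        return None
    y = lr if lr > 0 else -lr  # negative models are fitted on negated minima
    return 1.0 - gev_cdf(y, entry.xi, entry.mu, entry.sigma)


def tumor_normal_segments(
    tumor: WindowDepthTable,
    normal: WindowDepthTable,
    config: PipelineConfig | None = None,
) -> list[Segment]:
    """Segment a tumor-normal depth comparison, tumor as numerator.

    Segmental log-ratios are mode-centered genome-wide (weighted by window
    counts) so aneuploid/hyperploid dominant states define zero.
    """
    cfg = config or PipelineConfig()
    segments, _ = _segment_pair_track(tumor, normal, cfg)
    return segments


def _bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (informational output only)."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()


def call_scnas(
    segments: list[Segment],
    model: NoiseModel,
    alpha: float = 0.05,
    sample_id: str = "sample",
) -> list[SCNACall]:
    """Classify segments as amplification / deletion / neutral at level alpha."""
    pvals = [segment_pvalue(seg, model) for seg in segments]
    defined = [p for p in pvals if p is not None]
    adj_iter = iter(_bh_adjust(defined)) if defined else iter([])
    calls: list[SCNACall] = []
    for seg, p in zip(segments, pvals):
        flags = list(seg.flags)
        padj = None
        if p is None:
            direction = "neutral"
            if seg.seg_logratio != 0:
                flags.append("unmodeled")
        else:
            padj = next(adj_iter)
            if p <= alpha and seg.seg_logratio > 0:
                direction = "amplification"
            elif p <= alpha and seg.seg_logratio < 0:
                direction = "deletion"
            else:
                direction = "neutral"
        calls.append(
            SCNACall(
                sample_id=sample_id,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                n_windows=seg.n_windows,
                seg_logratio=seg.seg_logratio,
                direction=direction,
                p_value=p,
                p_adjusted=padj,
                flags=tuple(flags),
            )
        )
    calls.sort(key=lambda c: (c.sample_id, chrom_sort_key(c.chrom), c.start))
    return calls


def pool_normals(
    normals: list[WindowDepthTable],
    target_total: float,
    seed: int = 17,
    sample_id: str = "pooled_normal",
) -> WindowDepthTable:
    """Build a pooled reference by summing depths and thinning to a target.

    Per-window depths are summed over the normals and sub-sampled by
    Poisson thinning of the pooled base counts at rate
    lambda = target_total / pooled total, so the output totals match the
    target within sampling noise (~2%).
    """
    if len(normals) < 2:
        raise ValueError("pooling requires at least 2 normals")
    ref = normals[0].windows
    for t in normals[1:]:
        if not t.windows.same_tiling(ref):
            raise ValueError("normals do not share one window tiling")
    pooled_depth = np.sum([t.mean_depth for t in normals], axis=0)
    lengths = ref.lengths().astype(np.float64)
    pooled_total = float((pooled_depth * lengths).sum())
    lam = target_total / pooled_total
    if lam > 1 + 1e-9:
        raise ValueError("target exceeds pooled total mapped bases")
    if abs(lam - 1.0) < 1e-12:
        depth = pooled_depth
    else:
        rng = np.random.default_rng(seed)
        base_counts = pooled_depth * lengths * lam
        depth = rng.poisson(base_counts).astype(np.float64) / lengths
    total = float((depth * lengths).sum())
    return WindowDepthTable(
        sample_id=sample_id,
        total_mapped_bases=total,
        windows=ref,
        mean_depth=depth,
        gc_fraction=normals[0].gc_fraction.copy(),
    )


def _clip_intervals(
    intervals: list[tuple[str, int, int]], targets: TargetRegions | None
) -> dict[str, np.ndarray]:
    """Per chromosome, a sorted, merged (n, 2) array of interval bounds,
    clipped to targets when given."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if e <= s:
            continue
        if targets is None:
            by_chrom.setdefault(chrom, []).append((s, e))
        else:
            for tc, ts, te in zip(targets.chrom, targets.start, targets.end):
                if tc != chrom:
                    continue
                a, b = max(s, ts), min(e, te)
                if b > a:
                    by_chrom.setdefault(chrom, []).append((a, b))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _total_len(ivmap: dict[str, np.ndarray]) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in ivmap.values()))


def _overlap_len(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> int:
    total = 0
    for chrom, arr_a in a.items():
        arr_b = b.get(chrom)
        if arr_b is None:
            continue
        for s, e in arr_a:
            lo = np.minimum(e, arr_b[:, 1])
            hi = np.maximum(s, arr_b[:, 0])
            ov = np.maximum(lo - hi, 0)
            total += int(ov.sum())
    return total


@dataclass(frozen=True)
class EvaluationResult:
    sensitivity: float | None
    specificity: float
    concordance: dict[str, float | None]
    flags: tuple[str, ...] = ()


def evaluate_calls(
    calls: list[SCNACall],
    truth: list[tuple[str, int, int, str]],
    targets: TargetRegions | None = None,
) -> EvaluationResult:
    """Base-pair-level agreement between calls and a simulated truth set.

    ``truth`` holds (chrom, start, end, direction) intervals.  Sensitivity
    is direction-matched truth coverage; specificity is one minus the
    fraction of non-truth (neutral) bases covered by non-neutral calls;
    concordance is the per-direction truth coverage.  All lengths are
    restricted to target regions when ``targets`` is given.
    """
    directions = ("amplification", "deletion")
    truth_by_dir = {
        d: _clip_intervals(
            [(c, s, e) for c, s, e, td in truth if td == d], targets
        )
        for d in directions
    }
    calls_by_dir = {
        d: _clip_intervals(
            [(c.chrom, c.start, c.end) for c in calls if c.direction == d], targets
        )
        for d in directions
    }
    truth_all = _clip_intervals([(c, s, e) for c, s, e, _ in truth], targets)
    calls_all = _clip_intervals(
        [(c.chrom, c.start, c.end) for c in calls if c.direction != "neutral"],
        targets,
    )
    if targets is not None:
        genome = _clip_intervals(
            [(c, int(s), int(e)) for c, s, e in zip(targets.chrom, targets.start, targets.end)],
            None,
        )
    else:
        spans: dict[str, list] = {}
        for c in calls:
            spans.setdefault(c.chrom, []).append(c.end)
        genome = {ch: np.array([[0, max(v)]], dtype=np.int64) for ch, v in spans.items()}

    truth_len = _total_len(truth_all)
    concordance: dict[str, float | None] = {}
    matched = 0
    for d in directions:
        tl = _total_len(truth_by_dir[d])
        ov = _overlap_len(truth_by_dir[d], calls_by_dir[d])
        matched += ov
        concordance[d] = None if tl == 0 else ov / tl
    flags: tuple[str, ...] = ()
    if truth_len == 0:
        sensitivity = None
        flags = ("empty_truth",)
    else:
        sensitivity = matched / truth_len
    genome_len = _total_len(genome)
    neutral_len = genome_len - truth_len
    called_len = _total_len(calls_all)
    called_in_truth = _overlap_len(calls_all, truth_all)
    false_len = called_len - called_in_truth
    specificity = 1.0 if neutral_len == 0 else 1.0 - false_len / neutral_len
    return EvaluationResult(
        sensitivity=sensitivity,
        specificity=specificity,
        concordance=concordance,
        flags=flags,
    )


class SomaticCNVCaller(BaseEstimator):
    """End-to-end caller: fit a noise model on normals, score tumor-normal pairs.

    ``fit(X)`` takes a list of normal :class:`WindowDepthTable`;
    ``predict(X)`` takes a list of ``(tumor_table, normal_table)`` tuples
    and returns one list of :class:`SCNACall` per pair.
    """

    def __init__(
        self,
        alpha: float = 0.05,
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
        self.alpha = alpha
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
            alpha=self.alpha,
            seed=self.seed,
        )

    def fit(self, X: list[WindowDepthTable], y=None) -> "SomaticCNVCaller":
        est = ExtremeValueNoiseModel(
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
        ).fit(X)
        self.noise_model_ = est.model_
        self.comparisons_ = est.comparisons_
        return self

    def predict(
        self, X: list[tuple[WindowDepthTable, WindowDepthTable]]
    ) -> list[list[SCNACall]]:
        if not hasattr(self, "noise_model_"):
            raise RuntimeError("SomaticCNVCaller is not fitted")
        cfg = self._config()
        out = []
        for tumor, normal in X:
            segments = tumor_normal_segments(tumor, normal, cfg)
            out.append(
                call_scnas(
                    segments, self.noise_model_, alpha=self.alpha, sample_id=tumor.sample_id
                )
            )
        return out
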