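"""Synthetic whole-exome depth cohorts with known copy-number truth.

The generator reproduces the statistical structure the noise model
assumes: a shared per-window capture-efficiency signature (the platform
fingerprint, identical across samples, so it cancels in pairwise ratios),
sample-specific GC sensitivity, sample-specific capture-dropout blocks
(regional library-prep artifacts, the dominant source of pairwise
segmental noise), multiplicative overdispersion of window depths,
population germline CNVs shared between each normal and its matched
tumor, and purity-attenuated somatic events in tumors:

    expected log-ratio = log2(1 + purity * (CN/2 - 1))

Everything derives deterministically from ``SimSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomicWindows, TargetRegions, WindowDepthTable
from .depth_ratio import tile_windows

__all__ = [
    "GermlineCNV",
    "SomaticEvent",
    "SimSpec",
    "TruthSet",
    "simulate_normal_cohort",
    "simulate_tumor",
    "simulate_cohort",
    "expected_logratio",
]


@dataclass(frozen=True)
class GermlineCNV:
    chrom: str
    start: int
    end: int
    copy_number: int  # in {0, 1, 3, 4}
    population_frequency: float


@dataclass(frozen=True)
class SomaticEvent:
    chrom: str
    start: int
    end: int
    copy_number: int
    clonal_fraction: float = 1.0


@dataclass
class SimSpec:
    """Study design of a simulated cohort.

    ``dispersion`` is the squared coefficient of variation of the
    multiplicative depth noise (Gamma mixing, the overdispersion component
    of a negative binomial); 0 means noiseless depths.  Regional
    library-prep artifacts are modeled as per-sample capture-dropout
    blocks at random positions covering about ``block_coverage`` of each
    chromosome, with log2 magnitudes from ``block_log2``, plus rare
    severe dropouts (``severe_blocks_per_chrom`` expected per chromosome,
    magnitudes ``severe_log2``).  Blocks never stack within a sample and
    only lose coverage, so pairwise segmental noise appears in both
    log-ratio directions but is bounded by a single artifact's magnitude
    — diffuse in location across the many comparisons of a cohort, and
    well below the germline CNV scale — while fully shared platform
    biases cancel in the depth ratio.
    """

    n_normals: int = 16
    n_tumors: int = 4
    genome: tuple[tuple[str, int, float], ...] = (
        ("chr1", 5_000_000, 0.25),
        ("chr2", 5_000_000, 0.25),
        ("chr3", 5_000_000, 0.25),
        ("chr4", 5_000_000, 0.25),
    )
    base_depth: float = 60.0
    dispersion: float = 0.003
    gc_bias_amplitude: float = 0.6
    gc_sensitivity_sd: float = 0.25
    capture_log2_sd: float = 0.7
    block_coverage: float = 0.08
    block_windows: tuple[int, int] = (20, 40)
    block_log2: tuple[float, float] = (0.12, 0.15)
    severe_blocks_per_chrom: float = 0.4
    severe_log2: tuple[float, float] = (0.31, 0.36)
    severe_windows: tuple[int, int] = (30, 50)
    germline_cnvs: tuple[GermlineCNV, ...] = ()
    scna_events: dict[str, tuple[SomaticEvent, ...]] | None = None
    events_per_tumor: int = 2
    event_windows: tuple[int, int] = (60, 150)
    event_copy_numbers: tuple[int, ...] = (0, 1, 3, 4)
    purity: float | dict[str, float] | None = None
    tile_width: int = 100
    target_length: int = 400
    seed: int = 17

    def __post_init__(self):
        if self.n_normals < 2:
            raise ValueError("need at least 2 normals")
        if isinstance(self.purity, float) and not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        for cnv in self.germline_cnvs:
            if not self._inside_genome(cnv.chrom, cnv.start, cnv.end):
                raise ValueError(f"germline CNV outside genome: {cnv}")
            if not (0 <= cnv.population_frequency <= 1):
                raise ValueError("population frequency must lie in [0, 1]")

    def _inside_genome(self, chrom: str, start: int, end: int) -> bool:
        for c, length, _ in self.genome:
            if c == chrom:
                return 0 <= start < end <= length
        return False

    def normal_ids(self) -> list[str]:
        return [f"N{i:03d}" for i in range(self.n_normals)]

    def tumor_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(self.n_tumors)]


@dataclass
class TruthSet:
    """Ground truth: germline CNVs per sample, somatic events per tumor."""

    germline: dict[str, list[tuple[str, int, int, int]]] = field(default_factory=dict)
    somatic: dict[str, list[tuple[str, int, int, int, float]]] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)

    def somatic_directions(self, tumor_id: str) -> list[tuple[str, int, int, str]]:
        out = []
        for chrom, s, e, cn, _ in self.somatic.get(tumor_id, []):
            direction = "amplification" if cn > 2 else "deletion"
            out.append((chrom, s, e, direction))
        return out


def expected_logratio(copy_number: int, purity: float, clonal_fraction: float = 1.0) -> float:
    """Purity- and clonality-attenuated log2 ratio of a somatic event."""
    eff = purity * clonal_fraction
    return float(np.log2(1 + eff * (copy_number / 2 - 1)))


class _Platform:
    """Shared cohort structure derived deterministically from the spec seed."""

    def __init__(self, spec: SimSpec):
        self.spec = spec
        records = []
        for chrom, length, density in spec.genome:
            tl = spec.target_length
            period = max(tl + 1, int(round(tl / density)))
            for s in range(0, length - tl + 1, period):
                records.append((chrom, s, s + tl))
        self.targets = TargetRegions.from_records(records)
        self.windows: GenomicWindows = tile_windows(self.targets, spec.tile_width)
        n = len(self.windows)
        rng_gc = self._rng("gc")
        gc = np.empty(n)
        cap = np.empty(n)
        rng_cap = self._rng("capture")
        for chrom in self.windows.chromosomes():
            m = self.windows.chrom == chrom
            nm = int(m.sum())
            # GC varies target to target (high-frequency along the genome),
            # which keeps binned-median GC correction robust to focal events
            gc[m] = np.clip(0.5 + 0.12 * rng_gc.standard_normal(nm), 0.25, 0.75)
            cap[m] = np.exp2(rng_cap.standard_normal(nm) * spec.capture_log2_sd)
        self.gc = gc
        self.capture = cap

    _DOMAINS = ("gc", "capture", "germline", "normal", "tumor", "event", "purity")

    def _rng(self, domain: str, index: int = 0) -> np.random.Generator:
        """Stateless stream: same (domain, index) always yields the same rng."""
        key = (self._DOMAINS.index(domain), index)
        return np.random.default_rng(
            np.random.SeedSequence(self.spec.seed, spawn_key=key)
        )

    # ---- germline genotypes -------------------------------------------------
    def germline_cn(self, sample_index: int) -> tuple[np.ndarray, list]:
        """Per-window germline copy number for normal/tumor pair ``i``."""
        spec = self.spec
        cn = np.full(len(self.windows), 2.0)
        intervals = []
        rng = self._rng("germline", sample_index)
        for cnv in spec.germline_cnvs:
            if rng.random() < cnv.population_frequency:
                m = (
                    (self.windows.chrom == cnv.chrom)
                    & (self.windows.start >= cnv.start)
                    & (self.windows.end <= cnv.end)
                )
                cn[m] = cnv.copy_number
                intervals.append((cnv.chrom, cnv.start, cnv.end, cnv.copy_number))
        return cn, intervals

    # ---- per-sample depth realization --------------------------------------
    def realize_depth(
        self, cn: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, float]:
        spec = self.spec
        n = len(self.windows)
        gc_mult = 1.0 + spec.gc_sensitivity_sd * rng.standard_normal()
        gc_slope = spec.gc_bias_amplitude * gc_mult
        artifact = np.zeros(n)
        mean_w = (spec.block_windows[0] + spec.block_windows[1]) / 2
        for chrom in self.windows.chromosomes():
            m = np.flatnonzero(self.windows.chrom == chrom)
            nm = m.size
            n_common = rng.poisson(spec.block_coverage * nm / mean_w)
            n_severe = rng.poisson(spec.severe_blocks_per_chrom)
            placed: list[tuple[int, int]] = []
            for kind in range(n_common + n_severe):
                severe = kind >= n_common
                lo, hi = spec.severe_log2 if severe else spec.block_log2
                wlo, whi = spec.severe_windows if severe else spec.block_windows
                w = int(rng.integers(wlo, whi + 1))
                if nm <= w:
                    continue
                # rejection placement: blocks never stack within a sample
                for _attempt in range(20):
                    a = int(rng.integers(0, nm - w))
                    if all(a + w <= s or a >= e for s, e in placed):
                        placed.append((a, a + w))
                        # dropout-only: capture artifacts lose coverage, so
                        # pairwise log-ratios are bounded by one artifact's
                        # magnitude in either direction and never stack
                        artifact[m[a : a + w]] -= rng.uniform(lo, hi)
                        break
        mean = (
            spec.base_depth
            * self.capture
            * np.exp2(gc_slope * (self.gc - 0.5))
            * np.exp2(artifact)
            * (cn / 2.0)
        )
        if spec.dispersion > 0:
            shape = 1.0 / spec.dispersion
            noise = rng.gamma(shape, 1.0 / shape, size=n)
            depth = mean * noise
        else:
            depth = mean.copy()
        lengths = self.windows.lengths().astype(float)
        total = float((depth * lengths).sum())
        return depth, total


def _somatic_events(platform: _Platform, tumor_index: int) -> tuple[SomaticEvent, ...]:
    spec = platform.spec
    tid = spec.tumor_ids()[tumor_index]
    if spec.scna_events is not None:
        return tuple(spec.scna_events.get(tid, ()))
    rng = platform._rng("event", tumor_index)
    events: list[SomaticEvent] = []
    occupied: dict[str, list[tuple[int, int]]] = {
        c.chrom: [(c.start, c.end)] for c in spec.germline_cnvs
    }
    chroms = platform.windows.chromosomes()
    for _ in range(spec.events_per_tumor):
        for _attempt in range(50):
            chrom = chroms[int(rng.integers(len(chroms)))]
            m = platform.windows.chrom == chrom
            starts = platform.windows.start[m]
            ends = platform.windows.end[m]
            nwin = len(starts)
            k = int(rng.integers(spec.event_windows[0], spec.event_windows[1] + 1))
            if nwin < k + 20:
                continue
            a = int(rng.integers(10, nwin - k - 10))
            s, e = int(starts[a]), int(ends[a + k - 1])
            clash = any(
                not (e <= os or s >= oe) for os, oe in occupied.get(chrom, [])
            )
            if clash:
                continue
            cn = int(
                spec.event_copy_numbers[int(rng.integers(len(spec.event_copy_numbers)))]
            )
            events.append(SomaticEvent(chrom, s, e, cn))
            occupied.setdefault(chrom, []).append((s, e))
            break
    return tuple(events)


def _tumor_purity(spec: SimSpec, platform: _Platform, tumor_index: int) -> float:
    tid = spec.tumor_ids()[tumor_index]
    if isinstance(spec.purity, dict):
        return float(spec.purity[tid])
    if isinstance(spec.purity, float):
        return spec.purity
    rng = platform._rng("purity", tumor_index)
    return float(rng.uniform(0.5, 0.9))


def simulate_normal_cohort(spec: SimSpec) -> tuple[list[WindowDepthTable], TruthSet]:
    """Generate the normal cohort depth tables and their germline truth."""
    platform = _Platform(spec)
    truth = TruthSet()
    tables = []
    for i, sid in enumerate(spec.normal_ids()):
        cn, intervals = platform.germline_cn(i)
        rng = platform._rng("normal", i)
        depth, total = platform.realize_depth(cn, rng)
        tables.append(
            WindowDepthTable(
                sample_id=sid,
                total_mapped_bases=total,
                windows=platform.windows,
                mean_depth=depth,
                gc_fraction=platform.gc,
            )
        )
        truth.germline[sid] = intervals
    return tables, truth


def simulate_tumor(
    spec: SimSpec, tumor_id: str, platform: _Platform | None = None
) -> tuple[WindowDepthTable, list[tuple[str, int, int, int, float]], float]:
    """Generate one tumor table: (table, somatic truth intervals, purity).

    The tumor shares the germline profile of its matched normal (tumor i
    pairs with normal i modulo the cohort size) and mixes somatic copy
    number with the germline background at the tumor's purity.
    """
    if platform is None:
        platform = _Platform(spec)
    idx = spec.tumor_ids().index(tumor_id)
    cn_germ, _ = platform.germline_cn(idx % spec.n_normals)
    events = _somatic_events(platform, idx)
    purity = _tumor_purity(spec, platform, idx)
    cn_tumor_cell = cn_germ.copy()
    truth_rows = []
    for ev in events:
        m = (
            (platform.windows.chrom == ev.chrom)
            & (platform.windows.start >= ev.start)
            & (platform.windows.end <= ev.end)
        )
        cn_tumor_cell[m] = ev.copy_number
        truth_rows.append(
            (
                ev.chrom,
                ev.start,
                ev.end,
                ev.copy_number,
                expected_logratio(ev.copy_number, purity, ev.clonal_fraction),
            )
        )
    cn_mix = purity * cn_tumor_cell + (1 - purity) * cn_germ
    rng = platform._rng("tumor", idx)
    depth, total = platform.realize_depth(cn_mix, rng)
    table = WindowDepthTable(
        sample_id=tumor_id,
        total_mapped_bases=total,
        windows=platform.windows,
        mean_depth=depth,
        gc_fraction=platform.gc,
    )
    return table, truth_rows, purity


def simulate_cohort(
    spec: SimSpec,
) -> tuple[list[WindowDepthTable], list[WindowDepthTable], TruthSet]:
    """Full cohort: normal tables, tumor tables, combined truth."""
    platform = _Platform(spec)
    normals, truth = simulate_normal_cohort(spec)
    tumors = []
    for tid in spec.tumor_ids():
        table, somatic_rows, purity = simulate_tumor(spec, tid, platform)
        tumors.append(table)
        truth.somatic[tid] = somatic_rows
        truth.purity[tid] = purity
    return normals, tumors, truth
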