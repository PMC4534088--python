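"""Shared genomic containers and configuration.

All coordinates are 0-based half-open internally (BED convention); the
SEG-style call table is the only place 1-based inclusive coordinates appear.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TargetRegions",
    "GenomicWindows",
    "WindowDepthTable",
    "WindowTrack",
    "Segment",
    "SCNACall",
    "CohortManifest",
    "ManifestEntry",
    "ChromDirectionModel",
    "NoiseModel",
    "PipelineConfig",
    "chrom_sort_key",
]

POSITIVE = "positive"
NEGATIVE = "negative"
DIRECTIONS = (POSITIVE, NEGATIVE)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so chr2 sorts before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class TargetRegions:
    """Sorted, merged capture-target intervals (0-based half-open)."""

    chrom: tuple[str, ...]
    start: np.ndarray
    end: np.ndarray

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "TargetRegions":
        recs = sorted(records, key=lambda r: (chrom_sort_key(r[0]), r[1], r[2]))
        if not recs:
            raise ValueError("no target regions")
        for c, s, e in recs:
            if s >= e:
                raise ValueError(f"invalid region {c}:{s}-{e} (start >= end)")
            if s < 0:
                raise ValueError(f"negative coordinate in region {c}:{s}-{e}")
        merged: list[list] = []
        for c, s, e in recs:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], e)
            else:
                merged.append([c, s, e])
        return cls(
            chrom=tuple(m[0] for m in merged),
            start=np.asarray([m[1] for m in merged], dtype=np.int64),
            end=np.asarray([m[2] for m in merged], dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def span_end(self, chrom: str) -> int:
        ends = [e for c, e in zip(self.chrom, self.end) if c == chrom]
        if not ends:
            raise KeyError(chrom)
        return int(max(ends))


@dataclass(frozen=True)
class GenomicWindows:
    """A fixed tiling of windows (the shared skeleton of a cohort)."""

    chrom: np.ndarray  # object array of str
    start: np.ndarray  # int64
    end: np.ndarray  # int64

    def __post_init__(self):
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "start", np.asarray(self.start, dtype=np.int64))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.start)

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def same_tiling(self, other: "GenomicWindows") -> bool:
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.chrom, other.chrom))
            and bool(np.array_equal(self.start, other.start))
            and bool(np.array_equal(self.end, other.end))
        )

    def subset(self, mask: np.ndarray) -> "GenomicWindows":
        return GenomicWindows(self.chrom[mask], self.start[mask], self.end[mask])

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def span_end(self, chrom: str) -> int:
        m = self.chrom == chrom
        if not m.any():
            raise KeyError(chrom)
        return int(self.end[m].max())


@dataclass
class WindowDepthTable:
    """Per-window mean read depth for one sample over a shared tiling.

    ``total_mapped_bases`` is the per-sample normalizer of the window
    read-depth ratio (the count of uniquely mapped on-target bases).
    """

    sample_id: str
    total_mapped_bases: float
    windows: GenomicWindows
    mean_depth: np.ndarray
    gc_fraction: np.ndarray

    def __post_init__(self):
        self.mean_depth = np.asarray(self.mean_depth, dtype=np.float64)
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=np.float64)
        if len(self.mean_depth) != len(self.windows):
            raise ValueError("mean_depth length mismatch with windows")
        if len(self.gc_fraction) != len(self.windows):
            raise ValueError("gc_fraction length mismatch with windows")
        if not np.all(np.isfinite(self.mean_depth)) or np.any(self.mean_depth < 0):
            raise ValueError("mean_depth must be finite and >= 0")
        if self.total_mapped_bases <= 0:
            raise ValueError("total_mapped_bases must be > 0")


@dataclass
class WindowTrack:
    """Ordered per-window values: depth, GC fraction, or log2 ratio."""

    windows: GenomicWindows
    values: np.ndarray
    kind: str  # depth | gc | log_ratio

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.windows):
            raise ValueError("values length mismatch with windows")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, mask: np.ndarray) -> "WindowTrack":
        return WindowTrack(self.windows.subset(mask), self.values[mask], self.kind)


@dataclass(frozen=True)
class Segment:
    """A maximal run of windows sharing one segmental log2 ratio."""

    chrom: str
    start: int  # 0-based inclusive (first member window start)
    end: int  # 0-based exclusive (last member window end)
    n_windows: int
    seg_logratio: float
    flags: tuple[str, ...] = ()

    def shifted(self, delta: float) -> "Segment":
        return replace(self, seg_logratio=self.seg_logratio - delta)


@dataclass(frozen=True)
class SCNACall:
    """A segment in a tumor-normal comparison with its noise-tail p-value."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_windows: int
    seg_logratio: float
    direction: str  # amplification | deletion | neutral
    p_value: float | None
    p_adjusted: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    role: str  # normal | tumor
    path: str
    matched_normal: str | None = None


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]
    pooled_normal: bool = False

    def __post_init__(self):
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in manifest")
        normals = {e.sample_id for e in self.entries if e.role == "normal"}
        for e in self.entries:
            if e.role not in ("normal", "tumor"):
                raise ValueError(f"unknown role {e.role!r} for {e.sample_id}")
            if e.role == "tumor" and not self.pooled_normal:
                if e.matched_normal not in normals:
                    raise ValueError(
                        f"tumor {e.sample_id} names no existing matched normal "
                        "and pooled-normal mode is off"
                    )

    def normals(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "normal"]

    def tumors(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == "tumor"]


@dataclass
class ChromDirectionModel:
    """Noise summary for one chromosome and one log-ratio sign."""

    chrom: str
    direction: str
    r_tf: float
    r_te: float
    r_nt: float
    silhouette: float | None
    k: int
    xi: float | None
    mu: float | None
    sigma: float | None
    modeled: bool
    flags: tuple[str, ...] = ()


@dataclass
class NoiseModel:
    """Chromosome x direction noise thresholds and GEV parameters."""

    tile_width: int
    grid_step: float
    grid_max: float
    bin_size: int
    seed: int
    n_comparisons: int
    entries: dict[tuple[str, str], ChromDirectionModel] = field(default_factory=dict)

    def grid(self) -> np.ndarray:
        n = int(round(self.grid_max / self.grid_step)) + 1
        return np.round(np.arange(n) * self.grid_step, 10)

    def get(self, chrom: str, direction: str) -> ChromDirectionModel | None:
        return self.entries.get((chrom, direction))

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.entries}, key=chrom_sort_key)


@dataclass
class PipelineConfig:
    """All tunable knobs of the depth-ratio / CBS / noise pipeline."""

    tile_width: int = 100
    min_depth: float = 10.0
    min_mapq: int = 20
    gc_bins: int = 50
    gc_min_bin_windows: int = 20
    alpha_split: float = 0.01
    n_perm: int = 1000
    min_seg_windows: int = 3
    merge_tol: float = 0.05
    grid_step: float = 0.05
    grid_max: float = 1.0
    bin_size: int = 10_000
    min_extremes: int = 15
    alpha: float = 0.05
    seed: int = 17
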