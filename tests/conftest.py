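"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from evdcnv.core import GenomicWindows, PipelineConfig, TargetRegions, WindowDepthTable
from evdcnv.simulate import GermlineCNV, SimSpec


def make_windows(n: int, width: int = 100, chrom: str = "chr1") -> GenomicWindows:
    starts = np.arange(n) * width
    return GenomicWindows(
        np.array([chrom] * n, dtype=object), starts, starts + width
    )


def make_depth_table(
    depths,
    sample_id: str = "S",
    gc=None,
    windows: GenomicWindows | None = None,
    total: float | None = None,
) -> WindowDepthTable:
    depths = np.asarray(depths, dtype=float)
    if windows is None:
        windows = make_windows(len(depths))
    if gc is None:
        gc = np.full(len(depths), 0.5)
    lengths = windows.lengths().astype(float)
    if total is None:
        total = float((depths * lengths).sum())
    return WindowDepthTable(
        sample_id=sample_id,
        total_mapped_bases=total,
        windows=windows,
        mean_depth=depths,
        gc_fraction=np.asarray(gc, dtype=float),
    )


def small_cohort_spec(seed: int, n_normals: int = 16, n_tumors: int = 0, **kw) -> SimSpec:
    """Compact two-chromosome cohort used for noise-threshold studies."""
    defaults = dict(
        n_normals=n_normals,
        n_tumors=n_tumors,
        genome=(("chr1", 200_000, 0.1), ("chr2", 200_000, 0.1)),
        germline_cnvs=(GermlineCNV("chr1", 60_000, 75_000, 3, 0.2),),
        seed=seed,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


def calling_cohort_spec(seed: int, n_tumors: int = 20, **kw) -> SimSpec:
    """Four-chromosome cohort used for end-to-end calling studies."""
    defaults = dict(
        n_normals=16,
        n_tumors=n_tumors,
        genome=tuple((f"chr{i + 1}", 250_000, 0.1) for i in range(4)),
        germline_cnvs=(GermlineCNV("chr1", 60_000, 75_000, 3, 0.2),),
        events_per_tumor=2,
        event_windows=(60, 80),
        seed=seed,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Scaled-down segmentation config for simulation-heavy tests."""
    return PipelineConfig(n_perm=100, gc_bins=12)


@pytest.fixture(scope="session")
def targets_300bp() -> TargetRegions:
    return TargetRegions.from_records([("chr1", 0, 300)])
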