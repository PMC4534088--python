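"""Readers and writers for every external representation the tool touches.

BED targets and window-depth tables come in; SEG-style call tables and a
YAML noise-model document go out.  Internal coordinates are 0-based
half-open throughout; the SEG-style call table alone uses 1-based
inclusive coordinates, matching that format's convention.  All round
trips are identities to 6 decimal places.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .core import (
    DIRECTIONS,
    ChromDirectionModel,
    CohortManifest,
    GenomicWindows,
    ManifestEntry,
    NoiseModel,
    SCNACall,
    TargetRegions,
    WindowDepthTable,
    chrom_sort_key,
)

__all__ = [
    "read_bed_targets",
    "compute_window_depth",
    "write_depth_table",
    "read_depth_table",
    "write_calls",
    "read_calls",
    "write_model",
    "read_model",
    "read_manifest",
    "write_manifest",
]

log = logging.getLogger(__name__)

MODEL_FORMAT = "evdcnv-noise-model"
MODEL_VERSION = 1

CALL_COLUMNS = (
    "sample",
    "chrom",
    "start",
    "end",
    "num_windows",
    "seg_logratio",
    "direction",
    "p_value",
    "p_adjusted",
)


class ParseError(ValueError):
    pass


def read_bed_targets(path) -> TargetRegions:
    """Load a BED target file into merged, sorted regions.

    Overlapping or book-ended records on one chromosome merge on load.
    Malformed lines raise a parse error naming the line number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            records.append((chrom, start, end))
    if not records:
        raise ParseError(f"{path}: no target regions found")
    return TargetRegions.from_records(records)


def compute_window_depth(
    alignment_path,
    windows: GenomicWindows,
    min_mapq: int = 20,
    sample_id: str | None = None,
    gc_fraction: np.ndarray | None = None,
) -> WindowDepthTable:
    """Mean per-base depth per window from an indexed alignment.

    Duplicate-marked, secondary and supplementary alignments are excluded,
    as are reads below ``min_mapq`` (a guard against multi-mapping
    inflation).  ``total_mapped_bases`` sums depth x length over the
    target windows, keeping the table self-contained as the ratio
    normalizer.
    """
    import pysam

    with pysam.AlignmentFile(str(alignment_path)) as af:
        if not af.has_index():
            raise ValueError(f"{alignment_path}: alignment index required")
        refs = set(af.references)
        missing = sorted(set(windows.chromosomes()) - refs)
        if missing:
            raise ValueError(
                f"{alignment_path}: chromosomes absent from alignment header: "
                + ", ".join(missing)
            )

        def _keep(read) -> bool:
            return (
                not read.is_duplicate
                and not read.is_secondary
                and not read.is_supplementary
                and not read.is_unmapped
                and read.mapping_quality >= min_mapq
            )

        depth = np.zeros(len(windows))
        for i, (chrom, start, end) in enumerate(
            zip(windows.chrom, windows.start, windows.end)
        ):
            cov = af.count_coverage(
                chrom, int(start), int(end), quality_threshold=0, read_callback=_keep
            )
            depth[i] = np.asarray(cov).sum() / (end - start)
    lengths = windows.lengths().astype(float)
    total = float((depth * lengths).sum())
    if total <= 0:
        raise ValueError(f"{alignment_path}: no mapped bases over the target windows")
    if gc_fraction is None:
        gc_fraction = np.full(len(windows), np.nan)
    return WindowDepthTable(
        sample_id=sample_id or Path(str(alignment_path)).stem,
        total_mapped_bases=total,
        windows=windows,
        mean_depth=depth,
        gc_fraction=gc_fraction,
    )


def write_depth_table(table: WindowDepthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={table.sample_id}\n")
        fh.write(f"#total_mapped_bases={table.total_mapped_bases:.6f}\n")
        fh.write("chrom\tstart\tend\tmean_depth\tgc_fraction\n")
        for c, s, e, d, g in zip(
            table.windows.chrom,
            table.windows.start,
            table.windows.end,
            table.mean_depth,
            table.gc_fraction,
        ):
            fh.write(f"{c}\t{s}\t{e}\t{d:.6f}\t{g:.6f}\n")


def read_depth_table(path) -> WindowDepthTable:
    sample_id = None
    total = None
    chroms, starts, ends, depths, gcs = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "sample_id":
                    sample_id = value
                elif key == "total_mapped_bases":
                    total = float(value)
                continue
            if line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            depths.append(float(fields[3]))
            gcs.append(float(fields[4]))
    if sample_id is None or total is None:
        raise ParseError(f"{path}: missing #sample_id or #total_mapped_bases header")
    return WindowDepthTable(
        sample_id=sample_id,
        total_mapped_bases=total,
        windows=GenomicWindows(np.array(chroms, dtype=object), starts, ends),
        mean_depth=depths,
        gc_fraction=gcs,
    )


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "NA"
    if 0 < p < 1e-4:
        return f"{p:.6e}"
    return f"{p:.6f}"


def write_calls(calls: list[SCNACall], path) -> None:
    """Write a SEG-style call table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.chrom,
                        str(c.start + 1),
                        str(c.end),
                        str(c.n_windows),
                        f"{c.seg_logratio:.6f}",
                        c.direction,
                        _fmt_p(c.p_value),
                        _fmt_p(c.p_adjusted),
                    ]
                )
                + "\n"
            )


def read_calls(path) -> list[SCNACall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CALL_COLUMNS:
            raise ParseError(f"{path}: unexpected call-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(CALL_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(CALL_COLUMNS)} columns")
            calls.append(
                SCNACall(
                    sample_id=f[0],
                    chrom=f[1],
                    start=int(f[2]) - 1,
                    end=int(f[3]),
                    n_windows=int(f[4]),
                    seg_logratio=float(f[5]),
                    direction=f[6],
                    p_value=None if f[7] == "NA" else float(f[7]),
                    p_adjusted=None if f[8] == "NA" else float(f[8]),
                )
            )
    return calls


def _entry_to_dict(e: ChromDirectionModel) -> dict:
    d = {
        "r_tf": float(e.r_tf),
        "r_te": float(e.r_te),
        "r_nt": float(e.r_nt),
        "silhouette": None if e.silhouette is None else float(e.silhouette),
        "k": int(e.k),
        "modeled": bool(e.modeled),
        "flags": list(e.flags),
    }
    if e.modeled:
        d.update(xi=float(e.xi), mu=float(e.mu), sigma=float(e.sigma))
    return d


def write_model(model: NoiseModel, path) -> None:
    """Serialize the noise model to a self-describing YAML document."""
    chroms: dict[str, dict] = {}
    for (chrom, direction), entry in sorted(
        model.entries.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1])
    ):
        chroms.setdefault(chrom, {})[direction] = _entry_to_dict(entry)
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "tile_width": int(model.tile_width),
        "grid_step": float(model.grid_step),
        "grid_max": float(model.grid_max),
        "bin_size": int(model.bin_size),
        "seed": int(model.seed),
        "n_comparisons": int(model.n_comparisons),
        "chromosomes": chroms,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path) -> NoiseModel:
    """Load a noise model; the file's grid and tiling are authoritative."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ParseError(f"{path}: not a noise-model document")
    if doc.get("version") != MODEL_VERSION:
        raise ParseError(
            f"{path}: model version {doc.get('version')!r} != supported {MODEL_VERSION}"
        )
    model = NoiseModel(
        tile_width=int(doc["tile_width"]),
        grid_step=float(doc["grid_step"]),
        grid_max=float(doc["grid_max"]),
        bin_size=int(doc["bin_size"]),
        seed=int(doc["seed"]),
        n_comparisons=int(doc["n_comparisons"]),
    )
    for chrom, dirs in doc.get("chromosomes", {}).items():
        for direction in DIRECTIONS:
            if direction not in dirs:
                raise ParseError(
                    f"{path}: missing model entry for {chrom}/{direction}"
                )
            d = dirs[direction]
            modeled = bool(d.get("modeled", False))
            required = ("r_tf", "r_te", "r_nt", "k")
            for key in required:
                if key not in d:
                    raise ParseError(
                        f"{path}: missing parameter {key!r} for {chrom}/{direction}"
                    )
            if modeled:
                for key in ("xi", "mu", "sigma"):
                    if key not in d:
                        raise ParseError(
                            f"{path}: missing parameter {key!r} for {chrom}/{direction}"
                        )
            model.entries[(chrom, direction)] = ChromDirectionModel(
                chrom=chrom,
                direction=direction,
                r_tf=float(d["r_tf"]),
                r_te=float(d["r_te"]),
                r_nt=float(d["r_nt"]),
                silhouette=None if d.get("silhouette") is None else float(d["silhouette"]),
                k=int(d["k"]),
                xi=float(d["xi"]) if modeled else None,
                mu=float(d["mu"]) if modeled else None,
                sigma=float(d["sigma"]) if modeled else None,
                modeled=modeled,
                flags=tuple(d.get("flags", [])),
            )
    return model


def read_manifest(path) -> CohortManifest:
    """TSV manifest: sample_id, role, path, matched_normal (or '-')."""
    entries = []
    pooled = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.strip() == "#pooled_normal=true":
                    pooled = True
                continue
            if line.startswith("sample_id\t"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            matched = f[3] if len(f) > 3 and f[3] not in ("", "-") else None
            entries.append(ManifestEntry(f[0], f[1], f[2], matched))
    return CohortManifest(entries=entries, pooled_normal=pooled)


def write_manifest(manifest: CohortManifest, path) -> None:
    with open(path, "w") as fh:
        if manifest.pooled_normal:
            fh.write("#pooled_normal=true\n")
        fh.write("sample_id\trole\tpath\tmatched_normal\n")
        for e in manifest.entries:
            fh.write(
                f"{e.sample_id}\t{e.role}\t{e.path}\t{e.matched_normal or '-'}\n"
            )
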