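"""Plain-text readers and writers for the pipeline's tabular artifacts.

Matrices travel as CSV with a header row of algorithm ids and a first
column of instance ids; the aggregation mode is recorded in a JSON sidecar
(``<path>.meta.json``).  Run records use long-format TSV.  Fingerprints are
additionally accepted as one 0/1 string per instance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable
from .performance import PerformanceMatrix, RankMatrix, RunRecord

RUN_RECORD_COLUMNS = ["instance_id", "algorithm_id", "run_index", "binding_energy"]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_performance_csv(perf: PerformanceMatrix, path: str | Path) -> None:
    path = Path(path)
    perf.to_frame().to_csv(path, index_label="instance_id")
    _sidecar(path).write_text(json.dumps({"mode": perf.mode}) + "\n")


def read_performance_csv(path: str | Path, mode: str | None = None) -> PerformanceMatrix:
    path = Path(path)
    if mode is None:
        meta = _sidecar(path)
        if not meta.exists():
            raise ValueError(f"no mode given and no sidecar {meta} found")
        mode = json.loads(meta.read_text())["mode"]
    frame = pd.read_csv(path, index_col=0)
    return PerformanceMatrix(
        values=frame.to_numpy(dtype=float),
        row_ids=tuple(str(i) for i in frame.index),
        col_ids=tuple(str(c) for c in frame.columns),
        mode=mode,
    )


def write_rank_csv(ranks: RankMatrix, path: str | Path) -> None:
    ranks.to_frame().to_csv(path, index_label="instance_id")


def read_rank_csv(path: str | Path) -> RankMatrix:
    frame = pd.read_csv(path, index_col=0)
    return RankMatrix(
        ranks=frame.to_numpy(dtype=float),
        row_ids=tuple(str(i) for i in frame.index),
        col_ids=tuple(str(c) for c in frame.columns),
    )


def write_run_records_tsv(records: list[RunRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.instance_id, r.algorithm_id, r.run_index, r.binding_energy) for r in records],
        columns=RUN_RECORD_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_run_records_tsv(path: str | Path) -> list[RunRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RUN_RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"run-record TSV missing columns: {missing}")
    return [
        RunRecord(
            instance_id=str(row.instance_id),
            algorithm_id=str(row.algorithm_id),
            run_index=int(row.run_index),
            binding_energy=float(row.binding_energy),
        )
        for row in frame.itertuples(index=False)
    ]


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="instance_id")


def read_feature_csv(path: str | Path, kind: str = "md") -> FeatureTable:
    frame = pd.read_csv(path, index_col=0)
    return FeatureTable.from_frame(frame, kind=kind)


def read_fingerprint_strings(path: str | Path) -> FeatureTable:
    """Read fingerprints given as ``instance_id<TAB>0/1-string`` lines."""
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'id<TAB>bits', got {line!r}")
        rows.append((parts[0], parts[1].strip()))
    if not rows:
        raise ValueError("no fingerprint lines found")
    length = len(rows[0][1])
    values = np.empty((len(rows), length))
    for i, (inst, bits) in enumerate(rows):
        if len(bits) != length or set(bits) - {"0", "1"}:
            raise ValueError(f"instance {inst!r}: bits must be a {length}-char 0/1 string")
        values[i] = [int(b) for b in bits]
    return FeatureTable(
        values=values,
        row_ids=tuple(r[0] for r in rows),
        feature_names=tuple(f"fp{b}" for b in range(length)),
        kind="sf",
    )


def write_benchmark(benchmark, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic benchmark's artifacts (TSV/CSV) into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "run_records": outdir / "run_records.tsv",
        "descriptors": outdir / "descriptors.csv",
        "fingerprints": outdir / "fingerprints.csv",
        "truth": outdir / "truth.csv",
    }
    write_run_records_tsv(benchmark.run_records, paths["run_records"])
    write_feature_csv(benchmark.descriptor_features, paths["descriptors"])
    write_feature_csv(benchmark.fingerprint_features, paths["fingerprints"])
    benchmark.truth.to_csv(paths["truth"], index=False)
    return paths
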