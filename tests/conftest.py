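import numpy as np
import pytest

from dockselect import (
    FeatureTable,
    PerformanceMatrix,
    SelectorConfig,
    SyntheticConfig,
    aggregate_runs,
    generate_benchmark,
    rank_transform,
)


def make_dlg(energies, garbage_lines=True):
    """Compose a minimal AutoDock-4-style docking log with one run per energy."""
    lines = ["AutoDock 4.2 Release", ""]
    for i, e in enumerate(energies, start=1):
        if garbage_lines:
            lines += [f"Run {i} of {len(energies)}", "DOCKED: MODEL"]
        lines.append(
            f"DOCKED: USER    Estimated Free Energy of Binding    =  {e:+.2f} kcal/mol"
        )
        lines.append("DOCKED: ENDMDL")
    lines.append("CLUSTERING HISTOGRAM")
    return "\n".join(lines)


def perf_from_array(values, mode="AVG", row_prefix="i", col_prefix="A"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return PerformanceMatrix(
        values=values,
        row_ids=tuple(f"{row_prefix}{i + 1}" for i in range(m)),
        col_ids=tuple(f"{col_prefix}{j + 1}" for j in range(n)),
        mode=mode,
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A quick low-noise benchmark with strong planted structure."""
    cfg = SyntheticConfig(
        n_instances=90,
        n_algorithms=6,
        n_clusters=3,
        n_runs=6,
        n_informative_features=6,
        n_noise_features=20,
        run_noise_sd=0.1,
        cluster_gap=2.0,
        seed=7,
    )
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def small_perf(small_benchmark):
    b = small_benchmark
    return aggregate_runs(
        b.run_records, "AVG", row_order=b.instance_ids, col_order=b.algorithm_ids
    )


@pytest.fixture(scope="session")
def small_ranks(small_perf):
    return rank_transform(small_perf)


@pytest.fixture(scope="session")
def small_selector_config():
    return SelectorConfig(k=4, n_trees=50, seed=7)
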