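import numpy as np
import pandas as pd
import pytest

import stresstf as st


@pytest.fixture(scope="session")
def toy_matrix():
    """Two-group, 5-gene toy with hand-checkable size factors."""
    counts = pd.DataFrame(
        {
            "a1": [10, 20, 30, 100, 5],
            "a2": [12, 18, 33, 90, 6],
            "a3": [11, 22, 27, 110, 4],
            "b1": [40, 21, 29, 95, 5],
            "b2": [44, 19, 31, 105, 6],
            "b3": [39, 20, 30, 100, 5],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    samples = pd.DataFrame(
        {
            "strain": ["x"] * 6,
            "condition": ["A"] * 3 + ["B"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=counts.columns,
    )
    return st.CountMatrix(counts, samples)


@pytest.fixture(scope="session")
def planted_run():
    """Planted simulation plus full 4-contrast DE at the default thresholds.

    100 planted consensus genes (2000 x 0.05), one bifurcated gene, default
    effect sizes (|lfc| >= 1)."""
    cfg = st.SimulationConfig(n_genes=2000, de_fraction_strain=0.05, seed=0)
    matrix, truth = st.simulate_counts(cfg)
    size_factors = st.estimate_size_factors(matrix)
    gene_sets = []
    for cond in cfg.conditions:
        spec = st.ContrastSpec(
            f"{cond}:resistant_vs_control",
            matrix.samples_where(strain="resistant", condition=cond),
            matrix.samples_where(strain="control", condition=cond),
        )
        sub = matrix.subset_samples(list(spec.samples))
        disp = st.estimate_dispersion(
            sub, size_factors.reindex(sub.sample_ids), groups=[spec.group_a, spec.group_b]
        )
        result = st.wald_test(matrix, size_factors, disp, spec)
        gene_sets.append(st.call_de(result))
    return cfg, matrix, truth, gene_sets


def brute_force_bh(p):
    """Textbook step-up BH: p_(i) * m / i with right-to-left cummin."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
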