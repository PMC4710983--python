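import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import stresstf as st
from stresstf.de import SizeFactorError, adjust_bh

from conftest import brute_force_bh


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        sf = st.estimate_size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_hand_computed(self):
        # B = 2 x A exactly: geometric mean sqrt(2)*A, ratios 1/sqrt2 and sqrt2
        a = np.array([10, 20, 30, 100, 5])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        sf = st.estimate_size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])
        assert sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_single_gene_matrix(self):
        counts = pd.DataFrame({"A": [10], "B": [40]})
        sf = st.estimate_size_factors(counts)
        assert np.allclose(sf, [0.5, 2.0])

    def test_no_zero_free_gene_errors_and_fallback(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [7, 0]})
        with pytest.raises(SizeFactorError, match="pseudo_reference"):
            st.estimate_size_factors(counts)
        sf = st.estimate_size_factors(counts, pseudo_reference=True)
        assert np.all(sf > 0)

    def test_scaling_one_sample_rescales_only_its_relative_factor(self):
        # size factors are defined up to a common scale: tripling sample c
        # triples sf_c relative to every other sample and leaves the other
        # ratios untouched
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(100, size=(200, 4)) + 1, columns=list("abcd")
        )
        sf = st.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf2 = st.estimate_size_factors(scaled)
        assert sf2["c"] / sf2["a"] == pytest.approx(3 * sf["c"] / sf["a"], rel=1e-9)
        for s in "bd":
            assert sf2[s] / sf2["a"] == pytest.approx(sf[s] / sf["a"], rel=1e-9)


class TestDispersion:
    def test_constant_counts_raw_at_floor(self):
        counts = pd.DataFrame({s: [50, 200] for s in ("a", "b", "c", "d")})
        sf = pd.Series(1.0, index=counts.columns)
        raw = st.estimate_dispersion(counts, sf, shrink=False)
        assert np.allclose(raw, 1e-8)

    def test_poisson_counts_raw_mostly_at_floor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(500, size=(500, 6)))
        counts.columns = [f"s{i}" for i in range(6)]
        sf = pd.Series(1.0, index=counts.columns)
        raw = st.estimate_dispersion(counts, sf, shrink=False)
        # (s^2 - m)/m^2 <= 0 for about half of Poisson genes -> floored
        assert (raw <= 1e-8).mean() > 0.3
        assert raw.median() < 0.005

    def test_nb_dispersion_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        alpha, mu, n = 0.1, 500.0, 50
        r = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(300, 2 * n))
        )
        counts.columns = [f"s{i}" for i in range(2 * n)]
        sf = pd.Series(1.0, index=counts.columns)
        groups = [counts.columns[:n], counts.columns[n:]]
        est = st.estimate_dispersion(counts, sf, groups=groups)
        assert est.mean() == pytest.approx(alpha, rel=0.2)

    def test_between_group_signal_not_counted_as_dispersion(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            np.hstack(
                [rng.poisson(100, size=(200, 3)), rng.poisson(800, size=(200, 3))]
            ),
            columns=[f"s{i}" for i in range(6)],
        )
        sf = pd.Series(1.0, index=counts.columns)
        grouped = st.estimate_dispersion(
            counts, sf, groups=[counts.columns[:3], counts.columns[3:]], shrink=False
        )
        pooled = st.estimate_dispersion(counts, sf, shrink=False)
        assert grouped.median() < 0.01 < pooled.median()


class TestBH:
    def test_hand_example(self):
        padj = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert np.allclose(adjust_bh(np.array([1.0, 1.0, 1.0])), 1.0)
        assert adjust_bh(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_nan_propagation_and_universe(self):
        p = pd.Series([0.01, np.nan, 0.02, 0.03, 0.04])
        padj = adjust_bh(p)
        assert np.isnan(padj.iloc[1])
        assert np.allclose(padj.dropna(), brute_force_bh([0.01, 0.02, 0.03, 0.04]))

    @settings(derandomize=True, max_examples=50)
    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(
            adjust_bh(np.array(pvals)), brute_force_bh(pvals), atol=1e-12
        )

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        assert np.all(adjust_bh(p) >= p - 1e-15)


def _toy_single_gene(counts_a, counts_b, alpha=1e-8):
    counts = pd.DataFrame(
        [list(counts_a) + list(counts_b)],
        index=["g1"],
        columns=[f"a{i}" for i in range(len(counts_a))]
        + [f"b{i}" for i in range(len(counts_b))],
    )
    samples = pd.DataFrame(
        {
            "strain": ["x"] * len(counts.columns),
            "condition": ["A"] * len(counts_a) + ["B"] * len(counts_b),
            "replicate": list(range(len(counts_a))) + list(range(len(counts_b))),
        },
        index=counts.columns,
    )
    matrix = st.CountMatrix(counts, samples)
    sf = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(alpha, index=["g1"])
    spec = st.ContrastSpec(
        "toy", list(counts.columns[: len(counts_a)]), list(counts.columns[len(counts_a):])
    )
    return st.wald_test(matrix, sf, disp, spec)


class TestWald:
    def test_identical_groups_null(self):
        res = _toy_single_gene((30, 40, 50), (30, 40, 50), alpha=0.05)
        row = res.table.iloc[0]
        assert row["log2FoldChange"] == pytest.approx(0.0, abs=1e-6)
        assert row["pvalue"] == pytest.approx(1.0, abs=1e-4)

    def test_fourfold_toy_lfc_about_two(self):
        res = _toy_single_gene((40, 44, 39), (10, 12, 11))
        row = res.table.iloc[0]
        assert row["log2FoldChange"] == pytest.approx(2.0, abs=0.15)
        assert row["baseMean"] == pytest.approx(np.mean([40, 44, 39, 10, 12, 11]))
        assert row["stat"] == pytest.approx(row["log2FoldChange"] / row["lfcSE"])

    def test_matches_statsmodels_glm_oracle(self):
        import statsmodels.api as sm

        res = _toy_single_gene((10, 12, 11), (40, 44, 39))
        y = np.array([10, 12, 11, 40, 44, 39])
        X = sm.add_constant(np.array([1, 1, 1, 0, 0, 0]))
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1e-8)).fit()
        row = res.table.iloc[0]
        assert row["stat"] == pytest.approx(fit.tvalues[1], rel=1e-6)
        assert row["pvalue"] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 40], "b2": [0, 39]},
            index=["gz", "g1"],
        )
        samples = pd.DataFrame(
            {"strain": ["x"] * 4, "condition": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]},
            index=counts.columns,
        )
        matrix = st.CountMatrix(counts, samples)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.01, index=counts.index)
        res = st.wald_test(
            matrix, sf, disp, st.ContrastSpec("c", ["a1", "a2"], ["b1", "b2"])
        )
        assert np.isnan(res.table.loc["gz", "pvalue"])
        assert np.isfinite(res.table.loc["g1", "pvalue"])
        # BH universe excludes the untested gene
        assert res.table.loc["g1", "padj"] == pytest.approx(
            res.table.loc["g1", "pvalue"]
        )

    def test_lfc_invariant_to_library_scaling(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.poisson(1000, size=(200, 6)),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        samples = pd.DataFrame(
            {"strain": ["x"] * 6, "condition": ["A"] * 3 + ["B"] * 3,
             "replicate": [1, 2, 3, 1, 2, 3]},
            index=counts.columns,
        )
        matrix = st.CountMatrix(counts, samples)
        disp = pd.Series(0.01, index=matrix.genes)
        spec = st.ContrastSpec("c", ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        res = st.wald_test(matrix, st.estimate_size_factors(matrix), disp, spec)
        scaled_counts = counts.copy()
        scaled_counts["a1"] = scaled_counts["a1"] * 4
        scaled = st.CountMatrix(scaled_counts, samples)
        res2 = st.wald_test(scaled, st.estimate_size_factors(scaled), disp, spec)
        # size factors absorb the scaling; NB weighting leaves only a
        # negligible dependence on the absolute normalized scale
        assert np.allclose(
            res.table["log2FoldChange"], res2.table["log2FoldChange"], atol=0.01
        )

    @staticmethod
    def _rejection_rate(rng, lfc, n, mu_b=500.0, alpha=0.02, n_genes=400):
        mu_a = mu_b * 2**lfc
        r = 1 / alpha
        a = rng.negative_binomial(r, r / (r + mu_a), size=(n_genes, n))
        b = rng.negative_binomial(r, r / (r + mu_b), size=(n_genes, n))
        counts = pd.DataFrame(
            np.hstack([a, b]), columns=[f"s{i}" for i in range(2 * n)]
        )
        samples = pd.DataFrame(
            {"strain": "x", "condition": ["A"] * n + ["B"] * n,
             "replicate": list(range(n)) * 2},
            index=counts.columns,
        )
        matrix = st.CountMatrix(counts, samples)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(alpha, index=counts.index)
        res = st.wald_test(
            matrix, sf, disp,
            st.ContrastSpec("c", counts.columns[:n], counts.columns[n:]),
        )
        return (res.table["pvalue"] < 0.001).mean()

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(4)
        rates = [self._rejection_rate(rng, lfc, n=3) for lfc in (0.2, 0.4, 0.8)]
        assert rates[0] < rates[1] < rates[2]

    def test_power_monotone_in_replicates(self):
        rng = np.random.default_rng(6)
        rates = [self._rejection_rate(rng, 0.4, n=n) for n in (3, 6, 12)]
        assert rates[0] < rates[1] < rates[2]


class TestCallDE:
    def _result(self, rows):
        table = pd.DataFrame(
            rows,
            columns=["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        return st.ContrastResult("t", table, pd.Series(dtype=float))

    def test_empty_result(self):
        out = st.call_de(self._result([]))
        assert out.called == frozenset()

    def test_base_mean_boundary_exclusive_below(self):
        out = st.call_de(
            self._result([[999.9, 3.0, 0.1, 30.0, 1e-12, 1e-9]])
        )
        assert out.called == frozenset()

    def test_thresholds_inclusive_and_enumerated(self):
        rows = [
            [1000.0, 2.0, 0.1, 20.0, 1e-9, 0.001],   # both at boundary -> called up
            [5000.0, -1.5, 0.1, -15.0, 1e-9, 1e-6],  # called down
            [500.0, 2.0, 0.1, 20.0, 1e-9, 1e-6],     # fails abundance
            [5000.0, 2.0, 0.1, 20.0, 1e-2, 0.0011],  # fails significance
            [999.0, 0.5, 0.5, 1.0, 0.3, 0.5],        # fails both
            [2000.0, 1.0, 0.1, 10.0, 1e-9, 1e-7],    # called up
        ]
        out = st.call_de(self._result(rows))
        assert out.up == frozenset({"g0", "g5"})
        assert out.down == frozenset({"g1"})

    def test_nan_padj_never_called(self):
        out = st.call_de(self._result([[5000.0, np.nan, np.nan, np.nan, np.nan, np.nan]]))
        assert out.called == frozenset()

    def test_invariant_under_gene_reordering(self):
        rows = [
            [2000.0, 1.0, 0.1, 10.0, 1e-9, 1e-7],
            [3000.0, -1.0, 0.1, -10.0, 1e-9, 1e-7],
            [500.0, 1.0, 0.1, 10.0, 1e-9, 1e-7],
        ]
        res = self._result(rows)
        shuffled = st.ContrastResult(
            "t", res.table.iloc[[2, 0, 1]], pd.Series(dtype=float)
        )
        assert st.call_de(res).called == st.call_de(shuffled).called


def test_pydeseq2_cross_check_lfc_agreement():
    """Independent cross-check: LFC estimates agree with pyDESeq2 on a
    simulated two-group matrix (different dispersion machinery, same model)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    import warnings
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    cfg = st.SimulationConfig(n_genes=300, conditions=("blank", "AA"), seed=3)
    matrix, _ = st.simulate_counts(cfg)
    ids = matrix.samples_where(condition="AA")
    sub = matrix.subset_samples(ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=sub.counts.T,
            metadata=sub.samples[["strain"]],
            design="~strain",
            quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["strain", "resistant", "control"], quiet=True)
        ds.summary()
    sf = st.estimate_size_factors(sub)
    spec = st.ContrastSpec(
        "AA",
        matrix.samples_where(condition="AA", strain="resistant"),
        matrix.samples_where(condition="AA", strain="control"),
    )
    disp = st.estimate_dispersion(sub, sf, groups=[spec.group_a, spec.group_b])
    mine = st.wald_test(sub, sf, disp, spec).table
    theirs = ds.results_df
    r = np.corrcoef(mine["log2FoldChange"], theirs["log2FoldChange"])[0, 1]
    assert r > 0.999
    assert np.allclose(mine["baseMean"], theirs["baseMean"], rtol=1e-6)
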