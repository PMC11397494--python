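import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from cneaccel.expression import (
    classify_sex_bias,
    de_test,
    neighbor_bias_proportions,
    normalize_counts,
    transition_association,
)
from cneaccel.stats import fisher_exact_2x3, odds_ratio_2x2


def nb_counts(rng, means, dispersion):
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + np.asarray(means)))


class TestNormalization:
    def test_identical_samples_equal_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 200)
        counts = pd.DataFrame({"s1": col, "s2": col})
        f = normalize_counts(counts)
        assert np.isclose(f["s1"], f["s2"])

    def test_doubled_sample_has_double_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = normalize_counts(counts)
        assert np.isclose(f["b"] / f["a"], 2.0, rtol=0.01)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(30, (100, 3)), columns=list("abc"))
        f1 = normalize_counts(counts)
        f2 = normalize_counts(counts.iloc[::-1])
        assert np.allclose(f1, f2)

    def test_upper_quartile_fallback(self, caplog):
        counts = pd.DataFrame(
            {"a": [0, 10, 20, 30], "b": [5, 0, 40, 60]}
        )  # no gene nonzero in all samples? gene 2,3 are; make one zero
        counts.iloc[2, 0] = 0
        counts.iloc[3, 1] = 0
        with caplog.at_level("WARNING"):
            f = normalize_counts(counts)
        assert (f > 0).all()


class TestDeTest:
    @pytest.mark.parametrize("dispersion", [0.01, 0.1])
    def test_null_close_to_nominal(self, dispersion):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            nb_counts(rng, np.full((600, 8), 100.0), dispersion),
            columns=[f"s{i}" for i in range(8)],
        )
        de = de_test(counts, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        rate = (de["p"] < 0.05).mean()
        assert rate < 0.05 + 4 * np.sqrt(0.05 * 0.95 / 600)

    def test_planted_fourfold_recall(self):
        rng = np.random.default_rng(6)
        means = np.full((1000, 8), 100.0)
        means[:100, 4:] *= 4
        counts = pd.DataFrame(nb_counts(rng, means, 0.1), columns=[f"s{i}" for i in range(8)])
        de = de_test(counts, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert (de["q"][:100] < 0.01).mean() >= 0.9

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            nb_counts(rng, np.full((200, 8), 80.0), 0.1), columns=[f"s{i}" for i in range(8)]
        )
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        d1 = de_test(counts, a, b)
        d2 = de_test(counts, b, a)
        assert np.allclose(d1["log2fc"], -d2["log2fc"])
        assert np.allclose(d1["p"], d2["p"])

    def test_all_zero_gene_flagged_p_one(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            nb_counts(rng, np.full((50, 4), 50.0), 0.1), columns=list("abcd")
        )
        counts.iloc[0] = 0
        de = de_test(counts, ["a", "b"], ["c", "d"])
        assert de["p"].iloc[0] == 1.0 and de["all_zero"].iloc[0]

    def test_group_validation(self):
        counts = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            de_test(counts, ["a", "b"], ["b", "c"])
        with pytest.raises(ValueError):
            de_test(counts, ["a"], ["b", "c"])


class TestClassification:
    def _de(self, q, fc):
        return pd.DataFrame({"q": q, "log2fc": fc}, index=[f"g{i}" for i in range(len(q))])

    def test_threshold_boundary_and_directions(self):
        de = self._de([0.011, 0.005, 0.005], [2.0, 2.0, -2.0])
        calls = classify_sex_bias(de)
        assert list(calls) == ["Non", "XO-biased", "XX-biased"]

    def test_truth_agreement_on_simulation(self):
        from cneaccel.simulate import SimConfig, simulate_expression

        cfg = SimConfig(seed=41, n_orthologs=800)
        sim = simulate_expression(cfg)
        meta = sim.metadata.query("species=='A' and stage=='L4'")
        xx = meta.query("sex=='XX'")["sample"].tolist()
        xo = meta.query("sex=='XO'")["sample"].tolist()
        calls = classify_sex_bias(de_test(sim.counts["A"], xx, xo))
        assert (calls == sim.truth_class["A"]).mean() >= 0.9


class TestFisher2x3:
    def test_independent_margins_p_one_cases(self):
        assert fisher_exact_2x3([[0, 0, 0], [1, 2, 3]]) == 1.0
        assert fisher_exact_2x3([[5, 0, 0], [7, 0, 0]]) == 1.0

    def test_matches_r_fisher_test(self):
        # frozen from R: fisher.test(matrix(c(8,2,3,5,4,9),nrow=2,byrow=TRUE))
        p = fisher_exact_2x3([[8, 2, 3], [5, 4, 9]])
        assert np.isclose(p, 0.1775906614, atol=1e-9)

    def test_collapses_to_2x2_hypergeometric(self):
        # third column empty: equals the two-sided 2x2 exact test
        from scipy.stats import fisher_exact

        table23 = [[7, 3, 0], [2, 8, 0]]
        p22 = fisher_exact([[7, 3], [2, 8]])[1]
        assert np.isclose(fisher_exact_2x3(table23), p22, atol=1e-12)

    def test_strong_association_tiny_p(self):
        assert fisher_exact_2x3([[0, 30, 0], [85, 0, 85]]) < 1e-6


class TestNeighborProportions:
    def test_proportions_sum_to_one_and_detects_extreme_shift(self):
        genes = [f"g{i}" for i in range(200)]
        cls = pd.Series(["Non"] * 200, index=genes)
        cls.iloc[:20] = "XO-biased"
        calls = {"male_vs_herm": cls}
        res = neighbor_bias_proportions(calls, set(genes[:20]))
        row = res.iloc[0]
        props = [row[f"neighbor_prop_{c}"] for c in ("XX-biased", "XO-biased", "Non")]
        assert np.isclose(sum(props), 1.0)
        assert row["p"] < 1e-6

    def test_empty_neighbor_set_skipped(self, caplog):
        cls = pd.Series(["Non"] * 10, index=[f"g{i}" for i in range(10)])
        with caplog.at_level("WARNING"):
            res = neighbor_bias_proportions({"c": cls}, {"absent"})
        assert res.empty


class TestTransitionAssociation:
    def _calls(self, labels, prefix):
        return pd.Series(labels, index=[f"{prefix}{i}" for i in range(len(labels))])

    def test_counts_conserve_totals(self):
        rng = np.random.default_rng(9)
        n = 500
        a = self._calls(rng.choice(["XX-biased", "XO-biased", "Non"], n), "a")
        b = self._calls(rng.choice(["XX-biased", "XO-biased", "Non"], n), "b")
        orth = list(zip(a.index, b.index))
        neigh = set(a.index[:50])
        tab = transition_association(a, b, orth, neigh)
        assert tab.cells["n"].sum() == n == tab.n_orthologs
        assert tab.cells["n_neighbor"].sum() == len(neigh) == tab.n_neighbors

    def test_all_non_degenerate(self):
        a = self._calls(["Non"] * 20, "a")
        b = self._calls(["Non"] * 20, "b")
        tab = transition_association(a, b, list(zip(a.index, b.index)), {"a0"})
        assert (tab.cells["p"] == 1.0).all()
        occupied = tab.cells.query("n > 0")
        assert len(occupied) == 1

    def test_missing_call_excluded_and_counted(self):
        a = self._calls(["Non", "Non"], "a")
        b = self._calls(["Non"], "b")
        tab = transition_association(a, b, [("a0", "b0"), ("a1", "missing")], set())
        assert tab.n_orthologs == 1 and tab.n_excluded == 1

    def test_planted_cell_enrichment_detected(self):
        from cneaccel.simulate import SimConfig, simulate_expression

        cfg = SimConfig(seed=43, n_orthologs=10000, neighbor_or=3.0)
        sim = simulate_expression(cfg)
        tab = transition_association(
            sim.truth_class["A"], sim.truth_class["B"], sim.orthologs, sim.neighbor_genes
        )
        cell = tab.cells.query("class_a=='Non' and class_b=='XX-biased'").iloc[0]
        assert cell["odds_ratio"] > 1 and cell["q"] < 0.05

    def test_fisher_2x2_matches_hypergeometric_tail(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 61))
            k = int(rng.integers(1, n))
            m = int(rng.integers(1, n))
            a = int(rng.integers(max(0, k + m - n), min(k, m) + 1))
            t = [[a, k - a], [m - a, n - k - m + a]]
            one_sided = fisher_exact(t, alternative="greater")[1]
            assert np.isclose(one_sided, hypergeom.sf(a - 1, n, m, k), atol=1e-12)

    def test_odds_ratio_haldane_correction(self):
        assert odds_ratio_2x2([[2, 0], [3, 5]]) == (2.5 * 5.5) / (0.5 * 3.5)
        assert odds_ratio_2x2([[2, 1], [3, 5]], haldane=True) == pytest.approx(10 / 3)
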