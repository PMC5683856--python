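"""Dose-effect F statistics and the Welch gene-set test, checked
against hand computations and scipy as the independent reference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import biclustsig as bs
from biclustsig.io import GeneSet


def _experiment(values: np.ndarray, doses: list[str], genes=None) -> bs.DoseExperiment:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return bs.DoseExperiment(
        values=pd.DataFrame(values, index=genes, columns=samples),
        dose_of=pd.Series(doses, index=samples),
    )


class TestDoseFStatistics:
    def test_hand_computed_two_group_anova(self):
        # groups {0,2} and {3,5}: SSB=9, SSW=4, df=(1,2) -> F=4.5
        exp = _experiment([[0, 2, 3, 5]], ["a", "a", "b", "b"])
        fs = bs.dose_f_statistics(exp)
        assert fs.df_between == 1 and fs.df_within == 2
        assert fs.f.iloc[0] == pytest.approx(4.5, abs=1e-12)

    def test_constant_gene_has_zero_f(self):
        exp = _experiment([[2, 2, 2, 2]], ["a", "a", "b", "b"])
        fs = bs.dose_f_statistics(exp)
        assert fs.f.iloc[0] == 0.0
        assert np.isneginf(fs.log2_f.iloc[0])

    def test_zero_within_group_variance_gives_infinite_f(self):
        exp = _experiment([[1, 1, 4, 4]], ["a", "a", "b", "b"])
        fs = bs.dose_f_statistics(exp)
        assert np.isposinf(fs.f.iloc[0])
        assert fs.usable().empty

    def test_affine_invariance(self, rng):
        y = rng.normal(size=12)
        doses = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        f1 = bs.dose_f_statistics(_experiment([y], doses)).f.iloc[0]
        f2 = bs.dose_f_statistics(_experiment([3.7 * y - 11.0], doses)).f.iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_agrees_with_scipy_f_oneway(self, rng):
        X = rng.normal(size=(40, 12))
        doses = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        fs = bs.dose_f_statistics(_experiment(X, doses))
        ref = ss.f_oneway(X[:, :3], X[:, 3:6], X[:, 6:9], X[:, 9:], axis=1)
        np.testing.assert_allclose(fs.f.to_numpy(), ref.statistic, rtol=1e-10)

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        X = rng.normal(size=(25, 8))
        doses = ["lo"] * 4 + ["hi"] * 4
        fs = bs.dose_f_statistics(_experiment(X, doses))
        t = ss.ttest_ind(X[:, :4], X[:, 4:], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(fs.f.to_numpy(), t**2, rtol=1e-10)

    def test_dose_group_with_single_sample_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            _experiment([[1, 2, 3]], ["a", "a", "b"])


class TestWelch:
    def test_hand_computed_statistic(self):
        # means 5 vs 2, s2 4 vs 2/3 -> t = 3/sqrt(4/3 + 1/6) = 3/sqrt(1.5)
        t, df, p = bs.welch_t_test(np.array([3.0, 5, 7]), np.array([1.0, 2, 3, 2]))
        assert t == pytest.approx(3 / np.sqrt(1.5), abs=1e-12)
        ref = ss.ttest_ind([3, 5, 7], [1, 2, 3, 2], equal_var=False, alternative="greater")
        assert df == pytest.approx(ref.df, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_agrees_with_reference_on_random_pairs(self, rng, alternative):
        for _ in range(1000):
            a = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=rng.integers(3, 30))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=rng.integers(3, 30))
            t, df, p = bs.welch_t_test(a, b, alternative)
            ref = ss.ttest_ind(
                a, b, equal_var=False,
                alternative="greater" if alternative == "greater" else "two-sided",
            )
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestGeneSetEnrichment:
    def _null_stats(self, rng, n_genes=300):
        design = bs.DoseDesign(per_dose_shift=(0.0, 0.0, 0.0, 0.0), seed=int(rng.integers(2**31)))
        exp, _ = bs.generate_dose_experiment(n_genes, design)
        return bs.dose_f_statistics(exp), exp

    def test_whole_universe_set_scores_t_zero_p_half(self, rng):
        fs, exp = self._null_stats(rng)
        everything = GeneSet("all", "", tuple(exp.genes))
        r = bs.gene_set_enrichment(fs, everything)
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(0.5, abs=1e-12)
        assert r.n_in_set == r.n_background

    def test_nonfinite_genes_excluded_and_counted(self):
        arr = np.vstack(
            [
                np.array([[0, 2, 3, 5]]),      # usable
                np.array([[1, 3, 2, 6]]),      # usable
                np.array([[2, 2, 2, 2]]),      # F = 0 -> log2 F = -inf
                np.array([[1, 1, 4, 4]]),      # F = inf
            ]
        )
        exp = _experiment(arr, ["a", "a", "b", "b"], genes=["u1", "u2", "z", "i"])
        fs = bs.dose_f_statistics(exp)
        r = bs.gene_set_enrichment(fs, GeneSet("s", "", ("u1", "u2", "z")))
        assert r.n_excluded_nonfinite == 2
        assert r.n_in_set == 2
        assert r.n_background == 2

    def test_too_few_usable_set_genes_is_error(self, rng):
        fs, exp = self._null_stats(rng)
        with pytest.raises(ValueError, match="fewer than 2 usable"):
            bs.gene_set_enrichment(fs, GeneSet("tiny", "", ("nope1", exp.genes[0])))

    def test_unmeasured_set_genes_intersected_with_warning(self, rng, caplog):
        fs, exp = self._null_stats(rng)
        s = GeneSet("s", "", tuple(exp.genes[:10]) + ("missing_gene",))
        with caplog.at_level("WARNING"):
            r = bs.gene_set_enrichment(fs, s)
        assert r.n_in_set == 10
        assert any("not measured" in m for m in caplog.messages)

    def test_background_rest_excludes_members(self, rng):
        fs, exp = self._null_stats(rng)
        s = GeneSet("s", "", tuple(exp.genes[:20]))
        r_all = bs.gene_set_enrichment(fs, s, background="all")
        r_rest = bs.gene_set_enrichment(fs, s, background="rest")
        assert r_all.n_background == len(exp.genes)
        assert r_rest.n_background == len(exp.genes) - 20


class TestEnrichmentReport:
    def test_empty_set_list_gives_empty_table(self, rng):
        design = bs.DoseDesign(seed=0)
        exp, _ = bs.generate_dose_experiment(100, design)
        table = bs.enrichment_report(exp, [])
        assert len(table) == 0
        assert "p" in table.columns

    def test_single_set_row_matches_direct_call(self, rng):
        design = bs.DoseDesign(seed=3)
        exp, truth = bs.generate_dose_experiment(400, design)
        table = bs.enrichment_report(exp, [truth])
        direct = bs.gene_set_enrichment(bs.dose_f_statistics(exp), truth)
        assert table.loc[0, "set_name"] == truth.name
        assert table.loc[0, "t"] == pytest.approx(direct.t_statistic)
        assert table.loc[0, "p"] == pytest.approx(direct.p_value)

    def test_rows_sorted_by_p_and_planted_set_leads(self, rng):
        design = bs.DoseDesign(seed=11)
        exp, truth = bs.generate_dose_experiment(1000, design)
        decoys = bs.random_gene_sets(exp.genes, 20, 50, rng, prefix="decoy")
        table = bs.enrichment_report(exp, [truth] + decoys)
        assert table["p"].is_monotonic_increasing
        assert table.loc[0, "set_name"] == truth.name

    def test_bh_column_present_and_bounded(self, rng):
        design = bs.DoseDesign(seed=4)
        exp, truth = bs.generate_dose_experiment(500, design)
        decoys = bs.random_gene_sets(exp.genes, 5, 30, rng)
        table = bs.enrichment_report(exp, [truth] + decoys, bh=True)
        assert ((table["p_adj_bh"] >= table["p"] - 1e-15) & (table["p_adj_bh"] <= 1)).all()


def test_monotone_power_in_effect_size():
    """Median -log10 p over seeds never decreases as the per-dose shift
    magnitudes grow."""
    medians = []
    for scale in (0.25, 0.5, 1.0):
        logs = []
        for seed in range(100):
            design = bs.DoseDesign(
                per_dose_shift=(0.0, scale, 2 * scale, 3 * scale), seed=seed
            )
            exp, truth = bs.generate_dose_experiment(300, design)
            r = bs.gene_set_enrichment(bs.dose_f_statistics(exp), truth)
            logs.append(-np.log10(max(r.p_value, 1e-300)))
        medians.append(np.median(logs))
    assert medians[0] <= medians[1] <= medians[2]
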