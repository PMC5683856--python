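"""Median collapsing, control standardization, and study merging."""

import numpy as np
import pandas as pd
import pytest

import biclustsig as bs


def _study(values, samples, probe_map=None):
    return bs.ExpressionStudy(
        values=values,
        samples=samples,
        probe_to_gene=probe_map,
    )


def _meta(samples, conditions, controls):
    rows = []
    for s, c in zip(samples, conditions):
        rows.append(
            {
                "sample": s,
                "study": "st1",
                "condition": c,
                "dose": "",
                "timepoint": "",
                "is_control": c in controls,
                "replicate": "1",
            }
        )
    return pd.DataFrame(rows).set_index("sample")


class TestTechnicalCollapse:
    def test_three_probes_collapse_to_gene_median(self):
        values = pd.DataFrame(
            {"s1": [1.0, 3.0, 2.0], "ctl": [0.0, 0.0, 0.0]},
            index=["p1", "p2", "p3"],
        )
        pm = pd.DataFrame({"probe": ["p1", "p2", "p3"], "gene": ["G"] * 3})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        out = bs.collapse_technical_replicates(study)
        assert out.values.loc["G", "s1"] == 2.0

    def test_even_probe_count_uses_middle_pair_mean(self):
        values = pd.DataFrame({"s1": [1.0, 3.0], "ctl": [0.0, 0.0]}, index=["p1", "p2"])
        pm = pd.DataFrame({"probe": ["p1", "p2"], "gene": ["G", "G"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        assert bs.collapse_technical_replicates(study).values.loc["G", "s1"] == 2.0

    def test_single_probe_unchanged(self):
        values = pd.DataFrame({"s1": [1.5], "ctl": [0.0]}, index=["p1"])
        pm = pd.DataFrame({"probe": ["p1"], "gene": ["G"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        assert bs.collapse_technical_replicates(study).values.loc["G", "s1"] == 1.5

    def test_duplicate_probe_rows_median_first(self):
        values = pd.DataFrame(
            {"s1": [1.0, 5.0, 3.0], "ctl": [0.0, 0.0, 0.0]},
            index=["p1", "p1", "p1"],
        )
        pm = pd.DataFrame({"probe": ["p1"], "gene": ["G"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        assert bs.collapse_technical_replicates(study).values.loc["G", "s1"] == 3.0

    def test_unmapped_probe_dropped(self):
        values = pd.DataFrame({"s1": [1.0, 9.0], "ctl": [0.0, 0.0]}, index=["p1", "px"])
        pm = pd.DataFrame({"probe": ["p1"], "gene": ["G"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        out = bs.collapse_technical_replicates(study)
        assert list(out.values.index) == ["G"]

    def test_multi_symbol_probe_feeds_every_symbol(self):
        values = pd.DataFrame({"s1": [4.0], "ctl": [0.0]}, index=["p1"])
        pm = pd.DataFrame({"probe": ["p1", "p1"], "gene": ["G1", "G2"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        out = bs.collapse_technical_replicates(study)
        assert out.values.loc["G1", "s1"] == 4.0
        assert out.values.loc["G2", "s1"] == 4.0

    def test_idempotent(self):
        values = pd.DataFrame(
            {"s1": [1.0, 3.0, 7.0], "ctl": [0.0, 0.0, 0.0]}, index=["p1", "p2", "p3"]
        )
        pm = pd.DataFrame({"probe": ["p1", "p2", "p3"], "gene": ["G", "G", "H"]})
        study = _study(values, _meta(["s1", "ctl"], ["t", "c"], {"c"}), pm)
        once = bs.collapse_technical_replicates(study)
        twice = bs.collapse_technical_replicates(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestBiologicalCollapse:
    def _replicated_study(self, reps):
        samples = [f"s{i}" for i in range(len(reps))] + ["ctl"]
        values = pd.DataFrame(
            [list(reps) + [0.0]], index=["G"], columns=samples
        )
        meta = _meta(samples, ["t"] * len(reps) + ["c"], {"c"})
        return _study(values, meta)

    @pytest.mark.parametrize("reps,expected", [((2.0, 2.0, 2.0), 2.0), ((0.0, 10.0), 5.0)])
    def test_condition_median(self, reps, expected):
        out = bs.collapse_biological_replicates(self._replicated_study(reps))
        assert out.values.loc["G", "t"] == expected

    def test_replicate_order_irrelevant(self):
        a = bs.collapse_biological_replicates(self._replicated_study((1.0, 4.0, 9.0)))
        b = bs.collapse_biological_replicates(self._replicated_study((9.0, 1.0, 4.0)))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_idempotent(self):
        once = bs.collapse_biological_replicates(self._replicated_study((1.0, 4.0, 9.0)))
        twice = bs.collapse_biological_replicates(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestFoldChange:
    def _study(self):
        values = pd.DataFrame(
            {"t1": [5.0], "t2": [3.0], "ctl": [3.0]}, index=["G"]
        )
        meta = _meta(["t1", "t2", "ctl"], ["cond1", "cond2", "control"], {"control"})
        return _study_helper(values, meta)

    def test_log2fc_is_treated_minus_control(self):
        fc = bs.fold_change_vs_control(self._study())
        assert fc.values.loc["G", "cond1"] == 2.0
        assert fc.values.loc["G", "cond2"] == 0.0

    def test_control_columns_absent(self):
        fc = bs.fold_change_vs_control(self._study())
        assert "control" not in fc.values.columns

    def test_missing_control_mapping_names_condition(self):
        with pytest.raises(ValueError, match="cond2"):
            bs.fold_change_vs_control(self._study(), control_map={"cond1": "control"})

    def test_roundtrip_exact_without_noise(self):
        planted = (bs.planted_block(50, 10, 0, 12, 0, 4, "up", 2.0, 0.0),)
        cfg = bs.SimulationConfig(50, 10, noise_sd=0.0, planted=planted, seed=2)
        fc = bs.preprocess_study(bs.generate_raw_study(cfg, replicates=1, controls=1))
        expected, _ = bs.generate_compendium(cfg)
        pd.testing.assert_frame_equal(
            fc.values[expected.values.columns].loc[expected.values.index],
            expected.values,
        )

    def test_roundtrip_bounded_by_noise_scale(self):
        cfg = bs.SimulationConfig(
            60, 12, noise_sd=0.1,
            planted=(bs.planted_block(60, 12, 0, 15, 0, 5, "up", 2.0, 0.1),),
            seed=9,
        )
        fc = bs.preprocess_study(bs.generate_raw_study(cfg, replicates=3, controls=3))
        direct, _ = bs.generate_compendium(cfg)
        diff = (fc.values[direct.values.columns].loc[direct.values.index] - direct.values).abs()
        # medians of 3 replicates + control median: a few noise sd covers it
        assert diff.to_numpy().max() < 6 * 0.1


def _study_helper(values, meta):
    return bs.ExpressionStudy(values=values, samples=meta, probe_to_gene=None)


class TestMergeStudies:
    def _fc(self, genes, conds, study="st1", fill=1.0):
        values = pd.DataFrame(fill, index=list(genes), columns=list(conds), dtype=float)
        prov = pd.Series({c: study for c in conds}, dtype=object)
        return bs.FoldChangeMatrix(values=values, condition_study=prov)

    def test_self_merge_duplicates_provenance_tagged_columns(self):
        fc = self._fc("ABC", ["x", "y"])
        merged = bs.merge_studies([fc, fc])
        assert sorted(merged.values.index) == ["A", "B", "C"]
        assert merged.values.shape[1] == 4
        assert all("::" in c for c in merged.values.columns)

    def test_gene_universe_is_intersection(self):
        m = bs.merge_studies(
            [self._fc("ABC", ["x"]), self._fc("BCD", ["y"], study="st2")]
        )
        assert sorted(m.values.index) == ["B", "C"]

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            bs.merge_studies([self._fc("AB", ["x"]), self._fc("CD", ["y"], study="st2")])

    def test_union_mode_keeps_all_genes(self):
        m = bs.merge_studies(
            [self._fc("AB", ["x"]), self._fc("CD", ["y"], study="st2")], how="union"
        )
        assert sorted(m.values.index) == ["A", "B", "C", "D"]
        assert m.values.isna().any().any()

    def test_merge_order_only_permutes_columns(self):
        a = self._fc("ABC", ["x"], study="st1", fill=1.0)
        b = self._fc("BCA", ["y"], study="st2", fill=2.0)
        m1 = bs.merge_studies([a, b])
        m2 = bs.merge_studies([b, a])
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_series_equal(m1.condition_study, m2.condition_study)


def test_study_requires_control_sample():
    values = pd.DataFrame({"s1": [1.0]}, index=["G"])
    meta = _meta(["s1"], ["t"], set())
    with pytest.raises(ValueError, match="control"):
        bs.ExpressionStudy(values=values, samples=meta, probe_to_gene=None)


def test_study_rejects_missing_values():
    values = pd.DataFrame({"s1": [np.nan], "ctl": [0.0]}, index=["G"])
    with pytest.raises(ValueError, match="[Mm]issing"):
        bs.ExpressionStudy(
            values=values, samples=_meta(["s1", "ctl"], ["t", "c"], {"c"}), probe_to_gene=None
        )
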