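"""Normalization, differential testing, BH adjustment and the candidate filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import thymotrace as tt
from thymotrace.transcriptome_screen import differential_f_test


class TestNormalizeLog2:
    def test_zero_count_maps_to_zero_at_unit_pseudocount(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [5, 5]}, index=["g1", "g2"])
        expr = tt.normalize_log2(counts)
        assert expr.values.loc["g1", "s1"] == 0.0

    def test_hand_computed_toy(self):
        counts = pd.DataFrame({"s1": [10, 90], "s2": [20, 80]}, index=["g1", "g2"])
        expr = tt.normalize_log2(counts)
        # library sizes 100; value = log2(1e6 * c/100 + 1)
        assert expr.values.loc["g1", "s1"] == pytest.approx(np.log2(1e5 + 1))
        assert expr.values.loc["g2", "s1"] == pytest.approx(np.log2(9e5 + 1))
        assert expr.values.loc["g1", "s2"] == pytest.approx(np.log2(2e5 + 1))

    def test_within_sample_ordering_preserved(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(50, 3)))
        expr = tt.normalize_log2(counts)
        for c in counts.columns:
            np.testing.assert_array_equal(
                np.argsort(counts[c].to_numpy(), kind="stable"),
                np.argsort(expr.values[c].to_numpy(), kind="stable"),
            )

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 1]})
        with pytest.raises(ValueError, match="library"):
            tt.normalize_log2(counts)


class TestDifferentialFTest:
    def _toy(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g1"],
            columns=[f"s{i}" for i in range(6)],
        )
        return values, ["a", "a", "a", "b", "b", "b"]

    def test_two_group_closed_form(self):
        values, labels = self._toy()
        res = differential_f_test(values, labels)
        assert res.loc["g1", "F"] == pytest.approx(13.5)
        assert res.loc["g1", "p"] == pytest.approx(0.02131, abs=2e-4)
        assert res.loc["g1", "log2FC"] == pytest.approx(3.0)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(40, 9)))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = differential_f_test(values, labels)
        for g in values.index:
            ref = stats.f_oneway(
                values.loc[g][:3], values.loc[g][3:6], values.loc[g][6:]
            )
            assert res.loc[g, "F"] == pytest.approx(ref.statistic, abs=1e-9)
            assert res.loc[g, "p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(size=(20, 8)))
        labels = ["a"] * 4 + ["b"] * 4
        res = differential_f_test(values, labels)
        for g in values.index:
            t, _p, _df = tt.student_t_test(
                values.loc[g][:4].to_numpy(), values.loc[g][4:].to_numpy()
            )
            assert res.loc[g, "F"] == pytest.approx(t**2, abs=1e-9)

    def test_degenerate_gene_flagged(self):
        values = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["flat"])
        res = differential_f_test(values, ["a", "a", "b", "b"])
        assert np.isnan(res.loc["flat", "F"])
        assert res.loc["flat", "p"] == 1.0

    def test_permuting_samples_within_groups_invariant(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(10, 6)))
        labels = ["a", "a", "a", "b", "b", "b"]
        res = differential_f_test(values, labels)
        perm = [2, 0, 1, 5, 3, 4]
        res2 = differential_f_test(values.iloc[:, perm], [labels[i] for i in perm])
        np.testing.assert_allclose(res["F"], res2["F"])
        np.testing.assert_allclose(res["p"], res2["p"])

    def test_small_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            differential_f_test(values, ["a", "b", "b"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert tt.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = tt.bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_array_equal(tt.bh_adjust([1.0] * 5), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tt.bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(tt.bh_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominate_raw_and_monotone(self, pvals):
        q = tt.bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def planted_screen_fixture():
    """100-gene screen table: 5 genes pass all four filters, 95 fail one."""
    rows, go_map = {}, {}
    surface = ["GO:0009986"]

    def add(name, fc, q, mean_hi, go):
        rows[name] = {
            "log2FC": fc, "q": q, "mean_a": 1.0, "mean_b": mean_hi, "p": q / 2,
            "F": 10.0,
        }
        go_map[name] = surface if go else ["GO:0008150"]

    for i in range(5):
        add(f"hit{i}", 4.0 + i, 0.001, 8.0, True)
    for i in range(24):
        add(f"weak_fc{i}", 2.0, 0.001, 8.0, True)       # fails fold change
    add("boundary_fc", 3.0, 0.001, 8.0, True)           # exactly 3 -> fails
    for i in range(24):
        add(f"weak_q{i}", 5.0, 0.20, 8.0, True)         # fails FDR
    add("boundary_q", 5.0, 0.05, 8.0, True)             # exactly 0.05 -> fails
    for i in range(25):
        add(f"no_go{i}", 5.0, 0.001, 8.0, False)        # fails surface GO
    for i in range(20):
        add(f"low_expr{i}", 5.0, 0.001, 6.0, True)      # fails expression
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table, go_map


class TestCandidateFilter:
    def test_planted_pass_set_recovered_exactly(self):
        table, go_map = planted_screen_fixture()
        assert len(table) == 100
        result = tt.candidate_filter(table, go_map)
        assert sorted(result.candidates) == [f"hit{i}" for i in range(5)]

    def test_boundary_fold_change_fails(self):
        table, go_map = planted_screen_fixture()
        result = tt.candidate_filter(table, go_map)
        assert not result.table.loc["boundary_fc", "passed"]
        assert not result.table.loc["boundary_q", "passed"]

    def test_negative_fold_change_passes_absolute_filter(self):
        table, go_map = planted_screen_fixture()
        table.loc["hit0", "log2FC"] = -4.0
        assert "hit0" in tt.candidate_filter(table, go_map).candidates
        assert "hit0" not in tt.candidate_filter(table, go_map, signed=True).candidates

    def test_empty_surface_terms_empty_candidates(self):
        table, go_map = planted_screen_fixture()
        result = tt.candidate_filter(table, go_map, surface_terms=set())
        assert result.candidates == []

    def test_removing_any_predicate_yields_superset(self):
        table, go_map = planted_screen_fixture()
        base = set(tt.candidate_filter(table, go_map).candidates)
        relaxed = [
            tt.candidate_filter(table, go_map, thresholds={"fc": -1.0}),
            tt.candidate_filter(table, go_map, thresholds={"q": 2.0}),
            tt.candidate_filter(table, go_map, thresholds={"expr": -100.0}),
            tt.candidate_filter(
                table, {g: ["GO:0009986"] for g in table.index}
            ),
        ]
        for r in relaxed:
            assert base <= set(r.candidates)

    def test_unannotated_genes_counted(self):
        table, go_map = planted_screen_fixture()
        del go_map["no_go0"]
        result = tt.candidate_filter(table, go_map)
        assert result.n_unannotated == 1


class TestSignatureScore:
    def _expr(self):
        rng = np.random.default_rng(5)
        genes = ["Ccr7", "Sell", "Cd44"] + [f"g{i}" for i in range(7)]
        cols, meta = [], []
        stages = list(tt.STAGES)
        base = pd.DataFrame(
            rng.normal(5, 1, size=(10, 7)), index=genes, columns=stages
        )
        # naive T-cell phenotype planted in stage C: Ccr7/Sell up, Cd44 down
        base.loc["Ccr7", "C"] += 4
        base.loc["Sell", "C"] += 4
        base.loc["Cd44", "C"] -= 4
        values, names = [], []
        for s in stages:
            for r in (1, 2):
                values.append(base[s] + rng.normal(0, 0.05, 10))
                names.append(f"{s}_{r}")
                meta.append({"sample": f"{s}_{r}", "stage": s})
        frame = pd.concat(values, axis=1)
        frame.columns = names
        return tt.ExpressionMatrix(frame, pd.DataFrame(meta).set_index("sample"))

    def test_z_rows_normalized(self):
        z, _score = tt.signature_score(self._expr(), ["Ccr7", "Sell", "Cd44"])
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_single_gene_panel_equals_gene_z(self):
        expr = self._expr()
        z, score = tt.signature_score(expr, ["Ccr7"])
        np.testing.assert_allclose(score.to_numpy(), z.loc["Ccr7"].to_numpy())

    def test_naive_panel_peaks_in_planted_stage(self):
        expr = self._expr()
        # Cd44 is planted low, so its z enters with inverted sign via a
        # two-panel difference: score(up genes) - score(down gene)
        _z_up, up = tt.signature_score(expr, ["Ccr7", "Sell"])
        _z_dn, dn = tt.signature_score(expr, ["Cd44"])
        naive = up - dn
        assert naive.idxmax() == "C"

    def test_zero_variance_gene_zeroed(self):
        values = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 3.0]}, index=["flat", "var"]
        )
        meta = pd.DataFrame({"stage": ["A", "B"]}, index=values.columns)
        z, _ = tt.signature_score(
            tt.ExpressionMatrix(values, meta), ["flat", "var"]
        )
        np.testing.assert_array_equal(z.loc["flat"].to_numpy(), 0.0)

    def test_missing_panel_genes_skipped(self):
        expr = self._expr()
        z, _ = tt.signature_score(expr, ["Ccr7", "not_a_gene"])
        assert list(z.index) == ["Ccr7"]
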