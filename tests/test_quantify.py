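"""Downstream-quantitation tests: AUC-matrix PCA geometry, bead-calibration
round trips, Livak fold changes against a naive oracle, and gene-set
overlap arithmetic."""

import numpy as np
import pandas as pd
import pytest

from il4model import (
    fit_bead_calibration,
    livak_fold_change,
    monocyte_deg_sets,
    overlap_summary,
    pca_responses,
    quantify_receptors,
    simulate_bead_experiment,
    simulate_ct_table,
    simulate_gene_sets,
)


class TestPCA:
    def test_identical_rows_get_identical_scores(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [4.0, 0.0, 1.0], [2.0, 2.0, 2.0]],
            columns=["a", "b", "c"],
        )
        scores, _loadings, _evr = pca_responses(m)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[1], atol=1e-12)

    def test_rank_one_matrix_explained_by_pc1(self):
        base = np.array([1.0, 2.0, 3.0])
        m = pd.DataFrame(np.outer([1.0, 2.0, 3.5, 0.5], base), columns=list("abc"))
        _s, _l, evr = pca_responses(m)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_invariant_to_column_offsets(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        s1, _, _ = pca_responses(m)
        s2, _, _ = pca_responses(m + np.array([10.0, -3.0, 100.0]))
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-9)

    def test_incomplete_rows_are_excluded(self):
        m = pd.DataFrame(
            [[1, 2, 3], [2, 3, 4], [3, 4, 5], [np.nan, 1, 1]], columns=list("abc"),
            dtype=float,
        )
        scores, _, _ = pca_responses(m)
        assert len(scores) == 3

    def test_fewer_than_three_complete_rows_is_an_error(self):
        m = pd.DataFrame([[1, 2], [2, np.nan], [np.nan, 1]], columns=list("ab"))
        with pytest.raises(ValueError, match="3 complete rows"):
            pca_responses(m)

    def test_type_exclusive_ligands_separate_most_along_pc1(self, human_panel):
        """AUC profiles across the human panel: the type-II-only cytokine
        (hIL-13-like) and the type-I-only mimetic (hNeo-4-like) must sit
        farther apart on PC1 than the dual-receptor cytokine does from the
        mimetic."""
        from il4model import fit_hill, auc_log_dose, predict_curves

        rows = {}
        for ct, panel in human_panel.panels.items():
            curves = predict_curves(
                human_panel.doses, panel, list(human_panel.affinities.values()),
                human_panel.kx,
            )
            for c in curves:
                fit = fit_hill(c.doses, c.normalized_signal)
                rows.setdefault(ct, {})[c.ligand] = (
                    auc_log_dose(fit, min(c.doses), max(c.doses))
                    if fit.converged
                    else 0.0
                )
        matrix = pd.DataFrame(rows).T  # rows = cell profiles, columns = ligands
        _scores, loadings, _evr = pca_responses(matrix)
        pc1 = loadings.loc["PC1"]  # each ligand's coordinate on PC1
        d_13_neo = abs(pc1["hIL-13"] - pc1["hNeo-4"])
        d_4_neo = abs(pc1["hIL-4"] - pc1["hNeo-4"])
        assert d_13_neo > d_4_neo


class TestBeadCalibration:
    def test_exact_identity_line_recovered(self):
        abc = np.array([1e3, 1e4, 1e5, 1e6])
        cal = fit_bead_calibration(abc, abc + 100.0, background=100.0)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_query_at_bead_mfi_returns_bead_abc(self):
        abc = np.array([1e3, 1e4, 1e5, 1e6])
        mfi = 100.0 + 0.5 * abc**0.9  # arbitrary log-linear response
        cal = fit_bead_calibration(abc, mfi, background=100.0)
        res = quantify_receptors(cal, mfi[2], background=100.0)
        assert res.count == pytest.approx(1e5, rel=1e-9)

    def test_mdm_staining_recovers_381_to_1_ratio(self):
        beads, cells = simulate_bead_experiment(
            {"gamma_c": 38100.0, "IL13Ra1": 100.0}, noise_sd=0.0
        )
        cal = fit_bead_calibration(beads["abc"], beads["mfi"], background=50.0)
        counts = {
            r: quantify_receptors(cal, m).count
            for r, m in zip(cells["receptor"], cells["mfi"])
        }
        assert round(counts["gamma_c"] / counts["IL13Ra1"]) == 381

    def test_below_background_gives_sentinel_not_negative(self):
        cal = fit_bead_calibration([1e3, 1e4, 1e5], [1100, 10100, 100100], 100.0)
        res = quantify_receptors(cal, 50.0)
        assert res.below_detection
        assert np.isnan(res.count)

    def test_doubling_mfi_doubles_count_under_slope_one(self):
        cal = fit_bead_calibration([1e3, 1e4, 1e5], [1000.0, 10000.0, 100000.0], 0.0)
        a = quantify_receptors(cal, 2000.0).count
        b = quantify_receptors(cal, 4000.0).count
        assert b / a == pytest.approx(2.0, rel=1e-12)

    def test_round_trip_abc_mfi_abc_is_exact(self, rng):
        slope, intercept, bg = 0.93, 0.4, 75.0
        abc = 10.0 ** np.linspace(3, 6, 5)
        mfi = bg + 10.0 ** (slope * np.log10(abc) + intercept)
        cal = fit_bead_calibration(abc, mfi, bg)
        for true_count in 10.0 ** rng.uniform(3, 6, size=20):
            query = bg + 10.0 ** (slope * np.log10(true_count) + intercept)
            assert quantify_receptors(cal, query).count == pytest.approx(
                true_count, rel=1e-9
            )

    def test_out_of_range_query_flagged_extrapolated(self):
        cal = fit_bead_calibration([1e3, 1e4, 1e5], [1000.0, 10000.0, 100000.0], 0.0)
        assert quantify_receptors(cal, 10.0).extrapolated
        assert not quantify_receptors(cal, 5000.0).extrapolated

    def test_nonpositive_net_bead_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            fit_bead_calibration([1e2, 1e3, 1e4, 1e5], [90, 1100, 10100, 100100], 100.0)


class TestLivak:
    def test_control_condition_fold_change_is_one(self):
        table = simulate_ct_table({"Arg1": 3.0, "Il1b": -1.5})
        out = livak_fold_change(table, "GAPDH", "PBS")
        ctrl = out[out.condition == "PBS"]
        assert np.allclose(ctrl["fold_change"], 1.0)
        assert np.allclose(ctrl["log2_fc"], 0.0)

    def test_ddct_minus_three_gives_eightfold(self):
        table = simulate_ct_table({"Arg1": 3.0})
        out = livak_fold_change(table, "GAPDH", "PBS")
        treated = out[(out.condition == "treated") & (out.gene == "Arg1")]
        assert np.allclose(treated["fold_change"], 8.0)

    def test_matches_naive_spreadsheet_oracle(self, rng):
        """Randomized Ct values recomputed cell-by-cell the spreadsheet way."""
        genes = ["g1", "g2", "g3"]
        rows = []
        for cond in ("PBS", "treated"):
            for rep in range(4):
                s = f"{cond}_{rep}"
                rows.append({"sample": s, "condition": cond, "gene": "ctrl",
                             "ct": rng.uniform(17, 19)})
                for g in genes:
                    rows.append({"sample": s, "condition": cond, "gene": g,
                                 "ct": rng.uniform(22, 30)})
        table = pd.DataFrame(rows)
        out = livak_fold_change(table, "ctrl", "PBS").set_index(["sample", "gene"])

        ctrl_ct = table[table.gene == "ctrl"].set_index("sample")["ct"]
        for g in genes:
            sub = table[table.gene == g]
            dct = {r["sample"]: r["ct"] - ctrl_ct[r["sample"]] for _, r in sub.iterrows()}
            ref = np.mean([dct[s] for s in dct if s.startswith("PBS")])
            for s, v in dct.items():
                expect = 2.0 ** (-(v - ref))
                assert out.loc[(s, g), "fold_change"] == pytest.approx(expect, abs=1e-12)

    def test_shifting_target_cts_by_minus_one_doubles_fold_change(self):
        table = simulate_ct_table({"Arg1": 2.0}, noise_sd=0.0)
        base = livak_fold_change(table, "GAPDH", "PBS")
        shifted = table.copy()
        mask = (shifted.gene != "GAPDH") & (shifted.condition == "treated")
        shifted.loc[mask, "ct"] -= 1.0
        out = livak_fold_change(shifted, "GAPDH", "PBS")
        t0 = base[(base.condition == "treated")]["fold_change"].to_numpy()
        t1 = out[(out.condition == "treated")]["fold_change"].to_numpy()
        np.testing.assert_allclose(t1, 2.0 * t0)

    def test_geometric_summary_mode(self):
        table = simulate_ct_table({"Arg1": 3.0}, noise_sd=0.0)
        out = livak_fold_change(table, "GAPDH", "PBS", summary="geometric")
        summ = out.attrs["summary"]
        assert summ.loc[("treated", "Arg1"), "fc_geomean"] == pytest.approx(8.0)

    def test_missing_control_gene_names_sample(self):
        table = simulate_ct_table({"Arg1": 1.0})
        broken = table[~((table["sample"] == "PBS_1") & (table.gene == "GAPDH"))]
        with pytest.raises(ValueError, match="PBS_1"):
            livak_fold_change(broken, "GAPDH", "PBS")


class TestOverlap:
    def test_identical_sets_all_fractions_one(self):
        s = {"a": {"g1", "g2"}, "b": {"g1", "g2"}}
        out = overlap_summary(s)
        assert out["pairwise"][("a", "b")]["fraction_of_first"] == 1.0
        assert out["k_way_shared_fraction"] == 1.0

    def test_reported_pairwise_overlap_83_percent(self):
        sets = monocyte_deg_sets(seed=3)
        out = overlap_summary({k: sets[k] for k in ("hIL-4", "hNeo-4")})
        pair = out["pairwise"][("hIL-4", "hNeo-4")]
        assert out["sizes"]["hIL-4"] == 966
        assert pair["intersection"] == 805
        assert round(100 * pair["fraction_of_first"]) == 83

    def test_reported_triple_overlap_above_70_percent(self):
        sets = monocyte_deg_sets(seed=3)
        out = overlap_summary(sets)
        assert out["k_way_intersection"] == 798
        assert out["union"] == 1097
        assert out["k_way_shared_fraction"] == pytest.approx(798 / 1097)
        assert out["k_way_shared_fraction"] >= 0.70

    def test_counts_symmetric_and_obey_inclusion_exclusion(self):
        sets = monocyte_deg_sets(seed=11)
        out = overlap_summary(sets)
        names = list(sets)
        pair_sum = sum(
            out["pairwise"][tuple(sorted((a, b)))]["intersection"]
            if tuple(sorted((a, b))) in out["pairwise"]
            else out["pairwise"][(a, b)]["intersection"]
            for a, b in [(names[0], names[1]), (names[0], names[2]), (names[1], names[2])]
        )
        incl_excl = (
            sum(out["sizes"].values()) - pair_sum + out["k_way_intersection"]
        )
        assert incl_excl == out["union"]

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            out = overlap_summary({"a": ["g1", "g1", "g2"], "b": ["g2"]})
        assert out["sizes"]["a"] == 2

    def test_infeasible_overlap_raises(self):
        with pytest.raises(ValueError):
            simulate_gene_sets({"a": 10, "b": 5}, {("a", "b"): 7})
        with pytest.raises(ValueError, match="infeasible|negative"):
            simulate_gene_sets(
                {"a": 10, "b": 10, "c": 10},
                {("a", "b"): 9, ("a", "c"): 9, ("b", "c"): 9, ("a", "b", "c"): 0},
            )
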