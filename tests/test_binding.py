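"""Equilibrium-solver tests: closed forms, brute-force oracles, conservation
and detailed-balance invariants, and the hook-effect distinction between the
multivalent and sequential model variants."""

import numpy as np
import pytest

from il4model.binding import (
    IL4RA,
    IL13RA1,
    AffinityTable,
    CrosslinkConstant,
    ReceptorPanel,
    predict_curves,
    solve_equilibrium_multivalent,
    solve_equilibrium_sequential,
)


def _conservation_errors(state, panel):
    """Relative conservation error of each receptor chain."""
    errs = []
    for total, used in (
        (panel.r_alpha_total,
         state.free_alpha + state.binary_alpha + state.type_i + state.type_ii),
        (panel.r_gamma_total, state.free_gamma + state.binary_gamma + state.type_i),
        (panel.r_13_total, state.free_13 + state.binary_13 + state.type_ii),
    ):
        if total > 0:
            errs.append(abs(used - total) / total)
    return errs


def _random_system(rng):
    panel = ReceptorPanel(
        "random",
        10.0 ** rng.uniform(2, 5),
        10.0 ** rng.uniform(2, 5),
        10.0 ** rng.uniform(2, 5),
    )
    aff = AffinityTable(
        "lig",
        ka_alpha=10.0 ** rng.uniform(6, 10),
        ka_gamma=10.0 ** rng.uniform(4, 8),
        ka_13=10.0 ** rng.uniform(4, 8),
        private_receptor=IL4RA,
    )
    kx = CrosslinkConstant(10.0 ** rng.uniform(-12, -7))
    dose = 10.0 ** rng.uniform(-13, -6)
    return panel, aff, kx, dose


class TestMultivalentClosedForms:
    def test_zero_dose_leaves_receptors_free(self):
        panel = ReceptorPanel("x", 1000, 2000, 500)
        aff = AffinityTable("lig", 1e9, 1e6, 1e6)
        st = solve_equilibrium_multivalent(0.0, panel, aff, CrosslinkConstant(1e-10))
        assert st.binary_alpha == st.binary_gamma == st.binary_13 == 0
        assert st.type_i == st.type_ii == 0
        assert (st.free_alpha, st.free_gamma, st.free_13) == (1000, 2000, 500)

    def test_monovalent_limit_is_exact_langmuir(self):
        # no co-receptor binding: binary occupancy must follow Ka*L/(1+Ka*L)
        ka = 1.0 / 58e-9
        panel = ReceptorPanel("x", 1000, 1000, 0)
        aff = AffinityTable("lig", ka_alpha=ka, ka_gamma=0.0, ka_13=0.0)
        kx = CrosslinkConstant(1e-30)  # negligible crosslinking
        st = solve_equilibrium_multivalent(1.0 / ka, panel, aff, kx)
        assert st.binary_alpha == pytest.approx(500.0, rel=1e-9)
        for dose in (1e-10, 1e-8, 1e-6):
            st = solve_equilibrium_multivalent(dose, panel, aff, kx)
            expect = 1000 * ka * dose / (1 + ka * dose)
            assert st.binary_alpha == pytest.approx(expect, rel=1e-9)

    def test_matches_bruteforce_bisection_on_reduced_problem(self):
        """With IL-13Ra1 absent the system reduces to one unknown; the full
        solver must agree with an independent bisection root-finder."""
        panel = ReceptorPanel("x", 1000, 1000, 0)
        ka_a, ka_g = 1.0 / 58e-9, 1e7
        aff = AffinityTable("lig", ka_a, ka_g, 0.0)
        kx = 1e-11
        L = 1e-8

        def alpha_conservation(r_a):
            r_g = panel.r_gamma_total / (1 + ka_g * L + kx * ka_a * ka_g * L * r_a)
            return r_a * (1 + ka_a * L * (1 + kx * ka_g * r_g)) - panel.r_alpha_total

        lo, hi = 0.0, panel.r_alpha_total
        for _ in range(200):  # bisection to ~1e-60 absolute
            mid = 0.5 * (lo + hi)
            if alpha_conservation(mid) > 0:
                hi = mid
            else:
                lo = mid
        r_a = 0.5 * (lo + hi)
        r_g = panel.r_gamma_total / (1 + ka_g * L + kx * ka_a * ka_g * L * r_a)
        expected_type_i = kx * ka_a * ka_g * L * r_a * r_g

        st = solve_equilibrium_multivalent(L, panel, aff, CrosslinkConstant(kx))
        assert st.type_i == pytest.approx(expected_type_i, rel=1e-6)

    def test_bruteforce_oracle_over_random_draws(self, rng):
        """Full solver vs the reduced 1-D bisection on 100 random systems."""
        for _ in range(100):
            ra = 10.0 ** rng.uniform(2, 5)
            rg = 10.0 ** rng.uniform(2, 5)
            ka_a = 10.0 ** rng.uniform(6, 10)
            ka_g = 10.0 ** rng.uniform(4, 8)
            kx = 10.0 ** rng.uniform(-12, -8)
            L = 10.0 ** rng.uniform(-12, -7)
            panel = ReceptorPanel("x", ra, rg, 0)
            aff = AffinityTable("lig", ka_a, ka_g, 0.0)

            def cons(r_a):
                r_g = rg / (1 + ka_g * L + kx * ka_a * ka_g * L * r_a)
                return r_a * (1 + ka_a * L * (1 + kx * ka_g * r_g)) - ra

            lo, hi = 0.0, ra
            for _i in range(200):
                mid = 0.5 * (lo + hi)
                if cons(mid) > 0:
                    hi = mid
                else:
                    lo = mid
            r_a = 0.5 * (lo + hi)
            r_g_val = rg / (1 + ka_g * L + kx * ka_a * ka_g * L * r_a)
            expected = kx * ka_a * ka_g * L * r_a * r_g_val

            st = solve_equilibrium_multivalent(L, panel, aff, CrosslinkConstant(kx))
            assert st.type_i == pytest.approx(expected, rel=1e-6)


class TestInvariants:
    def test_conservation_holds_on_random_systems(self, rng):
        for _ in range(100):
            panel, aff, kx, dose = _random_system(rng)
            for solver in (solve_equilibrium_multivalent, solve_equilibrium_sequential):
                st = solver(dose, panel, aff, kx)
                assert max(_conservation_errors(st, panel)) <= 1e-9

    def test_path_symmetry_detailed_balance(self, rng):
        """type I computed through either binding order must coincide."""
        for _ in range(100):
            panel, aff, kx, dose = _random_system(rng)
            st = solve_equilibrium_multivalent(dose, panel, aff, kx)
            via_alpha = st.binary_alpha * kx.kx_star * aff.ka_gamma * st.free_gamma
            via_gamma = st.binary_gamma * kx.kx_star * aff.ka_alpha * st.free_alpha
            assert via_alpha == pytest.approx(via_gamma, rel=1e-9)
            assert st.type_i == pytest.approx(via_alpha, rel=1e-9)

    def test_scale_invariance_of_normalized_signal(self, rng):
        panel, aff, kx, _ = _random_system(rng)
        doses = np.logspace(-12, -7, 8)
        base = predict_curves(doses, panel, [aff], kx)[0]
        c = 37.0
        scaled_panel = ReceptorPanel(
            panel.cell_type,
            panel.r_alpha_total * c,
            panel.r_gamma_total * c,
            panel.r_13_total * c,
        )
        scaled = predict_curves(
            doses, scaled_panel, [aff], CrosslinkConstant(kx.kx_star / c)
        )[0]
        np.testing.assert_allclose(
            scaled.normalized_signal, base.normalized_signal, rtol=1e-9
        )

    def test_negative_inputs_rejected(self):
        panel = ReceptorPanel("x", 100, 100, 100)
        aff = AffinityTable("lig", 1e8, 1e6, 1e6)
        with pytest.raises(ValueError):
            solve_equilibrium_multivalent(-1e-9, panel, aff, CrosslinkConstant(1e-10))
        with pytest.raises(ValueError):
            ReceptorPanel("x", -1, 100, 100)
        with pytest.raises(ValueError):
            CrosslinkConstant(0.0)


class TestSequentialModel:
    def test_zero_dose_all_complexes_zero(self):
        panel = ReceptorPanel("x", 1000, 2000, 500)
        aff = AffinityTable("lig", 1e9, 1e6, 1e6)
        st = solve_equilibrium_sequential(0.0, panel, aff, CrosslinkConstant(1e-10))
        assert st.type_i == st.type_ii == 0
        assert st.binary_alpha == 0

    def test_forbids_binary_on_nonprivate_chains(self, rng):
        panel, aff, kx, dose = _random_system(rng)
        st = solve_equilibrium_sequential(dose, panel, aff, kx)
        assert st.binary_gamma == 0.0
        assert st.binary_13 == 0.0
        assert st.binary_alpha > 0

    def test_il13_class_ligand_forms_only_type_ii(self):
        panel = ReceptorPanel("x", 2000, 3000, 5000)
        aff = AffinityTable(
            "il13", ka_alpha=1 / 487e-9, ka_gamma=0.0, ka_13=1 / 30e-9,
            private_receptor=IL13RA1,
        )
        st = solve_equilibrium_sequential(1e-8, panel, aff, CrosslinkConstant(1e-8))
        assert st.type_i == 0.0
        assert st.binary_alpha == 0.0
        assert st.binary_13 > 0
        assert st.type_ii > 0

    def test_agrees_with_independent_sequential_solver(self, rng):
        """Disabling co-receptor solution capture reduces the multivalent
        system to the sequential one; an independent fixed-point solve of
        those equations must match solve_equilibrium_sequential."""
        for _ in range(25):
            panel, aff, kx_c, dose = _random_system(rng)
            kx = kx_c.kx_star
            ka, kg, k13 = aff.ka_alpha, aff.ka_gamma, aff.ka_13
            r_a, r_g, r_13 = (
                panel.r_alpha_total, panel.r_gamma_total, panel.r_13_total,
            )
            for _i in range(200_000):
                na = panel.r_alpha_total / (
                    1 + ka * dose * (1 + kx * (kg * r_g + k13 * r_13))
                )
                ng = panel.r_gamma_total / (1 + kx * ka * kg * dose * r_a)
                n13 = panel.r_13_total / (1 + kx * ka * k13 * dose * r_a)
                if (
                    abs(na - r_a) < 1e-13 * na
                    and abs(ng - r_g) < 1e-13 * max(ng, 1e-300)
                    and abs(n13 - r_13) < 1e-13 * max(n13, 1e-300)
                ):
                    r_a, r_g, r_13 = na, ng, n13
                    break
                r_a, r_g, r_13 = na, ng, n13
            st = solve_equilibrium_sequential(dose, panel, aff, kx_c)
            assert st.free_alpha == pytest.approx(r_a, rel=1e-9)
            assert st.type_i == pytest.approx(kx * ka * kg * dose * r_a * r_g, rel=1e-9)

    def test_hook_effect_separates_model_variants(self):
        """At very high dose the multivalent model loses ternary complexes to
        co-receptor sequestration; the sequential model cannot."""
        panel = ReceptorPanel("x", 2000, 3000, 0)
        aff = AffinityTable("lig", 1 / 1e-9, 1 / 100e-9, 0.0)
        kx = CrosslinkConstant(1e-8)
        doses = np.logspace(-14, -4, 41)
        multi = [
            s.type_i for s in solve_equilibrium_multivalent(doses, panel, aff, kx)
        ]
        seq = [
            s.type_i for s in solve_equilibrium_sequential(doses, panel, aff, kx)
        ]
        assert np.all(np.diff(seq) >= -1e-9 * np.max(seq)), "sequential must be monotone"
        peak = int(np.argmax(multi))
        assert peak < len(multi) - 1
        assert multi[-1] < 0.5 * multi[peak], "multivalent must hook downward"


class TestPredictCurves:
    def test_single_condition_self_normalizes_to_one(self):
        panel = ReceptorPanel("x", 1000, 2000, 300)
        aff = AffinityTable("lig", 1e9, 1e6, 1e6)
        curves = predict_curves([1e-9], panel, [aff], CrosslinkConstant(1e-9))
        assert curves[0].normalized_signal == (1.0,)

    def test_no_coreceptor_means_no_signal(self):
        panel = ReceptorPanel("x", 1000, 2000, 300)
        aff = AffinityTable("lig", 1e9, 0.0, 0.0)  # only the private chain binds
        curves = predict_curves(
            np.logspace(-12, -7, 6), panel, [aff], CrosslinkConstant(1e-9)
        )
        assert all(s == 0 for s in curves[0].signal)

    def test_joint_normalization_peaks_at_one_per_cell_type(self, human_panel):
        curves = predict_curves(
            human_panel.doses,
            human_panel.panels["Ramos"],
            list(human_panel.affinities.values()),
            human_panel.kx,
        )
        top = max(max(c.normalized_signal) for c in curves)
        assert top == pytest.approx(1.0, abs=1e-12)

    def test_type_i_exclusive_ligand_silent_on_type_ii_cells(self, human_panel):
        """An hNeo-4-like ligand (no IL-13Ra1 binding) must produce <10% of
        its type-I-cell signal on a type-II-dominant cell, each normalized
        to the natural cytokine of its own panel."""
        kx = human_panel.kx
        affs = [human_panel.affinities["hIL-4"], human_panel.affinities["hNeo-4"]]
        ratios = {}
        for ct in ("A549", "Ramos"):
            curves = predict_curves(
                human_panel.doses, human_panel.panels[ct], affs, kx
            )
            by_lig = {c.ligand: max(c.normalized_signal) for c in curves}
            ratios[ct] = by_lig["hNeo-4"]
        assert ratios["A549"] / ratios["Ramos"] < 0.1

    def test_zero_gamma_cell_gives_exactly_zero_neo4_signal(self, human_panel):
        curves = predict_curves(
            human_panel.doses,
            human_panel.panels["fibroblasts"],
            [human_panel.affinities["hNeo-4"]],
            human_panel.kx,
        )
        assert all(s == 0 for s in curves[0].signal)
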