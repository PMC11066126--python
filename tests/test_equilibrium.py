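"""Equilibrium solver: folded fractions, association constants, pre/post
steady states, activity, fitness and grid sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

import dimerfate as dd
from dimerfate.equilibrium import EquilibriumError

from oracles import ode_steady_state_single


REF_FP = dd.FitnessParams(alpha=80.0, beta=0.5)


class TestFoldedFraction:
    @pytest.mark.parametrize(
        "dg, expected",
        [
            (0.0, 0.5),
            (-5.0, 0.9933071490757153),  # direct evaluation of 1/(1+e^-5)
            (5.0, 1.0 - 0.9933071490757153),
        ],
    )
    def test_values(self, dg, expected):
        assert dd.folded_fraction(dg) == pytest.approx(expected, rel=1e-12)

    def test_destabilized_limit(self):
        assert dd.folded_fraction(50.0) < 1e-20

    def test_strictly_decreasing(self):
        grid = np.linspace(-20, 20, 81)
        vals = [dd.folded_fraction(g) for g in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            dd.folded_fraction(bad)


class TestAssociationConstant:
    def test_zero_energy(self):
        assert dd.association_constant(0.0) == 1.0

    def test_reference_value(self):
        # direct evaluation of exp(10 / (1.987e-3 * 298))
        assert dd.association_constant(-10.0) == pytest.approx(21602020.785951685, rel=1e-9)

    def test_heterodimer_mixing_entropy_factor(self):
        # assembling AB from two distinct pools carries a statistical factor 2
        for dg in (-12.0, -5.0, 0.0, 3.0):
            assert dd.association_constant(dg, is_heterodimer=True) == pytest.approx(
                2.0 * dd.association_constant(dg), rel=1e-14
            )

    def test_overflow_clamped(self):
        k = dd.association_constant(-1e6)
        assert math.isfinite(k) and k > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dd.association_constant(np.nan)
        with pytest.raises(ValueError):
            dd.association_constant(-5.0, T=0.0)


class TestPreDuplication:
    def test_reference_total_activity(self):
        # s=100, dG_fold=-5, dG_bind=-10, d=1.3, activities 0.1/1
        state = dd.reference_state()
        conc = dd.solve_pre_duplication(state)
        assert dd.total_activity(conc, state) == pytest.approx(38.2, abs=0.1)

    def test_no_binding_limit(self):
        # K -> 0: everything stays monomeric, c_A -> s*w/d
        state = dd.reference_state(dG_bind=40.0)
        conc = dd.solve_pre_duplication(state)
        s_folded = 100.0 * dd.folded_fraction(-5.0)
        assert conc.c_A == pytest.approx(s_folded / 1.3, rel=1e-6)
        assert conc.c_AA < 1e-15 * conc.c_A

    def test_flux_balance_random_states(self, rng):
        for _ in range(50):
            state = dd.reference_state(
                synthesis_rate=rng.uniform(10, 500),
                dG_fold=rng.uniform(-10, 1),
                dG_bind=rng.uniform(-15, -2),
            )
            conc = dd.solve_pre_duplication(state)
            s_folded = state.gene_A.synthesis_rate * dd.folded_fraction(state.gene_A.dG_fold)
            flux = s_folded - 1.3 * conc.c_A - 2 * 1.3 * conc.c_AA
            assert abs(flux) <= 1e-8 * s_folded

    def test_matches_ode_oracle(self):
        state = dd.reference_state(synthesis_rate=230.0, dG_fold=-3.0, dG_bind=-8.0)
        conc = dd.solve_pre_duplication(state)
        s_folded = 230.0 * dd.folded_fraction(-3.0)
        ref = ode_steady_state_single(s_folded, 1.3, 1.3, dd.association_constant(-8.0))
        assert conc.c_A == pytest.approx(ref[0], rel=1e-6)
        assert conc.c_AA == pytest.approx(ref[1], rel=1e-6)

    def test_dispatch_guards(self):
        pre = dd.reference_state()
        post = dd.reference_state(duplicated=True)
        with pytest.raises(ValueError):
            dd.solve_pre_duplication(post)
        with pytest.raises(ValueError):
            dd.solve_post_duplication(pre)


class TestPostDuplication:
    def test_identical_parameters_give_1_2_1(self):
        conc = dd.solve_post_duplication(dd.reference_state(duplicated=True))
        assert conc.c_AA == pytest.approx(conc.c_BB, rel=1e-8)
        assert conc.c_AB == pytest.approx(2.0 * conc.c_AA, rel=1e-8)
        assert conc.het_fraction_among_dimers == pytest.approx(50.0, rel=1e-8)

    def test_reference_post_activity(self):
        state = dd.reference_state(duplicated=True)
        conc = dd.solve_post_duplication(state)
        assert dd.total_activity(conc, state) == pytest.approx(76.4, abs=0.1)

    def test_silent_gene_b_reduces_to_single_gene(self):
        state = dd.reference_state(duplicated=True)
        state = replace(state, gene_B=replace(state.gene_B, synthesis_rate=0.0))
        conc = dd.solve_post_duplication(state)
        pre = dd.solve_pre_duplication(dd.reference_state())
        assert conc.c_B == pytest.approx(0.0, abs=1e-12)
        assert conc.c_AB == pytest.approx(0.0, abs=1e-10)
        assert conc.c_BB == pytest.approx(0.0, abs=1e-10)
        assert conc.c_A == pytest.approx(pre.c_A, rel=1e-8)
        assert conc.c_AA == pytest.approx(pre.c_AA, rel=1e-8)

    def test_label_swap_symmetry(self, rng):
        # exchanging all A/B parameters exchanges c_A<->c_B, c_AA<->c_BB
        for _ in range(25):
            s_a, s_b = rng.uniform(10, 500, size=2)
            f_a, f_b = rng.uniform(-8, 0, size=2)
            g_aa, g_ab, g_bb = rng.uniform(-14, -3, size=3)
            base = dd.reference_state(duplicated=True)
            st = replace(
                base,
                gene_A=dd.GeneState(s_a, f_a),
                gene_B=dd.GeneState(s_b, f_b),
                energies=dd.InteractionEnergies(g_aa, g_ab, g_bb),
            )
            sw = replace(
                base,
                gene_A=dd.GeneState(s_b, f_b),
                gene_B=dd.GeneState(s_a, f_a),
                energies=dd.InteractionEnergies(g_bb, g_ab, g_aa),
            )
            c1 = dd.solve_post_duplication(st)
            c2 = dd.solve_post_duplication(sw)
            assert c1.c_A == pytest.approx(c2.c_B, rel=1e-10)
            assert c1.c_B == pytest.approx(c2.c_A, rel=1e-10)
            assert c1.c_AA == pytest.approx(c2.c_BB, rel=1e-10)
            assert c1.c_BB == pytest.approx(c2.c_AA, rel=1e-10)
            assert c1.c_AB == pytest.approx(c2.c_AB, rel=1e-10)

    def test_matches_ode_oracle_randomized(self, ode_comparison):
        max_dev, max_flux = ode_comparison
        assert max_dev < 1e-6
        assert max_flux < 1e-8

    def test_degenerate_heterodimer_binding_falls_back(self):
        # K_AB below threshold: two independent single-gene systems, c_AB = 0
        state = dd.reference_state(duplicated=True)
        state = replace(
            state,
            gene_B=dd.GeneState(50.0, -4.0),
            energies=dd.InteractionEnergies(-10.0, 30.0, -8.0),
        )
        conc = dd.solve_post_duplication(state)
        assert conc.c_AB == 0.0
        pre_a = dd.solve_pre_duplication(dd.reference_state())
        pre_b = dd.solve_pre_duplication(
            dd.reference_state(synthesis_rate=50.0, dG_fold=-4.0, dG_bind=-8.0)
        )
        assert conc.c_A == pytest.approx(pre_a.c_A, rel=1e-10)
        assert conc.c_BB == pytest.approx(pre_b.c_AA, rel=1e-10)

    def test_strongly_destabilized_fold_still_solvable(self):
        # near-zero folded synthesis is the solver's hardest regime
        state = dd.reference_state(duplicated=True)
        state = replace(
            state,
            gene_A=dd.GeneState(100.0, 5.3),
            gene_B=dd.GeneState(100.0, 24.5),
            energies=dd.InteractionEnergies(-19.3, -11.3, -1.25),
        )
        conc = dd.solve_post_duplication(state)
        s_b = 100.0 * dd.folded_fraction(24.5)
        flux_b = s_b - 1.3 * (conc.c_B + 2 * conc.c_BB + conc.c_AB)
        assert abs(flux_b) <= 1e-8 * s_b


class TestActivityAndFitness:
    def test_total_activity_weighted_sum(self):
        state = dd.reference_state(duplicated=True)
        conc = dd.Concentrations(c_A=1.0, c_B=2.0, c_AA=3.0, c_AB=4.0, c_BB=5.0)
        assert dd.total_activity(conc, state) == pytest.approx(0.1 * 3 + 12.0)

    def test_zero_concentrations(self):
        state = dd.reference_state()
        assert dd.total_activity(dd.Concentrations(0.0, 0.0), state) == 0.0

    def test_het_activity_bias_mapping(self):
        low_het = dd.reference_state(het_activity_bias=-10.0)
        assert low_het.activity_AB == pytest.approx(0.9)
        assert low_het.activity_AA == 1.0
        high_het = dd.reference_state(het_activity_bias=10.0)
        assert high_het.activity_AB == 1.0
        assert high_het.activity_AA == pytest.approx(0.9)

    def test_fitness_fixed_points(self):
        assert dd.fitness(80.0, REF_FP) == 1.0
        assert dd.fitness(160.0, REF_FP) == pytest.approx(0.5, rel=1e-12)
        assert dd.fitness(40.0, REF_FP) == pytest.approx(0.5, rel=1e-12)

    def test_fitness_log_symmetry(self, rng):
        for _ in range(30):
            r = rng.uniform(1.01, 20.0)
            assert dd.fitness(80.0 * r, REF_FP) == pytest.approx(
                dd.fitness(80.0 / r, REF_FP), rel=1e-10
            )

    def test_fitness_nonpositive_activity_is_zero(self):
        assert dd.fitness(0.0, REF_FP) == 0.0
        assert dd.fitness(-3.0, REF_FP) == 0.0

    def test_fitness_params_validation(self):
        with pytest.raises(ValueError):
            dd.FitnessParams(alpha=-1.0)
        with pytest.raises(ValueError):
            dd.FitnessParams(beta=1.5)


class TestLandscapeGrid:
    def test_lockstep_fold_sweep_het_never_exceeds_half(self):
        state = dd.reference_state(duplicated=True)
        grid = dd.landscape_grid(
            state, {"dG_fold_A=dG_fold_B": np.linspace(-15, 5, 25)}
        )
        assert len(grid) == 25
        assert (grid["het_pct_dimers"] <= 50.0 + 1e-6).all()

    def test_fold_2d_sweep_het_never_exceeds_half(self):
        state = dd.reference_state(duplicated=True)
        grid = dd.landscape_grid(
            state,
            {"dG_fold_A": np.linspace(-15, 5, 12), "dG_fold_B": np.linspace(-15, 5, 12)},
        )
        assert len(grid) == 144
        assert (grid["het_pct_dimers"] <= 50.0 + 1e-6).all()

    def test_stronger_het_binding_monotone(self):
        state = dd.reference_state(duplicated=True)
        grid = dd.landscape_grid(state, {"dG_bind_AB": np.linspace(-2, -16, 30)})
        c_ab = grid["c_AB"].to_numpy()
        assert (np.diff(c_ab) >= -1e-9 * np.abs(c_ab[:-1])).all()

    def test_zero_length_sweep_single_reference_point(self):
        state = dd.reference_state(duplicated=True)
        grid = dd.landscape_grid(state, {"dG_fold_A": []})
        assert len(grid) == 1
        assert grid.loc[0, "het_pct_dimers"] == pytest.approx(50.0, rel=1e-8)

    def test_invalid_axis_rejected(self):
        state = dd.reference_state(duplicated=True)
        with pytest.raises(ValueError):
            dd.landscape_grid(state, {"dG_wrong": [1.0]})
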