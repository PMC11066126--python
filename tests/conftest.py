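"""Shared fixtures.

The heavyweight computations (ODE-oracle comparison over randomized states,
Wright-Fisher fixation frequencies, the residual-bias span of evolutionary
runs) are session-scoped so that module tests and the acceptance tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dimerfate as dd
from dimerfate.equilibrium import _assoc_const

from oracles import ode_steady_state, wright_fisher_fixation_freq


def random_post_states(n, rng):
    """Randomized post-duplication parameter sets: binding energies
    log-uniform in [-15, -2] kcal/mol, folded synthesis uniform in
    [10, 500] units/h, decay 1.3/h."""
    states = []
    for _ in range(n):
        dgs = -np.exp(rng.uniform(np.log(2.0), np.log(15.0), size=3))
        s_a, s_b = rng.uniform(10.0, 500.0, size=2)
        states.append(
            dict(
                s_a=s_a,
                s_b=s_b,
                d=1.3,
                dg_aa=dgs[0],
                dg_ab=dgs[1],
                dg_bb=dgs[2],
            )
        )
    return states


def solve_state(st):
    """Package solution for one randomized state dict (folded synthesis given
    directly, so dG_fold = -inf effectively)."""
    from dimerfate.equilibrium import _solve_post_core

    rt = dd.RT
    k_aa = _assoc_const(st["dg_aa"], False, rt)
    k_ab = _assoc_const(st["dg_ab"], True, rt)
    k_bb = _assoc_const(st["dg_bb"], False, rt)
    status, *conc = _solve_post_core(
        st["s_a"], st["s_b"], st["d"], st["d"], st["d"], st["d"], st["d"],
        k_aa, k_ab, k_bb,
    )
    assert status == 0
    return np.array(conc), (k_aa, k_ab, k_bb)


@pytest.fixture(scope="session")
def ode_comparison():
    """Analytic vs ODE-integrated equilibria on 100 randomized states.

    Returns (max relative deviation, max relative flux residual).
    """
    rng = np.random.default_rng(20240901)
    max_dev = 0.0
    max_flux = 0.0
    for st in random_post_states(100, rng):
        conc, (k_aa, k_ab, k_bb) = solve_state(st)
        ref = ode_steady_state(
            st["s_a"], st["s_b"], st["d"], st["d"], st["d"], st["d"], st["d"],
            k_aa, k_ab, k_bb,
        )
        dev = np.max(np.abs(conc - ref) / np.maximum(np.abs(ref), 1e-300))
        max_dev = max(max_dev, float(dev))
        c_a, c_b, c_aa, c_ab, c_bb = conc
        fa = st["s_a"] - st["d"] * (c_a + 2 * c_aa + c_ab)
        fb = st["s_b"] - st["d"] * (c_b + 2 * c_bb + c_ab)
        max_flux = max(max_flux, abs(fa) / st["s_a"], abs(fb) / st["s_b"])
    return max_dev, max_flux


@pytest.fixture(scope="session")
def wf_comparison():
    """Kimura diffusion vs Wright-Fisher brute force at s=0.01, N=1000.

    Returns (p_kimura, p_wf, standard error of p_wf).
    """
    s, pop_n, n_runs = 0.01, 1000, 100_000
    rng = np.random.default_rng(7)
    p_wf = wright_fisher_fixation_freq(s, pop_n, n_runs, rng)
    p_kim = dd.fixation_probability(1.0, 1.0 + s, pop_n)
    se = np.sqrt(p_wf * (1 - p_wf) / n_runs)
    return p_kim, p_wf, se


BIAS_LEVELS = (-0.4, -0.2, 0.0, 0.2, 0.4)


@pytest.fixture(scope="session")
def bias_span():
    """Parameter-recovery experiment: synthetic structures spanning
    residual-bias levels, each evolved for 20 replicates x 100 fixations.

    Returns a frame with columns residual_bias, enrichment, mean_het_pct.
    """
    rows = []
    for i, bias in enumerate(BIAS_LEVELS):
        spec = dd.SyntheticStructureSpec(
            n_positions=60, residual_bias=bias, seed=1000 + i
        )
        table = dd.generate_synthetic_structure(spec)
        cfg = dd.SimulationConfig(
            n_fixed_target=100, n_replicates=20, alpha=80.0, beta=0.5, seed=500 + i
        )
        res = dd.run_simulation(cfg, table)
        summary = res.summary()
        rows.append(
            dict(
                residual_bias=bias,
                enrichment=table.enrichment_score(),
                mean_het_pct=summary["mean_het_pct_dimers"],
                n_ok=summary["n_replicates_ok"],
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_table():
    """Minimal handcrafted empirical table (one position, 3 substitutions)."""
    df = pd.DataFrame(
        {
            "position": [1, 1, 2],
            "wt_aa": ["A", "A", "C"],
            "mut_aa": ["C", "D", "A"],
            "ddG_fold": [1.5, -0.25, 3.0],
            "ddG_bind_HM": [2.0, 0.5, -1.0],
            "ddG_bind_HET": [1.0, 0.0, -0.6],
        }
    )
    return dd.EmpiricalEffectTable(data=df, sequence="AC", name="tiny")
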