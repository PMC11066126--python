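"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own solution paths: the equilibrium
oracle integrates the explicit mass-action ODE system to steady state with
scipy, and the fixation oracle simulates discrete Wright-Fisher generations.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

#: dissociation rate used to realize a given association constant
#: k = r_assoc / (decay + r_dissoc); the steady state is independent of it.
R_DISSOC = 50.0


def ode_steady_state(
    s_a, s_b, d_a, d_b, d_aa, d_ab, d_bb, k_aa, k_ab, k_bb, t_end=600.0
):
    """Steady state of the 5-species mass-action system by stiff integration.

    Species order (c_A, c_B, c_AA, c_AB, c_BB); ``s_a``/``s_b`` are folded
    synthesis rates. Association/dissociation rates are chosen to realize the
    requested association constants.
    """
    r1 = r3 = r5 = R_DISSOC
    r2 = k_aa * (d_aa + r1)
    r4 = k_bb * (d_bb + r3)
    r6 = k_ab * (d_ab + r5)

    def rhs(_t, y):
        c_a, c_b, c_aa, c_ab, c_bb = y
        form_aa = r2 * c_a * c_a
        form_bb = r4 * c_b * c_b
        form_ab = r6 * c_a * c_b
        return [
            s_a - d_a * c_a - 2.0 * form_aa + 2.0 * r1 * c_aa - form_ab + r5 * c_ab,
            s_b - d_b * c_b - 2.0 * form_bb + 2.0 * r3 * c_bb - form_ab + r5 * c_ab,
            form_aa - (r1 + d_aa) * c_aa,
            form_ab - (r5 + d_ab) * c_ab,
            form_bb - (r3 + d_bb) * c_bb,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.zeros(5),
        method="LSODA",
        rtol=1e-12,
        atol=1e-16,
        dense_output=False,
    )
    assert sol.success, sol.message
    return sol.y[:, -1]


def ode_steady_state_single(s, d_mono, d_dimer, k, t_end=600.0):
    """Steady state of the single-gene (monomer, homodimer) system."""
    r1 = R_DISSOC
    r2 = k * (d_dimer + r1)

    def rhs(_t, y):
        c_a, c_aa = y
        form = r2 * c_a * c_a
        return [s - d_mono * c_a - 2.0 * form + 2.0 * r1 * c_aa, form - (r1 + d_dimer) * c_aa]

    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], method="LSODA", rtol=1e-12, atol=1e-16)
    assert sol.success, sol.message
    return sol.y[:, -1]


def wright_fisher_fixation_freq(s, pop_n, n_runs, rng):
    """Fraction of Wright-Fisher runs in which a single haploid mutant with
    relative fitness 1 + s fixes. Vectorized over runs."""
    count = np.full(n_runs, 1, dtype=np.int64)
    active = np.ones(n_runs, dtype=bool)
    fixed = 0
    w = 1.0 + s
    while active.any():
        i = count[active]
        p = i * w / (i * w + (pop_n - i))
        count[active] = rng.binomial(pop_n, p)
        newly_fixed = active & (count == pop_n)
        fixed += int(newly_fixed.sum())
        active &= (count > 0) & (count < pop_n)
    return fixed / n_runs


def spearman_bruteforce(x, y):
    """Rank-transform + Pearson, for cross-checking on small tie-free vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def ranks(v):
        r = np.empty(len(v))
        r[np.argsort(v)] = np.arange(1, len(v) + 1)
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
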