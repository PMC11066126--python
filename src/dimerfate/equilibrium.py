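"""Mass-action binding equilibrium for one or two paralogous dimer-forming genes.

The model: protein copies of gene A (and, after duplication, gene B) are
synthesized at rate ``s``, fold with probability ``w = 1/(1 + exp(dG_fold))``,
and the folded pool partitions between free monomers and dimers (AA, AB, BB)
according to association constants ``k_X = exp(-dG_bind,X / RT)``.  A factor
of 2 multiplies the heterodimer association constant to account for the
mixing-entropy advantage of forming AB from distinct subunit pools; with
identical paralogs this yields the statistical 1 AA : 2 AB : 1 BB ratio.
Every species decays at its own first-order rate, so the steady state balances
folded synthesis against decay through monomers and complexes.

Pre-duplication the steady state is the closed-form positive root of a
quadratic; post-duplication the monomer concentration c_A solves a quartic
whose remaining species follow by back-substitution, and the physical
solution is the unique root making all five concentrations positive.

Fitness acts on the specific-activity-weighted total activity through a
log-symmetric ("lognormal") function with optimum ``alpha`` and half/twice
penalty ``beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .defaults import (
    ACTIVITY_DIMER,
    ACTIVITY_MONOMER,
    K_AB_FLOOR,
    MAX_EXP_ARG,
    R_GAS,
    REF_DECAY,
    REF_DG_BIND,
    REF_DG_FOLD,
    REF_SYNTHESIS_RATE,
    RT,
    T_KELVIN,
)

__all__ = [
    "GeneState",
    "InteractionEnergies",
    "SystemState",
    "Concentrations",
    "FitnessParams",
    "EquilibriumError",
    "folded_fraction",
    "association_constant",
    "solve_pre_duplication",
    "solve_post_duplication",
    "solve_equilibrium",
    "total_activity",
    "fitness",
    "landscape_grid",
    "reference_state",
]


class EquilibriumError(RuntimeError):
    """Raised when no (or more than one) physical equilibrium solution exists."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneState:
    """One gene locus: synthesis rate (units h^-1), folding free energy
    (kcal/mol) and monomer decay rate (h^-1)."""

    synthesis_rate: float
    dG_fold: float
    decay_monomer: float = REF_DECAY

    def __post_init__(self) -> None:
        if not (self.synthesis_rate >= 0):
            raise ValueError("synthesis_rate must be >= 0")
        if not (self.decay_monomer > 0):
            raise ValueError("decay_monomer must be > 0")
        if not math.isfinite(self.dG_fold):
            raise ValueError("dG_fold must be finite")


@dataclass(frozen=True)
class InteractionEnergies:
    """Binding free energies (kcal/mol) of the three possible dimers."""

    dG_bind_AA: float
    dG_bind_AB: float | None = None
    dG_bind_BB: float | None = None

    def __post_init__(self) -> None:
        for name in ("dG_bind_AA", "dG_bind_AB", "dG_bind_BB"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SystemState:
    """All evolvable parameters of one locus pair plus fixed environment.

    ``gene_B is None`` denotes the pre-duplication system (single gene,
    only the AA homodimer exists).
    """

    gene_A: GeneState
    energies: InteractionEnergies
    gene_B: GeneState | None = None
    decay_AA: float = REF_DECAY
    decay_AB: float = REF_DECAY
    decay_BB: float = REF_DECAY
    activity_monomer: float = ACTIVITY_MONOMER
    activity_AA: float = ACTIVITY_DIMER
    activity_AB: float = ACTIVITY_DIMER
    activity_BB: float = ACTIVITY_DIMER
    temperature_K: float = T_KELVIN
    gas_constant: float = R_GAS

    def __post_init__(self) -> None:
        for name in ("decay_AA", "decay_AB", "decay_BB"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("activity_monomer", "activity_AA", "activity_AB", "activity_BB"):
            if not (getattr(self, name) >= 0):
                raise ValueError(f"{name} must be >= 0")
        if self.gene_B is not None:
            if self.energies.dG_bind_AB is None or self.energies.dG_bind_BB is None:
                raise ValueError("post-duplication state needs all three binding energies")

    @property
    def is_duplicated(self) -> bool:
        return self.gene_B is not None

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature_K

    def with_duplication(self) -> "SystemState":
        """Duplicate the locus: gene B is an identical copy of gene A and all
        three binding energies start at the ancestral homodimer value."""
        e = self.energies
        return replace(
            self,
            gene_B=GeneState(
                self.gene_A.synthesis_rate,
                self.gene_A.dG_fold,
                self.gene_A.decay_monomer,
            ),
            energies=InteractionEnergies(e.dG_bind_AA, e.dG_bind_AA, e.dG_bind_AA),
        )


@dataclass(frozen=True)
class Concentrations:
    """Equilibrium concentrations of the five molecular species (arbitrary
    concentration units). Pre-duplication, the B-containing species are 0."""

    c_A: float
    c_AA: float
    c_B: float = 0.0
    c_AB: float = 0.0
    c_BB: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c_A, self.c_B, self.c_AA, self.c_AB, self.c_BB])

    @property
    def total(self) -> float:
        return self.c_A + self.c_B + self.c_AA + self.c_AB + self.c_BB

    @property
    def dimer_total(self) -> float:
        return self.c_AA + self.c_AB + self.c_BB

    @property
    def het_fraction_among_dimers(self) -> float:
        """Heterodimer share among complexes, in percent."""
        d = self.dimer_total
        if d <= 0:
            raise ValueError("no dimers present")
        return 100.0 * self.c_AB / d


@dataclass(frozen=True)
class FitnessParams:
    """Lognormal fitness function: optimum activity ``alpha`` (h^-1) and the
    fitness ``beta`` attained at half or twice the optimum."""

    alpha: float = 80.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        if not (0 < self.beta < 1):
            raise ValueError("beta must be in (0, 1)")


# ---------------------------------------------------------------------------
# Compiled numerical core (shared with the evolution kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _folded_fraction(dg_fold: float) -> float:
    # logistic in -dG_fold, numerically stable on both tails
    if dg_fold >= 0.0:
        z = math.exp(-dg_fold)
        return z / (1.0 + z)
    return 1.0 / (1.0 + math.exp(dg_fold))


@njit(cache=True)
def _assoc_const(dg_bind: float, is_het: bool, rt: float) -> float:
    arg = -dg_bind / rt
    if arg > MAX_EXP_ARG:
        arg = MAX_EXP_ARG
    k = math.exp(arg)
    if is_het:
        k *= 2.0
    return k


@njit(cache=True)
def _solve_pre_core(s_folded: float, d_mono: float, d_dimer: float, k: float):
    # 2*d_AA*k*c^2 + d_A*c - s = 0 ; rationalized positive root, stable as k->0
    disc = math.sqrt(d_mono * d_mono + 8.0 * d_dimer * k * s_folded)
    c_a = 2.0 * s_folded / (d_mono + disc)
    return c_a, k * c_a * c_a


@njit(cache=True)
def _poly_roots(coeffs):
    """Roots of a polynomial (coefficients highest-order first, leading
    coefficient nonzero) via the companion-matrix eigenvalues."""
    n = coeffs.shape[0] - 1
    C = np.zeros((n, n), dtype=np.complex128)
    for i in range(1, n):
        C[i, i - 1] = 1.0
    for j in range(n):
        C[0, j] = -coeffs[j + 1] / coeffs[0]
    return np.linalg.eigvals(C)


@njit(cache=True)
def _cb_given_ca(c_a, s_b, d_b, d_bb, k_bb, Q):
    """c_B at fixed c_A from subunit B's own flux balance.

    s_B = d_B c_B + 2 d_BB k_BB c_B^2 + Q c_A c_B is a quadratic in c_B;
    the rationalized positive root is cancellation-free in every regime
    (including s_B -> 0, where it returns exactly 0).
    """
    e = d_b + Q * c_a
    return 2.0 * s_b / (e + math.sqrt(e * e + 8.0 * d_bb * k_bb * s_b))


@njit(cache=True)
def _aflux(c_a, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q):
    """Subunit-A flux residual h(c_A), with c_B eliminated via B's balance.

    h(0+) = s_A > 0 and h is negative at A's single-gene root, so the
    physical equilibrium is a bracketed zero of h; B's balance holds
    identically by construction of c_B.
    """
    c_b = _cb_given_ca(c_a, s_b, d_b, d_bb, k_bb, Q)
    return s_a - d_a * c_a - 2.0 * P * c_a * c_a - Q * c_a * c_b


@njit(cache=True)
def _polish_root(c_a, ca_max, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q):
    """Newton-polish c_A on the A-flux residual, clamped to (0, ca_max]."""
    for _ in range(100):
        e = d_b + Q * c_a
        sq = math.sqrt(e * e + 8.0 * d_bb * k_bb * s_b)
        c_b = 2.0 * s_b / (e + sq)
        h = s_a - d_a * c_a - 2.0 * P * c_a * c_a - Q * c_a * c_b
        hs = s_a + d_a * c_a + 2.0 * P * c_a * c_a + Q * c_a * c_b
        if abs(h) <= 1e-13 * max(hs, 1e-300):
            break
        dcb = -c_b * Q * (1.0 + e / sq) / (e + sq)
        dh = -d_a - 4.0 * P * c_a - Q * (c_b + c_a * dcb)
        if dh == 0.0:
            break
        new = c_a - h / dh
        if new <= 0.0:
            new = 0.5 * c_a
        elif new > ca_max:
            new = 0.5 * (c_a + ca_max)
        if new == c_a:
            break
        c_a = new
    return c_a


@njit(cache=True)
def _solve_post_core(
    s_a: float,
    s_b: float,
    d_a: float,
    d_b: float,
    d_aa: float,
    d_ab: float,
    d_bb: float,
    k_aa: float,
    k_ab: float,
    k_bb: float,
):
    """Solve the coupled 5-species steady state.

    Returns (status, c_A, c_B, c_AA, c_AB, c_BB) with status codes:
    0 ok; 1 no all-positive root; 2 multiple all-positive roots;
    3 flux balance violated at the selected root.
    """
    if k_ab < K_AB_FLOOR:
        # heterodimer formation negligible: two independent single-gene systems
        c_a, c_aa = _solve_pre_core(s_a, d_a, d_aa, k_aa)
        c_b, c_bb = _solve_pre_core(s_b, d_b, d_bb, k_bb)
        return 0, c_a, c_b, c_aa, 0.0, c_bb
    if s_a <= 0.0:
        # gene A effectively silent: mirror of the s_b -> 0 reduction
        c_b, c_bb = _solve_pre_core(s_b, d_b, d_bb, k_bb)
        return 0, 0.0, c_b, 0.0, 0.0, c_bb

    P = d_aa * k_aa
    Q = d_ab * k_ab
    Rr = d_bb * k_bb
    G = P * Rr / Q

    coeffs = np.empty(5)
    coeffs[0] = 2.0 * P * (4.0 * G - Q)
    coeffs[1] = d_a * (8.0 * G - Q) - 2.0 * d_b * P
    coeffs[2] = 2.0 * Rr * d_a * d_a / Q + s_a * (Q - 8.0 * G) - d_a * d_b - Q * s_b
    coeffs[3] = s_a * (d_b - 4.0 * d_a * Rr / Q)
    coeffs[4] = 2.0 * s_a * s_a * Rr / Q

    scale = 0.0
    for i in range(5):
        a = abs(coeffs[i])
        if a > scale:
            scale = a
    # the leading coefficient vanishes exactly at the symmetric state
    # (4*P*Rr == Q^2); trim near-zero leading terms and solve the reduced poly
    lead = 0
    while lead < 4 and abs(coeffs[lead]) <= 1e-12 * scale:
        lead += 1
    roots = _poly_roots(coeffs[lead:])

    # the largest c_A compatible with c_B >= 0 is A's single-gene root
    ca_max, _ = _solve_pre_core(s_a, d_a, d_aa, k_aa)

    n_cand = 0
    best_ca = 0.0
    cand_ca = np.zeros(4)
    for i in range(roots.shape[0]):
        re = roots[i].real
        im = roots[i].imag
        if abs(im) > 1e-9 * max(abs(re), 1e-300):
            continue
        if re <= 0.0 or re > ca_max * (1.0 + 1e-6):
            continue
        c_a = _polish_root(min(re, ca_max), ca_max, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q)
        # accept only roots that actually satisfy A's flux balance (spurious
        # quartic roots correspond to negative-c_B branches and do not)
        h = _aflux(c_a, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q)
        if abs(h) > 1e-8 * max(s_a, 1e-300):
            continue
        dup = False
        for j in range(n_cand):
            if abs(c_a - cand_ca[j]) <= 1e-6 * max(c_a, cand_ca[j]):
                dup = True
                break
        if dup:
            continue
        cand_ca[n_cand] = c_a
        n_cand += 1
        best_ca = c_a

    if n_cand > 1:
        return 2, 0.0, 0.0, 0.0, 0.0, 0.0
    if n_cand == 0:
        # quartic roots unusable (extreme conditioning, e.g. near-zero folded
        # synthesis or clamped association constants): bracket the zero of
        # the A-flux residual on (0, ca_max]; h(0+) = s_A > 0, h(ca_max) <= 0.
        hi = ca_max
        lo = 0.5 * ca_max
        ok = False
        for _ in range(2000):
            if _aflux(lo, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q) > 0.0:
                ok = True
                break
            hi = lo
            lo *= 0.5
            if lo < 1e-300:
                break
        if not ok:
            return 1, 0.0, 0.0, 0.0, 0.0, 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _aflux(mid, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q) > 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-15 * hi:
                break
        best_ca = _polish_root(
            0.5 * (lo + hi), ca_max, s_a, s_b, d_a, d_b, d_bb, k_bb, P, Q
        )

    c_a = best_ca
    c_b = _cb_given_ca(c_a, s_b, d_b, d_bb, k_bb, Q)
    c_aa = k_aa * c_a * c_a
    c_bb = k_bb * c_b * c_b
    c_ab = k_ab * c_a * c_b
    # subunit flux balance: synthesis of folded subunits == decay throughput
    fa = s_a - d_a * c_a - 2.0 * d_aa * c_aa - d_ab * c_ab
    fb = s_b - d_b * c_b - 2.0 * d_bb * c_bb - d_ab * c_ab
    den_a = max(s_a, d_a * c_a + 2.0 * d_aa * c_aa + d_ab * c_ab)
    den_b = max(s_b, d_b * c_b + 2.0 * d_bb * c_bb + d_ab * c_ab)
    if den_a > 0 and abs(fa) > 1e-8 * den_a:
        return 3, c_a, c_b, c_aa, c_ab, c_bb
    if den_b > 0 and abs(fb) > 1e-8 * den_b:
        return 3, c_a, c_b, c_aa, c_ab, c_bb
    return 0, c_a, c_b, c_aa, c_ab, c_bb


@njit(cache=True)
def _fitness_core(activity: float, alpha: float, beta: float) -> float:
    if activity <= 0.0:
        return 0.0
    x = math.log2(activity / alpha)
    return beta ** (x * x)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def folded_fraction(dG_fold: float) -> float:
    """Fraction of properly folded protein, ``w = 1 / (1 + exp(dG_fold))``.

    Strictly decreasing in ``dG_fold``: stabilizing (negative) energies give
    w -> 1, destabilizing energies w -> 0.
    """
    if not np.isfinite(dG_fold):
        raise ValueError("dG_fold must be finite")
    return _folded_fraction(float(dG_fold))


def association_constant(
    dG_bind: float,
    is_heterodimer: bool = False,
    R: float = R_GAS,
    T: float = T_KELVIN,
) -> float:
    """Association constant ``K = exp(-dG_bind / RT)`` (per concentration unit).

    For the heterodimer, K carries an extra factor of 2 correcting for the
    mixing entropy of assembling a complex from two distinct subunit pools.
    The exponent is clamped at ``MAX_EXP_ARG`` to avoid overflow for extreme
    (unphysical) binding energies; the clamp is far outside the simulated
    range.
    """
    if not np.isfinite(dG_bind):
        raise ValueError("dG_bind must be finite")
    if not T > 0:
        raise ValueError("temperature must be > 0")
    return _assoc_const(float(dG_bind), bool(is_heterodimer), R * T)


def _folded_synthesis(gene: GeneState) -> float:
    return gene.synthesis_rate * _folded_fraction(gene.dG_fold)


def solve_pre_duplication(state: SystemState) -> Concentrations:
    """Closed-form steady state of the single-gene (A, AA) system.

    The synthesis rate entering the balance is the *folded* synthesis rate
    ``s_A * w(dG_fold,A)``; misfolded copies are degraded and never assemble.
    """
    if state.is_duplicated:
        raise ValueError("state is post-duplication; use solve_post_duplication")
    g = state.gene_A
    k_aa = _assoc_const(state.energies.dG_bind_AA, False, state.RT)
    if k_aa <= 0:
        raise EquilibriumError("association constant must be positive")
    c_a, c_aa = _solve_pre_core(_folded_synthesis(g), g.decay_monomer, state.decay_AA, k_aa)
    return Concentrations(c_A=c_a, c_AA=c_aa)


def solve_post_duplication(state: SystemState) -> Concentrations:
    """Steady state of the five-species (A, B, AA, AB, BB) system.

    Solves the quartic in c_A via its companion matrix, back-substitutes the
    other species, and returns the unique root with all concentrations
    positive. Raises :class:`EquilibriumError` when no such root exists, when
    several do, or when the selected root violates subunit flux balance.
    """
    if not state.is_duplicated:
        raise ValueError("state is pre-duplication; use solve_pre_duplication")
    ga, gb, e = state.gene_A, state.gene_B, state.energies
    rt = state.RT
    k_aa = _assoc_const(e.dG_bind_AA, False, rt)
    k_ab = _assoc_const(e.dG_bind_AB, True, rt)
    k_bb = _assoc_const(e.dG_bind_BB, False, rt)
    status, c_a, c_b, c_aa, c_ab, c_bb = _solve_post_core(
        _folded_synthesis(ga),
        _folded_synthesis(gb),
        ga.decay_monomer,
        gb.decay_monomer,
        state.decay_AA,
        state.decay_AB,
        state.decay_BB,
        k_aa,
        k_ab,
        k_bb,
    )
    if status == 1:
        raise EquilibriumError(f"no all-positive equilibrium root for state {state!r}")
    if status == 2:
        raise EquilibriumError(f"multiple all-positive equilibrium roots for state {state!r}")
    if status == 3:
        raise EquilibriumError(f"flux balance violated at equilibrium for state {state!r}")
    return Concentrations(c_A=c_a, c_B=c_b, c_AA=c_aa, c_AB=c_ab, c_BB=c_bb)


def solve_equilibrium(state: SystemState) -> Concentrations:
    """Dispatch to the pre- or post-duplication solver."""
    if state.is_duplicated:
        return solve_post_duplication(state)
    return solve_pre_duplication(state)


def total_activity(conc: Concentrations, state: SystemState) -> float:
    """Specific-activity-weighted sum of equilibrium concentrations (h^-1)."""
    return (
        state.activity_monomer * (conc.c_A + conc.c_B)
        + state.activity_AA * conc.c_AA
        + state.activity_AB * conc.c_AB
        + state.activity_BB * conc.c_BB
    )


def fitness(activity: float, params: FitnessParams) -> float:
    """Lognormal fitness ``beta ** (log2(activity/alpha))**2``.

    Maximal (1) at ``activity == alpha``, symmetric on the log scale, and equal
    to ``beta`` at half or twice the optimum. Non-positive activity returns 0
    by convention (a dead system, not an error).
    """
    return _fitness_core(float(activity), params.alpha, params.beta)


def reference_state(
    synthesis_rate: float = REF_SYNTHESIS_RATE,
    dG_fold: float = REF_DG_FOLD,
    dG_bind: float = REF_DG_BIND,
    decay: float = REF_DECAY,
    duplicated: bool = False,
    het_activity_bias: float = 0.0,
) -> SystemState:
    """Construct the standard starting state of the model.

    ``het_activity_bias`` is a percentage in [-90, 90]: negative values make
    the heterodimer less specifically active than the homodimers (e.g. -10 ->
    activity 0.9 vs 1.0); positive values make the homodimers less active.
    """
    if not -90 <= het_activity_bias <= 90:
        raise ValueError("het_activity_bias must be within [-90, 90] percent")
    act_ab = ACTIVITY_DIMER
    act_hm = ACTIVITY_DIMER
    if het_activity_bias < 0:
        act_ab = ACTIVITY_DIMER * (1.0 + het_activity_bias / 100.0)
    elif het_activity_bias > 0:
        act_hm = ACTIVITY_DIMER * (1.0 - het_activity_bias / 100.0)
    state = SystemState(
        gene_A=GeneState(synthesis_rate, dG_fold, decay),
        energies=InteractionEnergies(dG_bind),
        decay_AA=decay,
        decay_AB=decay,
        decay_BB=decay,
        activity_AA=act_hm,
        activity_AB=act_ab,
        activity_BB=act_hm,
    )
    if duplicated:
        state = state.with_duplication()
    return state


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

_AXIS_SETTERS = {
    "s_A": lambda s, v: replace(s, gene_A=replace(s.gene_A, synthesis_rate=v)),
    "s_B": lambda s, v: replace(s, gene_B=replace(s.gene_B, synthesis_rate=v)),
    "dG_fold_A": lambda s, v: replace(s, gene_A=replace(s.gene_A, dG_fold=v)),
    "dG_fold_B": lambda s, v: replace(s, gene_B=replace(s.gene_B, dG_fold=v)),
    "dG_bind_AA": lambda s, v: replace(s, energies=replace(s.energies, dG_bind_AA=v)),
    "dG_bind_AB": lambda s, v: replace(s, energies=replace(s.energies, dG_bind_AB=v)),
    "dG_bind_BB": lambda s, v: replace(s, energies=replace(s.energies, dG_bind_BB=v)),
}

LANDSCAPE_AXES = tuple(_AXIS_SETTERS)


def landscape_grid(
    state: SystemState,
    axes: Mapping[str, Sequence[float]],
    fitness_params: FitnessParams | None = None,
) -> pd.DataFrame:
    """Evaluate equilibrium, activity and fitness over a 1- or 2-D grid.

    ``axes`` maps parameter names (see :data:`LANDSCAPE_AXES`) to value
    sequences; the grid is their Cartesian product.  An axis name may also be
    a '='-joined combination like ``"dG_fold_A=dG_fold_B"`` to sweep several
    parameters in lockstep.  Returns a long-format frame with one row per
    grid point: swept values, the five concentrations, heterodimer share among
    dimers, total activity and fitness.
    """
    if fitness_params is None:
        fitness_params = FitnessParams()
    if not 1 <= len(axes) <= 2:
        raise ValueError("1 or 2 sweep axes required")
    for name in axes:
        for part in name.split("="):
            if part not in _AXIS_SETTERS:
                raise ValueError(
                    f"unknown axis {part!r}; valid axes: {sorted(_AXIS_SETTERS)}"
                )
    names = list(axes)
    grids = [np.atleast_1d(np.asarray(axes[n], dtype=float)) for n in names]
    if any(g.size == 0 for g in grids):
        # zero-length sweep degenerates to a single reference evaluation
        grids = [np.array([np.nan]) for _ in names]

    rows = []
    mesh = np.meshgrid(*grids, indexing="ij")
    for idx in np.ndindex(mesh[0].shape):
        s = state
        point = {}
        for name, m in zip(names, mesh):
            v = m[idx]
            point[name] = v
            if np.isfinite(v):
                for part in name.split("="):
                    s = _AXIS_SETTERS[part](s, float(v))
        conc = solve_equilibrium(s)
        act = total_activity(conc, s)
        row = dict(point)
        row.update(
            c_A=conc.c_A,
            c_B=conc.c_B,
            c_AA=conc.c_AA,
            c_AB=conc.c_AB,
            c_BB=conc.c_BB,
            het_pct_dimers=(
                conc.het_fraction_among_dimers if conc.dimer_total > 0 else np.nan
            ),
            activity=act,
            fitness=fitness(act, fitness_params),
        )
        rows.append(row)
    return pd.DataFrame(rows)
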