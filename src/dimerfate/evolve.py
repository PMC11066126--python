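"""Origin-fixation Monte-Carlo evolution of a duplicated dimer-forming gene.

One replicate starts from the pre-duplication reference equilibrium, fixes
the duplication as event #1 (proposed repeatedly until it fixes; it is
beneficial under both standard fitness optima), and then proposes mutations
one at a time — coding mutations perturbing folding and binding energies of a
randomly chosen paralog, or (with probability ``p_exp``) expression mutations
rescaling that paralog's synthesis rate. After every proposal the five-species
equilibrium, total activity and fitness are recomputed from scratch and the
mutation fixes with a probability given by the Kimura diffusion approximation
(default) or a Metropolis rule. A replicate ends when ``n_fixed_target``
mutations (including the duplication) have fixed.

The inner propose/solve/accept loop is compiled with numba: near-neutral
mutations fix with probability ~1/N, so a 200-fixation replicate evaluates
the equilibrium solver O(1e5) times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import analysis
from .defaults import (
    REF_DECAY,
    REF_DG_BIND,
    REF_DG_FOLD,
    REF_SYNTHESIS_RATE,
)
from .effects import (
    EmpiricalEffectTable,
    ExpressionEffectModel,
    MutationEffect,
    ParametricEffectModel,
    sample_empirical_effect,
    sample_expression_effect,
    sample_parametric_effect,
)
from .equilibrium import (
    Concentrations,
    EquilibriumError,
    FitnessParams,
    GeneState,
    InteractionEnergies,
    SystemState,
    _assoc_const,
    _fitness_core,
    _folded_fraction,
    _solve_post_core,
    _solve_pre_core,
    fitness,
    reference_state,
    solve_equilibrium,
    total_activity,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationResult",
    "ReplicateFailure",
    "fixation_probability",
    "propose_mutation",
    "apply_effect",
    "propose_and_apply",
    "run_replicate",
    "run_simulation",
]

_KIND_NAMES = {0: "duplication", 1: "coding", 2: "expression"}


# ---------------------------------------------------------------------------
# Fixation probability
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fix_prob_kimura(f_old: float, f_new: float, pop_n: float) -> float:
    if f_new <= 0.0:
        return 0.0
    s = f_new / f_old - 1.0
    if abs(s) < 1e-12:
        return 1.0 / pop_n
    num = -math.expm1(-2.0 * s)
    z = -2.0 * pop_n * s
    if z > 700.0:
        return 0.0
    den = -math.expm1(z)
    p = num / den
    if p < 0.0:
        p = 0.0
    elif p > 1.0:
        p = 1.0
    return p


@njit(cache=True)
def _fix_prob_metropolis(f_old: float, f_new: float) -> float:
    if f_new <= 0.0:
        return 0.0
    r = f_new / f_old
    return r if r < 1.0 else 1.0


def fixation_probability(
    fitness_old: float,
    fitness_new: float,
    population_size: int = 1000,
    model: str = "kimura",
) -> float:
    """Probability that a new mutant with relative selection coefficient
    ``s = fitness_new/fitness_old - 1`` fixes in a haploid population.

    ``model="kimura"``: diffusion approximation
    ``p = (1 - exp(-2s)) / (1 - exp(-2Ns))``, continuous at s = 0 where it
    equals 1/N. ``model="metropolis"``: ``min(1, fitness_new/fitness_old)``,
    provided as an alternative acceptance rule behind the same interface.
    """
    if not fitness_old > 0:
        raise ValueError("fitness_old must be > 0")
    if model == "kimura":
        if population_size < 2:
            raise ValueError("population_size must be >= 2")
        return _fix_prob_kimura(float(fitness_old), float(fitness_new), float(population_size))
    if model == "metropolis":
        return _fix_prob_metropolis(float(fitness_old), float(fitness_new))
    raise ValueError(f"unknown fixation model {model!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated evolutionary scenario."""

    n_fixed_target: int = 200
    n_replicates: int = 50
    alpha: float = 80.0
    beta: float = 0.5
    p_exp: float = 0.0
    het_activity_bias: float = 0.0
    population_size: int = 1000
    seed: int = 0
    fixation_model: str = "kimura"
    selection: str = "lognormal"
    expression_model: ExpressionEffectModel = field(default_factory=ExpressionEffectModel)
    synthesis_rate: float = REF_SYNTHESIS_RATE
    dG_fold_init: float = REF_DG_FOLD
    dG_bind_init: float = REF_DG_BIND
    decay: float = REF_DECAY

    def __post_init__(self) -> None:
        if self.n_fixed_target < 1:
            raise ValueError("n_fixed_target must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 <= self.p_exp < 1):
            raise ValueError("p_exp must be in [0, 1)")
        if not -90 <= self.het_activity_bias <= 90:
            raise ValueError("het_activity_bias must be in [-90, 90]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.fixation_model not in ("kimura", "metropolis"):
            raise ValueError("fixation_model must be 'kimura' or 'metropolis'")
        if self.selection not in ("lognormal", "neutral"):
            raise ValueError("selection must be 'lognormal' or 'neutral'")
        FitnessParams(self.alpha, self.beta)  # validates alpha/beta

    @property
    def fitness_params(self) -> FitnessParams:
        return FitnessParams(self.alpha, self.beta)

    def initial_state(self, duplicated: bool = False) -> SystemState:
        return reference_state(
            synthesis_rate=self.synthesis_rate,
            dG_fold=self.dG_fold_init,
            dG_bind=self.dG_bind_init,
            decay=self.decay,
            duplicated=duplicated,
            het_activity_bias=self.het_activity_bias,
        )


# ---------------------------------------------------------------------------
# Proposal / application (Python-level mirror of the kernel semantics)
# ---------------------------------------------------------------------------


def propose_mutation(
    config: SimulationConfig,
    effect_source: ParametricEffectModel | EmpiricalEffectTable,
    rng: np.random.Generator,
) -> MutationEffect:
    """Draw one candidate mutation: expression with probability ``p_exp``,
    otherwise coding; the affected paralog is chosen uniformly."""
    is_expr = rng.random() < config.p_exp
    target = "A" if rng.random() < 0.5 else "B"
    if is_expr:
        return sample_expression_effect(config.expression_model, rng, target)
    if isinstance(effect_source, EmpiricalEffectTable):
        return sample_empirical_effect(effect_source, rng, target)
    return sample_parametric_effect(effect_source, rng, target)


def apply_effect(state: SystemState, effect: MutationEffect) -> SystemState:
    """Apply one mutation to a post-duplication state (pure; returns a copy).

    Coding effects on paralog X add ddG_fold to X's folding energy, ddG_HM to
    X's homodimer binding energy and ddG_HET to the shared heterodimer
    binding energy; the other paralog's homodimer is untouched. Expression
    effects rescale the target's synthesis rate.
    """
    if effect.kind == "duplication":
        return state.with_duplication()
    if not state.is_duplicated:
        raise ValueError("coding/expression effects apply to the duplicated state")
    e = state.energies
    if effect.kind == "expression":
        mult = max(effect.expr_multiplier, 0.0)
        if effect.target == "A":
            g = replace(state.gene_A, synthesis_rate=state.gene_A.synthesis_rate * mult)
            return replace(state, gene_A=g)
        g = replace(state.gene_B, synthesis_rate=state.gene_B.synthesis_rate * mult)
        return replace(state, gene_B=g)
    if effect.target == "A":
        g = replace(state.gene_A, dG_fold=state.gene_A.dG_fold + effect.ddG_fold)
        new_e = replace(
            e,
            dG_bind_AA=e.dG_bind_AA + effect.ddG_bind_HM,
            dG_bind_AB=e.dG_bind_AB + effect.ddG_bind_HET,
        )
        return replace(state, gene_A=g, energies=new_e)
    g = replace(state.gene_B, dG_fold=state.gene_B.dG_fold + effect.ddG_fold)
    new_e = replace(
        e,
        dG_bind_BB=e.dG_bind_BB + effect.ddG_bind_HM,
        dG_bind_AB=e.dG_bind_AB + effect.ddG_bind_HET,
    )
    return replace(state, gene_B=g, energies=new_e)


def propose_and_apply(
    state: SystemState,
    config: SimulationConfig,
    effect_source: ParametricEffectModel | EmpiricalEffectTable,
    rng: np.random.Generator,
) -> tuple[SystemState, MutationEffect]:
    """Draw one mutation and return the candidate state alongside it."""
    effect = propose_mutation(config, effect_source, rng)
    return apply_effect(state, effect), effect


# ---------------------------------------------------------------------------
# Compiled replicate kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _replicate_kernel(
    rng,
    n_fix,
    pop_n,
    alpha,
    beta,
    neutral,
    metropolis,
    p_exp,
    empirical,
    mean3,
    L3,
    emp,
    delta,
    omega,
    xi,
    s0,
    dgf0,
    dgb0,
    d_mono,
    d_dim,
    act_mono,
    act_hm,
    act_het,
    rt,
):
    kind = np.zeros(n_fix, dtype=np.int8)
    target = np.zeros(n_fix, dtype=np.int8)
    eff = np.full((n_fix, 3), np.nan)
    mult_rec = np.full(n_fix, np.nan)
    emp_idx = np.full(n_fix, -1, dtype=np.int64)
    state_rec = np.zeros((n_fix, 7))
    conc_rec = np.zeros((n_fix, 5))
    act_rec = np.zeros(n_fix)
    fit_rec = np.zeros(n_fix)
    prop_cum = np.zeros(n_fix, dtype=np.int64)

    sqrt1md2 = math.sqrt(1.0 - delta * delta)
    n_emp = emp.shape[0]
    n_prop = 0

    # --- pre-duplication state and the duplication as fixation #1 ---
    w0 = _folded_fraction(dgf0)
    k_hm0 = _assoc_const(dgb0, False, rt)
    c_a0, c_aa0 = _solve_pre_core(s0 * w0, d_mono, d_dim, k_hm0)
    act_pre = act_mono * c_a0 + act_hm * c_aa0
    f_pre = 1.0 if neutral else _fitness_core(act_pre, alpha, beta)

    k_het0 = _assoc_const(dgb0, True, rt)
    status, c_a, c_b, c_aa, c_ab, c_bb = _solve_post_core(
        s0 * w0, s0 * w0, d_mono, d_mono, d_dim, d_dim, d_dim, k_hm0, k_het0, k_hm0
    )
    if status != 0:
        return status, n_prop, 0, kind, target, eff, mult_rec, emp_idx, state_rec, conc_rec, act_rec, fit_rec, prop_cum
    act_post = act_mono * (c_a + c_b) + act_hm * (c_aa + c_bb) + act_het * c_ab
    f_cur = 1.0 if neutral else _fitness_core(act_post, alpha, beta)
    if metropolis:
        p_dup = _fix_prob_metropolis(f_pre, f_cur)
    else:
        p_dup = _fix_prob_kimura(f_pre, f_cur, pop_n)
    while True:
        n_prop += 1
        if rng.random() < p_dup:
            break

    s_a = s0
    s_b = s0
    dgf_a = dgf0
    dgf_b = dgf0
    dg_aa = dgb0
    dg_ab = dgb0
    dg_bb = dgb0

    kind[0] = 0
    state_rec[0, 0] = s_a
    state_rec[0, 1] = s_b
    state_rec[0, 2] = dgf_a
    state_rec[0, 3] = dgf_b
    state_rec[0, 4] = dg_aa
    state_rec[0, 5] = dg_ab
    state_rec[0, 6] = dg_bb
    conc_rec[0, 0] = c_a
    conc_rec[0, 1] = c_b
    conc_rec[0, 2] = c_aa
    conc_rec[0, 3] = c_ab
    conc_rec[0, 4] = c_bb
    act_rec[0] = act_post
    fit_rec[0] = _fitness_core(act_post, alpha, beta)
    prop_cum[0] = n_prop

    # --- coding / expression fixations 2..n_fix ---
    for i in range(1, n_fix):
        while True:
            n_prop += 1
            is_expr = rng.random() < p_exp
            tgt = 0 if rng.random() < 0.5 else 1

            c_s_a = s_a
            c_s_b = s_b
            c_dgf_a = dgf_a
            c_dgf_b = dgf_b
            c_dg_aa = dg_aa
            c_dg_ab = dg_ab
            c_dg_bb = dg_bb
            e_fold = np.nan
            e_hm = np.nan
            e_het = np.nan
            mult = np.nan
            row = -1

            if is_expr:
                u0 = rng.standard_normal()
                u1 = rng.standard_normal()
                eps = xi + omega * (delta * abs(u0) + sqrt1md2 * u1)
                mult = 1.0 + eps
                if mult < 0.0:
                    mult = 0.0
                if tgt == 0:
                    c_s_a = s_a * mult
                else:
                    c_s_b = s_b * mult
            else:
                if empirical:
                    row = int(rng.random() * n_emp)
                    if row >= n_emp:
                        row = n_emp - 1
                    e_fold = emp[row, 0]
                    e_hm = emp[row, 1]
                    e_het = emp[row, 2]
                else:
                    z0 = rng.standard_normal()
                    z1 = rng.standard_normal()
                    z2 = rng.standard_normal()
                    e_fold = mean3[0] + L3[0, 0] * z0 + L3[0, 1] * z1 + L3[0, 2] * z2
                    e_hm = mean3[1] + L3[1, 0] * z0 + L3[1, 1] * z1 + L3[1, 2] * z2
                    e_het = mean3[2] + L3[2, 0] * z0 + L3[2, 1] * z1 + L3[2, 2] * z2
                if tgt == 0:
                    c_dgf_a = dgf_a + e_fold
                    c_dg_aa = dg_aa + e_hm
                else:
                    c_dgf_b = dgf_b + e_fold
                    c_dg_bb = dg_bb + e_hm
                c_dg_ab = dg_ab + e_het

            k_aa = _assoc_const(c_dg_aa, False, rt)
            k_ab = _assoc_const(c_dg_ab, True, rt)
            k_bb = _assoc_const(c_dg_bb, False, rt)
            status, c_a, c_b, c_aa, c_ab, c_bb = _solve_post_core(
                c_s_a * _folded_fraction(c_dgf_a),
                c_s_b * _folded_fraction(c_dgf_b),
                d_mono,
                d_mono,
                d_dim,
                d_dim,
                d_dim,
                k_aa,
                k_ab,
                k_bb,
            )
            if status != 0:
                return status, n_prop, i, kind, target, eff, mult_rec, emp_idx, state_rec, conc_rec, act_rec, fit_rec, prop_cum

            act = act_mono * (c_a + c_b) + act_hm * (c_aa + c_bb) + act_het * c_ab
            f_new = 1.0 if neutral else _fitness_core(act, alpha, beta)
            if metropolis:
                p_fix = _fix_prob_metropolis(f_cur, f_new)
            else:
                p_fix = _fix_prob_kimura(f_cur, f_new, pop_n)
            if rng.random() < p_fix:
                s_a = c_s_a
                s_b = c_s_b
                dgf_a = c_dgf_a
                dgf_b = c_dgf_b
                dg_aa = c_dg_aa
                dg_ab = c_dg_ab
                dg_bb = c_dg_bb
                f_cur = f_new
                kind[i] = 2 if is_expr else 1
                target[i] = tgt
                eff[i, 0] = e_fold
                eff[i, 1] = e_hm
                eff[i, 2] = e_het
                mult_rec[i] = mult
                emp_idx[i] = row
                state_rec[i, 0] = s_a
                state_rec[i, 1] = s_b
                state_rec[i, 2] = dgf_a
                state_rec[i, 3] = dgf_b
                state_rec[i, 4] = dg_aa
                state_rec[i, 5] = dg_ab
                state_rec[i, 6] = dg_bb
                conc_rec[i, 0] = c_a
                conc_rec[i, 1] = c_b
                conc_rec[i, 2] = c_aa
                conc_rec[i, 3] = c_ab
                conc_rec[i, 4] = c_bb
                act_rec[i] = act
                fit_rec[i] = _fitness_core(act, alpha, beta)
                prop_cum[i] = n_prop
                break

    return 0, n_prop, n_fix, kind, target, eff, mult_rec, emp_idx, state_rec, conc_rec, act_rec, fit_rec, prop_cum


# ---------------------------------------------------------------------------
# Trajectories and batch runs
# ---------------------------------------------------------------------------

_STATE_COLS = ["s_A", "s_B", "dG_fold_A", "dG_fold_B", "dG_bind_AA", "dG_bind_AB", "dG_bind_BB"]
_CONC_COLS = ["c_A", "c_B", "c_AA", "c_AB", "c_BB"]


@dataclass
class Trajectory:
    """Ordered record of the fixed events of one replicate.

    ``records`` has one row per fixation (the duplication first) with the
    fixed effect, the full evolvable state after fixation, the equilibrium
    concentrations, total activity, fitness and the cumulative number of
    proposals. In empirical mode the per-paralog sequences are tracked from
    the recorded substitutions.
    """

    records: pd.DataFrame
    config: SimulationConfig
    n_proposed: int
    replicate_seed: int
    sequence_A: str | None = None
    sequence_B: str | None = None
    wt_sequence: str | None = None

    @property
    def n_fixed(self) -> int:
        return len(self.records)

    @property
    def final_concentrations(self) -> Concentrations:
        r = self.records.iloc[-1]
        return Concentrations(
            c_A=r["c_A"], c_B=r["c_B"], c_AA=r["c_AA"], c_AB=r["c_AB"], c_BB=r["c_BB"]
        )

    @property
    def final_state(self) -> SystemState:
        r = self.records.iloc[-1]
        base = self.config.initial_state(duplicated=True)
        return replace(
            base,
            gene_A=replace(base.gene_A, synthesis_rate=r["s_A"], dG_fold=r["dG_fold_A"]),
            gene_B=replace(base.gene_B, synthesis_rate=r["s_B"], dG_fold=r["dG_fold_B"]),
            energies=InteractionEnergies(r["dG_bind_AA"], r["dG_bind_AB"], r["dG_bind_BB"]),
        )

    def sequence_identity(self, which: str = "AB") -> float:
        """Fraction of identical residues: 'A' / 'B' vs wild type, 'AB'
        between the paralogs (empirical mode only)."""
        if self.sequence_A is None:
            raise ValueError("sequence tracking requires an empirical effect source")
        a, b = {
            "A": (self.sequence_A, self.wt_sequence),
            "B": (self.sequence_B, self.wt_sequence),
            "AB": (self.sequence_A, self.sequence_B),
        }[which]
        arr_a = np.frombuffer(a.encode(), dtype="S1")
        arr_b = np.frombuffer(b.encode(), dtype="S1")
        return float(np.mean(arr_a == arr_b))


@dataclass
class ReplicateFailure:
    """Diagnostic record of a replicate aborted by an equilibrium-solver
    failure."""

    replicate: int
    seed: int
    status: int
    n_fixed_before_failure: int
    message: str


@dataclass
class SimulationResult:
    """Replicate set for one condition."""

    trajectories: list[Trajectory]
    failures: list[ReplicateFailure]
    config: SimulationConfig

    @property
    def n_ok(self) -> int:
        return len(self.trajectories)

    def final_percentages(self) -> pd.DataFrame:
        """One row per successful replicate: final relative concentrations
        (percent, Eq.-10 style), heterodimer share among dimers, and outcome
        label."""
        rows = []
        for t in self.trajectories:
            conc = t.final_concentrations
            p = analysis.relative_concentrations(conc)
            row = dict(p)
            row["het_pct_dimers"] = conc.het_fraction_among_dimers
            row["label"] = analysis.classify_outcome(p)
            if t.sequence_A is not None:
                row["identity_A_wt"] = t.sequence_identity("A")
                row["identity_B_wt"] = t.sequence_identity("B")
                row["identity_A_B"] = t.sequence_identity("AB")
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        """Across-replicate means of the final relative concentrations plus
        label fractions (and sequence identities in empirical mode)."""
        if not self.trajectories:
            raise ValueError("no successful replicates to summarize")
        df = self.final_percentages()
        out = {f"mean_{k}": float(df[k].mean()) for k in ("p_A", "p_B", "p_AA", "p_AB", "p_BB")}
        out["mean_het_pct_dimers"] = float(df["het_pct_dimers"].mean())
        counts = df["label"].value_counts()
        for label in analysis.OUTCOME_LABELS:
            out[f"frac_{label}"] = float(counts.get(label, 0)) / len(df)
        for col in ("identity_A_wt", "identity_B_wt", "identity_A_B"):
            if col in df:
                out[f"mean_{col}"] = float(df[col].mean())
        out["n_replicates_ok"] = self.n_ok
        out["n_replicates_failed"] = len(self.failures)
        return out


def _kernel_inputs(config: SimulationConfig, effect_source):
    if isinstance(effect_source, EmpiricalEffectTable):
        empirical = True
        mean3 = np.zeros(3)
        L3 = np.zeros((3, 3))
        emp = np.ascontiguousarray(effect_source.effects_array)
    elif isinstance(effect_source, ParametricEffectModel):
        empirical = False
        mean3 = effect_source.mean_vector
        L3 = np.ascontiguousarray(effect_source.scale_matrix)
        emp = np.zeros((1, 3))
    else:
        raise TypeError(
            "effect_source must be a ParametricEffectModel or EmpiricalEffectTable"
        )
    delta, omega, xi = config.expression_model.shape_params
    st = config.initial_state()
    return dict(
        pop_n=float(config.population_size),
        alpha=config.alpha,
        beta=config.beta,
        neutral=config.selection == "neutral",
        metropolis=config.fixation_model == "metropolis",
        p_exp=config.p_exp,
        empirical=empirical,
        mean3=mean3,
        L3=L3,
        emp=emp,
        delta=delta,
        omega=omega,
        xi=xi,
        s0=config.synthesis_rate,
        dgf0=config.dG_fold_init,
        dgb0=config.dG_bind_init,
        d_mono=config.decay,
        d_dim=config.decay,
        act_mono=st.activity_monomer,
        act_hm=st.activity_AA,
        act_het=st.activity_AB,
        rt=st.RT,
    )


def run_replicate(
    config: SimulationConfig,
    effect_source: ParametricEffectModel | EmpiricalEffectTable,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Run one replicate to ``n_fixed_target`` fixations.

    Deterministic given the generator state: the same seed reproduces the
    trajectory bit-identically.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(config.seed if rng is None else rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    inputs = _kernel_inputs(config, effect_source)
    out = _replicate_kernel(rng, config.n_fixed_target, **inputs)
    status, n_prop, n_done = out[0], out[1], out[2]
    if status != 0:
        raise EquilibriumError(
            f"equilibrium solver failed (status {status}) after {n_done} fixations"
        )
    kind, target, eff, mult, emp_idx, state_rec, conc_rec, act_rec, fit_rec, prop_cum = out[3:]
    df = pd.DataFrame(
        {
            "fixation": np.arange(1, config.n_fixed_target + 1),
            "kind": [_KIND_NAMES[k] for k in kind],
            "target": np.where(target == 0, "A", "B"),
            "ddG_fold": eff[:, 0],
            "ddG_bind_HM": eff[:, 1],
            "ddG_bind_HET": eff[:, 2],
            "expr_multiplier": mult,
        }
    )
    seq_a = seq_b = wt = None
    if isinstance(effect_source, EmpiricalEffectTable):
        pos = np.full(len(df), -1)
        wt_aa = np.array([""] * len(df), dtype=object)
        mut_aa = np.array([""] * len(df), dtype=object)
        wt = effect_source.sequence
        la, lb = list(wt), list(wt)
        for i, row in enumerate(emp_idx):
            if row >= 0:
                p, w_res, m_res = effect_source.substitution(int(row))
                pos[i] = p
                wt_aa[i] = w_res
                mut_aa[i] = m_res
                (la if target[i] == 0 else lb)[p - 1] = m_res
        df["position"] = pos
        df["wt_aa"] = wt_aa
        df["mut_aa"] = mut_aa
        seq_a, seq_b = "".join(la), "".join(lb)
    for j, col in enumerate(_STATE_COLS):
        df[col] = state_rec[:, j]
    for j, col in enumerate(_CONC_COLS):
        df[col] = conc_rec[:, j]
    df["activity"] = act_rec
    df["fitness"] = fit_rec
    df["proposals_cum"] = prop_cum
    return Trajectory(
        records=df,
        config=config,
        n_proposed=int(n_prop),
        replicate_seed=seed,
        sequence_A=seq_a,
        sequence_B=seq_b,
        wt_sequence=wt,
    )


def run_simulation(
    config: SimulationConfig,
    effect_source: ParametricEffectModel | EmpiricalEffectTable,
) -> SimulationResult:
    """Run ``config.n_replicates`` independent replicates.

    Each replicate gets its own generator spawned from ``config.seed`` via
    ``numpy.random.SeedSequence``, so replicates are independent and the
    whole batch is reproducible. Solver failures abort the affected replicate
    only and are reported as :class:`ReplicateFailure` records.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    trajectories: list[Trajectory] = []
    failures: list[ReplicateFailure] = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        try:
            t = run_replicate(config, effect_source, rng)
            t.replicate_seed = i
            trajectories.append(t)
        except EquilibriumError as exc:
            failures.append(
                ReplicateFailure(
                    replicate=i,
                    seed=i,
                    status=-1,
                    n_fixed_before_failure=0,
                    message=str(exc),
                )
            )
    return SimulationResult(trajectories=trajectories, failures=failures, config=config)
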