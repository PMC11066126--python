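# dimerfate

Most proteins that form complexes assemble as homomers. When a
homodimer-forming gene duplicates, the two paralogous proteins A and B
suddenly co-exist in the same cell and assemble combinatorially into AA, BB
and the new heterodimer AB. `dimerfate` is a Python package for asking what
happens next: under realistic distributions of mutational effects on folding
and binding energies — and without any selection *for* heteromerization —
does the heterodimer take over, do the ancestral homodimers persist, or do
both survive? It is aimed at molecular-evolution and systems-biology
researchers studying paralog fate, neutral increases in complexity, and the
composition of protein interaction networks.

## Model

**Equilibrium layer.** Each gene synthesizes protein at rate *s* (units
h⁻¹); a copy folds with probability *w* = 1/(1 + e^{ΔG_fold}) and misfolded
copies are degraded. Folded monomers and dimers decay at first-order rates
(1.3 h⁻¹ by default) and dimerize with association constants
*k*_X = e^{−ΔG_bind,X/RT}, the heterodimer carrying a statistical factor 2
for mixing entropy. The five-species steady state (c_A, c_B, c_AA, c_AB,
c_BB) solves a quartic in c_A; with identical paralogs it is exactly
1 AA : 2 AB : 1 BB, i.e. 50% heterodimer among complexes. Total activity is
Σ a_X·c_X (a = 0.1 for monomers, 1 for dimers) and fitness is a lognormal
function of activity, maximal at the optimum α and equal to β at α/2 and 2α.

**Evolution layer.** Origin-fixation Monte Carlo: mutations are proposed
one at a time — coding mutations drawing correlated (ΔΔG_fold, ΔΔG_bind,HM,
ΔΔG_bind,HET) triples from a parametric model or from a per-structure
mutational-scan table, or (with probability p_exp) expression mutations
rescaling a synthesis rate — the equilibrium and fitness are recomputed, and
the mutation fixes with the Kimura probability (1 − e^{−2s})/(1 − e^{−2Ns}).
The duplication itself is the first fixation; runs end after 200 fixations.

**Bias statistic.** A substitution hits two interfaces in a homodimer but
one in a heterodimer, so the null expectation is ΔΔG_HET = 0.5·ΔΔG_HM. The
*residual* ΔΔG_HET − 0.5·ΔΔG_HM measures each mutation's deviation (negative
= heterodimer-favoring), and a table's *enrichment score* is the fraction of
residuals below −0.2 kcal/mol minus the fraction above +0.2. The package's
central result is that this weak, purely mutational bias predicts
heterodimer takeover.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
import dimerfate as dd

# symmetric post-duplication equilibrium
state = dd.reference_state(duplicated=True)
conc = dd.solve_post_duplication(state)
print(f"c_AA = {conc.c_AA:.2f}, c_AB = {conc.c_AB:.2f}, c_BB = {conc.c_BB:.2f}")
print(f"heterodimer share among dimers: {conc.het_fraction_among_dimers:.1f} %")
print(f"total activity: {dd.total_activity(conc, state):.1f} per hour")

# a synthetic mutational-scan table with a heterodimer-favoring bias
table = dd.generate_synthetic_structure(
    dd.SyntheticStructureSpec(n_positions=80, residual_bias=-0.2, seed=7)
)
print(f"enrichment of heterodimer-favoring residuals: {table.enrichment_score():+.3f}")

# evolve 10 replicates for 100 fixed mutations each
config = dd.SimulationConfig(n_fixed_target=100, n_replicates=10, seed=7)
summary = dd.run_simulation(config, table).summary()
print(f"mean final heterodimer share: {summary['mean_het_pct_dimers']:.1f} %")
print(f"replicates ending heterodimer-dominant: {summary['frac_HET_dominant']:.0%}")
print(f"paralog sequence identity: {summary['mean_identity_A_B']:.2f}")
```

Output:

```
c_AA = 19.10, c_AB = 38.20, c_BB = 19.10
heterodimer share among dimers: 50.0 %
total activity: 76.4 per hour
enrichment of heterodimer-favoring residuals: +0.251
mean final heterodimer share: 99.9 %
replicates ending heterodimer-dominant: 100%
paralog sequence identity: 0.30
```

Reading: the duplicated system starts at the combinatorial 1:2:1 optimum
(activity 76.4 h⁻¹, just under the fitness optimum of 80 h⁻¹). A table with
a modest heterodimer-favoring mutational bias (enrichment +0.25; a −0.2
kcal/mol shift off the diagonal) drives essentially complete heterodimer
takeover within 100 fixed mutations while the paralogs diverge to ~30%
sequence identity — no selection for heteromerization is involved.

## Command line

```bash
dimerfate sweep --axis dG_fold_A:-15:5:50 --axis dG_fold_B:-15:5:50 --out sweep/
dimerfate simulate --parametric --p-exp 0.9 --replicates 50 --fixations 200 --seed 1 --out run/
dimerfate generate-synthetic --n 9 --bias-range -0.4 0.4 --seed 1 --out tables/
dimerfate analyze run_a/ run_b/ --out report/
```

Every output directory contains a `run_metadata.json` echoing the full
configuration and seed, sufficient to reproduce the run bit-identically.

The numbered scripts under `analysis/` are narrative drivers over the same
library — equilibrium landscapes, the parametric p_exp sweep, and the
residual-bias parameter-recovery experiment — and write their tables under
`results/`.

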