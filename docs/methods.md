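# Methods

`dimerfate` models what happens to a homodimer-forming protein after its gene
duplicates: the two paralogs (A, B) now assemble into two homodimers (AA, BB)
and one heterodimer (AB), and evolution — sampled one mutation at a time —
decides whether the heterodimer takes over, the homodimers persist, or both
survive. This note documents the model, its parameters and units, the
numerical choices, what the synthetic data do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Biophysical model

**Folding.** Each protein folds with probability
`w = 1 / (1 + exp(dG_fold))` (dG_fold in kcal/mol; the Boltzmann two-state
fraction at the simulated temperature absorbed into the energy scale).
Misfolded copies are degraded and never assemble, so the *folded synthesis
rate* entering every balance equation is `s * w`. Mutations store their
folding effect on `dG_fold`; the gene-level rate `s` is touched only by
expression mutations.

**Assembly.** Dimer assembly is governed by association constants
`k_X = exp(-dG_bind,X / RT)` with `R = 1.987e-3 kcal/(K mol)`, `T = 298 K`.
The heterodimer constant carries an additional statistical factor 2 for the
mixing entropy of assembling AB from two distinct subunit pools. This factor
is what makes two *identical* paralogs settle at the combinatorial
1 AA : 2 AB : 1 BB ratio — 50% heterodimer among complexes — and it is
applied on `k_AB`, the unique placement that reproduces that ratio.

**Steady state.** Every species decays with a first-order rate (default
1.3 h^-1 for all monomers and dimers, the yeast-like value combining
degradation and dilution). Pre-duplication the steady state is the positive
root of a quadratic, solved in closed (rationalized) form. Post-duplication
the free monomer concentration c_A satisfies a quartic; the other four
species follow by back-substitution, and the physical solution is the unique
root with all five concentrations positive. Concentrations are in the
model's arbitrary units (synthesis in units/h); no molar conversion is
attempted.

**Activity and fitness.** Total activity is the specific-activity-weighted
sum of concentrations: 0.1 for free monomers, 1.0 for every dimer by
default. With the reference parameters (s = 100 units/h, dG_fold = -5,
dG_bind = -10, d = 1.3/h) this gives 38.2 h^-1 before duplication and
76.4 h^-1 after, which is why the fitness optimum is placed at alpha = 80
(duplication approaches the optimum) or alpha = 60 h^-1 (duplication
overshoots). Fitness is a lognormal function of activity with optimum
`alpha` and shoulder `beta`: we implement
`f(a) = beta ** (log2(a / alpha))**2`, the unique Gaussian-in-log form with
`f(alpha) = 1` and `f(alpha/2) = f(2 alpha) = beta` (default beta = 0.5).
The functional form is exposed as a parameterized object so an alternative
map can be substituted. Non-positive activity returns fitness 0 by
convention. Biased specific activities (the `het_activity_bias` percentage)
are set at the start of a scenario and never mutate; the less active dimer
class gets activity `1 - |bias|/100`.

**What is deliberately not modeled.** No explicit association/dissociation
rate constants as user-facing parameters (only their ratio, the association
constant, is identified by the equilibrium; the tests' ODE oracle confirms
the steady state is independent of the split). No folding stabilization by
binding, no higher-order oligomers, no evolving per-dimer specific
activities, no dominant-negative effects.

## Mutational effects

Three event kinds, mutually exclusive per proposal:

* **Coding** (probability `1 - p_exp`): a (ddG_fold, ddG_bind_HM,
  ddG_bind_HET) triple. In *parametric* mode it is drawn from a trivariate
  normal with marginals N(2.6, 4.6), N(0.4, 2.4) and N(0.2, 1.2) kcal/mol and
  correlations corr(HM, HET) = 0.9, corr(fold, HM) = corr(fold, HET) = 0.3 —
  the pooled statistics of FoldX-style scans of homodimer structures
  (positive means: random mutations are on average destabilizing; the
  homodimer mean and SD are about twice the heterodimer's because a
  substitution appears in both subunits of a homodimer but only one of a
  heterodimer). In *empirical* mode the triple is drawn uniformly from a
  per-structure table of all 19 substitutions per position; the sampled
  substitution is recorded so paralog sequences and identities can be
  tracked. The table is immutable during a run: effects are sampled from the
  wild-type-derived distribution and applied additively, a deliberate
  simplification that keeps the global distribution of effects constant and
  ignores epistasis.
* **Expression** (probability `p_exp`): a multiplicative synthesis-rate
  change `s -> s * (1 + eps)` with eps skew-normal (mean 0, SD 0.025, sample
  skewness -0.125; fit to promoter mutagenesis data). The "skew" parameter
  is interpreted as the distribution's sample skewness and the skew-normal
  (delta, omega, xi) are obtained in closed form from the first three
  moments; the resulting scipy-convention parameters are cross-checked
  against `scipy.stats.skewnorm.stats` in the tests. The `(1 + eps)` reading
  keeps the mean rate unchanged (a mean-zero multiplicative factor taken
  literally would annihilate synthesis).
* **Duplication**: doubles the locus with identical parameters; only ever
  the first fixation.

The affected paralog is chosen uniformly for every coding/expression event.
A coding mutation on A adds its effects to `dG_fold,A`, `dG_bind,AA` and
`dG_bind,AB`, leaving BB untouched (mirrored for B).

**Residual statistic.** Because a substitution hits two interfaces in a
homodimer but one in a heterodimer, the null expectation is
`ddG_HET = 0.5 * ddG_HM`. The residual `ddG_HET - 0.5 * ddG_HM` measures the
deviation: negative values favor the heterodimer. The enrichment score of a
set of residuals is `fraction(< -0.2) - fraction(> +0.2)` (kcal/mol
threshold, configurable; 0.1-0.4 give the same qualitative picture).

## Origin-fixation simulation

Mutations arise one at a time and fix or vanish before the next arises.
Each replicate: (1) start at the pre-duplication reference equilibrium;
(2) propose the duplication repeatedly until it fixes (it is beneficial
under both standard alpha values) and record it as fixation #1 — coding
drift before duplication is omitted; (3) propose coding/expression
mutations, recompute the full equilibrium, activity and fitness after every
proposal (no incremental updates), and accept with the fixation probability;
(4) stop at 200 fixations (50 replicates per condition by default).
Proposals that are rejected are counted but do not advance the fixation
budget.

The fixation probability defaults to the Kimura diffusion approximation
`p = (1 - exp(-2s)) / (1 - exp(-2Ns))` with `s = f_new/f_old - 1` and
haploid population size N = 1000, continuous at s = 0 where it equals 1/N.
The population size and the formula are reconstructions — the source
protocol does not specify them — so a Metropolis-style rule
(`min(1, f_new/f_old)`) is available behind the same interface, and the
Kimura default is validated against a brute-force Wright-Fisher oracle in
the tests. A `selection="neutral"` switch forces constant fitness, which
makes the acceptance rate exactly 1/N and isolates mutational bias from
selection in the tests.

Determinism: one user seed feeds a `numpy.random.SeedSequence`; each
replicate gets an independent spawned stream, and a fixed seed reproduces
every trajectory bit-identically. The inner propose/solve/accept loop is
compiled with numba because near-neutral acceptance (~1/N) means a
200-fixation replicate performs on the order of 1e5 equilibrium solves
(~1-3 s per replicate compiled).

## Numerical choices

* **Quartic solving.** The quartic's four roots come from the eigenvalues of
  its companion matrix. At the exactly symmetric state the leading
  coefficient vanishes identically (`4 d_AA k_AA d_BB k_BB = (d_AB k_AB)^2`),
  so leading coefficients below `1e-12 * max|coeff|` are trimmed and the
  reduced-degree polynomial is solved. Roots with `|imag| > 1e-9 |real|` are
  rejected.
* **Conditioning.** Back-substituting c_B from subunit A's flux balance
  cancels catastrophically when A binds strongly and B is nearly silent.
  c_B is therefore recovered from B's *own* flux balance — a rationalized
  quadratic in c_B that is cancellation-free in every regime — and each
  candidate root of the quartic is polished by Newton iteration on A's flux
  residual (tolerance 1e-13 relative). Roots that fail A's balance after
  polishing are spurious (negative-c_B branches) and are discarded. If no
  root survives (extremely ill-conditioned corners, e.g. folded synthesis
  ~1e-16 after massive destabilization), a guaranteed bisection bracket on
  (0, c_A_single-gene] finds the solution of the same residual. More than
  one surviving distinct root raises an error rather than silently picking
  one; this has never been observed.
* **Verification.** Both subunit flux balances are asserted to 1e-8
  relative at every returned equilibrium, and the solution is checked
  against stiff ODE integration of the explicit mass-action system on 100
  randomized states (energies log-uniform in [-15, -2], synthesis in
  [10, 500]) to < 1e-6 relative deviation.
* **Degenerate heterodimer binding.** For `k_AB < 1e-12` (dG_bind,AB above
  ~+16 kcal/mol) the coupled system degenerates; the solver switches to two
  independent single-gene equilibria with c_AB = 0, the continuous limit.
* **Overflow.** Association-constant exponents are clamped at 700 (K ~
  1e304); the clamp is far outside the evolved range and only protects
  against pathological inputs.
* **Expression multipliers** are floored at 0 so synthesis rates stay
  non-negative (the skew-normal makes `1 + eps < 0` practically impossible).

## Outcome analysis

Final states are summarized as relative concentrations
`p_X = 100 c_X / sum(c)` and classified with inclusive 70% thresholds in
fixed precedence: HET dominant (p_AB >= 70), HM dominant (p_AA + p_BB >=
70), both HM and HET (dimers together >= 70, neither class dominant),
monomers (p_A + p_B >= 70), ambiguous. The headline "percentage of
heterodimers" is reported both among all species and among dimers only
(`100 c_AB / (c_AA + c_AB + c_BB)`); the among-dimers variant is the one
that starts at exactly 50% after duplication and is used in the acceptance
quantities. Classification is applied per replicate and label fractions are
aggregated; across-replicate means of the final percentages are the
per-condition summary. Spearman correlations (asymptotic-t p-values, via
scipy) link per-structure enrichment scores to mean final heterodimer
shares, and the cumulative residual of fixed coding mutations is tracked
along each trajectory.

## Synthetic structure tables

`generate_synthetic_structure` emulates the statistical shape of a FoldX
deep mutational scan of one homodimer: a random wild-type sequence
(default 240 positions, the mean length of the real structure set), all 19
substitutions per position, effect triples from the parametric base model,
and a tunable `residual_bias` added to ddG_bind_HET that shifts the table
off the 0.5-slope diagonal (negative = heterodimer-favoring). What it does
*not* emulate: position-specific effect structure (buried vs. interface
vs. surface residues), outliers beyond normality, within-position effect
correlations, and any relationship between sequence and effect — so passing
parameter-recovery tests demonstrate that the simulator responds correctly
to a known planted bias, not that real structures have such biases.

## Problem sizes used in tests and analyses

The packaged analyses and the test suite run reduced but qualitatively
stable sizes chosen as the package's own defaults for desk-scale work: the
parameter-recovery experiment uses 5-9 bias levels x 10-20 replicates x
100 fixations on 60-80-position tables; the parametric p_exp sweep uses 25
replicates. The headline expression-dominated quantity (p_exp = 0.9) is
always computed at the full 50 replicates x 200 fixations. Because
per-replicate outcomes are strongly dispersed (individual replicates can
end heterodimer- or homodimer-dominant), the across-replicate mean of the
heterodimer share has a standard error of roughly 5 percentage points at 50
replicates; observed means under different seeds fall in the low-to-mid 40s
through high 50s.

## Known limitations

* The fixation model, population size and duplication-fixation mechanics
  are reconstructions (see above); conclusions that depend only on
  relative comparisons between conditions are insensitive to this choice,
  absolute time scales are not.
* Effects are sampled i.i.d. from a fixed distribution: no epistasis, no
  depletion of available substitutions, no back-mutation bookkeeping beyond
  sequence overwrites.
* The equilibrium treats binding as fully equilibrated between fixations;
  kinetic effects (assembly order, cotranslational assembly,
  compartmentalization) are out of scope.
* Empirical tables are trusted as given; the package validates their schema
  and invariants but cannot detect physically implausible energies.
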