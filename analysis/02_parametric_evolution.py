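#!/usr/bin/env python
"""Origin-fixation evolution under pooled (parametric) mutational effects.

Runs the two standard regimes at alpha = 80 h^-1:

* coding-only (p_exp = 0): mutations perturb folding/binding energies drawn
  from the correlated trivariate normal; replicates drift toward heterodimer
  or homodimer dominance stochastically, with a mid-range mean;
* expression-dominated (p_exp = 0.9): most mutations rescale synthesis
  rates; divergence in expression keeps the mean final heterodimer share in
  the 40-60% band.

Outputs: results/parametric_summary.tsv (one row per condition) and
results/parametric_pexp_sweep.tsv (mean final composition vs p_exp).
"""

from pathlib import Path

import pandas as pd

import dimerfate as dd

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REPLICATES = 25  # half the headline replicate count; see docs/methods.md
FIXATIONS = 200


def run(p_exp: float, seed: int) -> dict:
    cfg = dd.SimulationConfig(
        n_fixed_target=FIXATIONS, n_replicates=REPLICATES,
        alpha=80.0, beta=0.5, p_exp=p_exp, seed=seed,
    )
    res = dd.run_simulation(cfg, dd.ParametricEffectModel())
    s = res.summary()
    s["p_exp"] = p_exp
    return s


def main() -> None:
    rows = [run(p_exp, seed=100 + i) for i, p_exp in enumerate((0.0, 0.3, 0.6, 0.9))]
    df = pd.DataFrame(rows).set_index("p_exp")
    df.to_csv(OUT / "parametric_pexp_sweep.tsv", sep="\t")
    df[df.index.isin([0.0, 0.9])].to_csv(OUT / "parametric_summary.tsv", sep="\t")
    for p_exp, row in df.iterrows():
        print(
            f"p_exp={p_exp:.1f}: mean heterodimer {row['mean_het_pct_dimers']:.1f}% "
            f"of complexes | HET-dominant {row['frac_HET_dominant']:.0%}, "
            f"HM-dominant {row['frac_HM_dominant']:.0%}, "
            f"both {row['frac_both_HM_and_HET']:.0%}"
        )
    print(
        "\nHigher p_exp pulls outcomes toward the middle: expression "
        "divergence preserves both dimer classes."
    )


if __name__ == "__main__":
    main()
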