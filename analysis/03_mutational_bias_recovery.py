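#!/usr/bin/env python
"""Mutational bias drives heterodimer takeover: parameter recovery.

Generates synthetic per-structure effect tables spanning residual-bias
levels (the shift of heterodimer binding effects away from the 0.5-slope
diagonal), evolves each structure, and correlates each table's enrichment of
heterodimer-favoring residuals with the mean final heterodimer share. A
positive, significant Spearman correlation recovers the planted bias, and
the cumulative residual fixed along each trajectory anticorrelates with the
final heterodimer share.

Outputs: results/bias_recovery.tsv, results/bias_recovery_correlation.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import dimerfate as dd
from dimerfate.analysis import cumulative_fixed_residuals

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

BIASES = np.linspace(-0.4, 0.4, 9)
REPLICATES = 10
FIXATIONS = 100


def main() -> None:
    rows = []
    cum_finals = []
    for i, bias in enumerate(BIASES):
        table = dd.generate_synthetic_structure(
            dd.SyntheticStructureSpec(n_positions=80, residual_bias=float(bias), seed=3000 + i)
        )
        cfg = dd.SimulationConfig(
            n_fixed_target=FIXATIONS, n_replicates=REPLICATES, seed=200 + i
        )
        res = dd.run_simulation(cfg, table)
        s = res.summary()
        rows.append(
            dict(
                residual_bias=float(bias),
                enrichment=table.enrichment_score(),
                mean_het_pct=s["mean_het_pct_dimers"],
                frac_HET_dominant=s["frac_HET_dominant"],
                mean_identity_A_B=s.get("mean_identity_A_B", np.nan),
            )
        )
        for t in res.trajectories:
            cum_finals.append(
                (
                    cumulative_fixed_residuals(t).iloc[-1],
                    t.final_concentrations.het_fraction_among_dimers,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "bias_recovery.tsv", sep="\t", index=False)

    rho, p = dd.analysis.enrichment_outcome_correlation(df["enrichment"], df["mean_het_pct"])
    cum, fin = zip(*cum_finals)
    rho_cum, p_cum = stats.spearmanr(cum, fin)
    report = {
        "n_structures": len(df),
        "enrichment_vs_final_het": {"spearman_rho": rho, "p_value": p},
        "cumulative_fixed_residual_vs_final_het": {
            "spearman_rho": float(rho_cum),
            "p_value": float(p_cum),
            "n_replicates": len(cum_finals),
        },
    }
    with open(OUT / "bias_recovery_correlation.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nenrichment vs final HET%: Spearman rho={rho:.3f} (p={p:.2e})")
    print(
        f"cumulative fixed residual vs final HET%: rho={rho_cum:.3f} (p={p_cum:.2e})"
    )


if __name__ == "__main__":
    main()
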