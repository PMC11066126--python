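"""Post-processing of simulated trajectories.

Relative concentrations (percent of the summed species), outcome
classification against the 70% dominance thresholds, replicate summaries,
and the residual/enrichment statistics linking mutational bias to the final
heterodimer share.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import enrichment_score  # re-exported for analysis pipelines
from .equilibrium import Concentrations

__all__ = [
    "OUTCOME_LABELS",
    "relative_concentrations",
    "classify_outcome",
    "summarize_run",
    "enrichment_outcome_correlation",
    "cumulative_fixed_residuals",
    "enrichment_score",
]

#: The five mutually exclusive outcome labels, in classification precedence.
OUTCOME_LABELS = ("HET_dominant", "HM_dominant", "both_HM_and_HET", "monomers", "ambiguous")

_SPECIES = ("p_A", "p_B", "p_AA", "p_AB", "p_BB")


def relative_concentrations(conc: Concentrations | Sequence[float]) -> dict[str, float]:
    """Percent of each species among the summed concentrations,
    ``p_X = 100 * c_X / sum(c)``; the five values sum to 100."""
    if isinstance(conc, Concentrations):
        arr = conc.as_array()
    else:
        arr = np.asarray(conc, dtype=float)
        if arr.shape != (5,):
            raise ValueError("expected 5 concentrations (c_A, c_B, c_AA, c_AB, c_BB)")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("concentrations must be finite and non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("at least one concentration must be positive")
    pct = 100.0 * arr / total
    return dict(zip(_SPECIES, pct.tolist()))


def classify_outcome(percentages: Mapping[str, float]) -> str:
    """Classify a final state by its relative concentrations.

    Rules (inclusive 70% thresholds, applied in order):
    HET_dominant if p_AB >= 70; HM_dominant if p_AA + p_BB >= 70;
    both_HM_and_HET if the dimers together reach 70 but neither class does;
    monomers if p_A + p_B >= 70; ambiguous otherwise.
    """
    p_ab = percentages["p_AB"]
    p_hm = percentages["p_AA"] + percentages["p_BB"]
    p_mono = percentages["p_A"] + percentages["p_B"]
    if p_ab >= 70:
        return "HET_dominant"
    if p_hm >= 70:
        return "HM_dominant"
    if p_ab + p_hm >= 70:
        return "both_HM_and_HET"
    if p_mono >= 70:
        return "monomers"
    return "ambiguous"


def summarize_run(replicates: pd.DataFrame | Iterable[Mapping[str, float]]) -> dict:
    """Across-replicate means of the final percentages and label fractions.

    ``replicates``: one row/mapping per replicate with the five ``p_X``
    columns (e.g. :meth:`SimulationResult.final_percentages` output). Labels
    are computed per replicate, then counted.
    """
    df = pd.DataFrame(replicates)
    if len(df) == 0:
        raise ValueError("no replicates to summarize")
    out = {f"mean_{k}": float(df[k].mean()) for k in _SPECIES}
    labels = df.apply(lambda r: classify_outcome({k: r[k] for k in _SPECIES}), axis=1)
    for label in OUTCOME_LABELS:
        out[f"frac_{label}"] = float((labels == label).mean())
    if "het_pct_dimers" in df:
        out["mean_het_pct_dimers"] = float(df["het_pct_dimers"].mean())
    out["n_replicates"] = len(df)
    return out


def enrichment_outcome_correlation(
    enrichment_scores: Sequence[float], mean_final_het_pct: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation (rho, asymptotic-t p-value) between per-structure
    enrichment scores and mean final heterodimer percentages.

    A constant input vector leaves rho undefined; (nan, nan) is returned.
    """
    x = np.asarray(enrichment_scores, dtype=float)
    y = np.asarray(mean_final_het_pct, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cumulative_fixed_residuals(trajectory) -> pd.Series:
    """Running sum of the diagonal residual over fixed coding mutations.

    Accepts a :class:`~dimerfate.evolve.Trajectory` or its ``records`` frame;
    returns one value per fixation (non-coding events contribute 0), indexed
    by fixation number.
    """
    df = getattr(trajectory, "records", trajectory)
    res = np.zeros(len(df))
    coding = (df["kind"] == "coding").to_numpy()
    res[coding] = (
        df.loc[coding, "ddG_bind_HET"].to_numpy()
        - 0.5 * df.loc[coding, "ddG_bind_HM"].to_numpy()
    )
    return pd.Series(np.cumsum(res), index=df["fixation"].to_numpy(), name="cum_residual")
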