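"""Distributions of mutational effects.

Three sources of mutational perturbations feed the evolutionary simulations:

* :class:`ParametricEffectModel` — a correlated trivariate normal over
  (ddG_fold, ddG_bind homodimer, ddG_bind heterodimer), with defaults matching
  the pooled statistics of FoldX-style mutational scans of homodimer
  structures (fold ~ N(2.6, 4.6), HM ~ N(0.4, 2.4), HET ~ N(0.2, 1.2);
  corr(HM, HET) = 0.9, corr(fold, HM) = corr(fold, HET) = 0.3).
* :class:`EmpiricalEffectTable` — per-substitution ddG records for one
  structure (19 amino-acid substitutions per position), sampled uniformly.
* :class:`ExpressionEffectModel` — skew-normal multiplicative perturbations of
  synthesis rate (mean 0, SD 0.025, sample skewness -0.125, fit to promoter
  mutagenesis data).

This module also provides the diagonal-residual statistic
``residual = ddG_bind,HET - 0.5 * ddG_bind,HM`` and the enrichment score
measuring the excess of heterodimer-favoring over homodimer-favoring
residuals beyond a threshold (default 0.2 kcal/mol).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "ParametricEffectModel",
    "EmpiricalEffectTable",
    "ExpressionEffectModel",
    "MutationEffect",
    "EffectTableError",
    "sample_parametric_effect",
    "read_effect_table",
    "sample_empirical_effect",
    "sample_expression_effect",
    "residual",
    "enrichment_score",
]

#: The 20 standard amino acids, one-letter codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

TABLE_COLUMNS = ("position", "wt_aa", "mut_aa", "ddG_fold", "ddG_bind_HM", "ddG_bind_HET")


class EffectTableError(ValueError):
    """Malformed or invariant-violating per-substitution effect table."""


@dataclass(frozen=True)
class MutationEffect:
    """One sampled perturbation, of exactly one kind.

    ``coding`` effects carry the three ddG values (kcal/mol) and optionally a
    recorded substitution ``(position, wt_aa, mut_aa)``; ``expression``
    effects carry a synthesis-rate multiplier; ``duplication`` carries
    nothing.  ``target`` names the affected paralog.
    """

    kind: str
    target: str = "A"
    ddG_fold: float | None = None
    ddG_bind_HM: float | None = None
    ddG_bind_HET: float | None = None
    expr_multiplier: float | None = None
    substitution: tuple[int, str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("coding", "expression", "duplication"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.target not in ("A", "B"):
            raise ValueError("target must be 'A' or 'B'")
        coding_fields = (self.ddG_fold, self.ddG_bind_HM, self.ddG_bind_HET)
        if self.kind == "coding":
            if any(v is None for v in coding_fields) or self.expr_multiplier is not None:
                raise ValueError("coding effect must set exactly the ddG fields")
        elif self.kind == "expression":
            if self.expr_multiplier is None or any(v is not None for v in coding_fields):
                raise ValueError("expression effect must set exactly expr_multiplier")
        else:
            if self.expr_multiplier is not None or any(v is not None for v in coding_fields):
                raise ValueError("duplication carries no effect fields")


# ---------------------------------------------------------------------------
# Parametric (trivariate normal) effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParametricEffectModel:
    """Correlated trivariate normal over (ddG_fold, ddG_bind_HM, ddG_bind_HET).

    Means and SDs are in kcal/mol. Positive means reflect that random
    mutations are on average destabilizing. The implied 3x3 correlation
    matrix must be positive semi-definite (validated at construction).
    """

    mean_fold: float = 2.6
    sd_fold: float = 4.6
    mean_bind_HM: float = 0.4
    sd_bind_HM: float = 2.4
    mean_bind_HET: float = 0.2
    sd_bind_HET: float = 1.2
    corr_HM_HET: float = 0.9
    corr_HM_fold: float = 0.3
    corr_HET_fold: float = 0.3

    def __post_init__(self) -> None:
        for name in ("sd_fold", "sd_bind_HM", "sd_bind_HET"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("corr_HM_HET", "corr_HM_fold", "corr_HET_fold"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")
        if np.linalg.eigvalsh(self.correlation_matrix).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")

    @property
    def mean_vector(self) -> np.ndarray:
        """Means in component order (fold, HM, HET)."""
        return np.array([self.mean_fold, self.mean_bind_HM, self.mean_bind_HET])

    @property
    def sd_vector(self) -> np.ndarray:
        return np.array([self.sd_fold, self.sd_bind_HM, self.sd_bind_HET])

    @property
    def correlation_matrix(self) -> np.ndarray:
        c = np.array(
            [
                [1.0, self.corr_HM_fold, self.corr_HET_fold],
                [self.corr_HM_fold, 1.0, self.corr_HM_HET],
                [self.corr_HET_fold, self.corr_HM_HET, 1.0],
            ]
        )
        return c

    @property
    def scale_matrix(self) -> np.ndarray:
        """Matrix L with x = mean + L @ z, z ~ N(0, I); equals
        diag(sd) @ sqrt(corr). Uses an eigendecomposition square root so that
        singular-but-PSD correlation matrices (|corr| = 1) remain valid."""
        corr = self.correlation_matrix
        w, V = np.linalg.eigh(corr)
        w = np.clip(w, 0.0, None)
        root = V @ np.diag(np.sqrt(w)) @ V.T
        return np.diag(self.sd_vector) @ root

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw (size, 3) (or (3,) when size is None) correlated effects."""
        n = 1 if size is None else int(size)
        z = rng.standard_normal((n, 3))
        x = self.mean_vector + z @ self.scale_matrix.T
        return x[0] if size is None else x


def sample_parametric_effect(
    model: ParametricEffectModel, rng: np.random.Generator, target: str = "A"
) -> MutationEffect:
    """One coding mutation drawn from the trivariate normal model."""
    fold, hm, het = model.sample(rng)
    return MutationEffect(
        kind="coding", target=target, ddG_fold=fold, ddG_bind_HM=hm, ddG_bind_HET=het
    )


# ---------------------------------------------------------------------------
# Empirical per-substitution tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmpiricalEffectTable:
    """Per-substitution ddG records for one structure.

    ``data`` has columns position (1-based), wt_aa, mut_aa, ddG_fold,
    ddG_bind_HM, ddG_bind_HET; ``sequence`` is the wild-type amino-acid
    string. Folding effects are those estimated on the single-substituted
    (heteromer-like) complex, since the model uses them only to compute the
    folded fraction of individual subunits.
    """

    data: pd.DataFrame
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise EffectTableError(f"missing columns: {missing}")
        if len(df) == 0:
            raise EffectTableError("empty effect table")
        if (df["wt_aa"] == df["mut_aa"]).any():
            bad = df.index[df["wt_aa"] == df["mut_aa"]][0]
            raise EffectTableError(f"self-substitution at row {bad}")
        pos = df["position"].to_numpy()
        if pos.min() < 1 or pos.max() > len(self.sequence):
            raise EffectTableError("position outside sequence length")
        seq = np.array(list(self.sequence))
        if (seq[pos - 1] != df["wt_aa"].to_numpy()).any():
            raise EffectTableError("wt_aa inconsistent with sequence")
        if df.duplicated(subset=["position", "mut_aa"]).any():
            raise EffectTableError("duplicate (position, mut_aa) rows")
        for col in ("ddG_fold", "ddG_bind_HM", "ddG_bind_HET"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise EffectTableError(f"non-finite values in {col}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def effects_array(self) -> np.ndarray:
        """(n, 3) float array in component order (fold, HM, HET)."""
        return self.data[["ddG_fold", "ddG_bind_HM", "ddG_bind_HET"]].to_numpy(dtype=float)

    @property
    def residuals(self) -> np.ndarray:
        e = self.effects_array
        return e[:, 2] - 0.5 * e[:, 1]

    def enrichment_score(self, threshold: float = 0.2) -> float:
        return enrichment_score(self.residuals, threshold)

    def substitution(self, row: int) -> tuple[int, str, str]:
        r = self.data.iloc[row]
        return int(r["position"]), str(r["wt_aa"]), str(r["mut_aa"])

    def to_tsv(self, path: str | Path) -> None:
        write_effect_table(self, path)


def write_effect_table(table: EmpiricalEffectTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (UTF-8, '# sequence:' comment line,
    then a tab-separated header and one row per substitution)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sequence: {table.sequence}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for row in table.data.itertuples(index=False):
            fh.write(
                f"{int(row.position)}\t{row.wt_aa}\t{row.mut_aa}\t"
                f"{row.ddG_fold!r}\t{row.ddG_bind_HM!r}\t{row.ddG_bind_HET!r}\n"
            )


def read_effect_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> EmpiricalEffectTable:
    """Read a per-substitution effect table from TSV.

    ``column_map`` maps canonical column names to the names used in the file,
    so tables exported with a different header dialect (e.g. a
    MutateX-derived column order) can be read without rewriting:
    ``read_effect_table(p, column_map={"ddG_bind_HM": "ddg_homo", ...})``.
    """
    path = Path(path)
    sequence = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# sequence:"):
            sequence = first.split(":", 1)[1].strip()
            header_line = 1
        else:
            header_line = 0
    try:
        df = pd.read_csv(
            path, sep="\t", skiprows=header_line, comment=None,
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise EffectTableError(f"cannot parse {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise EffectTableError(f"{path}: missing columns {missing}")
    df = df[list(TABLE_COLUMNS)]
    for i, col in enumerate(("ddG_fold", "ddG_bind_HM", "ddG_bind_HET")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +1 header +1 1-based (+1 sequence comment when present)
            line = int(bad[0]) + 2 + header_line
            raise EffectTableError(f"{path}: non-numeric {col} at line {line}")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2 + header_line
            raise EffectTableError(f"{path}: missing {col} at line {line}")
        df[col] = vals.astype(float)
    df["position"] = df["position"].astype(int)
    if sequence is None:
        # reconstruct the wild-type sequence from per-position wt residues
        n = int(df["position"].max())
        seq = ["X"] * n
        for p, wt in zip(df["position"], df["wt_aa"]):
            seq[p - 1] = wt
        sequence = "".join(seq)
    return EmpiricalEffectTable(
        data=df.reset_index(drop=True), sequence=sequence, name=name or path.stem
    )


def sample_empirical_effect(
    table: EmpiricalEffectTable, rng: np.random.Generator, target: str = "A"
) -> MutationEffect:
    """Uniform draw over the table rows, recording the substitution."""
    if len(table) == 0:
        raise EffectTableError("cannot sample from an empty table")
    i = int(rng.integers(len(table)))
    fold, hm, het = table.effects_array[i]
    return MutationEffect(
        kind="coding",
        target=target,
        ddG_fold=float(fold),
        ddG_bind_HM=float(hm),
        ddG_bind_HET=float(het),
        substitution=table.substitution(i),
    )


# ---------------------------------------------------------------------------
# Expression (synthesis-rate) effects
# ---------------------------------------------------------------------------


def _skewnorm_shape(mean: float, sd: float, skew: float) -> tuple[float, float, float]:
    """Closed-form (delta, omega, xi) of a skew-normal with the given first
    three moments (``skew`` = sample skewness, |skew| < ~0.995)."""
    if abs(skew) >= 0.99527:
        raise ValueError("skew-normal sample skewness must be below ~0.995")
    g = abs(skew)
    b = (2.0 * g / (4.0 - math.pi)) ** (1.0 / 3.0)
    m = math.copysign(b / math.sqrt(1.0 + b * b), skew)  # = delta*sqrt(2/pi)
    delta = m * math.sqrt(math.pi / 2.0)
    omega = sd / math.sqrt(1.0 - m * m) if sd > 0 else 0.0
    xi = mean - omega * m
    return delta, omega, xi


@dataclass(frozen=True)
class ExpressionEffectModel:
    """Skew-normal relative perturbation of synthesis rate.

    The sampled value eps has mean ``mean``, standard deviation ``sd`` and
    sample skewness ``skew``; it is applied multiplicatively by the caller as
    ``s_new = s_old * (1 + eps)`` (the perturbations are expressed relative
    to the current rate).
    """

    mean: float = 0.0
    sd: float = 0.025
    skew: float = -0.125

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        _skewnorm_shape(self.mean, max(self.sd, 1e-12), self.skew)  # validate skew

    @property
    def shape_params(self) -> tuple[float, float, float]:
        """(delta, omega, xi) of the underlying skew-normal."""
        return _skewnorm_shape(self.mean, self.sd, self.skew)

    @property
    def scipy_params(self) -> tuple[float, float, float]:
        """(a, loc, scale) as used by scipy.stats.skewnorm."""
        delta, omega, xi = self.shape_params
        a = delta / math.sqrt(max(1.0 - delta * delta, 1e-300))
        return a, xi, omega

    def sample_epsilon(self, rng: np.random.Generator, size: int | None = None):
        """Draw eps via the two-normal representation
        X = delta*|U0| + sqrt(1-delta^2)*U1."""
        delta, omega, xi = self.shape_params
        n = 1 if size is None else int(size)
        u = rng.standard_normal((n, 2))
        x = delta * np.abs(u[:, 0]) + math.sqrt(1.0 - delta * delta) * u[:, 1]
        eps = xi + omega * x
        return float(eps[0]) if size is None else eps


def sample_expression_effect(
    model: ExpressionEffectModel, rng: np.random.Generator, target: str = "A"
) -> MutationEffect:
    """One synthesis-rate mutation: multiplier ``1 + eps``."""
    eps = model.sample_epsilon(rng)
    return MutationEffect(kind="expression", target=target, expr_multiplier=1.0 + eps)


# ---------------------------------------------------------------------------
# Residual / enrichment statistics
# ---------------------------------------------------------------------------


def residual(effect: MutationEffect) -> float:
    """Deviation from the half-slope diagonal,
    ``ddG_bind,HET - 0.5 * ddG_bind,HM``.

    A mutation on one subunit hits one of the two interfaces contributed by
    that subunit in the homodimer but only one interface in the heterodimer,
    so the null expectation is a heterodimer effect half the homodimer one.
    Negative residuals favor the heterodimer.
    """
    if effect.kind != "coding":
        raise ValueError("residual is defined for coding effects only")
    return effect.ddG_bind_HET - 0.5 * effect.ddG_bind_HM


def enrichment_score(residuals: Iterable[float], threshold: float = 0.2) -> float:
    """Fraction of residuals below ``-threshold`` minus fraction above
    ``+threshold`` (in [-1, 1]); positive = heterodimer-favoring bias."""
    r = np.asarray(list(residuals) if not isinstance(residuals, np.ndarray) else residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual list")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return float(np.mean(r < -threshold) - np.mean(r > threshold))
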