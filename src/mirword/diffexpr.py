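"""Two-arm differential expression with an empirical-Bayes moderated t.

The input is a log-scale expression matrix (genes x samples) from a
treated-vs-control overexpression experiment with at least two replicates
per arm. Per-gene sample variances ``s2_g`` (pooled, ``d_g = n1 + n2 - 2``
df) are shrunk toward a common prior variance ``s0^2`` with prior degrees of
freedom ``d0``::

    s2_tilde = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t_tilde  = lfc / sqrt(s2_tilde * (1/n1 + 1/n2))

``(d0, s0^2)`` are estimated by moment-matching the log sample variances
against a scaled-F prior: with ``e_g = log s2_g - digamma(d_g/2) +
log(d_g/2)``, the model implies ``var(e) = trigamma(d_g/2) +
trigamma(d0/2)`` and ``mean(e) = log s0^2 + digamma(d0/2) - log(d0/2)``;
``d0`` comes from inverting the trigamma equation numerically. When the
moment equations have no positive solution the prior df is infinite (full
pooling to ``s0^2``).

With ``d0 = 0`` the statistic reduces exactly to the classical pooled
two-sample t; as ``d0 -> inf`` every gene's variance is replaced by
``s0^2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .enrichment import RankedGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to the two arms of the experiment."""

    treated: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.treated) < 2 or len(self.control) < 2:
            raise ValueError("need >= 2 replicates per arm for variance estimation")
        if set(self.treated) & set(self.control):
            raise ValueError("a sample cannot belong to both arms")

    @property
    def n1(self) -> int:
        return len(self.treated)

    @property
    def n2(self) -> int:
        return len(self.control)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        """Read a two-column TSV (sample_id, arm) with arm in
        {treated, control}."""
        tbl = pd.read_csv(path, sep="\t", dtype=str)
        if tbl.shape[1] < 2:
            raise ValueError(f"design file {path} needs columns sample_id, arm")
        sample_col, arm_col = tbl.columns[:2]
        arms = tbl[arm_col].str.lower()
        bad = set(arms) - {"treated", "control"}
        if bad:
            raise ValueError(f"unknown arm label(s) {sorted(bad)} in {path}")
        return cls(
            treated=tuple(tbl.loc[arms == "treated", sample_col]),
            control=tuple(tbl.loc[arms == "control", sample_col]),
        )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene_id, header
    row required). Rows with missing values are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"expression matrix {path} has fewer than 2 sample columns")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene row(s) with missing values", n_missing)
        df = df.dropna(axis=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    return df.astype(float)


def normalize(matrix: pd.DataFrame, *, skip: bool = False) -> pd.DataFrame:
    """Median-center each sample column so all per-sample medians are zero.

    This simple location normalization stands in for heavier array
    normalization schemes; pass ``skip=True`` to accept a pre-normalized
    matrix unchanged. Downstream word enrichment depends only on the gene
    ranking, which is insensitive to the choice at this scale.
    """
    if skip:
        return matrix
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix - np.median(values, axis=0, keepdims=True)


@dataclass
class ModeratedTResult:
    """Per-gene moderated-t output plus the shared prior parameters.

    ``table`` is indexed by gene_id with columns ``lfc`` (treated - control),
    ``s2_g``, ``s2_tilde``, ``t_tilde`` and ``df`` (= d0 + d_g).
    """

    table: pd.DataFrame
    d0: float
    s0_squared: float
    n1: int
    n2: int

    @property
    def d_g(self) -> int:
        return self.n1 + self.n2 - 2

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < tol * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from pooled sample variances.

    Genes with zero sample variance are excluded from the fit (they carry no
    information about the variance distribution's spread on the log scale).
    Returns ``d0 = inf`` when the observed spread of log variances does not
    exceed what sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need >= 2 genes with positive variance to fit the prior")
    if positive.size < s2.size:
        logger.warning(
            "excluding %d zero-variance gene(s) from prior estimation",
            s2.size - positive.size,
        )
    e = np.log(positive) - digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(polygamma(1, d_g / 2.0))
    if excess <= 0:
        logger.warning(
            "log-variance spread below sampling expectation; using d0 = inf "
            "(full pooling)"
        )
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def fit_moderated_t(
    matrix: pd.DataFrame,
    design: GroupDesign,
    *,
    d0: float | None = None,
    s0_squared: float | None = None,
) -> ModeratedTResult:
    """Fit the moderated t-statistic for every gene.

    ``d0``/``s0_squared`` may be forced (e.g. ``d0=0`` recovers the
    classical pooled t; ``d0=inf`` with a given ``s0_squared`` applies full
    pooling); by default both are estimated from the data via
    :func:`estimate_variance_prior`.
    """
    missing = (set(design.treated) | set(design.control)) - set(matrix.columns)
    if missing:
        raise ValueError(f"design samples not in matrix: {sorted(missing)}")
    x1 = matrix[list(design.treated)].to_numpy(dtype=float)
    x2 = matrix[list(design.control)].to_numpy(dtype=float)
    n1, n2 = design.n1, design.n2
    d_g = n1 + n2 - 2
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = x1.var(axis=1, ddof=1) * (n1 - 1)
    ss2 = x2.var(axis=1, ddof=1) * (n2 - 1)
    s2_g = (ss1 + ss2) / d_g

    if d0 is None:
        d0, s0_est = estimate_variance_prior(s2_g, d_g)
        if s0_squared is None:
            s0_squared = s0_est
    elif d0 > 0 and s0_squared is None:
        _, s0_squared = estimate_variance_prior(s2_g, d_g)
    elif s0_squared is None:
        s0_squared = 0.0  # unused when d0 == 0

    if math.isinf(d0):
        s2_tilde = np.full_like(s2_g, s0_squared)
    else:
        s2_tilde = (d0 * s0_squared + d_g * s2_g) / (d0 + d_g)
    scale = s2_tilde * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_tilde = np.where(scale > 0, lfc / np.sqrt(scale), np.nan)
    n_undefined = int(np.isnan(t_tilde).sum())
    if n_undefined:
        logger.warning(
            "%d gene(s) have undefined moderated t (zero variance with d0=0)",
            n_undefined,
        )
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "s2_g": s2_g,
            "s2_tilde": s2_tilde,
            "t_tilde": t_tilde,
            "df": np.full(len(lfc), d0 + d_g),
        },
        index=matrix.index,
    )
    return ModeratedTResult(table=table, d0=d0, s0_squared=s0_squared, n1=n1, n2=n2)


def rank_genes(
    result: ModeratedTResult,
    direction: str = "down_first",
    metric: str = "t",
) -> RankedGeneList:
    """Order genes by expression change; rank 1 = most changed in the
    requested direction.

    ``metric`` selects the moderated t (``"t"``, default) or the log fold
    change (``"lfc"``). Ties break lexicographically on gene_id; genes with
    an undefined statistic are placed last with a warning.
    """
    if direction not in ("down_first", "up_first"):
        raise ValueError("direction must be down_first or up_first")
    if metric not in ("t", "lfc"):
        raise ValueError("metric must be 't' or 'lfc'")
    col = "t_tilde" if metric == "t" else "lfc"
    values = result.table[col]
    n_missing = int(values.isna().sum())
    if n_missing:
        logger.warning("%d gene(s) without a %s value ranked last", n_missing, col)
    sign = 1.0 if direction == "down_first" else -1.0
    keyed = sorted(
        values.items(),
        key=lambda kv: (np.isnan(kv[1]), sign * kv[1] if not np.isnan(kv[1]) else 0.0, kv[0]),
    )
    return RankedGeneList(genes=tuple(g for g, _ in keyed))
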