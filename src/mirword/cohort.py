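"""Tumor-cohort integration: miRNA-mRNA anticorrelation, subclass contrasts
and target-prediction intersection.

A cohort pairs a miRNA expression matrix and an mRNA expression matrix over
a shared sample set, with per-sample expression-subclass labels (proneural /
neural / classical / mesenchymal) and p53 mutation status. Candidate direct
targets — genes passing both external prediction thresholds — are ranked by
combining their down-regulation after miRNA overexpression (moderated t)
with their expression anticorrelation with the miRNA across the cohort
(Spearman rho): strong direct targets sit in the lower-left corner of the
(t, rho) plane.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUBCLASSES = ("proneural", "neural", "classical", "mesenchymal")
P53_STATES = ("wild-type", "mutant", "unknown")


@dataclass
class CohortDataset:
    """Paired miRNA/mRNA expression with sample annotations.

    Matrices are features x samples DataFrames. On construction both are
    restricted to the intersection of their sample sets (and of the
    annotation index), and the resulting n is logged — all downstream
    analyses operate on explicit intersections.
    """

    mirna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    subclass: pd.Series
    p53_status: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shared = (
            self.mirna_expr.columns.intersection(self.mrna_expr.columns)
        ).intersection(self.subclass.index)
        if self.p53_status is None:
            self.p53_status = pd.Series("unknown", index=shared)
        else:
            shared = shared.intersection(self.p53_status.index)
        if len(shared) == 0:
            raise ValueError("miRNA and mRNA matrices share no annotated samples")
        self.mirna_expr = self.mirna_expr[shared]
        self.mrna_expr = self.mrna_expr[shared]
        self.subclass = self.subclass[shared]
        self.p53_status = self.p53_status[shared]
        bad = set(self.subclass) - set(SUBCLASSES)
        if bad:
            raise ValueError(f"unknown subclass label(s): {sorted(bad)}")
        bad = set(self.p53_status) - set(P53_STATES)
        if bad:
            raise ValueError(f"unknown p53 status value(s): {sorted(bad)}")
        logger.info("cohort restricted to %d integrated samples", len(shared))

    @property
    def samples(self) -> pd.Index:
        return self.mirna_expr.columns


def spearman_correlation(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of average-ranked values. For n >= 10 the
    p-value uses the large-sample t approximation; for smaller n it is an
    exact permutation p (all n! orderings for n <= 7, else 10,000 seeded
    Monte-Carlo permutations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p
    # exact / Monte-Carlo permutation p for small n
    def _rho(perm_ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, perm_ry)[0, 1])

    target = abs(rho) - 1e-12
    if n <= 7:
        perms = list(itertools.permutations(ry))
        exceed = sum(abs(_rho(np.array(p_))) >= target for p_ in perms)
        return rho, exceed / len(perms)
    rng = rng or np.random.default_rng(0)
    n_mc = 10_000
    exceed = sum(abs(_rho(rng.permutation(ry))) >= target for _ in range(n_mc))
    return rho, (exceed + 1) / (n_mc + 1)


def subclass_test(
    values: pd.Series,
    labels: pd.Series,
    target_class: str,
    *,
    p53_status: pd.Series | None = None,
    p53_stratum: str | None = None,
) -> float:
    """One-tailed Wilcoxon rank-sum p for the alternative that expression in
    ``target_class`` is lower than in the pooled other subclasses.

    With ``p53_stratum`` set ("wild-type" or "mutant"), the test is run
    within that stratum only; samples with unknown p53 status are excluded
    from stratified tests and included otherwise. The exact null
    distribution is enumerated when min(n1, n2) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction is used.
    """
    values, labels = values.align(labels, join="inner")
    if p53_stratum is not None:
        if p53_status is None:
            raise ValueError("p53_stratum given without p53_status labels")
        stratum_mask = p53_status.reindex(values.index) == p53_stratum
        values, labels = values[stratum_mask], labels[stratum_mask]
    in_target = labels == target_class
    x = values[in_target].to_numpy(dtype=float)
    y = values[~in_target].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        where = f" in p53 stratum {p53_stratum!r}" if p53_stratum else ""
        raise ValueError(f"empty group for subclass test{where}")
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    )


def subclass_test_table(
    cohort: CohortDataset,
    mirna_id: str,
    target_class: str = "proneural",
    stratify_p53: bool = False,
) -> pd.DataFrame:
    """Run the one-tailed subclass contrast, optionally within each p53
    stratum, and return a tidy table (stratum, n_target, n_other, p)."""
    if mirna_id not in cohort.mirna_expr.index:
        raise ValueError(f"{mirna_id!r} not in cohort miRNA matrix")
    values = cohort.mirna_expr.loc[mirna_id]
    rows = []
    strata = ["wild-type", "mutant"] if stratify_p53 else [None]
    for stratum in strata:
        mask = (
            cohort.p53_status == stratum
            if stratum is not None
            else pd.Series(True, index=values.index)
        )
        n_target = int(((cohort.subclass == target_class) & mask).sum())
        n_other = int(((cohort.subclass != target_class) & mask).sum())
        p = subclass_test(
            values,
            cohort.subclass,
            target_class,
            p53_status=cohort.p53_status,
            p53_stratum=stratum,
        )
        rows.append(
            {
                "stratum": stratum or "all",
                "n_target": n_target,
                "n_other": n_other,
                "p_one_tailed": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TargetPredictionList:
    """External per-gene target-prediction scores (lower = stronger)."""

    predictor: str
    scores: pd.Series

    @classmethod
    def from_tsv(cls, predictor: str, path) -> "TargetPredictionList":
        tbl = pd.read_csv(path, sep="\t", dtype={0: str})
        s = pd.Series(tbl.iloc[:, 1].to_numpy(dtype=float), index=tbl.iloc[:, 0])
        if s.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in prediction list {path}")
        return cls(predictor=predictor, scores=s)


def intersect_predictions(
    list_a: TargetPredictionList,
    threshold_a: float,
    list_b: TargetPredictionList,
    threshold_b: float,
) -> set[str]:
    """Genes with score strictly below threshold in *both* prediction lists
    (genes missing from either list are excluded)."""
    if not (math.isfinite(threshold_a) and math.isfinite(threshold_b)):
        raise ValueError("thresholds must be finite")
    pass_a = set(list_a.scores.index[list_a.scores < threshold_a])
    pass_b = set(list_b.scores.index[list_b.scores < threshold_b])
    return pass_a & pass_b


def _deterministic_rank(values: pd.Series) -> pd.Series:
    """Ascending 1..n ranks with ties broken lexicographically on gene_id."""
    order = sorted(values.index, key=lambda g: (values[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)


def integrate(
    candidates,
    moderated_t: pd.Series,
    cohort: CohortDataset,
    mirna_id: str,
) -> pd.DataFrame:
    """Combine overexpression response and cohort anticorrelation per
    candidate gene.

    For each candidate: Spearman rho (and p) of its cohort mRNA expression
    against ``mirna_id``, its moderated t from the overexpression run, and a
    combined rank = rank(t ascending) + rank(rho ascending). Output is
    sorted by combined rank ascending, so position 1 is the gene most
    down-regulated *and* most anticorrelated. Candidates missing from the
    cohort mRNA matrix (or the t table) are logged and excluded.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("no candidate genes to integrate")
    if mirna_id not in cohort.mirna_expr.index:
        raise ValueError(f"{mirna_id!r} not in cohort miRNA matrix")
    mir = cohort.mirna_expr.loc[mirna_id].to_numpy(dtype=float)
    usable, skipped = [], []
    for g in candidates:
        if g in cohort.mrna_expr.index and g in moderated_t.index:
            usable.append(g)
        else:
            skipped.append(g)
    if skipped:
        logger.warning(
            "%d candidate(s) missing from cohort or t table: %s%s",
            len(skipped),
            ", ".join(skipped[:5]),
            "..." if len(skipped) > 5 else "",
        )
    if not usable:
        raise ValueError("no candidate present in both cohort and t table")
    rows = {}
    for g in usable:
        rho, p = spearman_correlation(
            cohort.mrna_expr.loc[g].to_numpy(dtype=float), mir
        )
        rows[g] = {"rho": rho, "p_rho": p, "t_tilde": float(moderated_t[g])}
    tbl = pd.DataFrame.from_dict(rows, orient="index")
    tbl["rank_t"] = _deterministic_rank(tbl["t_tilde"])
    tbl["rank_rho"] = _deterministic_rank(tbl["rho"])
    tbl["combined_rank"] = tbl["rank_t"] + tbl["rank_rho"]
    tbl = tbl.loc[sorted(tbl.index, key=lambda g: (tbl.at[g, "combined_rank"], g))]
    tbl.index.name = "gene_id"
    return tbl
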