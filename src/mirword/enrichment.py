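"""Ranked-list 3'UTR word enrichment with shuffle and permutation nulls.

Given genes ordered by expression change after a miRNA overexpression
(rank 1 = most down-regulated) and their 3'UTRs, every DNA word of the
requested lengths is scored for concentration of its occurrences among the
top of the list, and the scores are calibrated against an empirical null.

The observed statistic for a word is a running-sum maximum over
standardized counts: with ``x_i`` the word's (optionally binary or
length-normalized) count in the UTR at rank ``i`` and ``z_i = (x_i -
mean(x)) / sd(x)`` (population sd over all ``G`` genes),

    R_k   = (sum_{i<=k} z_i) / sqrt(G),        k = 1..G
    score = max_k R_k.

A large score means occurrences pile up among the most down-regulated
genes. The null pools two sources per word: ``B`` scores from uniformly
re-permuted gene orders (fixed counts) and ``S`` scores from re-counting on
independently dinucleotide-shuffled copies of every UTR (fixed order). Each
word's Z is its observed score standardized by its own null mean and sd.

The false discovery rate at level ``z`` is the empirical null exceedance
ratio, computed within each word-length stratum (word-count scale, and
hence score variance, depends on length):

    FDR(z) = mean-null-count{Z_null >= z} / max(1, obs-count{Z_obs >= z}),

capped at 1 and made monotone (non-decreasing as Z decreases) by a running
maximum down the Z-ranked list. Words whose count vector is constant across
genes, or whose null sample is degenerate, are reported as unscorable and
excluded from ranking.

Randomness: one master seed; child streams are derived per
(kind, word-length, replicate) via ``numpy`` spawn keys, so results do not
depend on evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import (
    MIR34A_5P,
    MatureMiRNA,
    SeedAlignment,
    UtrRecord,
    WordCountMatrix,
    align_word_to_mirna,
    dinucleotide_shuffle,
    format_aligned_word,
    kmer_spectra,
)

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by expression change; index 0 = rank 1 = most
    down-regulated."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked gene list contains duplicate ids")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def G(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(genes=tuple(reversed(self.genes)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedGeneList":
        """Read a ranked-list TSV whose first column is gene_id, already in
        rank order (header row required)."""
        tbl = pd.read_csv(path, sep="\t", dtype={0: str})
        return cls(genes=tuple(tbl.iloc[:, 0]))


@dataclass(frozen=True)
class WordScore:
    word: str
    score: float
    null_mean: float
    null_sd: float
    z: float
    rank: int
    fdr: float
    alignment: SeedAlignment | None

    @property
    def formatted_word(self) -> str:
        return format_aligned_word(self.word, self.alignment)


# ---------------------------------------------------------------------------
# scoring kernels
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _max_prefix_kernel(zmat, order, out):  # pragma: no cover - jitted
        n_genes, n_words = zmat.shape
        s = np.zeros(n_words, np.float64)
        best = np.full(n_words, -1.0e300, np.float64)
        for i in range(n_genes):
            r = order[i]
            for w in range(n_words):
                s[w] += zmat[r, w]
                if s[w] > best[w]:
                    best[w] = s[w]
        out[:] = best


def _max_prefix_scores(zmat: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Running-sum maxima (unnormalized) for every word column of the
    (genes x words) matrix ``zmat`` under the gene ordering ``order``.

    The kernel streams whole gene rows in permuted order and carries the
    running sum and maximum per word, which keeps memory access contiguous.
    """
    n_genes, n_words = zmat.shape
    out = np.empty(n_words, dtype=np.float64)
    if n_words == 0:
        return out
    if _HAVE_NUMBA:
        _max_prefix_kernel(zmat, order.astype(np.int64), out)
        return out
    # numpy fallback: chunk over words to bound memory
    chunk = max(1, 32_000_000 // max(1, n_genes))
    for lo in range(0, n_words, chunk):
        sub = zmat[order, lo : lo + chunk].astype(np.float64)
        np.cumsum(sub, axis=0, out=sub)
        out[lo : lo + chunk] = sub.max(axis=0)
    return out


def _standardize(
    counts: np.ndarray,
    *,
    binary: bool = False,
    per_kb: bool = False,
    utr_lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform and z-standardize a (genes x words) count block.

    Returns ``(zmat, scorable)`` where ``zmat`` is (genes x words) float64,
    C-contiguous, with constant-count words zeroed out, and ``scorable``
    marks words with non-constant counts.
    """
    x = counts.astype(np.float64)
    if binary:
        x = (x > 0).astype(np.float64)
    if per_kb:
        if utr_lengths is None:
            raise ValueError("per_kb normalization needs utr_lengths")
        x = x / (np.asarray(utr_lengths, dtype=np.float64)[:, None] / 1000.0)
    mean = x.mean(axis=0)
    # population variance via sum of squares (single pass over the block)
    msq = np.einsum("ij,ij->j", x, x) / x.shape[0]
    var = np.maximum(msq - mean * mean, 0.0)
    sd = np.sqrt(var)
    scorable = sd > 0
    safe_sd = np.where(scorable, sd, 1.0)
    x -= mean
    x /= safe_sd
    if not scorable.all():
        x[:, ~scorable] = 0.0
    return np.ascontiguousarray(x), scorable


def word_score(
    ranked: RankedGeneList,
    counts: WordCountMatrix,
    word: str,
    *,
    binary: bool = False,
    per_kb: bool = False,
    utr_lengths: np.ndarray | None = None,
) -> float:
    """Observed running-sum score of one word on a ranked gene list."""
    order = _ranked_order(ranked, counts.genes)
    col = counts.column(word)[:, None]
    zmat, scorable = _standardize(
        col, binary=binary, per_kb=per_kb, utr_lengths=utr_lengths
    )
    if not scorable[0]:
        raise ValueError(f"word {word!r} has a constant count vector; unscorable")
    score = _max_prefix_scores(zmat, order)[0]
    return float(score / np.sqrt(len(ranked)))


def _ranked_order(ranked: RankedGeneList, genes: Sequence[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in ranked.genes if g not in pos]
    if missing:
        raise ValueError(f"{len(missing)} ranked gene(s) missing from count matrix")
    return np.array([pos[g] for g in ranked.genes], dtype=np.int64)


def permutation_null(
    ranked: RankedGeneList,
    counts: WordCountMatrix,
    word: str,
    B: int,
    rng: np.random.Generator,
    **options,
) -> np.ndarray:
    """``B`` null scores for one word from uniformly permuted gene orders."""
    if B < 0:
        raise ValueError("B must be non-negative")
    order = _ranked_order(ranked, counts.genes)
    col = counts.column(word)[:, None]
    zmat, scorable = _standardize(col, **options)
    if not scorable[0]:
        raise ValueError(f"word {word!r} has a constant count vector; unscorable")
    G = len(ranked)
    out = np.empty(B, dtype=np.float64)
    for b in range(B):
        perm = rng.permutation(order)
        out[b] = _max_prefix_scores(zmat, perm)[0]
    return out / np.sqrt(G)


def shuffle_null(
    utrs: Sequence[UtrRecord],
    words: Sequence[str] | None,
    S: int,
    rng: np.random.Generator,
    *,
    lengths: Iterable[int] | None = None,
) -> list[WordCountMatrix]:
    """``S`` replicate count matrices on dinucleotide-shuffled UTR copies."""
    if S < 1:
        raise ValueError("S must be >= 1")
    replicates = []
    for _ in range(S):
        shuffled = [
            UtrRecord(u.gene_id, dinucleotide_shuffle(u.sequence, rng)) for u in utrs
        ]
        replicates.append(
            WordCountMatrix.from_utrs(shuffled, lengths=lengths, words=words)
        )
    return replicates


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (kind, length, replicate) slot."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


_KIND_PERMUTATION = 0
_KIND_SHUFFLE = 1


@dataclass
class WordEnrichmentResult:
    """Full output of :func:`score_all_words`."""

    scores: list[WordScore]
    unscorable: list[str]
    B: int
    S: int
    seed: int
    lengths: tuple[int, ...]
    options: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "word": s.word,
                "rendered": s.formatted_word,
                "score": s.score,
                "null_mean": s.null_mean,
                "null_sd": s.null_sd,
                "z": s.z,
                "rank": s.rank,
                "fdr": s.fdr,
                "alignment": (
                    f"{s.alignment.mirna_first}-{s.alignment.mirna_last}"
                    if s.alignment
                    else "none"
                ),
            }
            for s in self.scores
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def top(self, k: int) -> pd.DataFrame:
        return report_top_words(self.scores, k)


def score_all_words(
    ranked: RankedGeneList,
    utrs: Sequence[UtrRecord],
    lengths: Iterable[int] = (5, 6, 7),
    B: int = 500,
    S: int = 5,
    seed: int = 0,
    mirna: MatureMiRNA = MIR34A_5P,
    *,
    binary: bool = False,
    per_kb: bool = False,
) -> WordEnrichmentResult:
    """Score the full word universe of the given lengths against the ranked
    list and calibrate Z / rank / FDR on the pooled null.

    Genes in the ranked list without a UTR are dropped with a warning.
    Null calibration (and the FDR's null exceedance pool) is stratified by
    word length. Each word is annotated with its best reverse-complement
    alignment to ``mirna``.
    """
    lengths = tuple(sorted(set(int(k) for k in lengths)))
    if B < 100 or S < 1:
        raise ValueError("need B >= 100 and S >= 1 for a reported FDR")
    utr_by_gene = {u.gene_id: u for u in utrs}
    kept = [g for g in ranked.genes if g in utr_by_gene]
    if len(kept) < len(ranked.genes):
        logger.warning(
            "dropping %d ranked gene(s) without a UTR", len(ranked.genes) - len(kept)
        )
    ranked_utrs = [utr_by_gene[g] for g in kept]
    G = len(ranked_utrs)
    if G < 10:
        raise ValueError("need >= 10 ranked genes with UTRs")
    utr_len = np.array([len(u) for u in ranked_utrs], dtype=np.float64)
    opts = dict(binary=binary, per_kb=per_kb, utr_lengths=utr_len)
    identity = np.arange(G, dtype=np.int64)
    sqrt_g = np.sqrt(G)

    per_word: list[tuple[str, float, float, float, float, float]] = []
    unscorable: list[str] = []
    for k in lengths:
        obs_counts = WordCountMatrix.from_utrs(ranked_utrs, lengths=[k])
        words_k = obs_counts.words
        zmat, scorable = _standardize(obs_counts.counts, **opts)
        unscorable.extend(w for w, ok in zip(words_k, scorable) if not ok)
        idx = np.flatnonzero(scorable)
        if idx.size == 0:
            continue
        if idx.size < zmat.shape[1]:
            zmat = np.ascontiguousarray(zmat[:, idx])
        obs = _max_prefix_scores(zmat, identity) / sqrt_g

        null = np.empty((idx.size, B + S), dtype=np.float64)
        for b in range(B):
            rng = child_rng(seed, _KIND_PERMUTATION, k, b)
            null[:, b] = _max_prefix_scores(zmat, rng.permutation(G)) / sqrt_g
        for s_i in range(S):
            rng = child_rng(seed, _KIND_SHUFFLE, k, s_i)
            shuffled = [
                dinucleotide_shuffle(u.sequence, rng) for u in ranked_utrs
            ]
            sh_counts = kmer_spectra(shuffled, k)
            zmat_s, _ = _standardize(
                sh_counts if idx.size == sh_counts.shape[1] else sh_counts[:, idx],
                **opts,
            )
            null[:, B + s_i] = _max_prefix_scores(zmat_s, identity) / sqrt_g

        null_mean = null.mean(axis=1)
        null_sd = null.std(axis=1)
        degenerate = null_sd == 0
        if degenerate.any():
            unscorable.extend(words_k[idx[j]] for j in np.flatnonzero(degenerate))
        good = ~degenerate
        z_obs = np.full(idx.size, np.nan)
        z_obs[good] = (obs[good] - null_mean[good]) / null_sd[good]
        z_null = (null[good] - null_mean[good, None]) / null_sd[good, None]
        fdr = _empirical_fdr(z_obs[good], z_null.ravel(), B + S)
        for j_local, j in enumerate(np.flatnonzero(good)):
            per_word.append(
                (
                    words_k[idx[j]],
                    float(obs[j]),
                    float(null_mean[j]),
                    float(null_sd[j]),
                    float(z_obs[j]),
                    float(fdr[j_local]),
                )
            )

    # global rank by Z descending, ties lexicographic on the word
    per_word.sort(key=lambda t: (-t[4], t[0]))
    scores = [
        WordScore(
            word=w,
            score=sc,
            null_mean=nm,
            null_sd=nsd,
            z=z,
            rank=r + 1,
            fdr=f,
            alignment=align_word_to_mirna(w, mirna),
        )
        for r, (w, sc, nm, nsd, z, f) in enumerate(per_word)
    ]
    return WordEnrichmentResult(
        scores=scores,
        unscorable=sorted(unscorable),
        B=B,
        S=S,
        seed=seed,
        lengths=lengths,
        options=dict(binary=binary, per_kb=per_kb),
    )


def _empirical_fdr(z_obs: np.ndarray, z_null: np.ndarray, n_reps: int) -> np.ndarray:
    """Empirical null-exceedance FDR per observed Z, capped at 1 and
    monotonized (running max down the Z-sorted order)."""
    n = z_obs.size
    null_sorted = np.sort(z_null)
    obs_sorted = np.sort(z_obs)
    order = np.argsort(-z_obs, kind="stable")
    fdr = np.empty(n, dtype=np.float64)
    running = 0.0
    for pos, j in enumerate(order):
        z = z_obs[j]
        mean_null = (z_null.size - np.searchsorted(null_sorted, z, side="left")) / n_reps
        n_obs_ge = n - np.searchsorted(obs_sorted, z, side="left")
        raw = min(1.0, mean_null / max(1, n_obs_ge))
        running = max(running, raw)
        fdr[j] = running
    return fdr


def report_top_words(scores: Sequence[WordScore], k: int) -> pd.DataFrame:
    """Top-``k`` words by Z as a report table.

    Words are rendered with seed-matching letters uppercase (full capitals
    for a complete seed-region match) and unaligned words fully lowercase.
    """
    if not scores:
        raise ValueError("no scored words to report")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        logger.warning("requested top %d but only %d words scored", k, len(scores))
        k = len(scores)
    ordered = sorted(scores, key=lambda s: s.rank)[:k]
    return pd.DataFrame(
        {
            "word": [s.formatted_word for s in ordered],
            "z": [s.z for s in ordered],
            "rank": [s.rank for s in ordered],
            "fdr": [s.fdr for s in ordered],
        }
    )
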