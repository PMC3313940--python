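"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators mirror the two study designs the pipeline targets:

* :func:`generate_utrs` — random i.i.d.-composition 3'UTRs in which a
  fraction ``f`` of genes ("carriers") receives 1-2 spliced-in copies of a
  planted seed word (default ``CACTGCC``, the reverse complement of
  miR-34a-5p bases 2-8).
* :func:`generate_overexpression` — a triplicate treated-vs-control
  log-expression matrix where carriers are shifted down by ``delta`` in the
  treated arm, with i.i.d. Gaussian noise on the log scale.
* :func:`generate_cohort` — a four-subclass tumor cohort (default sizes
  55/28/52/56, total 191) in which the miRNA is shifted down in the
  proneural subclass and one designated target mRNA is anticorrelated with
  the realized miRNA profile through a shared latent factor; decoy mRNAs
  are independent. p53 status is assigned i.i.d., independent of subclass.

Every generator is a pure function of its parameters and seed; the full
parameter set travels in a :class:`SyntheticTruth` manifest so that a run
can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SUBCLASSES, CohortDataset
from .diffexpr import GroupDesign
from .sequences import DNA_ALPHABET, UtrRecord

logger = logging.getLogger(__name__)

#: reverse complement of miR-34a-5p seed bases 2-8
DEFAULT_PLANTED_WORD = "CACTGCC"

#: subtype-classified cohort sizes used as defaults
DEFAULT_SUBCLASS_SIZES = {
    "proneural": 55,
    "neural": 28,
    "classical": 52,
    "mesenchymal": 56,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth and the full generating-parameter manifest."""

    planted_word: str
    carrier_fraction: float
    effect_size: float
    noise_sd: float
    cohort_shift: float
    anticorrelation: float
    seed: int
    carriers: tuple[str, ...] = ()
    target_gene: str = ""
    extras: tuple[tuple[str, object], ...] = ()

    def to_manifest(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["carriers"] = list(payload["carriers"])
        payload["extras"] = {k: v for k, v in payload["extras"]}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _random_utr(length: int, base_probs: np.ndarray, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=length, p=base_probs)
    return "".join(DNA_ALPHABET[c] for c in codes)


def generate_utrs(
    G: int = 2000,
    length_range: tuple[int, int] = (200, 1200),
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    f: float = 0.2,
    planted_word: str = DEFAULT_PLANTED_WORD,
    rng: np.random.Generator | None = None,
) -> tuple[list[UtrRecord], np.ndarray]:
    """Random 3'UTRs with a planted word in a fraction ``f`` of genes.

    Lengths are uniform over ``length_range``; bases i.i.d. at
    ``base_composition`` (order A, C, G, T). Carriers receive 1 or 2 copies
    of ``planted_word`` spliced in at random non-overlapping offsets (the
    flanking sequence is preserved, so each insertion contributes at least
    one exact occurrence). Returns the records plus a boolean carrier mask.
    ``f = 0`` gives a pure-null fixture.
    """
    if G < 10:
        raise ValueError("need G >= 10 genes")
    if not 0 <= f < 1:
        raise ValueError("carrier fraction must be in [0, 1)")
    probs = np.asarray(base_composition, dtype=float)
    if probs.size != 4 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    lo, hi = length_range
    if len(planted_word) > lo:
        raise ValueError("planted word does not fit in the minimum UTR length")
    rng = rng or np.random.default_rng(0)
    n_carriers = int(round(f * G))
    if f > 0 and n_carriers < 1:
        logger.warning("f*G < 1: generating zero carriers (pure-null mode)")
    carrier_idx = rng.choice(G, size=n_carriers, replace=False) if n_carriers else []
    carriers = np.zeros(G, dtype=bool)
    carriers[carrier_idx] = True
    width = len(str(G - 1))
    records = []
    for i in range(G):
        seq = _random_utr(int(rng.integers(lo, hi + 1)), probs, rng)
        if carriers[i]:
            n_copies = int(rng.integers(1, 3))
            offsets = sorted(rng.choice(len(seq) + 1, size=n_copies, replace=False))
            for n_done, off in enumerate(offsets):
                pos = off + n_done * len(planted_word)
                seq = seq[:pos] + planted_word + seq[pos:]
        records.append(UtrRecord(f"g{i:0{width}d}", seq))
    return records, carriers


def generate_overexpression(
    carriers: np.ndarray,
    n_reps: int = 3,
    delta: float = 1.0,
    sigma: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    gene_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroupDesign]:
    """Two-arm log-expression matrix with carriers shifted down when
    treated.

    Treated values are ``baseline - delta*[carrier] + N(0, sigma)``; control
    values ``baseline + N(0, sigma)``; per-gene baselines are i.i.d.
    ``N(baseline_mean, baseline_sd)``. ``delta = 0`` yields a null
    experiment for calibration.
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per arm")
    carriers = np.asarray(carriers, dtype=bool)
    G = carriers.size
    rng = rng or np.random.default_rng(0)
    if gene_ids is None:
        width = len(str(G - 1))
        gene_ids = [f"g{i:0{width}d}" for i in range(G)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=G)
    shift = delta * carriers.astype(float)
    treated = (
        baseline[:, None] - shift[:, None] + rng.normal(0, sigma, size=(G, n_reps))
    )
    control = baseline[:, None] + rng.normal(0, sigma, size=(G, n_reps))
    treated_ids = [f"mir_{r+1}" for r in range(n_reps)]
    control_ids = [f"ctrl_{r+1}" for r in range(n_reps)]
    matrix = pd.DataFrame(
        np.hstack([treated, control]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=treated_ids + control_ids,
    )
    return matrix, GroupDesign(treated=tuple(treated_ids), control=tuple(control_ids))


def pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose population Spearman
    correlation is ``rho_s`` (inverse of rho_s = (6/pi) asin(r/2))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_cohort(
    n_by_subclass: dict[str, int] | None = None,
    delta: float = 1.0,
    rho_target: float = 0.6,
    p53_mut_fraction: float = 0.35,
    n_decoys: int = 99,
    mirna_id: str = "miR-sim",
    target_gene: str = "target",
    baseline: float = 8.0,
    rng: np.random.Generator | None = None,
) -> tuple[CohortDataset, dict]:
    """Four-subclass cohort with the miRNA down in the proneural subclass
    and one anticorrelated target mRNA.

    The miRNA profile is ``baseline - delta*[proneural] + N(0, 1)``. The
    target mRNA shares a latent factor with the *realized* (standardized)
    miRNA profile: ``target = baseline - a*z(miRNA) + sqrt(1-a^2)*N(0,1)``
    with ``a = 2 sin(pi*rho_target/6)``, which makes the population Spearman
    correlation approximately ``-rho_target``. Decoy mRNAs are independent
    ``N(baseline, 1)``. p53 mutation status is i.i.d. Bernoulli
    (``p53_mut_fraction``), independent of subclass.
    """
    sizes = dict(n_by_subclass or DEFAULT_SUBCLASS_SIZES)
    if set(sizes) != set(SUBCLASSES):
        raise ValueError(f"n_by_subclass must cover exactly {SUBCLASSES}")
    if any(v < 2 for v in sizes.values()):
        raise ValueError("every subclass needs >= 2 samples")
    if not 0 <= rho_target < 1:
        raise ValueError("rho_target must be in [0, 1)")
    rng = rng or np.random.default_rng(0)
    labels = [c for c in SUBCLASSES for _ in range(sizes[c])]
    n = len(labels)
    samples = pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id")
    subclass = pd.Series(labels, index=samples, name="subclass")
    is_pn = (subclass == "proneural").to_numpy()

    mir = baseline - delta * is_pn.astype(float) + rng.normal(0, 1, size=n)
    mir_z = (mir - mir.mean()) / mir.std()
    a = pearson_for_spearman(rho_target)
    target = baseline - a * mir_z + math.sqrt(1 - a * a) * rng.normal(0, 1, size=n)
    decoy_ids = [f"decoy{j:04d}" for j in range(n_decoys)]
    decoys = baseline + rng.normal(0, 1, size=(n_decoys, n))

    mirna_expr = pd.DataFrame([mir], index=pd.Index([mirna_id]), columns=samples)
    mrna_expr = pd.DataFrame(
        np.vstack([target[None, :], decoys]),
        index=pd.Index([target_gene] + decoy_ids, name="gene_id"),
        columns=samples,
    )
    p53 = pd.Series(
        np.where(rng.random(n) < p53_mut_fraction, "mutant", "wild-type"),
        index=samples,
        name="p53_status",
    )
    cohort = CohortDataset(
        mirna_expr=mirna_expr, mrna_expr=mrna_expr, subclass=subclass, p53_status=p53
    )
    truth = {
        "mirna_id": mirna_id,
        "target_gene": target_gene,
        "delta": delta,
        "rho_target": rho_target,
        "latent_loading": a,
        "n_samples": n,
        "n_by_subclass": sizes,
        "p53_mut_fraction": p53_mut_fraction,
    }
    return cohort, truth


def write_overexpression_fixture(
    outdir: str | Path,
    G: int = 2000,
    f: float = 0.2,
    delta: float = 1.0,
    sigma: float = 1.0,
    length_range: tuple[int, int] = (200, 1200),
    base_composition: tuple[float, float, float, float] = (0.25,) * 4,
    planted_word: str = DEFAULT_PLANTED_WORD,
    n_reps: int = 3,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate and write a full overexpression fixture: UTR FASTA,
    expression TSV, design TSV and a YAML truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100,)))
    utrs, carriers = generate_utrs(
        G=G,
        length_range=length_range,
        base_composition=base_composition,
        f=f,
        planted_word=planted_word,
        rng=rng,
    )
    matrix, design = generate_overexpression(
        carriers,
        n_reps=n_reps,
        delta=delta,
        sigma=sigma,
        gene_ids=[u.gene_id for u in utrs],
        rng=rng,
    )
    with open(outdir / "utrs.fasta", "w") as fh:
        for u in utrs:
            fh.write(f">{u.gene_id}\n{u.sequence}\n")
    matrix.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    with open(outdir / "design.tsv", "w") as fh:
        fh.write("sample_id\tarm\n")
        for s in design.treated:
            fh.write(f"{s}\ttreated\n")
        for s in design.control:
            fh.write(f"{s}\tcontrol\n")
    truth = SyntheticTruth(
        planted_word=planted_word,
        carrier_fraction=f,
        effect_size=delta,
        noise_sd=sigma,
        cohort_shift=0.0,
        anticorrelation=0.0,
        seed=seed,
        carriers=tuple(u.gene_id for u, c in zip(utrs, carriers) if c),
        extras=(
            ("G", G),
            ("length_range", list(length_range)),
            ("base_composition", list(base_composition)),
            ("n_reps", n_reps),
        ),
    )
    truth.to_manifest(outdir / "truth.yaml")
    return truth


def write_cohort_fixture(
    outdir: str | Path,
    delta: float = 1.0,
    rho_target: float = 0.6,
    p53_mut_fraction: float = 0.35,
    n_decoys: int = 99,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate and write a cohort fixture: miRNA/mRNA TSV matrices, sample
    annotations, and a YAML truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(200,)))
    cohort, truth_info = generate_cohort(
        delta=delta,
        rho_target=rho_target,
        p53_mut_fraction=p53_mut_fraction,
        n_decoys=n_decoys,
        rng=rng,
    )
    cohort.mirna_expr.to_csv(outdir / "mirna_expr.tsv", sep="\t", float_format="%.6g")
    cohort.mrna_expr.to_csv(outdir / "mrna_expr.tsv", sep="\t", float_format="%.6g")
    ann = pd.DataFrame(
        {"subclass": cohort.subclass, "p53_status": cohort.p53_status}
    )
    ann.index.name = "sample_id"
    ann.to_csv(outdir / "annotations.tsv", sep="\t")
    truth = SyntheticTruth(
        planted_word="",
        carrier_fraction=0.0,
        effect_size=0.0,
        noise_sd=1.0,
        cohort_shift=delta,
        anticorrelation=rho_target,
        seed=seed,
        target_gene=truth_info["target_gene"],
        extras=tuple(
            (k, v)
            for k, v in truth_info.items()
            if k not in ("target_gene",)
        ),
    )
    truth.to_manifest(outdir / "truth.yaml")
    return truth
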