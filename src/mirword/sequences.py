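"""Sequence primitives: 3'UTR records, k-mer counting, dinucleotide-preserving
shuffling and canonical miRNA seed-site scanning.

Conventions used throughout the package:

* DNA alphabet is ``{A, C, G, T}``; sequences are sanitized on input
  (uppercased, ``U`` mapped to ``T``, any other character dropped with a
  logged warning).
* Word occurrences are counted with overlaps, i.e. every start position at
  which the word matches contributes one count.
* Coordinates are 0-based, half-open, on the given (sense) strand; 3'UTRs
  are assumed to be supplied in mRNA orientation, so no reverse-strand
  scanning is performed.
* miRNA positions are 1-based from the 5' end, as is standard for seed
  nomenclature (seed region = bases 2-8).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_ENCODE = np.full(256, -1, dtype=np.int16)
for _i, _c in enumerate(DNA_ALPHABET):
    _ENCODE[ord(_c)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase, map U->T and drop any residual non-ACGT characters.

    Dropped characters (typically Ns or IUPAC ambiguity codes) are reported
    through the module logger so that silent data loss is visible.
    """
    seq = raw.upper().replace("U", "T")
    cleaned = "".join(c for c in seq if c in DNA_ALPHABET)
    n_dropped = len(seq) - len(cleaned)
    if n_dropped:
        logger.warning(
            "dropped %d non-ACGT character(s) while sanitizing %s",
            n_dropped,
            context or "a sequence",
        )
    return cleaned


@dataclass(frozen=True)
class UtrRecord:
    """One gene's 3'UTR sequence (DNA, sense strand)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        if any(c not in DNA_ALPHABET for c in self.sequence):
            raise ValueError(
                f"sequence for {self.gene_id!r} contains non-ACGT characters; "
                "sanitize before constructing UtrRecord"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3', RNA alphabet. Length must be >= 8 so that seed
    positions 1-8 exist."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError("mature miRNA must be at least 8 nt (seed bases 1-8)")
        if any(c not in "ACGU" for c in self.sequence):
            raise ValueError("miRNA sequence must be RNA over {A,C,G,U}")

    @property
    def dna(self) -> str:
        """The miRNA sequence written in the DNA alphabet (U->T)."""
        return self.sequence.replace("U", "T")

    def seed_match(self, first: int, last: int) -> str:
        """DNA reverse complement of miRNA bases ``first..last`` (1-based,
        inclusive) — the word searched for in a target 3'UTR."""
        return reverse_complement(self.dna[first - 1 : last])


#: Mature hsa-miR-34a-5p, bundled because the seed-site examples and the
#: default enrichment annotation are defined against it.
MIR34A_5P = MatureMiRNA("hsa-miR-34a-5p", "UGGCAGUGUCUUAGCUGGUUGU")

#: Packaged FASTA with the two synthesized PDGFRA 3'UTR reporter
#: oligonucleotides (sense and antisense strands of the segment carrying the
#: two miR-34a sites).
PDGFRA_REPORTER_FASTA = Path(__file__).parent / "data" / "pdgfra_reporter_oligos.fasta"


def read_fasta(path: str | Path) -> list[UtrRecord]:
    """Read a (multi-)FASTA of 3'UTRs into sanitized :class:`UtrRecord` s.

    The header token up to the first whitespace becomes the gene id.
    Duplicate ids and empty files are errors; non-ACGT characters are
    dropped with a warning via :func:`sanitize_sequence`.
    """
    records: list[UtrRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen.add(gene_id)
        seq = sanitize_sequence(str(entry.seq), context=gene_id)
        records.append(UtrRecord(gene_id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def enumerate_words(lengths: Iterable[int]) -> list[str]:
    """All distinct DNA words of the given lengths, ordered by length then
    lexicographically (A < C < G < T)."""
    lens = sorted(set(int(x) for x in lengths))
    if not lens:
        raise ValueError("lengths must be non-empty")
    if any(k <= 0 for k in lens):
        raise ValueError("word lengths must be positive")
    words: list[str] = []
    for k in lens:
        words.extend("".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k))
    return words


def count_word(sequence: str, word: str) -> int:
    """Number of (possibly overlapping) occurrences of ``word`` in
    ``sequence``; 0 when the word is longer than the sequence."""
    if not word or len(word) > len(sequence):
        return 0
    n = 0
    start = sequence.find(word)
    while start != -1:
        n += 1
        start = sequence.find(word, start + 1)
    return n


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as int16 codes 0..3."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.min(initial=0) < 0:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def count_kmers(seq: str, k: int) -> np.ndarray:
    """Occurrence counts (overlapping) of every DNA k-mer in ``seq``.

    Returns a length-``4**k`` integer vector indexed lexicographically
    (A=0 < C < G < T), matching :func:`enumerate_words` order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(seq) < k:
        return np.zeros(4**k, dtype=np.int64)
    enc = encode_sequence(seq).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = sliding_window_view(enc, k) @ powers
    return np.bincount(codes, minlength=4**k)


def kmer_spectra(seqs: Sequence[str], k: int) -> np.ndarray:
    """K-mer spectra for a batch of sequences as one (n_seqs x 4**k) array.

    All sequences' k-mer codes are offset by ``seq_index * 4**k`` and
    counted in a single bincount pass, which is markedly faster than
    per-sequence calls for large word universes.
    """
    n_words = 4**k
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    code_blocks = []
    for i, seq in enumerate(seqs):
        if len(seq) < k:
            continue
        enc = encode_sequence(seq).astype(np.int64)
        codes = sliding_window_view(enc, k) @ powers
        code_blocks.append(codes + i * n_words)
    if not code_blocks:
        return np.zeros((len(seqs), n_words), dtype=np.int64)
    flat = code_blocks[0] if len(code_blocks) == 1 else np.concatenate(code_blocks)
    return np.bincount(flat, minlength=len(seqs) * n_words).reshape(
        len(seqs), n_words
    )


def word_index(word: str) -> int:
    """Lexicographic index of a DNA word among words of its length."""
    idx = 0
    for c in word:
        idx = idx * 4 + DNA_ALPHABET.index(c)
    return idx


@dataclass
class WordCountMatrix:
    """Occurrence counts of a fixed word list across a gene collection.

    ``counts[i, j]`` is the overlapping-occurrence count of ``words[j]`` in
    the UTR of ``genes[i]``.
    """

    words: list[str]
    genes: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.words)):
            raise ValueError("counts shape does not match genes x words")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_utrs(
        cls,
        utrs: Sequence[UtrRecord],
        lengths: Iterable[int] | None = None,
        words: Sequence[str] | None = None,
    ) -> "WordCountMatrix":
        """Count words in every UTR.

        Either ``lengths`` (count the full k-mer universe for those lengths)
        or an explicit ``words`` list must be given. Counting is done via a
        per-length k-mer spectrum (base-4 encoding + bincount), which equals
        the brute-force sliding-window count.
        """
        if (lengths is None) == (words is None):
            raise ValueError("give exactly one of lengths= or words=")
        if lengths is not None:
            word_list = enumerate_words(lengths)
            ks = sorted(set(len(w) for w in word_list))
            columns = {k: None for k in ks}  # full spectrum per k
        else:
            word_list = list(words)  # type: ignore[arg-type]
            ks = sorted(set(len(w) for w in word_list))
            columns = {
                k: np.array([word_index(w) for w in word_list if len(w) == k])
                for k in ks
            }
        seqs = [u.sequence for u in utrs]
        blocks = []
        for k in ks:
            spect = kmer_spectra(seqs, k)
            sel = columns[k]
            blocks.append(spect if sel is None else spect[:, sel])
        counts = np.concatenate(blocks, axis=1)
        # reorder columns to the requested word order
        ordered = [w for k in ks for w in word_list if len(w) == k]
        if ordered != word_list:
            pos = {w: j for j, w in enumerate(ordered)}
            counts = counts[:, [pos[w] for w in word_list]]
        return cls(words=list(word_list), genes=[u.gene_id for u in utrs], counts=counts)

    def column(self, word: str) -> np.ndarray:
        return self.counts[:, self.words.index(word)]

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV export (gene_id, word, count), non-zero entries."""
        with open(path, "w") as fh:
            fh.write("gene_id\tword\tcount\n")
            nz_i, nz_j = np.nonzero(self.counts)
            for i, j in zip(nz_i, nz_j):
                fh.write(f"{self.genes[i]}\t{self.words[j]}\t{self.counts[i, j]}\n")


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erikson)
# ---------------------------------------------------------------------------


def _last_edges_form_tree(last_edge: dict[str, str], sink: str) -> bool:
    # with <= 4 vertices, just follow pointers with a step bound
    for v in last_edge:
        cur = v
        for _ in range(len(last_edge) + 1):
            if cur == sink:
                break
            cur = last_edge[cur]
        else:
            return False
    return True


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Uniform dinucleotide-preserving shuffle of a DNA string.

    Uses the Altschul-Erikson construction: the sequence is viewed as an
    Eulerian walk on the graph whose vertices are bases and whose edges are
    the overlapping dinucleotides; a random "last edge" out of every
    non-terminal vertex is drawn until those edges form a tree into the
    terminal base, the remaining out-edges are permuted uniformly, and the
    walk is replayed. The result has exactly the input's multiset of
    overlapping dinucleotides (hence its length, mononucleotide counts and
    both end bases) and is uniform over all such arrangements.

    Sequences shorter than 2 nt, or with a single distinct base, are
    returned unchanged.
    """
    n = len(sequence)
    if n < 2:
        return sequence
    verts = sorted(set(sequence))
    if len(verts) == 1:
        return sequence
    succ: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(sequence, sequence[1:]):
        succ[a].append(b)
    sink = sequence[-1]
    non_sink = [v for v in verts if v != sink and succ[v]]
    while True:
        last_edge = {v: succ[v][rng.integers(len(succ[v]))] for v in non_sink}
        if _last_edges_form_tree(last_edge, sink):
            break
    out_edges: dict[str, list[str]] = {}
    for v in verts:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        arranged = [edges[i] for i in order]
        if v in last_edge:
            arranged.append(last_edge[v])
        out_edges[v] = arranged
    ptr = {v: 0 for v in verts}
    out = [sequence[0]]
    cur = sequence[0]
    for _ in range(n - 1):
        nxt = out_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# canonical seed-site scanning
# ---------------------------------------------------------------------------

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    """One canonical miRNA seed-match site in a UTR (0-based, half-open)."""

    site_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected[self.site_type]:
            raise ValueError("site span does not match its type")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    p = haystack.find(needle)
    while p != -1:
        hits.append(p)
        p = haystack.find(needle, p + 1)
    return hits


def find_seed_sites(utr: UtrRecord | str, mirna: MatureMiRNA) -> list[SeedSite]:
    """Scan a UTR for canonical seed sites of ``mirna``.

    Site definitions (DNA sense strand of the UTR, miRNA positions 1-based):

    * 6mer     — reverse complement of miRNA bases 2-7
    * 7mer-m8  — reverse complement of bases 2-8
    * 7mer-A1  — 6mer followed immediately by an A
    * 8mer     — 7mer-m8 followed immediately by an A

    Each seed-match locus is reported once at its maximal site type; when
    candidate sites of different loci overlap, longer types win and ties go
    to the leftmost site, so the returned list is non-overlapping.
    """
    seq = utr.sequence if isinstance(utr, UtrRecord) else utr
    six = mirna.seed_match(2, 7)
    candidates: list[SeedSite] = []
    for p in _find_all(seq, six):
        has_m8 = p > 0 and seq[p - 1] == mirna.seed_match(8, 8)
        has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        if has_m8 and has_a1:
            candidates.append(SeedSite("8mer", p - 1, p + 7))
        elif has_m8:
            candidates.append(SeedSite("7mer-m8", p - 1, p + 6))
        elif has_a1:
            candidates.append(SeedSite("7mer-A1", p, p + 7))
        else:
            candidates.append(SeedSite("6mer", p, p + 6))
    # greedy maximal, longest first, then leftmost
    candidates.sort(key=lambda s: (-(s.end - s.start), s.start))
    accepted: list[SeedSite] = []
    for site in candidates:
        if all(site.end <= a.start or site.start >= a.end for a in accepted):
            accepted.append(site)
    accepted.sort(key=lambda s: s.start)
    return accepted


@dataclass(frozen=True)
class SeedAlignment:
    """Where a word (or contiguous sub-word) matches a miRNA by reverse
    complement.

    ``word_start:word_end`` is the half-open matched span within the word;
    ``mirna_first..mirna_last`` are the matched miRNA bases, 1-based
    inclusive. Word position ``word_start`` pairs with miRNA base
    ``mirna_last`` (antiparallel pairing)."""

    word_start: int
    word_end: int
    mirna_first: int
    mirna_last: int

    @property
    def covers_seed(self) -> bool:
        return self.mirna_first >= 2 and self.mirna_last <= 8


def align_word_to_mirna(word: str, mirna: MatureMiRNA) -> SeedAlignment | None:
    """Best reverse-complement alignment of ``word`` against ``mirna``.

    The word, or a contiguous sub-word of length >= 5, is matched against
    every contiguous stretch of the miRNA. Among matches, preference goes to
    the one with the largest overlap with the seed region (bases 2-8), then
    to the longest match, then to 5'-most positions for determinism.
    Returns ``None`` when nothing of length >= 5 matches.
    """
    mdna = mirna.dna
    best: tuple[tuple[int, int, int, int], SeedAlignment] | None = None
    for wlen in range(len(word), 4, -1):
        for ws in range(len(word) - wlen + 1):
            sub = word[ws : ws + wlen]
            for ms in _find_all(mdna, reverse_complement(sub)):
                aln = SeedAlignment(ws, ws + wlen, ms + 1, ms + wlen)
                seed_overlap = max(
                    0, min(aln.mirna_last, 8) - max(aln.mirna_first, 2) + 1
                )
                key = (seed_overlap, wlen, -aln.mirna_first, -ws)
                if best is None or key > best[0]:
                    best = (key, aln)
    return best[1] if best else None


def format_aligned_word(word: str, alignment: SeedAlignment | None) -> str:
    """Render a word with seed-matching letters uppercase, others lowercase
    (the convention used in top-word reports). Unaligned words render fully
    lowercase."""
    if alignment is None:
        return word.lower()
    out = []
    for p, c in enumerate(word):
        if alignment.word_start <= p < alignment.word_end:
            base = alignment.mirna_last - (p - alignment.word_start)
            out.append(c.upper() if 2 <= base <= 8 else c.lower())
        else:
            out.append(c.lower())
    return "".join(out)


def seed_sites_to_tsv(
    sites_by_gene: dict[str, list[SeedSite]], path: str | Path
) -> None:
    """Write scanned sites as TSV (gene_id, site_type, start, end)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsite_type\tstart\tend\n")
        for gene_id, sites in sites_by_gene.items():
            for s in sites:
                fh.write(f"{gene_id}\t{s.site_type}\t{s.start}\t{s.end}\n")
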