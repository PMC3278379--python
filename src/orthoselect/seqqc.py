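"""Sequence quality control: six-frame translation, ORF extraction,
dual-space redundancy clustering and ambiguity filtering.

Raw cDNA reads are reduced to a high-quality non-redundant set in four
moves: every read is translated in six frames and its longest ATG-initiated
open reading frame noted; reads are clustered at >= 95% identity in
nucleotide space and, via their ORF proteins, in protein space; the
intersection of the two representative sets is the non-redundant set; and
records still carrying ambiguity letters (N in nucleotide records, X in
proteins) are removed.

Identity between two sequences is defined as the number of matching
positions in the best local alignment divided by the length of the shorter
sequence, so a clean truncation of a longer read scores 1.0 against its
source. Clustering is single linkage; the representative of a cluster is
its longest member (ties broken by lexicographically smallest id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codonsel import translate_codon

NT_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# blastn-like nucleotide scoring; BLOSUM62 for proteins.
NT_SCORING = {"match": 2.0, "mismatch": -3.0, "open": -5.0, "extend": -2.0}
AA_GAP = {"open": -11.0, "extend": -1.0}


@dataclass(frozen=True)
class SequenceRecord:
    """One cDNA or protein sequence flowing through the pipeline."""

    id: str
    sequence: str
    alphabet: str  # "nt" or "aa"
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    """A redundancy cluster with its longest member as representative."""

    member_ids: frozenset[str]
    representative_id: str
    space: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


def get_aligner(space: str, mode: str) -> Align.PairwiseAligner:
    """A configured pairwise aligner (local or global) for nt or aa space."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if space == "nt":
        aligner.match_score = NT_SCORING["match"]
        aligner.mismatch_score = NT_SCORING["mismatch"]
        aligner.open_gap_score = NT_SCORING["open"]
        aligner.extend_gap_score = NT_SCORING["extend"]
    elif space == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = AA_GAP["open"]
        aligner.extend_gap_score = AA_GAP["extend"]
    else:
        raise ValueError(f"unknown space {space!r}")
    return aligner


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i:i + 3]) for i in range(0, n, 3))


def six_frame_translate(record: SequenceRecord) -> list[str]:
    """Translate in frames +1, +2, +3, -1, -2, -3 under the standard code.

    Codons containing N translate to 'X'; trailing partial codons are
    dropped. Stop codons appear as '*'.
    """
    if record.alphabet != "nt":
        raise ValueError("six-frame translation requires a nucleotide record")
    seq = record.sequence.upper()
    if len(seq) < 3:
        raise ValueError(f"{record.id}: sequence shorter than one codon")
    rc = reverse_complement(seq)
    return [_translate_frame(seq[f:]) for f in range(3)] + \
           [_translate_frame(rc[f:]) for f in range(3)]


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated reading frame product with its source coordinates.

    ``frame`` indexes the six-frame order (0..2 forward, 3..5 reverse);
    ``aa_start`` is the 0-based position of the initiator Met within the
    frame translation; ``cds`` is the nucleotide sequence encoding
    ``protein`` (taken from the reverse complement for frames 3..5).
    """

    frame: int
    aa_start: int
    protein: str
    cds: str
    stop_terminated: bool


def find_longest_orf(record: SequenceRecord) -> Orf | None:
    """Longest ATG..stop (or ATG..frame-end) product over all six frames.

    Ties are broken by frame order then by position within the frame. The
    stop symbol is not part of the returned protein. Returns None when no
    frame contains a Met.
    """
    seq = record.sequence.upper()
    frames = six_frame_translate(record)
    strands = [seq, reverse_complement(seq)]
    best: Orf | None = None
    for f, prot in enumerate(frames):
        strand = strands[0] if f < 3 else strands[1]
        offset = f % 3
        start = 0
        while True:
            m = prot.find("M", start)
            if m == -1:
                break
            stop = prot.find("*", m)
            if stop == -1:
                product, terminated, end = prot[m:], False, len(prot)
            else:
                product, terminated, end = prot[m:stop], True, stop
            if best is None or len(product) > len(best.protein):
                cds = strand[offset + 3 * m: offset + 3 * end]
                best = Orf(f, m, product, cds, terminated)
            # later Met inside the same span can only be shorter
            start = end + 1 if stop != -1 else len(prot)
    return best


def longest_orf_protein(record: SequenceRecord) -> SequenceRecord:
    """The longest ORF as a protein record (empty sequence when no ATG).

    Records with an empty protein are flagged for downstream exclusion by
    their zero length.
    """
    orf = find_longest_orf(record)
    protein = orf.protein if orf is not None else ""
    return SequenceRecord(record.id, protein, "aa", record.species)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Best-local-alignment matches divided by the shorter sequence length."""
    if a.alphabet != b.alphabet:
        raise ValueError("cannot compare records of different alphabets")
    if not a.sequence or not b.sequence:
        return 0.0
    aligner = get_aligner(a.alphabet, "local")
    alignments = aligner.align(a.sequence.upper(), b.sequence.upper())
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0
    counts = alignments[0].counts()
    return counts.identities / min(len(a), len(b))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def candidate_pairs(records: Sequence[SequenceRecord],
                    k: int | None = None,
                    min_shared: int | None = None) -> list[tuple[int, int]]:
    """Index pairs sharing at least ``min_shared`` k-mers (prescreen before DP).

    At >= 95% identity over the shorter sequence, a large fraction of exact
    k-mers is preserved, so redundant pairs always clear the bar; unrelated
    sequences share k-mers only by chance and are skipped before any
    quadratic alignment is attempted.
    """
    if not records:
        return []
    if k is None:
        k = 11 if records[0].alphabet == "nt" else 5
    if min_shared is None:
        min_shared = 3 if records[0].alphabet == "nt" else 2
    kmers = [_kmer_set(r.sequence.upper(), k) for r in records]
    index: dict[str, list[int]] = {}
    for i, ks in enumerate(kmers):
        for km in ks:
            index.setdefault(km, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for hits in index.values():
        if 1 < len(hits) <= 200:
            for x in range(len(hits)):
                for y in range(x + 1, len(hits)):
                    pair = (hits[x], hits[y])
                    shared[pair] = shared.get(pair, 0) + 1
    return sorted(p for p, c in shared.items() if c >= min_shared)


def cluster_sequences(records: Sequence[SequenceRecord],
                      threshold: float = 0.95,
                      space: str | None = None) -> list[Cluster]:
    """Single-linkage clustering at pairwise identity >= threshold.

    Every record lands in exactly one cluster; the representative is the
    longest member, ties broken by lexicographically smallest id. Clusters
    are returned sorted by representative id.
    """
    if not records:
        return []
    if space is None:
        space = records[0].alphabet
    if any(r.alphabet != space for r in records):
        raise ValueError("all records must match the clustering space")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in clustering input")

    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in candidate_pairs(records):
        if find(i) != find(j) and \
                pairwise_identity(records[i], records[j]) >= threshold:
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda i: (-len(records[i]), records[i].id))
        clusters.append(Cluster(frozenset(records[i].id for i in members),
                                records[rep].id, space))
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def intersect_nonredundant(nt_reps: Iterable[str],
                           aa_reps: Iterable[str]) -> set[str]:
    """Ids that are representatives in both nucleotide and protein space."""
    return set(nt_reps) & set(aa_reps)


def filter_ambiguous(records: Sequence[SequenceRecord]
                     ) -> tuple[list[SequenceRecord], list[str]]:
    """Drop records containing letters outside their strict alphabet.

    Nucleotide records must be pure A/C/G/T and proteins pure 20-letter
    amino acids (case-insensitive); everything else — N, X, IUPAC ambiguity
    codes — removes the record.
    """
    kept, removed = [], []
    for r in records:
        letters = set(r.sequence.upper())
        ok = letters <= (NT_ALPHABET if r.alphabet == "nt" else AA_ALPHABET)
        (kept if ok else removed).append(r if ok else r.id)
    return kept, removed


@dataclass(frozen=True)
class LengthStats:
    n: int
    min: int
    max: int
    mean: float
    sd: float
    sd_convention: str = "sample (n-1)"
    degenerate: bool = False


def length_stats(records: Sequence[SequenceRecord]) -> LengthStats:
    """Count, range, mean and sample standard deviation of lengths."""
    if not records:
        raise ValueError("length_stats requires at least one record")
    lengths = [len(r) for r in records]
    n = len(lengths)
    mean = sum(lengths) / n
    if n == 1:
        return LengthStats(1, lengths[0], lengths[0], mean, 0.0,
                           degenerate=True)
    var = sum((x - mean) ** 2 for x in lengths) / (n - 1)
    return LengthStats(n, min(lengths), max(lengths), mean, math.sqrt(var))
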