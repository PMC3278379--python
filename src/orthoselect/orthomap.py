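"""Ortholog assignment by an eight-step iterative homology filter.

Public reference sets for a newly sequenced species are incomplete, so
reciprocal-best-hit orthology is not available: a query may have no
reciprocal partner simply because its own species' reference lacks the
gene. Instead, local-alignment hits are filtered through eight
successively relaxed criteria on four statistics — the match-length ratio
(aligned length over the shorter of query and subject), mismatches, gap
openings and percent identity. Step 1 demands a full-length perfect-ratio
match with no mismatches or gaps at >= 99% identity; step 8 accepts hits
covering 52% of the shorter sequence at >= 97% identity. A query assigned
at an earlier (stricter) step is never revisited, so relaxing the filter
only ever adds assignments.

Queries are classified *known* when the filter links them to any sequence
in the public reference set of their own species, *novel* otherwise.
Accepted assignments are verified by Needleman-Wunsch global alignment to
reject hits whose homology is only local, and queries with verified
orthologs in all three target species become four-species ortholog groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqqc import SequenceRecord, get_aligner, candidate_pairs, _kmer_set

TARGET_SPECIES = ("dog", "human", "mouse")


@dataclass(frozen=True)
class HomologyHit:
    """One local-alignment hit in BLAST tabular (outfmt-6) terms."""

    query_id: str
    subject_id: str
    percent_identity: float
    match_length: int
    mismatches: int
    gap_openings: int
    evalue: float
    bitscore: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")
        if self.match_length < 1:
            raise ValueError("match length must be >= 1")
        if self.mismatches < 0 or self.gap_openings < 0:
            raise ValueError("mismatches and gap openings must be >= 0")


@dataclass(frozen=True)
class StepCriteria:
    """Acceptance thresholds of one filter step.

    ``min_ratio`` is either a float (match-length ratio lower bound) or the
    string sentinel ``"equal-to-min"`` demanding that the aligned length
    equal the shorter sequence exactly.
    """

    step: int
    min_ratio: float | str
    max_mismatches: int
    max_gaps: int
    min_pident: float


STEP_CRITERIA: tuple[StepCriteria, ...] = (
    StepCriteria(1, "equal-to-min", 0, 0, 99.0),
    StepCriteria(2, 0.99, 0, 0, 99.0),
    StepCriteria(3, 0.87, 4, 0, 99.0),
    StepCriteria(4, 0.725, 5, 0, 99.0),
    StepCriteria(5, 0.69, 4, 1, 99.0),
    StepCriteria(6, 0.625, 8, 1, 98.0),
    StepCriteria(7, 0.575, 13, 2, 97.0),
    StepCriteria(8, 0.52, 12, 2, 97.0),
)


@dataclass(frozen=True)
class OrthologAssignment:
    query_id: str
    species: str
    subject_gene_id: str
    step_accepted: int
    chosen_hit: HomologyHit


@dataclass(frozen=True)
class OrthologGroup:
    cat_gene_id: str
    dog_gene_id: str
    human_gene_id: str
    mouse_gene_id: str
    status: str  # known / novel

    def gene_id(self, species: str) -> str:
        return getattr(self, f"{species}_gene_id")


# ---------------------------------------------------------------------------
# Hit acquisition
# ---------------------------------------------------------------------------

_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore")


def parse_blast_tabular(path: Path | str,
                        lengths: Mapping[str, int] | None = None
                        ) -> list[HomologyHit]:
    """Parse 12-column BLAST outfmt-6 rows, preserving row order.

    ``lengths`` optionally supplies query/subject sequence lengths (they are
    not part of the tabular format but the filter needs them).
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}")
            try:
                hit = HomologyHit(
                    query_id=fields[0], subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    match_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                    query_length=(lengths or {}).get(fields[0]),
                    subject_length=(lengths or {}).get(fields[1]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(match_length, identities, mismatches, gap_openings) of one local
    alignment; match_length counts aligned columns including internal gaps."""
    c = alignment.counts()
    gap_cols = c.internal_insertions + c.internal_deletions
    openings = c.open_internal_insertions + c.open_internal_deletions
    return (c.identities + c.mismatches + gap_cols, c.identities,
            c.mismatches, openings)


def search_homologs(queries: Sequence[SequenceRecord],
                    subjects: Sequence[SequenceRecord],
                    min_score: float = 50.0,
                    min_shared_kmers: int = 3) -> list[HomologyHit]:
    """Internal local-alignment homology search.

    Subjects sharing at least ``min_shared_kmers`` k-mers with the query
    (the seeding heuristic every local search tool uses) are aligned with
    the Smith-Waterman engine and reported when the raw score clears
    ``min_score``. Statistics come from the optimal traceback; the raw
    alignment score doubles as the bit score, and the reported e-value is
    the Karlin-Altschul-shaped quantity m*n*2^-score, which preserves score
    ordering. Hits are ordered by query id, then bitscore descending, then
    subject id.
    """
    if not queries or not subjects:
        return []
    space = queries[0].alphabet
    k = 11 if space == "nt" else 5
    aligner = get_aligner(space, "local")
    subject_kmers = [_kmer_set(s.sequence.upper(), k) for s in subjects]
    hits = []
    for q in queries:
        q_kmers = _kmer_set(q.sequence.upper(), k)
        q_hits = []
        for s, s_kmers in zip(subjects, subject_kmers):
            shared = len(q_kmers & s_kmers)
            if shared < min_shared_kmers:
                continue
            alignments = aligner.align(q.sequence.upper(), s.sequence.upper())
            if len(alignments) == 0:
                continue
            score = alignments.score
            if score < min_score:
                continue
            mlen, ident, mism, gaps = _alignment_stats(alignments[0])
            if mlen == 0:
                continue
            evalue = len(q) * len(s) * math.pow(2.0, -min(score, 1000.0))
            q_hits.append(HomologyHit(
                query_id=q.id, subject_id=s.id,
                percent_identity=round(100.0 * ident / mlen, 2),
                match_length=mlen, mismatches=mism, gap_openings=gaps,
                evalue=evalue, bitscore=float(score),
                query_length=len(q), subject_length=len(s)))
        q_hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
        hits.extend(q_hits)
    return hits


# ---------------------------------------------------------------------------
# The eight-step filter
# ---------------------------------------------------------------------------

def match_length_ratio(hit: HomologyHit) -> float:
    """Aligned length over the shorter of query and subject."""
    if hit.query_length is None or hit.subject_length is None:
        raise ValueError(
            f"hit {hit.query_id} vs {hit.subject_id} lacks sequence lengths")
    return hit.match_length / min(hit.query_length, hit.subject_length)


def satisfies(hit: HomologyHit, criteria: StepCriteria) -> bool:
    """Whether a hit meets one step's four conditions (boundaries inclusive)."""
    if criteria.min_ratio == "equal-to-min":
        if hit.query_length is None or hit.subject_length is None:
            raise ValueError("equal-to-min criterion requires lengths")
        ratio_ok = hit.match_length == min(hit.query_length,
                                           hit.subject_length)
    else:
        ratio_ok = match_length_ratio(hit) >= criteria.min_ratio
    return (ratio_ok
            and hit.mismatches <= criteria.max_mismatches
            and hit.gap_openings <= criteria.max_gaps
            and hit.percent_identity >= criteria.min_pident)


def iterative_filter(hits: Iterable[HomologyHit], species: str,
                     gene_map: Mapping[str, str] | None = None
                     ) -> list[OrthologAssignment]:
    """Assign each query its best qualifying hit over steps 1..8.

    Steps run strictly in order; within a step, still-unassigned queries
    take their best satisfying hit (highest bitscore, then lowest e-value,
    then lexicographically smallest subject id). Assignments are final: a
    later, laxer step never revises an earlier one. Queries with no
    qualifying hit at any step stay unassigned.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    assigned: dict[str, OrthologAssignment] = {}
    for criteria in STEP_CRITERIA:
        for query_id, q_hits in by_query.items():
            if query_id in assigned:
                continue
            qualifying = [h for h in q_hits if satisfies(h, criteria)]
            if not qualifying:
                continue
            best = min(qualifying,
                       key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
            gene = (gene_map or {}).get(best.subject_id, best.subject_id)
            assigned[query_id] = OrthologAssignment(
                query_id, species, gene, criteria.step, best)
    return [assigned[q] for q in sorted(assigned)]


def classify_known_novel(query_ids: Iterable[str],
                         public_hits: Iterable[HomologyHit]
                         ) -> dict[str, str]:
    """known iff the filter assigns the query to any public own-species
    sequence; novel otherwise."""
    assignments = iterative_filter(public_hits, species="self")
    known = {a.query_id for a in assignments}
    return {q: ("known" if q in known else "novel") for q in query_ids}


def verify_global(query: SequenceRecord, subject: SequenceRecord,
                  min_global_identity: float = 0.80) -> bool:
    """Needleman-Wunsch check that homology is global, not merely local.

    Passes iff matches / alignment-length >= ``min_global_identity``. A
    strong local hit embedded in otherwise unrelated sequences fails here
    and the assignment is dropped.
    """
    if query.alphabet != subject.alphabet:
        raise ValueError("global verification needs a shared alphabet")
    if min_global_identity <= 0:
        return True
    aligner = get_aligner(query.alphabet, "global")
    alignment = aligner.align(query.sequence.upper(),
                              subject.sequence.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns >= min_global_identity


def verify_assignments(assignments: Sequence[OrthologAssignment],
                       queries: Mapping[str, SequenceRecord],
                       subjects: Mapping[str, SequenceRecord],
                       min_global_identity: float = 0.80
                       ) -> list[OrthologAssignment]:
    """Keep assignments whose query/subject pass the global-identity gate."""
    kept = []
    for a in assignments:
        q = queries[a.query_id]
        s = subjects[a.chosen_hit.subject_id]
        if verify_global(q, s, min_global_identity):
            kept.append(a)
    return kept


def build_ortholog_groups(assignments: Mapping[str, Sequence[OrthologAssignment]],
                          statuses: Mapping[str, str],
                          cat_gene_map: Mapping[str, str] | None = None
                          ) -> list[OrthologGroup]:
    """Groups for cat queries with verified dog AND human AND mouse orthologs.

    ``assignments`` maps each target species to its assignment list;
    ``statuses`` maps query id to known/novel; ``cat_gene_map`` optionally
    collapses query (transcript) ids to cat gene ids.
    """
    per_species: dict[str, dict[str, str]] = {}
    for sp in TARGET_SPECIES:
        per_species[sp] = {a.query_id: a.subject_gene_id
                           for a in assignments.get(sp, [])}
    groups = []
    complete = set.intersection(*(set(per_species[sp]) for sp in TARGET_SPECIES))
    for query_id in sorted(complete):
        cat_gene = (cat_gene_map or {}).get(query_id, query_id)
        groups.append(OrthologGroup(
            cat_gene_id=cat_gene,
            dog_gene_id=per_species["dog"][query_id],
            human_gene_id=per_species["human"][query_id],
            mouse_gene_id=per_species["mouse"][query_id],
            status=statuses.get(query_id, "known")))
    return groups
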