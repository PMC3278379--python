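"""Annotation transfer through orthology and selection-stratified summaries.

A newly sequenced species has no annotation of its own, so every gene
inherits the full term set of its (human or mouse) ortholog — GO terms,
anatomical and developmental expression terms, pathways, phenotypes,
diseases — as a plain relational join through the ortholog groups. On top
of the transferred tables this module computes:

* per-term coverage summaries (gene count and percentage of the ortholog
  set annotated with each term);
* per-term mean omega (genes sharing a term are grouped and their dN/dS
  averaged per species pair — terms whose genes evolve slowly or fast
  stand out);
* omega-quartile stratification (genes ranked by dN/dS under one species
  pair and split 25/50/25 into conserved, middle, and divergent groups);
* exact hypergeometric term enrichment of any gene group against a
  universe, with optional Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .codonsel import OmegaEstimate
from .orthomap import OrthologGroup

NAMESPACES = frozenset({
    "go_process", "go_function", "go_location", "anatomy", "cell_type",
    "pathology", "dev_stage", "pathway", "phenotype", "disease",
})


@dataclass(frozen=True)
class AnnotationTable:
    """A namespaced gene -> term relation ((gene_id, term) pairs, unique)."""

    namespace: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate (gene_id, term) rows")
        if any(not term for _, term in self.rows):
            raise ValueError("terms must be non-empty")

    @classmethod
    def from_pairs(cls, namespace: str,
                   pairs: Iterable[tuple[str, str]]) -> "AnnotationTable":
        return cls(namespace, tuple(sorted(set(pairs))))

    @classmethod
    def read_tsv(cls, namespace: str, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(namespace,
                              zip(df["gene_id"], df["term"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["gene_id", "term"])

    def terms_of(self, gene_id: str) -> set[str]:
        return {t for g, t in self.rows if g == gene_id}

    def genes_of(self, term: str) -> set[str]:
        return {g for g, t in self.rows if t == term}

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.rows}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.rows}


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Transfer and coverage
# ---------------------------------------------------------------------------

def transfer_annotations(groups: Sequence[OrthologGroup],
                         source_table: AnnotationTable,
                         source_species: str = "human") -> AnnotationTable:
    """Give each cat gene the full term set of its ortholog (greedy join).

    Genes without an ortholog in the source species inherit nothing; two
    cat genes sharing one source ortholog both receive its terms.
    """
    if source_species not in ("dog", "human", "mouse"):
        raise ValueError(f"unsupported source species {source_species!r}")
    by_source: dict[str, set[str]] = {}
    for gene, term in source_table.rows:
        by_source.setdefault(gene, set()).add(term)
    pairs = []
    for group in groups:
        source_gene = group.gene_id(source_species)
        for term in by_source.get(source_gene, ()):
            pairs.append((group.cat_gene_id, term))
    return AnnotationTable.from_pairs(source_table.namespace, pairs)


def expression_summary(table: AnnotationTable,
                       total_genes: int) -> pd.DataFrame:
    """Per-term gene count and percentage of the ortholog set.

    Percentage = 100 * count / total_genes at 4 decimals; terms sorted
    lexicographically. The frame's ``attrs["genes_covered"]`` reports how
    many distinct genes the namespace annotates.
    """
    if total_genes < 1:
        raise ValueError("total_genes must be >= 1")
    counts = (table.to_frame().groupby("term")["gene_id"].nunique()
              .sort_index())
    df = pd.DataFrame({
        "term": counts.index,
        "count": counts.to_numpy(),
    })
    df["percentage"] = [round_half_up(100.0 * c / total_genes, 4)
                        for c in df["count"]]
    df.attrs["genes_covered"] = len(table.genes)
    df.attrs["total_genes"] = total_genes
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Grouped omega
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermOmegaSummary:
    term: str
    n_genes: int
    mean_omega: dict[str, float]
    sd_omega: dict[str, float]
    n_excluded: int  # annotated genes dropped for unusable omega


def term_omega_summary(table: AnnotationTable,
                       omegas: Sequence[OmegaEstimate],
                       min_genes: int = 2) -> list[TermOmegaSummary]:
    """Mean and sd of omega per term and species pair.

    Only estimates with status finite or zero contribute; genes whose
    omega is infinite, undefined or saturated for a pair are excluded from
    that pair's mean and counted in ``n_excluded``. Terms with fewer than
    ``min_genes`` usable genes (under the first species pair) are dropped.
    """
    usable: dict[str, dict[str, float]] = {}
    unusable: set[tuple[str, str]] = set()
    pairs: list[str] = []
    for e in omegas:
        if e.species_pair not in pairs:
            pairs.append(e.species_pair)
        if e.usable:
            usable.setdefault(e.species_pair, {})[e.gene_id] = e.omega
        else:
            unusable.add((e.species_pair, e.gene_id))
    out = []
    for term in sorted(table.terms):
        genes = sorted(table.genes_of(term))
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        n_usable = 0
        n_excluded = 0
        for pair in pairs:
            vals = [usable[pair][g] for g in genes
                    if pair in usable and g in usable[pair]]
            n_excluded += sum((pair, g) in unusable for g in genes)
            if len(vals) >= min_genes:
                means[pair] = float(np.mean(vals))
                sds[pair] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            n_usable = max(n_usable, len(vals))
        if n_usable >= min_genes and means:
            out.append(TermOmegaSummary(term, n_usable, means, sds,
                                        n_excluded))
    return out


@dataclass(frozen=True)
class StratifiedGroups:
    """25/50/25 partition of genes ranked by omega under one species pair."""

    conserved: tuple[str, ...]
    middle: tuple[str, ...]
    divergent: tuple[str, ...]
    lower_threshold: float
    upper_threshold: float
    key_pair: str

    @property
    def all_genes(self) -> set[str]:
        return set(self.conserved) | set(self.middle) | set(self.divergent)


def stratify_by_omega(omega_by_gene: Mapping[str, float], key_pair: str,
                      fractions: tuple[float, float, float] = (0.25, 0.50, 0.25)
                      ) -> StratifiedGroups:
    """Split genes into conserved / middle / divergent by ranked omega.

    Tail sizes are round-half-up(fraction * n); ranking ties are broken by
    gene id so group sizes are exact. Thresholds are the omega values of
    the boundary genes (last conserved, first divergent).
    """
    n = len(omega_by_gene)
    if n < 4:
        raise ValueError("stratification needs at least 4 genes")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ranked = sorted(omega_by_gene, key=lambda g: (omega_by_gene[g], g))
    k_low = int(round_half_up(fractions[0] * n))
    k_high = int(round_half_up(fractions[2] * n))
    conserved = tuple(ranked[:k_low])
    divergent = tuple(ranked[n - k_high:])
    middle = tuple(ranked[k_low:n - k_high])
    return StratifiedGroups(
        conserved, middle, divergent,
        lower_threshold=omega_by_gene[conserved[-1]],
        upper_threshold=omega_by_gene[divergent[0]],
        key_pair=key_pair)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int            # group genes carrying the term
    K: int            # universe genes carrying the term
    n: int            # group size
    N: int            # universe size
    p_value: float
    q_value: float | None = None


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(group_ids: Iterable[str],
                              table: AnnotationTable,
                              universe_ids: Iterable[str],
                              with_q_values: bool = True
                              ) -> list[EnrichmentResult]:
    """Exact upper-tail enrichment of every term in a gene group.

    The annotation table is restricted to the universe before counting.
    Results are sorted by p ascending, then term. Benjamini-Hochberg
    q-values are reported alongside the raw p-values (never replacing
    them).
    """
    group = set(group_ids)
    universe = set(universe_ids)
    if not group <= universe:
        raise ValueError("group must be a subset of the universe")
    N, n = len(universe), len(group)
    term_genes: dict[str, set[str]] = {}
    for gene, term in table.rows:
        if gene in universe:
            term_genes.setdefault(term, set()).add(gene)
    results = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & group)
        p = hypergeometric_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(term, k, K, n, N, p))
    results.sort(key=lambda r: (r.p_value, r.term))
    if with_q_values and results:
        m = len(results)
        q = [r.p_value * m / (i + 1) for i, r in enumerate(results)]
        for i in range(m - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        results = [EnrichmentResult(r.term, r.k, r.K, r.n, r.N, r.p_value,
                                    min(1.0, qi))
                   for r, qi in zip(results, q)]
    return results


def network_gene_ratio(n_terms_hit: int, n_genes: int) -> float:
    """100 * terms / genes, rounded half-up to one decimal (a coarse
    measure of how many distinct networks a gene group touches)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return round_half_up(100.0 * n_terms_hit / n_genes, 1)


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
          "p": r.p_value, "q": r.q_value} for r in results],
        columns=["term", "k", "K", "n", "N", "p", "q"])
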