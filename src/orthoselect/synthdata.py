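"""Synthetic four-species orthologous-family benchmark generator.

Emulates the data a four-way cDNA comparative study consumes: orthologous
coding sequences for cat, dog, human and mouse evolved from a common
ancestor under a known per-gene omega (dN/dS), redundant and truncated
duplicate reads, ambiguity-contaminated copies, Ensembl-style per-species
reference dumps in which a chosen fraction of cat genes is withheld (the
"novel" genes a real EST project discovers), and namespaced annotation
tables in which term groups track the simulated selection regimes.

The generative model is the counting estimator's inverse: sequences evolve
on a star phylogeny (one independent branch per species), candidate point
mutations are proposed uniformly over sites and alternative bases at an
expected ``branch_subs`` attempts per site per branch, mutations creating
internal stop codons are rejected, synonymous changes fix with probability
1 and nonsynonymous ones with probability omega (for omega > 1 the
asymmetry flips: synonymous acceptance is scaled by 1/omega instead).
Every consumer of the generator therefore has exact ground truth: the true
omega per gene, the true ortholog identifiers, the known/novel flag, and
the ids of every injected duplicate or contaminated copy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codonsel import (CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate_codon)
from .seqqc import SequenceRecord

DEFAULT_SPECIES = ("cat", "dog", "human", "mouse")
SPECIES_TAGS = {"cat": "FCA", "dog": "CFA", "human": "HSA", "mouse": "MUS"}
BASES = "ACGT"

# Default selection regimes: most mammalian orthologs are under strong
# purifying selection (genome-wide median omega ~ 0.1), with a conserved
# core and a smaller weakly-constrained tail.
DEFAULT_OMEGA_GROUPS = (
    ("strong_purifying", 0.02, 0.25),
    ("purifying", 0.10, 0.50),
    ("weak_purifying", 0.40, 0.25),
)

DEFAULT_NAMESPACES = ("go_process", "go_location", "anatomy", "pathway")
VALID_NAMESPACES = frozenset({
    "go_process", "go_function", "go_location", "anatomy", "cell_type",
    "pathology", "dev_stage", "pathway", "phenotype", "disease",
})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic benchmark dataset.

    ``codon_length`` may be a single codon count or an inclusive
    (min, max) range sampled per gene. ``omega_groups`` are
    (label, omega, fraction) triples; genes are assigned to groups
    deterministically by index so the configured fractions are met
    exactly. ``branch_subs`` is the expected number of substitution
    attempts per nucleotide site on each of the four independent
    branches.
    """

    n_genes: int = 100
    species: tuple[str, ...] = DEFAULT_SPECIES
    codon_length: int | tuple[int, int] = (150, 400)
    branch_subs: float = 0.01
    omega_groups: tuple[tuple[str, float, float], ...] = DEFAULT_OMEGA_GROUPS
    dup_rate: float = 0.3
    ambiguity_rate: float = 0.5
    novel_fraction: float = 0.25
    namespaces: tuple[str, ...] = DEFAULT_NAMESPACES
    terms_per_namespace: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_genes < 1:
            errors.append("n_genes must be >= 1")
        if len(self.species) != 4 or len(set(self.species)) != 4:
            errors.append("species must be 4 unique labels")
        total = sum(f for _, _, f in self.omega_groups)
        if abs(total - 1.0) > 1e-9:
            errors.append("omega group fractions must sum to 1")
        if any(w < 0 or not math.isfinite(w) for _, w, _ in self.omega_groups):
            errors.append("omega values must be finite and >= 0")
        lo = self.codon_length if isinstance(self.codon_length, int) \
            else self.codon_length[0]
        if lo < 30:
            errors.append("codon_length must be >= 30")
        for name, value in (("dup_rate", self.dup_rate),
                            ("ambiguity_rate", self.ambiguity_rate),
                            ("novel_fraction", self.novel_fraction)):
            if not 0.0 <= value <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        unknown = set(self.namespaces) - VALID_NAMESPACES
        if unknown:
            errors.append(f"unknown namespaces: {sorted(unknown)}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class Family:
    """One orthologous gene family with its simulated truth."""

    gene_index: int
    base_id: str
    omega: float
    group: str
    ancestor: str
    cds: dict[str, str]  # species -> CDS


@dataclass
class TruthTable:
    """Ground truth for one generated dataset (JSON round-trippable)."""

    omega: dict[str, float] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)
    orthologs: dict[str, dict[str, str]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)  # known / novel
    annotations: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    copies: dict[str, list[str]] = field(default_factory=dict)
    contaminated: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        return cls(**json.loads(text))


def gene_base_id(gene_index: int) -> str:
    return f"GSYN{gene_index + 1:06d}"


def species_gene_id(species: str, gene_index: int) -> str:
    return f"{SPECIES_TAGS[species]}_{gene_base_id(gene_index)}"


def transcript_id(species: str, gene_index: int) -> str:
    return species_gene_id(species, gene_index) + ".t1"


def protein_id(species: str, gene_index: int) -> str:
    return species_gene_id(species, gene_index) + ".p1"


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_NONSTOP = tuple(c for c in SENSE_CODONS if c != "ATG") + ("ATG",)
_START_FREE = tuple(sorted(set(SENSE_CODONS)))


def random_cds(rng: np.random.Generator, codon_length: int) -> str:
    """A stop-free CDS starting with ATG, ``codon_length`` codons long."""
    body = rng.choice(len(_START_FREE), size=codon_length - 1)
    return "ATG" + "".join(_START_FREE[i] for i in body)


def _evolve_branch(cds: str, omega: float, branch_subs: float,
                   rng: np.random.Generator) -> str:
    """Evolve one sequence along one branch under selection strength omega."""
    seq = list(cds)
    length = len(seq)
    n_attempts = rng.poisson(branch_subs * length)
    p_nonsyn = min(omega, 1.0)
    p_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    for _ in range(n_attempts):
        site = int(rng.integers(length))
        old = seq[site]
        alternatives = [b for b in BASES if b != old]
        new = alternatives[int(rng.integers(3))]
        codon_start = site - site % 3
        codon = seq[codon_start:codon_start + 3]
        mutant = codon.copy()
        mutant[site - codon_start] = new
        mutant_codon = "".join(mutant)
        if mutant_codon in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA["".join(codon)] == CODON_TO_AA[mutant_codon]
        p_accept = p_syn if synonymous else p_nonsyn
        if p_accept >= 1.0 or rng.random() < p_accept:
            seq[site] = new
    return "".join(seq)


def simulate_family(config: SimulationConfig, gene_index: int,
                    omega: float) -> Family:
    """Simulate one four-species family from a fresh random ancestor.

    Each species' sequence evolves independently from the ancestor along
    its own branch (star phylogeny, equal expected divergence). The family
    RNG is derived from (seed, gene_index) so families are independent and
    individually reproducible.
    """
    if not math.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be finite and >= 0, got {omega}")
    rng = np.random.default_rng([config.seed, gene_index])
    if isinstance(config.codon_length, int):
        n_codons = config.codon_length
    else:
        lo, hi = config.codon_length
        n_codons = int(rng.integers(lo, hi + 1))
    ancestor = random_cds(rng, n_codons)
    cds = {sp: _evolve_branch(ancestor, omega, config.branch_subs, rng)
           for sp in config.species}
    group = _omega_group_of(config, gene_index)[0]
    return Family(gene_index, gene_base_id(gene_index), omega, group,
                  ancestor, cds)


def _group_boundaries(config: SimulationConfig) -> list[int]:
    """Cumulative gene-count boundaries realising the group fractions."""
    bounds, cum = [], 0.0
    for _, _, frac in config.omega_groups:
        cum += frac
        bounds.append(int(math.floor(cum * config.n_genes + 0.5)))
    bounds[-1] = config.n_genes
    return bounds


def _omega_group_of(config: SimulationConfig,
                    gene_index: int) -> tuple[str, float]:
    for (label, omega, _), bound in zip(config.omega_groups,
                                        _group_boundaries(config)):
        if gene_index < bound:
            return label, omega
    raise IndexError(f"gene index {gene_index} out of range")


def simulate_families(config: SimulationConfig) -> list[Family]:
    """All families of one dataset, group-assigned deterministically by index."""
    out = []
    for i in range(config.n_genes):
        _, omega = _omega_group_of(config, i)
        out.append(simulate_family(config, i, omega))
    return out


# ---------------------------------------------------------------------------
# Redundancy and ambiguity injection
# ---------------------------------------------------------------------------

def inject_redundancy(records: Sequence[SequenceRecord],
                      config: SimulationConfig,
                      truth: TruthTable) -> list[SequenceRecord]:
    """Add duplicate reads: exact copies or 5'/3' truncations >= 95% length.

    Each input record receives one copy with probability ``dup_rate``. A
    truncation keeps at least 95% of the source length, so identity to the
    source over the shorter sequence is 1.0 and clustering at the 95%
    stringency must merge the pair. Copy ids append ``.d<n>`` to the source
    id; the truth table records the links.
    """
    rng = np.random.default_rng([config.seed, 10_001])
    out = list(records)
    for rec in records:
        if rng.random() >= config.dup_rate:
            continue
        kind = int(rng.integers(3))  # 0 exact, 1 5'-truncated, 2 3'-truncated
        seq = rec.sequence
        if kind != 0:
            keep = int(math.ceil(len(seq) * float(rng.uniform(0.95, 0.999))))
            seq = seq[-keep:] if kind == 1 else seq[:keep]
        copy_id = f"{rec.id}.d{len(truth.copies.get(rec.id, [])) + 1}"
        out.append(SequenceRecord(copy_id, seq, rec.alphabet, rec.species))
        truth.copies.setdefault(rec.id, []).append(copy_id)
    return out


def inject_ambiguity(records: Sequence[SequenceRecord], rate: float,
                     seed: int, truth: TruthTable,
                     eligible: set[str] | None = None) -> list[SequenceRecord]:
    """Replace a few bases with 'N' in a ``rate`` fraction of records.

    Only records whose ids are in ``eligible`` (default: all) are
    candidates; contaminated ids are appended to ``truth.contaminated``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("ambiguity rate must be in [0, 1]")
    rng = np.random.default_rng([seed, 10_002])
    out = []
    for rec in records:
        candidate = eligible is None or rec.id in eligible
        if candidate and rng.random() < rate:
            n_sites = max(1, int(rng.poisson(3)))
            positions = rng.choice(len(rec.sequence),
                                   size=min(n_sites, len(rec.sequence)),
                                   replace=False)
            seq = list(rec.sequence)
            for p in positions:
                seq[int(p)] = "N"
            out.append(SequenceRecord(rec.id, "".join(seq), rec.alphabet,
                                      rec.species))
            truth.contaminated.append(rec.id)
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def generate_annotations(config: SimulationConfig,
                         families: Sequence[Family],
                         truth: TruthTable) -> dict[str, list[tuple[str, str]]]:
    """Per-namespace (human_gene_id, term) tables tracking the omega groups.

    Every namespace gets a pool of generic terms assigned at random (1-3
    per gene); the ``pathway`` namespace additionally gives most genes a
    term named after their selection-regime group, so that grouped-omega
    summaries and enrichment have a planted signal with known truth.
    """
    rng = np.random.default_rng([config.seed, 10_003])
    tables: dict[str, list[tuple[str, str]]] = {}
    for ns in config.namespaces:
        pool = [f"{ns}_term_{i + 1:02d}" for i in range(config.terms_per_namespace)]
        rows: set[tuple[str, str]] = set()
        for fam in families:
            gid = species_gene_id("human", fam.gene_index)
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(pool), size=min(k, len(pool)),
                                replace=False)
            terms = {pool[int(i)] for i in chosen}
            if ns == "pathway" and rng.random() < 0.9:
                terms.add(f"{fam.group}_pathway")
            for t in sorted(terms):
                rows.add((gid, t))
            entry = truth.annotations.setdefault(fam.base_id, {})
            entry[ns] = sorted(t for g, t in rows if g == gid)
        tables[ns] = sorted(rows)
    return tables


# ---------------------------------------------------------------------------
# Dataset assembly and I/O
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A complete in-memory synthetic benchmark."""

    config: SimulationConfig
    families: list[Family]
    queries: list[SequenceRecord]          # cat reads incl. copies
    references: dict[str, list[SequenceRecord]]   # species -> cDNA records
    annotations: dict[str, list[tuple[str, str]]]
    truth: TruthTable


def _novel_indices(config: SimulationConfig) -> set[int]:
    n_novel = int(math.floor(config.novel_fraction * config.n_genes + 0.5))
    rng = np.random.default_rng([config.seed, 10_004])
    picked = rng.choice(config.n_genes, size=n_novel, replace=False)
    return {int(i) for i in picked}


def generate(config: SimulationConfig) -> Dataset:
    """Generate families, query reads, references, annotations and truth."""
    families = simulate_families(config)
    truth = TruthTable()
    novel = _novel_indices(config)
    cat = config.species[0]

    primaries = []
    for fam in families:
        tid = transcript_id(cat, fam.gene_index)
        primaries.append(SequenceRecord(tid, fam.cds[cat], "nt", cat))
        truth.omega[fam.base_id] = fam.omega
        truth.group[fam.base_id] = fam.group
        truth.orthologs[fam.base_id] = {
            sp: species_gene_id(sp, fam.gene_index) for sp in config.species}
        truth.status[fam.base_id] = \
            "novel" if fam.gene_index in novel else "known"

    queries = inject_redundancy(primaries, config, truth)
    copy_ids = {cid for cids in truth.copies.values() for cid in cids}
    queries = inject_ambiguity(queries, config.ambiguity_rate, config.seed,
                               truth, eligible=copy_ids)

    references: dict[str, list[SequenceRecord]] = {}
    for sp in config.species:
        refs = []
        for fam in families:
            if sp == cat and fam.gene_index in novel:
                continue  # withheld: these cat genes are "novel"
            refs.append(SequenceRecord(transcript_id(sp, fam.gene_index),
                                       fam.cds[sp], "nt", sp))
        references[sp] = refs

    annotations = generate_annotations(config, families, truth)
    return Dataset(config, families, queries, references, annotations, truth)


def write_fasta(records: Iterable[SequenceRecord], path: Path,
                headers: Mapping[str, str] | None = None,
                width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = headers.get(rec.id, rec.id) if headers else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fasta(path: Path, alphabet: str = "nt",
               species: str = "") -> list[SequenceRecord]:
    """Read FASTA; for Ensembl-style ``GENE|TRANSCRIPT|PROTEIN species=X``
    headers the record id is the transcript id and species is parsed."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        rec_species, rec_id = species, rec.id
        if " species=" in header:
            rec_species = header.split(" species=", 1)[1].split()[0]
        if "|" in rec.id:
            rec_id = rec.id.split("|")[1]
        out.append(SequenceRecord(rec_id, str(rec.seq).upper(), alphabet,
                                  rec_species))
    return out


def transcript_gene_map(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Map transcript-style ids (GENE.t1[.d1]) to their gene id."""
    return {r.id: r.id.split(".")[0] for r in records}


def write_reference_sets(dataset: Dataset, outdir: Path) -> dict[str, Path]:
    """Write the full on-disk benchmark: reference FASTAs (cDNA and protein
    per species, cat public set missing the novel genes), query FASTA,
    annotation TSVs and the truth JSON. Returns the path of every file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dataset.config
    paths: dict[str, Path] = {}

    for sp in config.species:
        refs = dataset.references[sp]
        headers = {}
        peps = []
        for rec in refs:
            idx = int(rec.id.split("GSYN")[1].split(".")[0]) - 1
            headers[rec.id] = (f"{species_gene_id(sp, idx)}|{rec.id}|"
                               f"{protein_id(sp, idx)} species={sp}")
            protein = "".join(translate_codon(rec.sequence[i:i + 3])
                              for i in range(0, len(rec.sequence), 3))
            peps.append(SequenceRecord(rec.id, protein, "aa", sp))
        cdna_path = outdir / f"{sp}.cdna.fa"
        pep_path = outdir / f"{sp}.pep.fa"
        write_fasta(refs, cdna_path, headers)
        write_fasta(peps, pep_path, headers)
        paths[f"{sp}_cdna"] = cdna_path
        paths[f"{sp}_pep"] = pep_path

    query_path = outdir / "queries.fa"
    write_fasta(dataset.queries, query_path)
    paths["queries"] = query_path

    for ns, rows in dataset.annotations.items():
        ns_path = outdir / f"annotation.{ns}.tsv"
        with open(ns_path, "w") as fh:
            fh.write("gene_id\tterm\n")
            for gid, term in rows:
                fh.write(f"{gid}\t{term}\n")
        paths[f"annotation_{ns}"] = ns_path

    truth_path = outdir / "truth.json"
    truth_path.write_text(dataset.truth.to_json())
    paths["truth"] = truth_path
    return paths
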