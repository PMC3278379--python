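"""End-to-end orchestration: QC -> ortholog mapping -> dN/dS -> annotation.

One configuration drives the whole run. Inputs are either user-supplied
FASTA/TSV files or a synthetic benchmark generated in place; each stage
writes its intermediate tables as TSV and the run closes with a
machine-readable JSON report of per-stage counts. Identical configuration
and seed give byte-identical output files (stage wall-times are logged to
stderr only, so they never perturb the artifacts).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from . import annotsel, codonsel, orthomap, seqqc, synthdata
from .annotsel import AnnotationTable
from .codonsel import OmegaEstimate
from .orthomap import OrthologAssignment, OrthologGroup, TARGET_SPECIES
from .seqqc import SequenceRecord

logger = logging.getLogger("orthoselect")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset paths trigger synthetic input."""

    outdir: str = "orthoselect_out"
    seed: int = 0
    # input files (optional; synthetic generation is used when absent)
    query_fasta: str | None = None
    reference_dir: str | None = None
    annotation_dir: str | None = None
    # synthetic-data parameters (used when query_fasta is None)
    simulation: dict[str, Any] = field(default_factory=dict)
    # stage parameters
    clustering_threshold: float = 0.95
    global_identity: float = 0.80
    min_score: float = 50.0
    min_genes: int = 2
    fractions: tuple[float, float, float] = (0.25, 0.50, 0.25)
    key_pair: str = "cat-dog"
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        errors = []
        for key in ("clustering_threshold", "global_identity"):
            value = getattr(self, key)
            if not 0.0 <= value <= 1.0:
                errors.append(f"{key}: must be in [0, 1], got {value}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            errors.append("fractions: must sum to 1")
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            errors.append("fractions: need 3 positive values")
        if self.min_genes < 1:
            errors.append("min_genes: must be >= 1")
        if self.query_fasta is not None and self.reference_dir is None:
            errors.append("reference_dir: required when query_fasta is given")
        if self.simulation:
            try:
                self.simulation_config()
            except (ValueError, TypeError) as exc:
                errors.append(f"simulation: {exc}")
        return errors

    def simulation_config(self) -> synthdata.SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        for key in ("species", "codon_length", "namespaces"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        if "omega_groups" in params:
            params["omega_groups"] = tuple(
                tuple(g) for g in params["omega_groups"])
        return synthdata.SimulationConfig(**params)


def validate_config(path: Path | str) -> PipelineConfig:
    """Load and validate a YAML config, collecting all errors before raising."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    errors = [f"{key}: unknown configuration key"
              for key in raw if key not in known]
    config = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(config.fractions, list):
        config.fractions = tuple(config.fractions)
    errors.extend(config.validate())
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return config


@dataclass
class RunReport:
    """Per-stage counts of one pipeline run (the JSON artifact excludes
    wall-times so reruns are byte-identical)."""

    version: str = __version__
    config: dict[str, Any] = field(default_factory=dict)
    counts: dict[str, Any] = field(default_factory=dict)
    wall_times: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"version": self.version, "config": self.config,
                   "counts": self.counts}
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    nonredundant: list[SequenceRecord]       # nt records passing everything
    proteins: dict[str, SequenceRecord]      # id -> ORF protein record
    orfs: dict[str, seqqc.Orf]
    n_input: int
    n_nt_clusters: int
    n_aa_clusters: int
    n_intersection: int
    removed_ambiguous: list[str]
    no_orf: list[str]


def run_qc(queries: Sequence[SequenceRecord],
           threshold: float = 0.95) -> QCResult:
    """Translate, cluster in both spaces, intersect, drop ambiguous records."""
    orfs: dict[str, seqqc.Orf] = {}
    proteins: dict[str, SequenceRecord] = {}
    no_orf = []
    for rec in queries:
        orf = seqqc.find_longest_orf(rec)
        if orf is None or not orf.protein:
            no_orf.append(rec.id)
            continue
        orfs[rec.id] = orf
        proteins[rec.id] = SequenceRecord(rec.id, orf.protein, "aa",
                                          rec.species)
    with_orf = [r for r in queries if r.id in proteins]

    nt_clusters = seqqc.cluster_sequences(with_orf, threshold, "nt")
    aa_clusters = seqqc.cluster_sequences(
        [proteins[r.id] for r in with_orf], threshold, "aa")
    nr_ids = seqqc.intersect_nonredundant(
        (c.representative_id for c in nt_clusters),
        (c.representative_id for c in aa_clusters))

    nr_records = [r for r in with_orf if r.id in nr_ids]
    kept_nt, removed_nt = seqqc.filter_ambiguous(nr_records)
    kept_ids = {r.id for r in kept_nt}
    _, removed_aa = seqqc.filter_ambiguous(
        [proteins[r.id] for r in nr_records if r.id in kept_ids])
    removed = sorted(set(removed_nt) | set(removed_aa))
    final = [r for r in kept_nt if r.id not in set(removed_aa)]
    return QCResult(final, proteins, orfs, len(queries), len(nt_clusters),
                    len(aa_clusters), len(nr_ids), removed, no_orf)


@dataclass
class OrthologyResult:
    assignments: dict[str, list[OrthologAssignment]]
    statuses: dict[str, str]
    groups: list[OrthologGroup]
    n_dropped_verification: int


def run_orthomap(nonredundant: Sequence[SequenceRecord],
                 references: Mapping[str, Sequence[SequenceRecord]],
                 cat_species: str = "cat",
                 min_score: float = 50.0,
                 global_identity: float = 0.80) -> OrthologyResult:
    """Eight-step assignment per target species + known/novel classification."""
    query_map = {r.id: r for r in nonredundant}
    dropped = 0
    assignments: dict[str, list[OrthologAssignment]] = {}
    for sp in TARGET_SPECIES:
        refs = references.get(sp, [])
        gene_map = synthdata.transcript_gene_map(refs)
        hits = orthomap.search_homologs(nonredundant, refs,
                                        min_score=min_score)
        raw = orthomap.iterative_filter(hits, sp, gene_map)
        subj_map = {r.id: r for r in refs}
        # verification runs on the underlying transcript records
        verified = []
        for a in raw:
            q = query_map[a.query_id]
            s = subj_map[a.chosen_hit.subject_id]
            if orthomap.verify_global(q, s, global_identity):
                verified.append(a)
            else:
                dropped += 1
        assignments[sp] = verified
        logger.info("orthomap: %s: %d/%d queries assigned (%d dropped)",
                    sp, len(verified), len(nonredundant), len(raw) - len(verified))

    public = references.get(cat_species, [])
    public_hits = orthomap.search_homologs(nonredundant, public,
                                           min_score=min_score)
    statuses = orthomap.classify_known_novel(
        [r.id for r in nonredundant], public_hits)
    cat_gene_map = synthdata.transcript_gene_map(nonredundant)
    groups = orthomap.build_ortholog_groups(assignments, statuses,
                                            cat_gene_map)
    return OrthologyResult(assignments, statuses, groups, dropped)


def _protein_of(cds: str) -> str:
    return "".join(codonsel.translate_codon(cds[i:i + 3])
                   for i in range(0, len(cds) - len(cds) % 3, 3))


def run_dnds(groups: Sequence[OrthologGroup],
             orths: OrthologyResult,
             qc: QCResult,
             references: Mapping[str, Sequence[SequenceRecord]]
             ) -> list[OmegaEstimate]:
    """Protein-guided codon alignment + NG86 rates for every group x pair."""
    aligner = seqqc.get_aligner("aa", "global")
    ref_by_sp = {sp: {r.id: r for r in references.get(sp, [])}
                 for sp in TARGET_SPECIES}
    subject_of = {
        sp: {a.query_id: a.chosen_hit.subject_id
             for a in orths.assignments.get(sp, [])}
        for sp in TARGET_SPECIES}
    query_of_gene = {}
    for a in orths.assignments.get("dog", []):
        query_of_gene.setdefault(a.query_id.split(".")[0], a.query_id)
    estimates = []
    for group in groups:
        query_id = query_of_gene.get(group.cat_gene_id)
        if query_id is None or query_id not in qc.orfs:
            continue
        orf = qc.orfs[query_id]
        cds_a, prot_a = orf.cds, orf.protein
        for sp in TARGET_SPECIES:
            subject_id = subject_of[sp].get(query_id)
            subject = ref_by_sp[sp].get(subject_id)
            if subject is None:
                continue
            cds_b = subject.sequence
            prot_b = _protein_of(cds_b)
            alignment = aligner.align(prot_a, prot_b)[0]
            row_a, row_b = str(alignment[0]), str(alignment[1])
            codon_alignment = codonsel.codon_align(
                cds_a[:3 * len(prot_a)], cds_b[:3 * len(prot_b)],
                (row_a, row_b))
            _, estimate = codonsel.estimate_rates(
                codon_alignment, gene_id=group.cat_gene_id,
                species_pair=f"cat-{sp}")
            estimates.append(estimate)
    return estimates


@dataclass
class AnnotationResult:
    transferred: dict[str, AnnotationTable]
    summaries: dict[str, Any]                # namespace -> DataFrame
    term_omega: dict[str, list[annotsel.TermOmegaSummary]]
    strata: annotsel.StratifiedGroups | None
    enrichment: dict[str, list[annotsel.EnrichmentResult]]


def run_annot(groups: Sequence[OrthologGroup],
              annotation_tables: Mapping[str, AnnotationTable],
              estimates: Sequence[OmegaEstimate],
              key_pair: str = "cat-dog",
              min_genes: int = 2,
              fractions: tuple[float, float, float] = (0.25, 0.50, 0.25)
              ) -> AnnotationResult:
    """Transfer annotations, summarise coverage and omega, stratify, enrich."""
    transferred = {
        ns: annotsel.transfer_annotations(groups, table)
        for ns, table in sorted(annotation_tables.items())}
    total = len(groups)
    summaries = {ns: annotsel.expression_summary(t, total)
                 for ns, t in transferred.items()} if total else {}
    term_omega = {ns: annotsel.term_omega_summary(t, estimates, min_genes)
                  for ns, t in transferred.items()}

    key_omegas = {e.gene_id: e.omega for e in estimates
                  if e.species_pair == key_pair and e.usable}
    strata = None
    enrichment: dict[str, list[annotsel.EnrichmentResult]] = {}
    if len(key_omegas) >= 4:
        strata = annotsel.stratify_by_omega(key_omegas, key_pair, fractions)
        universe = set(key_omegas)
        for ns, table in transferred.items():
            for label, ids in (("conserved", strata.conserved),
                               ("divergent", strata.divergent)):
                enrichment[f"{ns}:{label}"] = annotsel.hypergeometric_enrichment(
                    set(ids), table, universe)
    return AnnotationResult(transferred, summaries, term_omega, strata,
                            enrichment)


# ---------------------------------------------------------------------------
# Full run + artifact writing
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig):
    if config.query_fasta is not None:
        queries = synthdata.read_fasta(Path(config.query_fasta), "nt", "cat")
        refdir = Path(config.reference_dir)
        references = {
            sp: synthdata.read_fasta(refdir / f"{sp}.cdna.fa", "nt", sp)
            for sp in ("cat",) + TARGET_SPECIES}
        tables = {}
        if config.annotation_dir:
            for path in sorted(Path(config.annotation_dir).glob(
                    "annotation.*.tsv")):
                ns = path.name.split(".")[1]
                tables[ns] = AnnotationTable.read_tsv(ns, path)
        return queries, references, tables, None
    sim = config.simulation_config()
    dataset = synthdata.generate(sim)
    tables = {ns: AnnotationTable.from_pairs(ns, rows)
              for ns, rows in dataset.annotations.items()}
    return dataset.queries, dataset.references, tables, dataset


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages, write artifacts under ``config.outdir``."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={**asdict(config),
                               "fractions": list(config.fractions)})
    clock = time.perf_counter

    t0 = clock()
    queries, references, tables, dataset = _load_inputs(config)
    report.wall_times["input"] = clock() - t0
    logger.info("input: %d query records, %d namespaces",
                len(queries), len(tables))

    t0 = clock()
    qc = run_qc(queries, config.clustering_threshold)
    report.wall_times["seqqc"] = clock() - t0
    logger.info("seqqc: %d -> %d non-redundant high-quality records",
                qc.n_input, len(qc.nonredundant))

    t0 = clock()
    orths = run_orthomap(qc.nonredundant, references,
                         min_score=config.min_score,
                         global_identity=config.global_identity)
    report.wall_times["orthomap"] = clock() - t0
    logger.info("orthomap: %d four-species ortholog groups", len(orths.groups))

    t0 = clock()
    estimates = run_dnds(orths.groups, orths, qc, references)
    report.wall_times["codonsel"] = clock() - t0

    t0 = clock()
    annot = run_annot(orths.groups, tables, estimates,
                      key_pair=config.key_pair, min_genes=config.min_genes,
                      fractions=config.fractions)
    report.wall_times["annotsel"] = clock() - t0

    status_counts: dict[str, int] = {}
    for e in estimates:
        status_counts[e.status] = status_counts.get(e.status, 0) + 1
    known = sum(1 for s in orths.statuses.values() if s == "known")
    report.counts = {
        "input_sequences": qc.n_input,
        "no_orf": len(qc.no_orf),
        "nt_clusters": qc.n_nt_clusters,
        "aa_clusters": qc.n_aa_clusters,
        "nonredundant": qc.n_intersection,
        "removed_ambiguous": len(qc.removed_ambiguous),
        "post_qc": len(qc.nonredundant),
        "known": known,
        "novel": len(orths.statuses) - known,
        "assigned": {sp: len(orths.assignments[sp]) for sp in TARGET_SPECIES},
        "dropped_verification": orths.n_dropped_verification,
        "ortholog_groups": len(orths.groups),
        "omega_by_status": dict(sorted(status_counts.items())),
        "terms_summarized": {ns: len(v) for ns, v in annot.term_omega.items()},
        "enrichment_sets": len(annot.enrichment),
    }
    _write_artifacts(outdir, qc, orths, estimates, annot, report)
    for stage, seconds in report.wall_times.items():
        logger.info("timing: %s: %.2fs", stage, seconds)
    return report


def _write_artifacts(outdir: Path, qc: QCResult, orths: OrthologyResult,
                     estimates: Sequence[OmegaEstimate],
                     annot: AnnotationResult, report: RunReport) -> None:
    synthdata.write_fasta(
        sorted(qc.nonredundant, key=lambda r: r.id),
        outdir / "nonredundant.fa")

    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("query_id\tspecies\tsubject_gene_id\tstep_accepted\t"
                 "pident\tratio\tmismatches\tgaps\n")
        for sp in TARGET_SPECIES:
            for a in orths.assignments.get(sp, []):
                h = a.chosen_hit
                fh.write(f"{a.query_id}\t{sp}\t{a.subject_gene_id}\t"
                         f"{a.step_accepted}\t{h.percent_identity:.2f}\t"
                         f"{orthomap.match_length_ratio(h):.4f}\t"
                         f"{h.mismatches}\t{h.gap_openings}\n")

    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("cat_gene_id\tdog_gene_id\thuman_gene_id\tmouse_gene_id\t"
                 "status\n")
        for g in orths.groups:
            fh.write(f"{g.cat_gene_id}\t{g.dog_gene_id}\t{g.human_gene_id}\t"
                     f"{g.mouse_gene_id}\t{g.status}\n")

    with open(outdir / "omega.tsv", "w") as fh:
        fh.write("gene_id\tpair\tdN\tdS\tomega\tstatus\n")
        for e in sorted(estimates, key=lambda e: (e.gene_id, e.species_pair)):
            fh.write(f"{e.gene_id}\t{e.species_pair}\t{e.dN:.6f}\t"
                     f"{e.dS:.6f}\t{e.omega:.6f}\t{e.status}\n")

    for ns, df in annot.summaries.items():
        df.to_csv(outdir / f"summary.{ns}.tsv", sep="\t", index=False,
                  float_format="%.4f")

    with open(outdir / "term_omega.tsv", "w") as fh:
        fh.write("namespace\tterm\tn_genes\tpair\tmean_omega\tsd_omega\n")
        for ns in sorted(annot.term_omega):
            for s in annot.term_omega[ns]:
                for pair in sorted(s.mean_omega):
                    fh.write(f"{ns}\t{s.term}\t{s.n_genes}\t{pair}\t"
                             f"{s.mean_omega[pair]:.6f}\t"
                             f"{s.sd_omega[pair]:.6f}\n")

    if annot.strata is not None:
        s = annot.strata
        with open(outdir / "strata.tsv", "w") as fh:
            fh.write("gene_id\tgroup\n")
            for label, ids in (("conserved", s.conserved),
                               ("middle", s.middle),
                               ("divergent", s.divergent)):
                for gid in ids:
                    fh.write(f"{gid}\t{label}\n")

    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("set\tterm\tk\tK\tn\tN\tp\tq\n")
        for key in sorted(annot.enrichment):
            for r in annot.enrichment[key]:
                fh.write(f"{key}\t{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                         f"{r.p_value:.6e}\t{r.q_value:.6e}\n")

    (outdir / "report.json").write_text(report.to_json())
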