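"""Eight-step iterative ortholog filter, homology search and verification."""

import random

import pytest

from orthoselect.orthomap import (HomologyHit, STEP_CRITERIA,
                                  parse_blast_tabular, search_homologs,
                                  match_length_ratio, satisfies,
                                  iterative_filter, classify_known_novel,
                                  verify_global, build_ortholog_groups,
                                  OrthologAssignment)
from orthoselect.seqqc import SequenceRecord
from orthoselect import synthdata
from orthoselect.pipeline import run_qc, run_orthomap

from tests import oracles


def make_hit(query="q", subject="s", pident=99.5, length=300, mm=0, gaps=0,
             evalue=1e-50, bitscore=500.0, qlen=300, slen=300):
    return HomologyHit(query, subject, pident, length, mm, gaps, evalue,
                       bitscore, qlen, slen)


def nt(seq, rid, species="cat"):
    return SequenceRecord(rid, seq, "nt", species)


class TestParsing:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t99.50\t300\t0\t0\t1\t300\t1\t300"
                        "\t1e-150\t550\n")
        hits = parse_blast_tabular(path, lengths={"q1": 300, "s1": 450})
        assert len(hits) == 1
        h = hits[0]
        assert h.percent_identity == 99.5
        assert h.match_length == 300
        assert h.query_length == 300 and h.subject_length == 450

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_blast_tabular(path) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\t99.5\t300\t0\t0\t1\t300\t1\t300\t1e-9\t50\n"
                        "q2\ts2\t98\t200\t1\t0\t1\t200\t1\t200\t1e-9\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_blast_tabular(path)


class TestStepCriteria:
    def test_the_eight_printed_steps(self):
        printed = [("equal-to-min", 0, 0, 99.0), (0.99, 0, 0, 99.0),
                   (0.87, 4, 0, 99.0), (0.725, 5, 0, 99.0),
                   (0.69, 4, 1, 99.0), (0.625, 8, 1, 98.0),
                   (0.575, 13, 2, 97.0), (0.52, 12, 2, 97.0)]
        assert [(c.min_ratio, c.max_mismatches, c.max_gaps, c.min_pident)
                for c in STEP_CRITERIA] == printed
        assert [c.step for c in STEP_CRITERIA] == list(range(1, 9))

    def test_match_length_ratio(self):
        assert match_length_ratio(make_hit(length=300, qlen=300,
                                           slen=450)) == 1.0
        assert match_length_ratio(make_hit(length=290, qlen=300,
                                           slen=450)) == pytest.approx(0.9667,
                                                                       abs=5e-5)
        assert match_length_ratio(make_hit(length=156, qlen=300,
                                           slen=450)) == pytest.approx(0.52)

    def test_missing_lengths_is_an_error(self):
        hit = make_hit(qlen=None, slen=None)
        with pytest.raises(ValueError):
            match_length_ratio(hit)

    def test_step_one_requires_exact_minimum_length(self):
        full = make_hit(pident=99.2, length=300, qlen=300, slen=450)
        assert satisfies(full, STEP_CRITERIA[0])
        near = make_hit(pident=99.2, length=299, qlen=300, slen=450)
        assert not satisfies(near, STEP_CRITERIA[0])

    def test_mid_stringency_hit_lands_at_step_three(self):
        hit = make_hit(pident=99.5, length=270, mm=3, qlen=300, slen=450)
        assert not satisfies(hit, STEP_CRITERIA[0])
        assert not satisfies(hit, STEP_CRITERIA[1])
        assert satisfies(hit, STEP_CRITERIA[2])

    def test_hopeless_hit_fails_every_step(self):
        hit = make_hit(pident=96.0, length=150, mm=15, gaps=3, qlen=300,
                       slen=300)
        assert not any(satisfies(hit, c) for c in STEP_CRITERIA)

    def test_criteria_nesting_structure(self):
        """Step 1 nests in step 2 (equality implies ratio 1 >= 0.99); later
        steps are NOT uniformly laxer: mismatch caps dip at steps 5 and 8."""
        rng = random.Random(42)
        for _ in range(300):
            hit = make_hit(pident=rng.uniform(96.5, 100.0),
                           length=rng.randint(150, 300),
                           mm=rng.randint(0, 16), gaps=rng.randint(0, 3),
                           qlen=300, slen=rng.randint(300, 500))
            if satisfies(hit, STEP_CRITERIA[0]):
                assert satisfies(hit, STEP_CRITERIA[1])
        mm = [c.max_mismatches for c in STEP_CRITERIA]
        assert mm[4] < mm[3] and mm[7] < mm[6]  # printed non-monotonicity


class TestIterativeFilter:
    def test_earlier_step_wins_over_better_late_hit(self):
        step1 = make_hit(subject="s_late_alphabet", pident=99.5, length=300,
                         bitscore=400)
        step3 = make_hit(subject="s_better_score", pident=99.5, length=270,
                         mm=3, bitscore=900)
        result = iterative_filter([step1, step3], "dog")
        assert len(result) == 1
        assert result[0].subject_gene_id == "s_late_alphabet"
        assert result[0].step_accepted == 1

    def test_step_eight_only_hit_is_assigned_at_step_eight(self):
        hit = make_hit(pident=97.0, length=160, mm=12, gaps=2, qlen=300,
                       slen=310)
        result = iterative_filter([hit], "dog")
        assert result[0].step_accepted == 8

    def test_tie_broken_by_subject_id(self):
        a = make_hit(subject="s_b")
        b = make_hit(subject="s_a")
        result = iterative_filter([a, b], "dog")
        assert result[0].subject_gene_id == "s_a"

    def test_monotonicity_late_steps_never_revise_early_assignments(self):
        rng = random.Random(1)
        hits = _random_hits(rng, n_queries=10, n_hits=40)
        full = {a.query_id: (a.step_accepted, a.subject_gene_id)
                for a in iterative_filter(hits, "dog")}
        # rerun with only hits qualifying at steps 1..4 available
        early = [h for h in hits
                 if any(satisfies(h, c) for c in STEP_CRITERIA[:4])]
        partial = {a.query_id: (a.step_accepted, a.subject_gene_id)
                   for a in iterative_filter(early, "dog")}
        for q, (step, subject) in partial.items():
            if step <= 4:
                assert full[q] == (step, subject)

    def test_matches_brute_force_enumeration_oracle(self):
        rng = random.Random(202)
        for trial in range(20):
            hits = _random_hits(rng, n_queries=rng.randint(2, 8),
                                n_hits=rng.randint(5, 50))
            got = {a.query_id: (a.step_accepted, a.subject_gene_id)
                   for a in iterative_filter(hits, "dog")}
            assert got == oracles.brute_force_assign(hits)


def _random_hits(rng, n_queries, n_hits):
    hits = []
    for _ in range(n_hits):
        qlen = rng.randint(200, 400)
        slen = rng.randint(200, 400)
        length = rng.randint(100, min(qlen, slen))
        hits.append(HomologyHit(
            query_id=f"q{rng.randint(1, n_queries)}",
            subject_id=f"s{rng.randint(1, 12)}",
            percent_identity=round(rng.uniform(96.0, 100.0), 2),
            match_length=length, mismatches=rng.randint(0, 15),
            gap_openings=rng.randint(0, 3),
            evalue=rng.choice([1e-50, 1e-80, 1e-100]),
            bitscore=float(rng.randint(100, 800)),
            query_length=qlen, subject_length=slen))
    return hits


class TestSearchAndVerification:
    def test_identical_query_gets_perfect_top_hit(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        hits = search_homologs([nt(seq, "q")], [nt(seq, "s", "dog")])
        assert hits[0].percent_identity == 100.0
        assert hits[0].mismatches == 0 and hits[0].gap_openings == 0
        assert hits[0].match_length == 300

    def test_three_substitutions_counted(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        mutated = list(seq)
        for p in (50, 150, 250):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        hits = search_homologs([nt(seq, "q")],
                               [nt("".join(mutated), "s", "dog")])
        assert hits[0].mismatches == 3
        assert hits[0].percent_identity == pytest.approx(99.0)

    def test_search_score_matches_dp_oracle(self, rng):
        a = "".join(rng.choice("ACGT") for _ in range(200))
        b = list(a)
        for p in rng.sample(range(200), 8):
            b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
        hits = search_homologs([nt(a, "q")], [nt("".join(b), "s", "dog")],
                               min_shared_kmers=1)
        assert hits[0].bitscore == pytest.approx(
            oracles.sw_score(a, "".join(b)))

    def test_empty_subjects(self):
        assert search_homologs([nt("ACGT" * 30, "q")], []) == []

    def test_global_verification_rejects_local_only_homology(self, rng):
        core = "".join(rng.choice("ACGT") for _ in range(150))
        pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        query = nt(pad(225) + core + pad(225), "q")
        subject = nt(pad(220) + core + pad(230), "s", "dog")
        assert verify_global(query, nt(query.sequence, "copy"), 0.8)
        assert not verify_global(query, subject, 0.8)
        assert verify_global(query, subject, 0.0)


class TestKnownNovelAndGroups:
    def test_exact_copy_is_known(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(240))
        hits = search_homologs([nt(seq, "q")], [nt(seq, "public", "cat")])
        assert classify_known_novel(["q"], hits) == {"q": "known"}

    def test_query_without_public_match_is_novel(self):
        assert classify_known_novel(["q"], []) == {"q": "novel"}

    def test_groups_require_all_three_target_species(self):
        def assign(sp, queries):
            return [OrthologAssignment(q, sp, f"{sp}_{q}", 1,
                                       make_hit(query=q)) for q in queries]
        assignments = {"dog": assign("dog", ["q1", "q2"]),
                       "human": assign("human", ["q1", "q2"]),
                       "mouse": assign("mouse", ["q1"])}
        groups = build_ortholog_groups(assignments, {"q1": "known",
                                                     "q2": "novel"})
        assert len(groups) == 1
        assert groups[0].cat_gene_id == "q1"
        assert groups[0].dog_gene_id == "dog_q1"


class TestRecoveryOnSyntheticData:
    def test_zero_divergence_recovers_every_family(self):
        config = synthdata.SimulationConfig(
            n_genes=12, codon_length=(80, 120), branch_subs=0.0,
            dup_rate=0.0, ambiguity_rate=0.0, novel_fraction=0.25, seed=3)
        dataset = synthdata.generate(config)
        qc = run_qc(dataset.queries)
        orths = run_orthomap(qc.nonredundant, dataset.references)
        assert len(orths.groups) == 12
        truth_status = {synthdata.transcript_id("cat", i):
                        dataset.truth.status[synthdata.gene_base_id(i)]
                        for i in range(12)}
        assert orths.statuses == truth_status
        for g in orths.groups:
            base = g.cat_gene_id.replace("FCA_", "")
            assert g.dog_gene_id == f"CFA_{base}"
            assert g.human_gene_id == f"HSA_{base}"
            assert g.mouse_gene_id == f"MUS_{base}"

    def test_low_divergence_with_redundancy_recovers_pairs(self, small_dataset):
        qc = run_qc(small_dataset.queries)
        orths = run_orthomap(qc.nonredundant, small_dataset.references)
        n_true = small_dataset.config.n_genes
        recovered = correct = 0
        for sp in ("dog", "human", "mouse"):
            for a in orths.assignments[sp]:
                recovered += 1
                base = a.query_id.split(".")[0].replace("FCA_", "")
                correct += a.subject_gene_id.endswith(base)
        assert recovered / (3 * n_true) >= 0.95
        assert correct == recovered  # no non-orthologous pairings
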