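"""Identity statistics, resolvability, ASV validation, read concatenation."""

import math
import random

import pytest

from nestprime import (
    ReferenceDB,
    ReferenceRecord,
    TaxonomyLabel,
    concat_read_pair,
    group_similarity,
    pairwise_identity,
    protein_assignment_check,
    resolvability,
    reverse_complement,
    truncate_db_to_amplicon,
)
from nestprime.design import make_pair
from nestprime.petb import PETB_F, PETB_R, PETB_50F
from nestprime.synthetic import SimulationConfig, make_reference_db, simulate_asvs


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 100.0),
            ("AAAA", "AAAT", 75.0),
            ("ACGTACGT", "ACGAACGA", 75.0),
            ("ACGT", "ACGY", 100.0),  # compatible IUPAC codes match
        ],
    )
    def test_ungapped_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetry_and_self(self):
        rng = random.Random(0)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(30))
            b = "".join(rng.choice("ACGT") for _ in range(30))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)
            assert pairwise_identity(a, a) == 100.0

    def test_ungapped_equals_global_when_no_gaps_needed(self):
        rng = random.Random(1)
        for _ in range(10):
            a = "".join(rng.choice("ACGT") for _ in range(40))
            b = list(a)
            for i in rng.sample(range(40), 3):
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
            b = "".join(b)
            assert pairwise_identity(a, b, "ungapped") == pytest.approx(
                pairwise_identity(a, b, "global_align"))

    def test_length_mismatch_suggests_global(self):
        with pytest.raises(ValueError, match="global_align"):
            pairwise_identity("ACGT", "ACG")


@pytest.fixture(scope="module")
def planted_db():
    cfg = SimulationConfig(
        seed=11, n_clades=2, n_subclades_per_clade=2,
        n_records_per_subclade=3, gene_length=657,
        conserved_windows=(
            (22, 41, PETB_F.forward_footprint),
            (50, 66, "TCCAGGACATCGCTGAC"),
            (601, 618, PETB_R.forward_footprint),
            (619, 634, reverse_complement("GCTTCCGGATCATCAG")),
        ),
    )
    return ReferenceDB(make_reference_db(cfg).records, aligned=False)


class TestTruncateDB:
    def test_uniform_round2_amplicons(self, planted_db):
        pair = make_pair(PETB_50F, PETB_R)
        trunc, dropped = truncate_db_to_amplicon(planted_db, pair)
        assert dropped == []
        assert {len(r.sequence) for r in trunc.records} == {569}
        assert all(r.taxonomy == o.taxonomy
                   for r, o in zip(trunc.records, planted_db.records))

    def test_record_without_site_is_dropped(self, planted_db):
        records = list(planted_db.records)
        records.append(ReferenceRecord("no_site", "ACGT" * 200,
                                       TaxonomyLabel("5.1", "x", "")))
        db = ReferenceDB(records)
        _, dropped = truncate_db_to_amplicon(db, make_pair(PETB_50F, PETB_R))
        assert dropped == ["no_site"]

    def test_primer_toggle_changes_length_by_primer_sum(self, planted_db):
        pair = make_pair(PETB_50F, PETB_R)
        with_p, _ = truncate_db_to_amplicon(planted_db, pair, include_primers=True)
        without, _ = truncate_db_to_amplicon(planted_db, pair, include_primers=False)
        delta = len(PETB_50F) + len(PETB_R)
        assert all(len(a.sequence) - len(b.sequence) == delta
                   for a, b in zip(with_p.records, without.records))


def _two_group_db(divergence=0.2, seed=3, n=5, length=400):
    """Two groups of sequences diverged from separate ancestors."""
    rng = random.Random(seed)
    records = []
    for g in ("g1", "g2"):
        anc = [rng.choice("ACGT") for _ in range(length)]
        for i in range(n):
            seq = [
                rng.choice([b for b in "ACGT" if b != c])
                if rng.random() < divergence / 4 else c
                for c in anc
            ]
            records.append(ReferenceRecord(f"{g}_{i}", "".join(seq),
                                           TaxonomyLabel("5.1", g, "")))
    return ReferenceDB(records)


class TestGroupSimilarity:
    def test_identical_pair_scores_100(self):
        db = ReferenceDB([
            ReferenceRecord("a", "ACGTACGT", TaxonomyLabel("5.1", "g", "")),
            ReferenceRecord("b", "ACGTACGT", TaxonomyLabel("5.1", "g", "")),
        ])
        (rep,) = group_similarity(db, "clade")
        assert rep.within_min == rep.within_mean == 100.0

    def test_singleton_flagged_not_scored(self):
        db = ReferenceDB([ReferenceRecord("a", "ACGT",
                                          TaxonomyLabel("5.1", "solo", ""))])
        (rep,) = group_similarity(db, "clade")
        assert rep.singleton and rep.within_min is None

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_configured_divergence(self, seed):
        """Mean within-group identity tracks the generator's mutation rate.

        Two sequences mutated independently from one ancestor at per-site
        rate p differ at a site with probability 2p(3/4) - small double-hit
        corrections; the Monte-Carlo estimate must sit within 3 SE.
        """
        p = 0.05
        length = 600
        db = make_reference_db(SimulationConfig(
            seed=seed, n_clades=1, n_subclades_per_clade=1,
            n_records_per_subclade=6, gene_length=length,
            within_subclade_divergence=p,
        ))
        (rep,) = group_similarity(db, "clade")
        # exact expected per-site difference for two branches of rate p with
        # uniform substitution to the 3 other bases
        q = 2 * p * (1 - p) + p * p * (2 / 3)
        se = math.sqrt(q * (1 - q) / length)  # per-pair; mean over pairs is tighter
        expected = 100 * (1 - q)
        assert abs(rep.within_mean - expected) <= 3 * 100 * se

    def test_separated_groups_between_below_within(self):
        db = _two_group_db(divergence=0.2)
        reports = group_similarity(db, "clade", between=True)
        for rep in reports:
            assert max(rep.between_max.values()) < rep.within_min


class TestResolvability:
    def test_diverged_groups_resolvable(self):
        db = _two_group_db(divergence=0.2)
        (v,) = resolvability(db, "clade")
        assert v.resolvable and v.between_max < min(v.within_min_a, v.within_min_b)

    def test_shared_sequence_entangles(self):
        shared = "ACGT" * 25
        db = ReferenceDB([
            ReferenceRecord("a1", shared, TaxonomyLabel("5.1", "A", "")),
            ReferenceRecord("a2", shared[:-1] + "T", TaxonomyLabel("5.1", "A", "")),
            ReferenceRecord("b1", shared, TaxonomyLabel("5.1", "B", "")),
            ReferenceRecord("b2", shared[:-1] + "G", TaxonomyLabel("5.1", "B", "")),
        ])
        (v,) = resolvability(db, "clade")
        assert not v.resolvable
        assert ("a1", "b1", 100.0) in v.entangled_pairs

    def test_single_group_empty_verdicts(self):
        db = ReferenceDB([
            ReferenceRecord("a", "ACGT", TaxonomyLabel("5.1", "A", "")),
            ReferenceRecord("b", "AGGT", TaxonomyLabel("5.1", "A", "")),
        ])
        assert resolvability(db, "clade") == []


@pytest.fixture(scope="module")
def amplicon_db():
    db = make_reference_db(SimulationConfig(
        seed=21, n_clades=2, n_subclades_per_clade=1,
        n_records_per_subclade=3, gene_length=300,
        between_clade_divergence=0.25, within_subclade_divergence=0.02,
    ))
    return ReferenceDB(db.records, aligned=False)


class TestProteinAssignmentCheck:
    def test_identical_asv_is_correct(self, amplicon_db):
        rec = amplicon_db.records[0]
        summary = protein_assignment_check(
            [("asv1", rec.sequence, rec.taxonomy.clade)], amplicon_db)
        (check,) = summary.checks
        assert check.best_identity == pytest.approx(100.0)
        assert check.correctly_assigned and summary.rate_overall == 100.0

    def test_random_sequence_is_incorrect(self, amplicon_db):
        rng = random.Random(4)
        junk = "".join(rng.choice("ACGT") for _ in range(300))
        summary = protein_assignment_check([("junk", junk, "clade1")], amplicon_db)
        assert not summary.checks[0].correctly_assigned
        assert summary.checks[0].best_identity < 95.0

    def test_threshold_zero_accepts_everything(self, amplicon_db):
        rng = random.Random(5)
        junk = "".join(rng.choice("ACGT") for _ in range(90))
        summary = protein_assignment_check([("j", junk, "clade1")], amplicon_db,
                                           threshold=0.0)
        assert summary.rate_overall == 100.0

    def test_monotone_in_threshold(self, amplicon_db):
        sim = simulate_asvs(amplicon_db, n_per_group=6, error_rate=0.03,
                            spurious_fraction=0.3, seed=8)
        triples = sim.as_assignment_triples()
        correct_at = []
        for thr in (80.0, 90.0, 95.0, 99.0):
            s = protein_assignment_check(triples, amplicon_db, threshold=thr)
            correct_at.append({c.asv_id for c in s.checks if c.correctly_assigned})
        for lo, hi in zip(correct_at, correct_at[1:]):
            assert hi <= lo  # raising the threshold never adds correct ASVs

    def test_untranslatable_asv_excluded_from_rate(self, amplicon_db):
        rec = amplicon_db.records[0]
        summary = protein_assignment_check(
            [("ok", rec.sequence, rec.taxonomy.clade), ("tiny", "AC", "clade1")],
            amplicon_db)
        assert summary.n_excluded == 1 and summary.rate_overall == 100.0


class TestConcatReadPair:
    def test_spacer_and_orientation(self):
        rng = random.Random(6)
        fwd = "".join(rng.choice("ACGT") for _ in range(250))
        rev = "".join(rng.choice("ACGT") for _ in range(280))
        merged = concat_read_pair(fwd, rev, spacer_n=10)
        assert len(merged) == 540
        assert merged[250:260] == "N" * 10
        assert merged.startswith(fwd)
        assert merged.endswith(reverse_complement(rev))

    def test_zero_spacer_plain_concatenation(self):
        assert concat_read_pair("ACGT", "AAAA", spacer_n=0) == "ACGT" + "TTTT"
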