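"""Alignment scores vs a brute-force DP oracle; E-values; hit filtering."""

import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from plasbhr import homology
from plasbhr.homology import (
    Alignment,
    DEFAULT_THRESHOLDS,
    HitThresholds,
    align_local,
    evalue,
    passes,
    search_category,
)
from plasbhr.orfs import OrfRecord
from plasbhr.seqio import Category, PlasmidRecord, ReferenceEntry, reverse_complement
from plasbhr.simulate import _random_dna

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """General-gap-cost local alignment DP (Waterman-Eggert form).

    O(n*m*(n+m)): each cell scans all gap lengths explicitly, so it shares no
    affine-state machinery with the implementation under test. A gap of
    length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            val = max(0, H[i - 1][j - 1] + score(a[i - 1], b[j - 1]))
            for k in range(1, i + 1):
                val = max(val, H[i - k][j] - gap_open - gap_extend * k)
            for k in range(1, j + 1):
                val = max(val, H[i][j - k] - gap_open - gap_extend * k)
            H[i][j] = val
            best = max(best, val)
    return best


def _blosum(x: str, y: str) -> float:
    return _BLOSUM62[x][y]


class TestAlignLocal:
    def test_self_alignment(self):
        aln = align_local("MKV", "MKV", "protein")
        assert aln.identity == 1.0
        assert aln.ref_cover == 1.0
        # BLOSUM62: M/M=5, K/K=5, V/V=4
        assert aln.raw_score == 14

    def test_matches_bruteforce_oracle_protein(self):
        rand = random.Random(42)
        for _ in range(170):
            a = "".join(rand.choices(_AA, k=rand.randint(5, 30)))
            b = "".join(rand.choices(_AA, k=rand.randint(5, 30)))
            expected = sw_oracle(a, b, _blosum, 11, 1)
            aln = align_local(a, b, "protein")
            got = 0 if aln is None else aln.raw_score
            assert got == expected, (a, b)

    def test_matches_bruteforce_oracle_nucleotide(self):
        rand = random.Random(43)
        score = lambda x, y: 2 if x == y else -3
        for _ in range(30):
            a = "".join(rand.choices("ACGT", k=rand.randint(8, 30)))
            b = "".join(rand.choices("ACGT", k=rand.randint(8, 30)))
            expected = max(
                sw_oracle(a, b, score, 5, 2),
                sw_oracle(a, reverse_complement(b), score, 5, 2),
            )
            aln = align_local(a, b, "nucleotide")
            got = 0 if aln is None else aln.raw_score
            assert got == expected, (a, b)

    def test_score_symmetry(self):
        rand = random.Random(44)
        for _ in range(50):
            a = "".join(rand.choices(_AA, k=rand.randint(10, 40)))
            b = "".join(rand.choices(_AA, k=rand.randint(10, 40)))
            ab = align_local(a, b, "protein")
            ba = align_local(b, a, "protein")
            assert (ab is None) == (ba is None)
            if ab is not None:
                assert ab.raw_score == ba.raw_score

    def test_reverse_strand_coordinates(self, rng):
        motif = _random_dna(rng, 30)
        target = "T" * 50 + motif + "T" * 30
        aln = align_local(reverse_complement(motif), target, "nucleotide")
        assert aln.strand == "-"
        assert aln.target_span == (50, 80)
        assert aln.identity == 1.0

    def test_accelerated_matches_exact(self, rng):
        backbone = _random_dna(rng, 12000)
        motif = _random_dna(rng, 300)
        seq = backbone[:7000] + reverse_complement(motif) + backbone[7300:]
        fast = align_local(motif, seq, "nucleotide", accelerate=True)
        exact = align_local(motif, seq, "nucleotide", accelerate=False)
        assert fast.raw_score == exact.raw_score
        assert fast.target_span == exact.target_span
        assert fast.strand == exact.strand == "-"

    def test_empty_input_rejected(self):
        with pytest.raises(homology.AlignmentError):
            align_local("", "MKV", "protein")


class TestEvalue:
    def test_zero_score_formula(self):
        lam, k = homology.GAPPED_KA["protein"]
        expected = 200 * 1000 * 2 ** (math.log(k) / math.log(2))
        assert evalue(0, 200, 1000, "protein") == pytest.approx(expected)
        assert evalue(0, 200, 1000, "protein") > 0

    def test_linear_in_database_length(self):
        assert evalue(50, 100, 2_000_000, "protein") == pytest.approx(
            2 * evalue(50, 100, 1_000_000, "protein")
        )

    def test_frozen_regression_value(self):
        # E(S=100, m=200, n=1e6, protein) computed once from the formula
        assert evalue(100, 200, 1_000_000, "protein") == pytest.approx(
            2.0804207922205098e-05, rel=1e-9
        )
        assert homology.bitscore(100, "protein") == pytest.approx(43.12818987, rel=1e-8)

    def test_monotone_decreasing_in_score(self):
        values = [evalue(s, 300, 1_000_000, "protein") for s in range(0, 500, 7)]
        assert all(x > y for x, y in zip(values, values[1:]))


def _orf(orf_id: str, plasmid_id: str, protein: str) -> OrfRecord:
    return OrfRecord(
        orf_id=orf_id, plasmid_id=plasmid_id, start=0,
        end=3 * len(protein) + 3, strand="+", protein=protein,
    )


def _ref(seq: str, category=Category.REP, family="IncF", rid="r1") -> ReferenceEntry:
    return ReferenceEntry(
        id=rid, category=category, family=family, molecule="protein", sequence=seq,
    )


class TestSearchCategory:
    def test_planted_reference_found_with_full_identity(self, rng):
        protein = "M" + "".join(rng.choice(list(_AA), size=299))
        ref = _ref(protein)
        targets = [_orf("p1_1", "p1", protein)]
        (hit,) = search_category([ref], targets)
        assert hit.identity == 1.0
        assert hit.ref_cover == 1.0
        assert hit.category is Category.REP
        assert hit.plasmid_id == "p1"

    def test_random_targets_produce_no_hits(self, rng):
        ref = _ref("M" + "".join(rng.choice(list(_AA), size=299)))
        targets = [
            _orf(f"p{i}_1", f"p{i}", "".join(rng.choice(list(_AA), size=300)))
            for i in range(100)
        ]
        assert search_category([ref], targets) == []

    def test_strict_inequality_at_identity_boundary(self):
        base = dict(
            ref_id="r", target_id="t", raw_score=500, bitscore=130.0,
            evalue=1e-30, ref_cover=0.9, ref_span=(0, 90),
            target_span=(0, 90), strand="n/a",
        )
        thresholds = HitThresholds(1e-5, 0.5, 0.5)
        assert not passes(Alignment(identity=0.5, **base), thresholds)
        assert passes(Alignment(identity=0.501, **base), thresholds)
        # same strictness on coverage and E-value
        assert not passes(
            Alignment(identity=0.9, **{**base, "ref_cover": 0.5}), thresholds
        )
        assert not passes(
            Alignment(identity=0.9, **{**base, "evalue": 1e-5}), thresholds
        )

    def test_results_invariant_to_input_order(self, rng):
        prot_a = "M" + "".join(rng.choice(list(_AA), size=199))
        prot_b = "M" + "".join(rng.choice(list(_AA), size=249))
        refs = [_ref(prot_a, rid="r1"), _ref(prot_b, family="IncX", rid="r2")]
        targets = [_orf("p1_1", "p1", prot_a), _orf("p2_1", "p2", prot_b)]
        forward = search_category(refs, targets)
        shuffled = search_category(refs[::-1], targets[::-1])
        assert forward == shuffled
        assert len(forward) == 2

    def test_mixed_categories_rejected(self):
        refs = [_ref("MKVLMKVL"), _ref("MKVLMKVL", category=Category.PAR,
                                       family="sopB", rid="r2")]
        with pytest.raises(ValueError, match="one category"):
            search_category(refs, [_orf("p1_1", "p1", "MKVL")])

    def test_nucleotide_search_on_plasmids(self, rng):
        motif = _random_dna(rng, 250)
        backbone = _random_dna(rng, 8000)
        seq = backbone[:4000] + motif + backbone[4250:]
        ref = ReferenceEntry(
            id="oriT_F", category=Category.ORIT, family="oriT_F",
            molecule="nucleotide", sequence=motif,
        )
        plasmid = PlasmidRecord(id="p1", sequence=seq)
        decoy = PlasmidRecord(id="p2", sequence=_random_dna(rng, 8000))
        hits = search_category([ref], [plasmid, decoy])
        assert [h.plasmid_id for h in hits] == ["p1"]
        assert hits[0].identity == 1.0
        assert hits[0].target_span == (4000, 4250)
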