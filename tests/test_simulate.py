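"""Synthetic cohort generator: determinism, planted-truth consistency."""

import numpy as np
import pytest

from plasbhr import homology, seqio, simulate
from plasbhr.orfs import find_orfs, translate
from plasbhr.seqio import Category, PlasmidRecord, reverse_complement
from plasbhr.simulate import (
    GenerationError,
    SimConfig,
    make_reference_panel,
    mutate_protein,
    plant_cassette,
    simulate_cohort,
    write_cohort,
)


class TestReferencePanel:
    def test_same_seed_is_byte_identical(self, tmp_path):
        for i, seed in enumerate((5, 5)):
            cohort = simulate.Cohort(
                plasmids=[], panel=make_reference_panel(seed), truth=[]
            )
            write_cohort(cohort, tmp_path / f"v{i}")
        a = sorted((tmp_path / "v0").glob("panel_*.fasta"))
        b = sorted((tmp_path / "v1").glob("panel_*.fasta"))
        assert [p.read_bytes() for p in a] == [p.read_bytes() for p in b]
        assert make_reference_panel(6) != make_reference_panel(5)

    def test_panel_roundtrips_through_loader(self, tmp_path):
        cohort = simulate.Cohort(plasmids=[], panel=make_reference_panel(1), truth=[])
        write_cohort(cohort, tmp_path)
        paths = {
            p.stem.removeprefix("panel_").upper(): p
            for p in tmp_path.glob("panel_*.fasta")
        }
        entries = seqio.load_reference_sets(paths)
        assert len(entries) == len(cohort.panel)
        reloaded = {(e.category, e.family): e.sequence for e in entries}
        original = {(e.category, e.family): e.sequence for e in cohort.panel}
        assert reloaded == original

    def test_families_unique_within_category(self, panel):
        seen = set()
        for e in panel:
            assert (e.category, e.family) not in seen
            seen.add((e.category, e.family))

    def test_panel_composition(self, panel):
        by_cat = {}
        for e in panel:
            by_cat.setdefault(e.category, []).append(e)
        for category in Category:
            assert category in by_cat
        t4ss = [e.family for e in by_cat[Category.T4SS]]
        assert any(f.endswith("_ATPase") for f in t4ss)
        assert len({f.split("_")[0] for f in t4ss}) == 2
        assert all(100 <= len(e.sequence) <= 600 for e in panel if e.molecule == "protein")
        assert all(e.sequence.startswith("M") for e in panel if e.molecule == "protein")


class TestPlantCassette:
    def test_zero_divergence_recovers_exact_protein(self, rng):
        protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=150))
        backbone = simulate._random_dna(rng, 3000)
        planted, (start, end, strand) = plant_cassette(backbone, protein, 0.0, rng)
        orfs = find_orfs(PlasmidRecord(id="p", sequence=planted))
        assert protein in [o.protein for o in orfs]
        match = [o for o in orfs if o.protein == protein][0]
        assert (match.start, match.end, match.strand) == (start, end, strand)

    def test_divergence_fraction_reflected_in_alignment_identity(self, rng):
        identities = []
        for _ in range(20):
            protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=200))
            mutated = mutate_protein(protein, 0.2, rng)
            aln = homology.align_local(protein, mutated, "protein")
            identities.append(aln.identity)
        assert np.mean(identities) == pytest.approx(0.8, abs=0.05)

    def test_heavy_divergence_misses_strict_identity_threshold(self, rng):
        ref = simulate.make_reference_panel(2)
        sopb = [e for e in ref if e.family == "sopB"][0]
        backbone = simulate._random_dna(rng, 4000)
        planted, _ = plant_cassette(backbone, sopb.sequence, 0.6, rng)
        orfs = find_orfs(PlasmidRecord(id="p", sequence=planted))
        hits = homology.search_category([sopb], orfs)  # PAR tier: identity > 80%
        assert hits == []

    def test_no_slot_raises_generation_error(self, rng):
        protein = "M" * 40
        with pytest.raises(GenerationError):
            plant_cassette("ACGT" * 25, protein, 0.0, rng)  # backbone too short


class TestSimulateCohort:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = SimConfig(seed=11, n_plasmids=8, n_clusters=1, cluster_size=2)
        for sub in ("a", "b"):
            write_cohort(simulate_cohort(config), tmp_path / sub)
        for name in ("cohort.fasta", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_truth_tsv_roundtrip(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path)
        reloaded = simulate.load_truth_tsv(tmp_path / "truth.tsv")
        assert [t.plasmid_id for t in reloaded] == [
            t.plasmid_id for t in small_cohort.truth
        ]
        for got, want in zip(reloaded, small_cohort.truth):
            assert got.true_class == want.true_class
            assert got.true_bhr == want.true_bhr
            assert got.true_cluster == want.true_cluster
            assert got.planted_categories == want.planted_categories

    def test_spans_translate_back_to_planted_proteins(self):
        config = SimConfig(
            seed=21, n_plasmids=6, n_clusters=0, cassette_divergence=0.0,
            orit_divergence=0.0,
        )
        cohort = simulate_cohort(config)
        proteins = {
            (e.category, e.sequence) for e in cohort.panel if e.molecule == "protein"
        }
        nt_refs = {
            (e.category, e.sequence) for e in cohort.panel if e.molecule == "nucleotide"
        }
        checked = 0
        for truth in cohort.truth:
            seq = {p.id: p.sequence for p in cohort.plasmids}[truth.plasmid_id]
            for category, start, end, strand in truth.planted_spans:
                piece = seq[start:end]
                if strand == "-":
                    piece = reverse_complement(piece)
                if category in seqio.NUCLEOTIDE_CATEGORIES:
                    assert (category, piece) in nt_refs
                else:
                    protein = translate(piece[:-3], initiator=True)
                    assert (category, protein) in proteins
                checked += 1
        assert checked > 0

    def test_spans_non_overlapping_and_in_bounds(self, small_cohort):
        lengths = {p.id: p.length for p in small_cohort.plasmids}
        for truth in small_cohort.truth:
            spans = sorted((s, e) for _, s, e, _ in truth.planted_spans)
            assert all(0 <= s < e <= lengths[truth.plasmid_id] for s, e in spans)
            assert all(b[0] >= a[1] - 3 for a, b in zip(spans, spans[1:]))

    def test_true_bhr_consistent_with_planted_categories(self, small_cohort):
        for truth in small_cohort.truth:
            cats = truth.planted_categories
            tat = Category.TOXIN in cats and (
                Category.ANTITOXIN in cats or Category.RNA_ANTITOXIN in cats
            )
            n = sum(
                (
                    tat,
                    Category.PAR in cats,
                    Category.PSI in cats,
                    Category.MPS in cats,
                    Category.MTASE in cats,
                )
            )
            assert truth.true_bhr == (n >= 3)

    def test_cluster_members_share_class_and_near_identity(self, small_cohort):
        by_cluster = {}
        for t in small_cohort.truth:
            if t.true_cluster:
                by_cluster.setdefault(t.true_cluster, []).append(t)
        seqs = {p.id: p.sequence for p in small_cohort.plasmids}
        assert len(by_cluster) == 2
        for members in by_cluster.values():
            assert len(members) == 2
            assert len({m.true_class for m in members}) == 1
            a, b = (seqs[m.plasmid_id] for m in members)
            assert len(a) == len(b)
            diff = sum(x != y for x, y in zip(a, b)) / len(a)
            assert diff < 0.02 + 0.005

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"class_mix": {"conjugative": 0.5, "mobilizable": 0.4, "non_mobilizable": 0.0}},
            {"n_plasmids": 3, "n_clusters": 2, "cluster_size": 3},
            {"cassette_divergence": 0.7},
            {"within_cluster_subst": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
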