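"""Synthetic plasmid cohorts with planted, machine-readable ground truth.

The generator emulates the statistical structure of an AR-isolate plasmid
cohort: three mobility classes with class-conditional log-normal lengths and
GC content (conjugative > mobilizable > non-mobilizable lengths; conjugative
highest GC), functional protein cassettes planted at a controlled amino-acid
divergence, oriT motifs planted at nucleotide divergence, ARG enrichment in
mobile plasmids, and groups of near-identical plasmids for ANI clustering.

Planting conventions (chosen so that ground truth is exactly recoverable):

* every reference protein starts with M, and a cassette is written as an
  in-frame TAA guard, the reverse-translated coding sequence (uniform codon
  choice, table 11) and a TAA stop, inserted by overwriting backbone at a
  random non-overlapping position on a random strand. The guard stop pins
  the ORF start, so at 0% divergence the ORF caller recovers exactly the
  planted protein.
* divergence substitutes ``round(divergence * len)`` amino-acid positions
  (never the initiator M) with uniform different residues, so alignment
  identity to the reference is 1 - divergence by construction.
* within-cluster copies substitute backbone positions outside planted
  cassettes only, so copies keep their seed's planted truth exactly while
  whole-sequence identity drops by roughly the substitution rate times the
  backbone fraction.

A single master seed drives everything; per-plasmid substreams are derived
by counter so cohorts are stable under changes of ``n_plasmids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mobility import CONJUGATIVE, MOBILITY_CLASSES, MOBILIZABLE, NON_MOBILIZABLE
from .orfs import CODON_TO_AA
from .seqio import (
    Category,
    NUCLEOTIDE_CATEGORIES,
    PlasmidRecord,
    ReferenceEntry,
    reference_fasta_header,
    reverse_complement,
    write_fasta,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


class GenerationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference conditions: 60 plasmids in a
    0.4/0.3/0.3 conjugative/mobilizable/non-mobilizable mix, log-normal
    lengths with medians 15/8/4 kb, backbone GC 0.58/0.50/0.44, cassettes at
    5% amino-acid divergence, oriT at 2% nucleotide divergence, per-feature
    plant probabilities 0.65/0.45/0.15, ARG carriage 0.8/0.6/0.2, and three
    planted clusters of three near-identical plasmids (2% backbone
    substitution).
    """

    seed: int = 0
    n_plasmids: int = 60
    class_mix: dict[str, float] = field(
        default_factory=lambda: {CONJUGATIVE: 0.4, MOBILIZABLE: 0.3, NON_MOBILIZABLE: 0.3}
    )
    length_lognormal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            CONJUGATIVE: (float(np.log(15000)), 0.30),
            MOBILIZABLE: (float(np.log(8000)), 0.35),
            NON_MOBILIZABLE: (float(np.log(4000)), 0.40),
        }
    )
    length_floor_per_class: dict[str, int] = field(
        default_factory=lambda: {CONJUGATIVE: 9000, MOBILIZABLE: 4000, NON_MOBILIZABLE: 1500}
    )
    gc_per_class: dict[str, float] = field(
        default_factory=lambda: {CONJUGATIVE: 0.58, MOBILIZABLE: 0.50, NON_MOBILIZABLE: 0.44}
    )
    cassette_divergence: float = 0.05
    orit_divergence: float = 0.02
    feature_prob_per_class: dict[str, float] = field(
        default_factory=lambda: {CONJUGATIVE: 0.65, MOBILIZABLE: 0.45, NON_MOBILIZABLE: 0.15}
    )
    arg_prob_per_class: dict[str, float] = field(
        default_factory=lambda: {CONJUGATIVE: 0.8, MOBILIZABLE: 0.6, NON_MOBILIZABLE: 0.2}
    )
    vf_prob: float = 0.15
    rep_prob: float = 0.95
    second_rep_prob: float = 0.15
    relaxase_in_mobilizable_prob: float = 0.5
    n_clusters: int = 3
    cluster_size: int = 3
    within_cluster_subst: float = 0.02

    def __post_init__(self) -> None:
        if set(self.class_mix) != set(MOBILITY_CLASSES):
            raise ValueError(f"class_mix must cover {MOBILITY_CLASSES}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        for name, p in [
            ("cassette_divergence", self.cassette_divergence),
            ("orit_divergence", self.orit_divergence),
            ("vf_prob", self.vf_prob),
            ("relaxase_in_mobilizable_prob", self.relaxase_in_mobilizable_prob),
            ("within_cluster_subst", self.within_cluster_subst),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.cassette_divergence > 0.6:
            raise ValueError("cassette_divergence must be <= 0.6")
        for d in (self.feature_prob_per_class, self.arg_prob_per_class):
            for p in d.values():
                if not 0 <= p <= 1:
                    raise ValueError("probabilities must lie in [0,1]")
        for floor in self.length_floor_per_class.values():
            if floor < 1000:
                raise ValueError("length floors must be >= 1000 nt")
        if self.n_clusters < 0 or self.cluster_size < 2:
            raise ValueError("need n_clusters >= 0 and cluster_size >= 2")
        if self.n_plasmids < self.n_clusters * self.cluster_size:
            raise ValueError(
                "n_plasmids too small for the requested clusters "
                f"({self.n_clusters} x {self.cluster_size})"
            )


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic plasmid.

    ``true_cluster`` is 1-based for members of planted near-identity groups
    and 0 for singletons. Spans are ORF coordinates (0-based half-open, stop
    codon included) on the forward strand.
    """

    plasmid_id: str
    true_class: str
    planted_categories: dict[Category, frozenset[str]]
    true_bhr: bool
    true_cluster: int
    planted_spans: list[tuple[Category, int, int, str]]


@dataclass
class Cohort:
    plasmids: list[PlasmidRecord]
    panel: list[ReferenceEntry]
    truth: list[TruthRecord]


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "M" + "".join(rng.choice(list(_AA20), size=length - 1))


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


_PANEL_SPEC: list[tuple[str, Category, str, str | None, tuple[int, int]]] = [
    ("repA_F", Category.REP, "IncF", None, (250, 330)),
    ("repA_X", Category.REP, "IncX", None, (250, 330)),
    ("traI_F", Category.RELAXASE, "MOBF", None, (320, 420)),
    ("mobA_P", Category.RELAXASE, "MOBP", None, (320, 420)),
    ("traC", Category.T4SS, "MPFF_traC_ATPase", None, (180, 260)),
    ("traB", Category.T4SS, "MPFF_traB", None, (130, 220)),
    ("traK", Category.T4SS, "MPFF_traK", None, (130, 220)),
    ("traE", Category.T4SS, "MPFF_traE", None, (110, 190)),
    ("traV", Category.T4SS, "MPFF_traV", None, (110, 190)),
    ("traL", Category.T4SS, "MPFF_traL", None, (100, 160)),
    ("virB4", Category.T4SS, "MPFT_virB4_ATPase", None, (180, 260)),
    ("virB3", Category.T4SS, "MPFT_virB3", None, (100, 170)),
    ("virB6", Category.T4SS, "MPFT_virB6", None, (130, 220)),
    ("virB8", Category.T4SS, "MPFT_virB8", None, (120, 200)),
    ("virB9", Category.T4SS, "MPFT_virB9", None, (130, 220)),
    ("ccdB_1", Category.TOXIN, "ccdB", "ccdA", (100, 120)),
    ("vapC_1", Category.TOXIN, "vapC", "vapB", (110, 140)),
    ("hok_1", Category.TOXIN, "hok", "sok", (100, 115)),
    ("ccdA_1", Category.ANTITOXIN, "ccdA", "ccdB", (100, 115)),
    ("vapB_1", Category.ANTITOXIN, "vapB", "vapC", (100, 120)),
    ("sopB_1", Category.PAR, "sopB", None, (160, 250)),
    ("parA_1", Category.PAR, "parA", None, (160, 250)),
    ("psiB_1", Category.PSI, "psiB", None, (110, 160)),
    ("psiA_1", Category.PSI, "psiA", None, (110, 160)),
    ("traN_1", Category.MPS, "traN", None, (200, 300)),
    ("traG_1", Category.MPS, "traG", None, (200, 300)),
    ("mtase_EcoKI", Category.MTASE, "M_EcoKI", None, (200, 300)),
    ("mtase_EcoRI", Category.MTASE, "M_EcoRI", None, (200, 300)),
    ("tem1", Category.ARG, "TEM-1", "beta_lactam", (270, 290)),
    ("sul1", Category.ARG, "sul1", "sulfonamide", (260, 290)),
    ("aph3", Category.ARG, "aph3-Ia", "aminoglycoside", (250, 280)),
    ("hlyA_1", Category.VF, "hlyA", None, (250, 380)),
    ("espC_1", Category.VF, "espC", None, (250, 380)),
    ("oriT_F", Category.ORIT, "oriT_F", None, (240, 260)),
    ("sok_1", Category.RNA_ANTITOXIN, "sok", None, (110, 130)),
]


def make_reference_panel(seed: int) -> list[ReferenceEntry]:
    """Deterministic reference panel standing in for curated databases.

    Two or more families per protein category (a full MPF gene set per MPF
    type, including one ATPase-flagged gene), cognate toxin-antitoxin pairs
    (including the RNA antitoxin sok paired with hok), three ARGs with
    antibiotic classes, two VFs and one oriT. Same seed, same panel, byte
    for byte.
    """
    rng = np.random.default_rng([int(seed), 101])
    entries = []
    for entry_id, category, family, third, (lo, hi) in _PANEL_SPEC:
        if category in NUCLEOTIDE_CATEGORIES:
            seq = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            molecule = "nucleotide"
        else:
            seq = _random_protein(rng, lo, hi)
            molecule = "protein"
        entries.append(
            ReferenceEntry(
                id=entry_id,
                category=category,
                family=family,
                molecule=molecule,
                sequence=seq,
                cognate_partner=third if category in (Category.TOXIN, Category.ANTITOXIN) else None,
                arg_class=third if category is Category.ARG else None,
            )
        )
    return entries


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute ``round(divergence * len)`` positions (never the initial M)."""
    if not 0 <= divergence <= 0.6:
        raise ValueError("divergence must be in [0, 0.6]")
    n_sub = round(divergence * len(protein))
    if n_sub == 0:
        return protein
    positions = rng.choice(np.arange(1, len(protein)), size=min(n_sub, len(protein) - 1), replace=False)
    out = list(protein)
    for pos in positions:
        choices = [a for a in _AA20 if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def mutate_nucleotides(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Substitute ``round(rate * n_mutable)`` positions outside protected spans."""
    mask = np.ones(len(sequence), dtype=bool)
    for start, end in protected:
        mask[start:end] = False
    mutable = np.flatnonzero(mask)
    n_sub = round(rate * mutable.size)
    if n_sub == 0:
        return sequence
    positions = rng.choice(mutable, size=n_sub, replace=False)
    out = list(sequence)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))] for aa in protein
    )


def _find_slot(
    backbone_len: int,
    insert_len: int,
    occupied: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    attempts: int = 500,
) -> int | None:
    for _ in range(attempts):
        start = int(rng.integers(0, backbone_len - insert_len + 1))
        if all(start + insert_len <= s or start >= e for s, e in occupied):
            return start
    return None


def plant_cassette(
    backbone: str,
    protein: str,
    divergence: float,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, tuple[int, int, str]]:
    """Plant a protein cassette into a backbone by overwriting a random slot.

    Returns the new backbone and the ORF span ``(start, end, strand)`` in
    forward coordinates (stop codon included). The insert is an in-frame TAA
    guard + coding sequence + TAA; ``occupied``, when given, is consulted for
    non-overlap and updated in place with the full insert span.
    """
    mutated = mutate_protein(protein, divergence, rng)
    dna = "TAA" + reverse_translate(mutated, rng) + "TAA"
    if len(dna) > len(backbone):
        raise GenerationError(
            f"backbone of {len(backbone)} nt cannot hold a {len(dna)} nt cassette"
        )
    occ = occupied if occupied is not None else []
    start = _find_slot(len(backbone), len(dna), occ, rng)
    if start is None:
        raise GenerationError(
            "no non-overlapping slot found; use a longer backbone"
        )
    strand = "+" if rng.random() < 0.5 else "-"
    insert = dna if strand == "+" else reverse_complement(dna)
    new_backbone = backbone[:start] + insert + backbone[start + len(insert):]
    occ.append((start, start + len(dna)))
    coding_len = len(dna) - 6  # strip guard and final stop
    if strand == "+":
        span = (start + 3, start + 3 + coding_len + 3, "+")
    else:
        span = (start, start + coding_len + 3, "-")
    return new_backbone, span


def _plant_nucleotide(
    backbone: str,
    motif: str,
    divergence: float,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
) -> tuple[str, tuple[int, int, str]]:
    mutated = mutate_nucleotides(motif, divergence, rng)
    if len(mutated) > len(backbone):
        raise GenerationError("backbone too short for nucleotide motif")
    start = _find_slot(len(backbone), len(mutated), occupied, rng)
    if start is None:
        raise GenerationError("no non-overlapping slot found; use a longer backbone")
    strand = "+" if rng.random() < 0.5 else "-"
    insert = mutated if strand == "+" else reverse_complement(mutated)
    new_backbone = backbone[:start] + insert + backbone[start + len(insert):]
    occupied.append((start, start + len(insert)))
    return new_backbone, (start, start + len(insert), strand)


def _panel_families(panel: Sequence[ReferenceEntry]) -> dict[Category, list[ReferenceEntry]]:
    by_cat: dict[Category, list[ReferenceEntry]] = {}
    for entry in panel:
        by_cat.setdefault(entry.category, []).append(entry)
    return by_cat


def _choose(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def _generate_plasmid(
    pid: str,
    cls: str,
    config: SimConfig,
    panel: Sequence[ReferenceEntry],
    rng: np.random.Generator,
    force_bhr: bool,
) -> tuple[PlasmidRecord, TruthRecord, list[tuple[int, int]]]:
    by_cat = _panel_families(panel)
    mu, sigma = config.length_lognormal_params[cls]
    length = int(rng.lognormal(mu, sigma))
    length = max(length, config.length_floor_per_class[cls])
    length = min(length, 450_000)

    plan: list[tuple[Category, ReferenceEntry]] = []  # protein cassettes
    nt_plan: list[tuple[Category, ReferenceEntry]] = []  # nucleotide motifs

    if rng.random() < config.rep_prob:
        reps = list(by_cat[Category.REP])
        first_rep = _choose(rng, reps)
        plan.append((Category.REP, first_rep))
        if rng.random() < config.second_rep_prob:
            others = [e for e in reps if e.family != first_rep.family]
            if others:
                plan.append((Category.REP, _choose(rng, others)))

    if cls == CONJUGATIVE:
        plan.append((Category.RELAXASE, _choose(rng, by_cat[Category.RELAXASE])))
        mpf_types = sorted({e.family.split("_")[0] for e in by_cat[Category.T4SS]})
        chosen_type = _choose(rng, mpf_types)
        plan.extend(
            (Category.T4SS, e)
            for e in by_cat[Category.T4SS]
            if e.family.split("_")[0] == chosen_type
        )
        nt_plan.append((Category.ORIT, _choose(rng, by_cat[Category.ORIT])))
    elif cls == MOBILIZABLE:
        nt_plan.append((Category.ORIT, _choose(rng, by_cat[Category.ORIT])))
        if rng.random() < config.relaxase_in_mobilizable_prob:
            plan.append((Category.RELAXASE, _choose(rng, by_cat[Category.RELAXASE])))

    p_feat = config.feature_prob_per_class[cls]
    feature_flags = {name: bool(rng.random() < p_feat) for name in ("TAT", "PAR", "PSI", "MPS", "MTASE")}
    if force_bhr:
        for name in ("TAT", "PAR", "PSI"):
            feature_flags[name] = True
    if feature_flags["TAT"]:
        toxin = _choose(rng, by_cat[Category.TOXIN])
        plan.append((Category.TOXIN, toxin))
        partner_entries = [
            e
            for e in by_cat.get(Category.ANTITOXIN, []) + by_cat.get(Category.RNA_ANTITOXIN, [])
            if e.family == toxin.cognate_partner
        ]
        partner = partner_entries[0]
        if partner.category is Category.RNA_ANTITOXIN:
            nt_plan.append((Category.RNA_ANTITOXIN, partner))
        else:
            plan.append((Category.ANTITOXIN, partner))
    for name, cat in (("PAR", Category.PAR), ("PSI", Category.PSI), ("MPS", Category.MPS), ("MTASE", Category.MTASE)):
        if feature_flags[name]:
            plan.append((cat, _choose(rng, by_cat[cat])))

    if rng.random() < config.arg_prob_per_class[cls]:
        args = list(by_cat[Category.ARG])
        first = _choose(rng, args)
        plan.append((Category.ARG, first))
        if rng.random() < 0.4:
            rest = [e for e in args if e.family != first.family]
            plan.append((Category.ARG, _choose(rng, rest)))
    if rng.random() < config.vf_prob:
        plan.append((Category.VF, _choose(rng, by_cat[Category.VF])))

    cassette_nt = sum(3 * len(e.sequence) + 9 for _, e in plan) + sum(
        len(e.sequence) for _, e in nt_plan
    )
    length = max(length, int(1.4 * cassette_nt))
    backbone = _random_dna(rng, length, config.gc_per_class[cls])

    occupied: list[tuple[int, int]] = []
    spans: list[tuple[Category, int, int, str]] = []
    planted: dict[Category, set[str]] = {}
    for cat, entry in plan:
        for attempt in range(4):
            try:
                backbone, (s, e, strand) = plant_cassette(
                    backbone, entry.sequence, config.cassette_divergence, rng, occupied
                )
                break
            except GenerationError:
                if attempt == 3:
                    raise
                backbone = backbone + _random_dna(
                    rng, max(2000, len(backbone) // 4), config.gc_per_class[cls]
                )
        spans.append((cat, s, e, strand))
        planted.setdefault(cat, set()).add(entry.family)
    for cat, entry in nt_plan:
        divergence = config.orit_divergence
        for attempt in range(4):
            try:
                backbone, (s, e, strand) = _plant_nucleotide(
                    backbone, entry.sequence, divergence, rng, occupied
                )
                break
            except GenerationError:
                if attempt == 3:
                    raise
                backbone = backbone + _random_dna(
                    rng, max(2000, len(backbone) // 4), config.gc_per_class[cls]
                )
        spans.append((cat, s, e, strand))
        planted.setdefault(cat, set()).add(entry.family)

    n_features = sum(feature_flags.values())
    record = PlasmidRecord(id=pid, sequence=backbone, source_isolate="synthetic")
    truth = TruthRecord(
        plasmid_id=pid,
        true_class=cls,
        planted_categories={c: frozenset(fams) for c, fams in planted.items()},
        true_bhr=n_features >= 3,
        true_cluster=0,
        planted_spans=sorted(spans, key=lambda t: t[1]),
    )
    return record, truth, occupied


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort with planted truth.

    The first ``n_clusters`` plasmids are cluster seeds: they are forced to
    be BHR candidates (so ANI dereplication of candidates sees every planted
    cluster) and receive ``cluster_size - 1`` near-identical copies appended
    after the independent plasmids.
    """
    panel = make_reference_panel(config.seed)
    classes = sorted(config.class_mix)
    probs = [config.class_mix[c] for c in classes]

    n_copies = config.n_clusters * (config.cluster_size - 1)
    n_base = config.n_plasmids - n_copies

    plasmids: list[PlasmidRecord] = []
    truths: list[TruthRecord] = []
    protected: list[list[tuple[int, int]]] = []
    for i in range(n_base):
        rng = np.random.default_rng([int(config.seed), 1, i])
        cls = str(rng.choice(classes, p=probs))
        is_seed = i < config.n_clusters
        record, truth, occ = _generate_plasmid(
            f"P{i + 1:03d}", cls, config, panel, rng, force_bhr=is_seed
        )
        if is_seed:
            truth.true_cluster = i + 1
        plasmids.append(record)
        truths.append(truth)
        protected.append(occ)

    idx = n_base
    for k in range(config.n_clusters):
        seed_plasmid, seed_truth = plasmids[k], truths[k]
        for c in range(config.cluster_size - 1):
            rng = np.random.default_rng([int(config.seed), 2, k, c])
            seq = mutate_nucleotides(
                seed_plasmid.sequence,
                config.within_cluster_subst,
                rng,
                protected=protected[k],
            )
            pid = f"P{idx + 1:03d}"
            plasmids.append(
                PlasmidRecord(id=pid, sequence=seq, source_isolate="synthetic")
            )
            truths.append(
                TruthRecord(
                    plasmid_id=pid,
                    true_class=seed_truth.true_class,
                    planted_categories=dict(seed_truth.planted_categories),
                    true_bhr=seed_truth.true_bhr,
                    true_cluster=k + 1,
                    planted_spans=list(seed_truth.planted_spans),
                )
            )
            idx += 1
    return Cohort(plasmids=plasmids, panel=panel, truth=truths)


def write_truth_tsv(path: str | Path, truths: Sequence[TruthRecord]) -> None:
    with open(path, "w") as handle:
        handle.write(
            "plasmid_id\ttrue_class\tplanted_categories\ttrue_bhr\ttrue_cluster\tspans\n"
        )
        for t in truths:
            cats = ";".join(
                f"{cat}:{fam}"
                for cat in sorted(t.planted_categories, key=lambda c: c.value)
                for fam in sorted(t.planted_categories[cat])
            )
            spans = ";".join(
                f"{cat}:{s}-{e}:{strand}" for cat, s, e, strand in t.planted_spans
            )
            handle.write(
                f"{t.plasmid_id}\t{t.true_class}\t{cats}\t{t.true_bhr}\t"
                f"{t.true_cluster}\t{spans}\n"
            )


def load_truth_tsv(path: str | Path) -> list[TruthRecord]:
    truths = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("plasmid_id\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in handle:
            pid, cls, cats, bhr, cluster, spans = line.rstrip("\n").split("\t")
            planted: dict[Category, set[str]] = {}
            if cats:
                for token in cats.split(";"):
                    cat, fam = token.split(":", 1)
                    planted.setdefault(Category(cat), set()).add(fam)
            span_list = []
            if spans:
                for token in spans.split(";"):
                    cat, span, strand = token.split(":")
                    s, e = span.split("-")
                    span_list.append((Category(cat), int(s), int(e), strand))
            truths.append(
                TruthRecord(
                    plasmid_id=pid,
                    true_class=cls,
                    planted_categories={c: frozenset(f) for c, f in planted.items()},
                    true_bhr=bhr == "True",
                    true_cluster=int(cluster),
                    planted_spans=span_list,
                )
            )
    return truths


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write cohort.fasta, per-category panel FASTAs and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cohort_path = outdir / "cohort.fasta"
    write_fasta(cohort_path, [(p.id, p.sequence) for p in cohort.plasmids])
    paths["cohort"] = cohort_path
    by_cat = _panel_families(cohort.panel)
    for category, entries in sorted(by_cat.items(), key=lambda kv: kv[0].value):
        panel_path = outdir / f"panel_{category.value.lower()}.fasta"
        write_fasta(
            panel_path,
            [(reference_fasta_header(e), e.sequence) for e in entries],
        )
        paths[f"panel_{category.value.lower()}"] = panel_path
    truth_path = outdir / "truth.tsv"
    write_truth_tsv(truth_path, cohort.truth)
    paths["truth"] = truth_path
    return paths
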