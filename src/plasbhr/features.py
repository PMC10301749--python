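"""Host-range feature profiles and broad-host-range candidate selection.

Five feature categories bear on how well a plasmid persists across diverse
hosts: complete toxin-antitoxin systems (post-segregational killing),
partitioning proteins (active segregation), plasmid SOS inhibition,
mating-pair stabilization, and solitary DNA methyltransferases (restriction
avoidance). A plasmid carrying at least 3 of the 5 is flagged as a
broad-host-range (BHR) candidate.

The toxin-antitoxin feature requires the complete cognate pair by default —
a lone toxin may simply be a secreted effector — with a lone-toxin mode
available. Antitoxin evidence may come from protein or RNA-antitoxin
(nucleotide) searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .homology import Hit
from .seqio import Category


@dataclass
class FeatureProfile:
    plasmid_id: str
    tat_system: bool
    par: bool
    psi: bool
    mps: bool
    mtase: bool
    n_features: int
    bhr_candidate: bool
    toxins_found: frozenset[str] = field(default_factory=frozenset)
    antitoxins_found: frozenset[str] = field(default_factory=frozenset)
    arg_families: frozenset[str] = field(default_factory=frozenset)
    vf_families: frozenset[str] = field(default_factory=frozenset)


def detect_tat(
    hits: Sequence[Hit],
    cognate_map: Mapping[str, str],
    pair_mode: bool = True,
) -> tuple[bool, frozenset[str], frozenset[str]]:
    """Detect a toxin-antitoxin system among one plasmid's hits.

    ``cognate_map`` maps toxin family -> cognate antitoxin family (built from
    the reference panel, e.g. ccdB -> ccdA). A complete system requires some
    toxin whose cognate antitoxin family is also hit (protein or RNA); with
    ``pair_mode=False`` a lone toxin suffices.
    """
    toxins = frozenset(h.family for h in hits if h.category is Category.TOXIN)
    antitoxins = frozenset(
        h.family
        for h in hits
        if h.category in (Category.ANTITOXIN, Category.RNA_ANTITOXIN)
    )
    if pair_mode:
        complete = any(cognate_map.get(t) in antitoxins for t in toxins)
    else:
        complete = bool(toxins)
    return complete, toxins, antitoxins


def build_profile(
    plasmid_id: str,
    hits: Sequence[Hit],
    cognate_map: Mapping[str, str],
    pair_mode: bool = True,
    min_features: int = 3,
) -> FeatureProfile:
    """Five-category feature profile and BHR flag for one plasmid."""
    ids = {h.plasmid_id for h in hits}
    if ids and ids != {plasmid_id}:
        raise ValueError(f"hits belong to {ids}, not {plasmid_id!r}")
    tat, toxins, antitoxins = detect_tat(hits, cognate_map, pair_mode=pair_mode)
    categories = {h.category for h in hits}
    par = Category.PAR in categories
    psi = Category.PSI in categories
    mps = Category.MPS in categories
    mtase = Category.MTASE in categories
    n_features = sum((tat, par, psi, mps, mtase))
    return FeatureProfile(
        plasmid_id=plasmid_id,
        tat_system=tat,
        par=par,
        psi=psi,
        mps=mps,
        mtase=mtase,
        n_features=n_features,
        bhr_candidate=n_features >= min_features,
        toxins_found=toxins,
        antitoxins_found=antitoxins,
        arg_families=frozenset(h.family for h in hits if h.category is Category.ARG),
        vf_families=frozenset(h.family for h in hits if h.category is Category.VF),
    )


def vf_free_subset(profiles: Iterable[FeatureProfile]) -> list[str]:
    """Sorted ids of BHR candidates carrying no known virulence factor."""
    return sorted(
        p.plasmid_id for p in profiles if p.bhr_candidate and not p.vf_families
    )


def write_features_tsv(
    path: str | Path,
    profiles: Sequence[FeatureProfile],
    arg_class_map: Mapping[str, str] | None = None,
) -> None:
    arg_class_map = arg_class_map or {}
    with open(path, "w") as handle:
        handle.write(
            "plasmid_id\ttat_system\tpar\tpsi\tmps\tmtase\tn_features\t"
            "bhr_candidate\ttoxins\tantitoxins\targs\targ_classes\tvfs\n"
        )
        for p in profiles:
            classes = sorted({arg_class_map[a] for a in p.arg_families if a in arg_class_map})
            handle.write(
                f"{p.plasmid_id}\t{p.tat_system}\t{p.par}\t{p.psi}\t{p.mps}\t"
                f"{p.mtase}\t{p.n_features}\t{p.bhr_candidate}\t"
                f"{','.join(sorted(p.toxins_found))}\t"
                f"{','.join(sorted(p.antitoxins_found))}\t"
                f"{','.join(sorted(p.arg_families))}\t{','.join(classes)}\t"
                f"{','.join(sorted(p.vf_families))}\n"
            )
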