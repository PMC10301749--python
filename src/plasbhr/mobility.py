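"""Rule-based plasmid mobility calls and MOB/MPF/Inc typing.

A plasmid is *conjugative* (self-transmissible) when it encodes both a
relaxase and the T4SS mating-pair-formation machinery; *mobilizable* when it
is not conjugative but carries an origin of transfer (and can therefore be
mobilized in trans); otherwise *non-mobilizable*. Because a relaxase alone
also suffices for mobilization in trans, a relaxed rule treating a lone
relaxase as mobilizable is available (``rule="relaxase_or_orit"``); the
default ``strict_paper`` rule requires the oriT itself.

T4SS evidence: the machinery is a multi-gene apparatus, so a single gene hit
is not accepted. The default rule requires a hit to a VirB4/TraC-class MPF
ATPase (reference families carrying the ``_ATPase`` suffix) plus at least 3
distinct T4SS reference genes overall. T4SS reference families follow the
``<MPFtype>_<gene>`` naming convention, e.g. ``MPFF_traC_ATPase``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .homology import Hit
from .seqio import Category

CONJUGATIVE = "conjugative"
MOBILIZABLE = "mobilizable"
NON_MOBILIZABLE = "non_mobilizable"
MOBILITY_CLASSES = (CONJUGATIVE, MOBILIZABLE, NON_MOBILIZABLE)

STRICT_PAPER = "strict_paper"
RELAXASE_OR_ORIT = "relaxase_or_orit"


@dataclass
class MobilityCall:
    plasmid_id: str
    mobility: str
    relaxase_present: bool
    t4ss_present: bool
    orit_present: bool
    mob_type: str | None = None
    mpf_type: str | None = None
    inc_types: frozenset[str] = field(default_factory=frozenset)


def mpf_type_of(family: str) -> str:
    """MPF type encoded as the prefix of a T4SS family name (``MPFF_traN``)."""
    return family.split("_")[0]


def is_mpf_atpase(family: str) -> bool:
    return family.endswith("_ATPase")


def t4ss_machinery_present(
    t4ss_hits: Sequence[Hit], min_genes: int = 3, require_atpase: bool = True
) -> bool:
    families = {h.family for h in t4ss_hits}
    if len(families) < min_genes:
        return False
    if require_atpase and not any(is_mpf_atpase(f) for f in families):
        return False
    return True


def assign_types(
    hits: Sequence[Hit],
) -> tuple[str | None, str | None, frozenset[str]]:
    """(mob_type, mpf_type, inc_types) from one plasmid's hits.

    MOB type is the family of the highest-bitscore relaxase hit (ties broken
    lexicographically); MPF type is the type with the most distinct T4SS gene
    hits (ties by highest single bitscore, then lexicographically); Inc types
    are the families of all Rep hits — multi-replicon plasmids keep them all.
    """
    relaxase = [h for h in hits if h.category is Category.RELAXASE]
    mob_type = None
    if relaxase:
        mob_type = min(relaxase, key=lambda h: (-h.bitscore, h.family)).family

    t4ss = [h for h in hits if h.category is Category.T4SS]
    mpf_type = None
    if t4ss:
        per_type: dict[str, tuple[set[str], float]] = {}
        for h in t4ss:
            genes, best = per_type.get(mpf_type_of(h.family), (set(), float("-inf")))
            genes.add(h.family)
            per_type[mpf_type_of(h.family)] = (genes, max(best, h.bitscore))
        mpf_type = min(
            per_type, key=lambda t: (-len(per_type[t][0]), -per_type[t][1], t)
        )

    inc_types = frozenset(h.family for h in hits if h.category is Category.REP)
    return mob_type, mpf_type, inc_types


def call_mobility(
    hits: Sequence[Hit],
    plasmid_id: str | None = None,
    rule: str = STRICT_PAPER,
    t4ss_min_genes: int = 3,
    t4ss_require_atpase: bool = True,
) -> MobilityCall:
    """Classify one plasmid from its filtered hits.

    ``plasmid_id`` is only needed for hit-less plasmids; otherwise it is taken
    from the hits (which must all share one plasmid).
    """
    ids = {h.plasmid_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"call_mobility got hits from multiple plasmids: {ids}")
    if ids:
        pid = ids.pop()
        if plasmid_id is not None and plasmid_id != pid:
            raise ValueError(f"hits belong to {pid!r}, not {plasmid_id!r}")
        plasmid_id = pid
    elif plasmid_id is None:
        raise ValueError("plasmid_id required when there are no hits")
    if rule not in (STRICT_PAPER, RELAXASE_OR_ORIT):
        raise ValueError(f"unknown mobilizable rule {rule!r}")

    relaxase_present = any(h.category is Category.RELAXASE for h in hits)
    orit_present = any(h.category is Category.ORIT for h in hits)
    t4ss_present = t4ss_machinery_present(
        [h for h in hits if h.category is Category.T4SS],
        min_genes=t4ss_min_genes,
        require_atpase=t4ss_require_atpase,
    )

    if relaxase_present and t4ss_present:
        mobility = CONJUGATIVE
    elif orit_present or (rule == RELAXASE_OR_ORIT and relaxase_present):
        mobility = MOBILIZABLE
    else:
        mobility = NON_MOBILIZABLE

    mob_type, mpf_type, inc_types = assign_types(hits)
    return MobilityCall(
        plasmid_id=plasmid_id,
        mobility=mobility,
        relaxase_present=relaxase_present,
        t4ss_present=t4ss_present,
        orit_present=orit_present,
        mob_type=mob_type,
        mpf_type=mpf_type,
        inc_types=inc_types,
    )


def write_mobility_tsv(path: str | Path, calls: Iterable[MobilityCall]) -> None:
    with open(path, "w") as handle:
        handle.write(
            "plasmid_id\tmobility\tmob_type\tmpf_type\tinc_types\t"
            "relaxase_present\tt4ss_present\torit_present\n"
        )
        for c in calls:
            handle.write(
                f"{c.plasmid_id}\t{c.mobility}\t{c.mob_type or ''}\t"
                f"{c.mpf_type or ''}\t{','.join(sorted(c.inc_types))}\t"
                f"{c.relaxase_present}\t{c.t4ss_present}\t{c.orit_present}\n"
            )
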