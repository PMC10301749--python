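"""Fragment-based average nucleotide identity and threshold clustering.

ANIb-style procedure: the query is cut into consecutive non-overlapping
1 kb fragments, each locally aligned to the subject (both strands, BLAST-like
nucleotide scoring); fragments whose best alignment covers >= 70% of the
fragment at >= 30% identity count as aligned, and ANI is the mean alignment
identity (percent) over aligned fragments. The value is symmetrized as the
mean of the two directed ANIs. No fragment aligning leaves the pair's ANI
undefined (NaN), which never links plasmids during clustering.

Unrelated sequence pairs are expensive to reject fragment by fragment, so a
prescreen estimates identity from the edit distance of a few probe fragments
(both strands) and skips the pair when even the best probe falls far below
the clustering regime; the full per-fragment alignment is only run for pairs
that could plausibly exceed ~80% ANI. ``prescreen=False`` disables this.

Clustering at a threshold (conventionally 95%) uses single-linkage connected
components; complete linkage is available as a knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx
import numpy as np

from .homology import align_local
from .seqio import PlasmidRecord, reverse_complement

#: fragment is "aligned" when alignment covers >= this fraction of it ...
FRAGMENT_MIN_COVER = 0.7
#: ... at >= this identity (ANIb gates)
FRAGMENT_MIN_IDENTITY = 0.3
#: prescreen identity estimate below which a pair is declared unrelated
PRESCREEN_MIN_IDENTITY = 0.7
_PRESCREEN_PROBES = 3


class AniError(ValueError):
    pass


@dataclass(frozen=True)
class AniResult:
    """Symmetrized ANI for one pair; ``ani`` is NaN when undefined.

    ``aligned_fraction`` is the fraction of a's fragments that aligned to b.
    """

    id_a: str
    id_b: str
    ani: float
    aligned_fraction: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ani)


def _fragments(sequence: str, fragment_nt: int) -> list[str]:
    n_whole = len(sequence) // fragment_nt
    return [
        sequence[i * fragment_nt : (i + 1) * fragment_nt] for i in range(n_whole)
    ]


def _prescreen_identity(frags: Sequence[str], subject: str) -> float:
    """Upper-ish identity estimate from edit distance of probe fragments."""
    best = 0.0
    rc = reverse_complement(subject)
    for frag in frags[:_PRESCREEN_PROBES]:
        for tgt in (subject, rc):
            res = edlib.align(frag, tgt, mode="HW", task="distance")
            d = res["editDistance"]
            if d >= 0:
                best = max(best, 1.0 - d / len(frag))
    return best


def _directed_ani(
    query: str, subject: str, fragment_nt: int, prescreen: bool
) -> tuple[float, float]:
    """(mean identity % over aligned fragments or NaN, aligned fraction)."""
    frags = _fragments(query, fragment_nt)
    if prescreen and _prescreen_identity(frags, subject) < PRESCREEN_MIN_IDENTITY:
        return float("nan"), 0.0
    identities = []
    for frag in frags:
        aln = align_local(frag, subject, "nucleotide")
        if aln is None:
            continue
        frag_cover = (aln.ref_span[1] - aln.ref_span[0]) / len(frag)
        if frag_cover >= FRAGMENT_MIN_COVER and aln.identity >= FRAGMENT_MIN_IDENTITY:
            identities.append(aln.identity)
    if not identities:
        return float("nan"), 0.0
    return 100.0 * float(np.mean(identities)), len(identities) / len(frags)


def pairwise_ani(
    a: PlasmidRecord,
    b: PlasmidRecord,
    fragment_nt: int = 1000,
    prescreen: bool = True,
) -> AniResult:
    """Symmetrized fragment-based ANI between two plasmids."""
    for rec in (a, b):
        if rec.length < fragment_nt:
            raise AniError(
                f"plasmid {rec.id!r} ({rec.length} nt) is shorter than the "
                f"fragment size {fragment_nt}; lower fragment_nt"
            )
    ani_ab, frac_ab = _directed_ani(a.sequence, b.sequence, fragment_nt, prescreen)
    ani_ba, _ = _directed_ani(b.sequence, a.sequence, fragment_nt, prescreen)
    if math.isnan(ani_ab):
        ani = ani_ba
    elif math.isnan(ani_ba):
        ani = ani_ab
    else:
        ani = (ani_ab + ani_ba) / 2.0
    return AniResult(id_a=a.id, id_b=b.id, ani=ani, aligned_fraction=frac_ab)


def all_pairs_ani(
    plasmids: Sequence[PlasmidRecord],
    fragment_nt: int = 1000,
    prescreen: bool = True,
) -> list[AniResult]:
    results = []
    for i, a in enumerate(plasmids):
        for b in plasmids[i + 1 :]:
            results.append(pairwise_ani(a, b, fragment_nt, prescreen))
    return results


@dataclass
class ClusterAssignment:
    """Partition of plasmids into ANI clusters (1-based, ordered by the
    lexicographically smallest member id)."""

    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, cid in self.assignment.items():
            out.setdefault(cid, []).append(pid)
        return {cid: sorted(ids) for cid, ids in out.items()}


def cluster_at_threshold(
    results: Iterable[AniResult],
    threshold_pct: float = 95.0,
    ids: Iterable[str] | None = None,
    linkage: str = "single",
) -> ClusterAssignment:
    """Cluster plasmids whose ANI reaches the threshold.

    Single linkage (default) takes connected components of the graph with an
    edge wherever ``ani >= threshold_pct``; undefined ANIs never link.
    Complete linkage greedily merges only when every cross pair reaches the
    threshold. Missing pairs are treated as below threshold.
    """
    results = list(results)
    graph = nx.Graph()
    for pid in ids or ():
        graph.add_node(pid)
    for r in results:
        graph.add_node(r.id_a)
        graph.add_node(r.id_b)
        if r.defined and r.ani >= threshold_pct:
            graph.add_edge(r.id_a, r.id_b)

    if linkage == "single":
        components = [sorted(c) for c in nx.connected_components(graph)]
    elif linkage == "complete":
        components = _complete_linkage(graph.nodes, results, threshold_pct)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    components.sort(key=lambda c: c[0])
    assignment = {
        pid: cid for cid, comp in enumerate(components, start=1) for pid in comp
    }
    return ClusterAssignment(assignment=assignment)


def _complete_linkage(nodes, results: Sequence[AniResult], threshold_pct: float):
    ani: dict[frozenset[str], float] = {}
    for r in results:
        if r.defined:
            ani[frozenset((r.id_a, r.id_b))] = r.ani
    clusters = [[n] for n in sorted(nodes)]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if all(
                    ani.get(frozenset((x, y)), float("-inf")) >= threshold_pct
                    for x in clusters[i]
                    for y in clusters[j]
                ):
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return clusters


def write_ani_tsv(path: str | Path, results: Sequence[AniResult]) -> None:
    with open(path, "w") as handle:
        handle.write("id_a\tid_b\tani\taligned_fraction\n")
        for r in results:
            ani = f"{r.ani:.4f}" if r.defined else "NA"
            handle.write(f"{r.id_a}\t{r.id_b}\t{ani}\t{r.aligned_fraction:.4f}\n")


def write_clusters_tsv(path: str | Path, clusters: ClusterAssignment) -> None:
    sizes: dict[int, int] = {}
    for cid in clusters.assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    with open(path, "w") as handle:
        handle.write("plasmid_id\tcluster_id\tcluster_size\n")
        for pid in sorted(clusters.assignment):
            cid = clusters.assignment[pid]
            handle.write(f"{pid}\t{cid}\t{sizes[cid]}\n")
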