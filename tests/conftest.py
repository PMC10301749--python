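"""Shared fixtures: reference panels, small synthetic cohorts, hit factories."""

from __future__ import annotations

import numpy as np
import pytest

from plasbhr import homology, orfs, seqio, simulate
from plasbhr.homology import Hit
from plasbhr.seqio import Category


@pytest.fixture(scope="session")
def panel():
    return simulate.make_reference_panel(7)


@pytest.fixture(scope="session")
def small_cohort():
    """12-plasmid cohort with two planted clusters of two, 5% divergence."""
    config = simulate.SimConfig(seed=3, n_plasmids=12, n_clusters=2, cluster_size=2)
    return simulate.simulate_cohort(config)


def characterize_hits(cohort) -> dict[str, list[Hit]]:
    """Run ORF calling + all homology searches; hits grouped by plasmid."""
    all_orfs = []
    for p in cohort.plasmids:
        all_orfs.extend(orfs.find_orfs(p))
    by_cat: dict[Category, list] = {}
    for r in cohort.panel:
        by_cat.setdefault(r.category, []).append(r)
    hits: list[Hit] = []
    for category in sorted(by_cat, key=lambda c: c.value):
        targets = (
            cohort.plasmids
            if category in seqio.NUCLEOTIDE_CATEGORIES
            else all_orfs
        )
        hits.extend(homology.search_category(by_cat[category], targets))
    return homology.group_hits_by_plasmid(hits)


@pytest.fixture(scope="session")
def small_cohort_hits(small_cohort):
    return characterize_hits(small_cohort)


def make_hit(
    category: Category,
    family: str,
    plasmid_id: str = "p1",
    bitscore: float = 100.0,
    identity: float = 0.95,
    ref_id: str | None = None,
    target_id: str = "p1_1",
) -> Hit:
    """Synthetic passing hit for rule-level tests."""
    return Hit(
        ref_id=ref_id or f"{family}_ref",
        target_id=target_id,
        raw_score=200,
        bitscore=bitscore,
        evalue=1e-30,
        identity=identity,
        ref_cover=0.95,
        ref_span=(0, 100),
        target_span=(0, 100),
        strand="n/a",
        category=category,
        family=family,
        plasmid_id=plasmid_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
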