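"""Kruskal-Wallis / Dunn against hand-computed and permutation oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_hit
from plasbhr.features import build_profile
from plasbhr.mobility import MobilityCall
from plasbhr.seqio import Category, PlasmidRecord
from plasbhr.simulate import _random_dna
from plasbhr.stats import (
    dunn_posthoc,
    kruskal_dunn,
    kruskal_wallis,
    mobile_fraction_pct,
    summarize_cohort,
)


def _oracle_h(groups):
    """Tie-corrected H, written from the textbook formula (midranks by hand)."""
    pooled = sorted(x for g in groups for x in g)
    n = len(pooled)
    rank_of = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        rank_of[pooled[i]] = (i + 1 + j) / 2.0
        i = j
    h = sum(
        len(g) * (sum(rank_of[x] for x in g) / len(g)) ** 2 for g in groups
    )
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction else 0.0


class TestKruskalWallis:
    def test_identical_groups_are_null(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_data_degenerates_to_null(self):
        assert kruskal_wallis([[1, 1, 1], [1, 1]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            kruskal_wallis([[1.0], []])

    def test_matches_independent_rank_sum_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [
                list(rng.integers(0, 8, size=int(rng.integers(3, 10))))
                for _ in range(k)
            ]
            h, p = kruskal_wallis(groups)
            expected_h = _oracle_h(groups)
            assert h == pytest.approx(expected_h, rel=1e-10, abs=1e-10)
            assert p == pytest.approx(float(sps.chi2.sf(expected_h, k - 1)))

    def test_hand_worked_tie_corrected_example(self):
        # 9 observations, ties at 2, 3 and 5: H = 5.9556 / (1 - 18/720)
        h, p = kruskal_wallis([[1, 2, 3], [2, 3, 4], [5, 5, 6]])
        assert h == pytest.approx(6.108262108262101, rel=1e-12)
        assert p == pytest.approx(0.04716368565943292, rel=1e-9)

    def test_permutation_p_matches_exact_enumeration(self):
        # [1,2,3] vs [4,5,6]: 2 of the C(6,3)=20 assignments reach H_obs
        _, p_perm = kruskal_wallis(
            [[1, 2, 3], [4, 5, 6]], permutation=20000, seed=5
        )
        assert p_perm == pytest.approx(0.1, abs=0.01)

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = [list(rng.normal(size=8)) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[math.exp(x) for x in g] for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestDunnPosthoc:
    def test_identical_groups_give_zero_z(self):
        ((_, _, z, p_adj),) = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p_adj == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # g1=[1,2,3,4], g2=[3,5,6,8], g3=[9,10,11,12]; tie at 3; Bonferroni x3
        groups = [[1, 2, 3, 4], [3, 5, 6, 8], [9, 10, 11, 12]]
        res = dunn_posthoc(groups, labels=["g1", "g2", "g3"])
        expected = {
            ("g1", "g2"): (-1.276989332134754, 0.604818040614503),
            ("g1", "g3"): (-2.9960134330853845, 0.008206031509608606),
            ("g2", "g3"): (-1.7190241009506304, 0.2568299506555814),
        }
        for gi, gj, z, p_adj in res:
            ez, ep = expected[(gi, gj)]
            assert z == pytest.approx(ez, rel=1e-10)
            assert p_adj == pytest.approx(ep, rel=1e-9)

    def test_far_shifted_group_has_smallest_adjusted_p(self, rng):
        groups = [
            list(rng.normal(0, 1, 10)),
            list(rng.normal(0, 1, 10)),
            list(rng.normal(30, 1, 10)),
        ]
        res = dunn_posthoc(groups, labels=["a", "b", "c"])
        by_pair = {(gi, gj): p for gi, gj, _, p in res}
        assert by_pair[("a", "c")] < by_pair[("a", "b")]
        assert by_pair[("b", "c")] < by_pair[("a", "b")]

    def test_adjusted_p_not_below_raw(self, rng):
        groups = [list(rng.normal(size=7)) for _ in range(4)]
        for _, _, z, p_adj in dunn_posthoc(groups):
            raw = 2 * sps.norm.sf(abs(z))
            assert p_adj >= raw - 1e-15

    def test_holm_not_more_conservative_than_bonferroni(self, rng):
        groups = [list(rng.normal(loc, 1, 8)) for loc in (0, 0.5, 2)]
        bonf = {(a, b): p for a, b, _, p in dunn_posthoc(groups, adjust="bonferroni")}
        holm = {(a, b): p for a, b, _, p in dunn_posthoc(groups, adjust="holm")}
        assert all(holm[k] <= bonf[k] + 1e-15 for k in bonf)


class TestSummarize:
    def test_reported_mobile_fraction_one_decimal(self):
        assert mobile_fraction_pct(68, 77) == 88.3

    @staticmethod
    def _toy_cohort(rng, n_per_class=10, shift=30000):
        plasmids, calls, profiles = [], [], []
        for ci, mobility in enumerate(["conjugative", "non_mobilizable"]):
            for i in range(n_per_class):
                pid = f"{mobility[:4]}{i}"
                length = 5000 + ci * shift + int(rng.integers(0, 2000))
                plasmids.append(PlasmidRecord(id=pid, sequence=_random_dna(rng, length)))
                calls.append(
                    MobilityCall(
                        plasmid_id=pid, mobility=mobility,
                        relaxase_present=False, t4ss_present=False, orit_present=False,
                    )
                )
                hits = [make_hit(Category.ARG, "TEM-1", plasmid_id=pid)] if ci == 0 else []
                profiles.append(build_profile(pid, hits, {}))
        return profiles, calls, plasmids

    def test_separated_lengths_detected_by_dunn(self, rng):
        profiles, calls, plasmids = self._toy_cohort(rng)
        summary = summarize_cohort(profiles, calls, plasmids)
        tests = summary["tests"]
        assert tests["length_nt"].kw_p < 0.05
        (pair,) = tests["length_nt"].pairwise
        assert pair[3] < 0.05  # conj vs non-mob lengths differ
        arg = summary["arg_table"]
        assert arg.loc[0, "arg_family"] == "TEM-1"
        assert arg.loc[0, "mobile_fraction_pct"] == 100.0

    def test_single_class_cohort_skips_comparisons(self, rng):
        profiles, calls, plasmids = self._toy_cohort(rng, n_per_class=4)
        keep = [c.plasmid_id for c in calls if c.mobility == "conjugative"]
        summary = summarize_cohort(
            [p for p in profiles if p.plasmid_id in keep],
            [c for c in calls if c.plasmid_id in keep],
            [p for p in plasmids if p.id in keep],
        )
        assert summary["tests"] == {}
        assert summary["notices"]
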