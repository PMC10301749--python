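"""Nonparametric cohort comparisons and summary tables.

Group differences in plasmid length, GC content and ARG presence across the
three mobility classes are assessed with the Kruskal-Wallis rank test
(tie-corrected H, chi-square approximation with k-1 df) followed by Dunn's
multiple-comparison z tests. Dunn's p-values are Bonferroni-adjusted over the
k(k-1)/2 pairs by default (classical Dunn 1964); Holm is available. ARG
presence is encoded 0/1 and run through the same rank machinery.

An exact Monte-Carlo permutation p-value for the Kruskal-Wallis test is
available behind a flag for small samples where the chi-square approximation
is questionable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FeatureProfile
from .mobility import MOBILITY_CLASSES, MobilityCall
from .seqio import PlasmidRecord


@dataclass
class KruskalDunnResult:
    h_statistic: float
    kw_p: float
    pairwise: list[tuple[str, str, float, float]]  # (group_i, group_j, z, p_adj)
    n_per_group: dict[str, int]


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} has no observations")
    return arrays


def _h_statistic(arrays: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (used by the permutation mode)."""
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        r_mean = ranks[start : start + g.size].mean()
        h += g.size * r_mean**2
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0.0:  # all observations identical
        return 0.0
    return h / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    permutation: int | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis H and p across groups.

    With ``permutation=N`` the p-value is the Monte-Carlo fraction of N
    label permutations with H at least as large as observed (add-one
    estimator); otherwise the chi-square approximation is used.
    """
    arrays = _validate_groups(groups)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # exchangeable by construction; no evidence
    h, p = sps.kruskal(*arrays)
    if permutation:
        sizes = [g.size for g in arrays]
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutation):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            if _h_statistic(parts) >= h - 1e-12:
                count += 1
        p = (count + 1) / (permutation + 1)
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> list[tuple[str, str, float, float]]:
    """Dunn's pairwise z tests on pooled midranks.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with the tie term ``T = sum(t^3 - t)``; two-sided normal p-values adjusted
    over all k(k-1)/2 comparisons.
    """
    arrays = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels must match groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    means = []
    start = 0
    for g in arrays:
        means.append(ranks[start : start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_core = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    pairs = []
    raw_p = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            denom = math.sqrt(
                variance_core * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            )
            z = 0.0 if denom == 0 else (means[i] - means[j]) / denom
            pairs.append((labels[i], labels[j], z))
            raw_p.append(2.0 * sps.norm.sf(abs(z)))
    if not raw_p:
        return []
    method = {"bonferroni": "bonferroni", "holm": "holm"}[adjust]
    adj = multipletests(raw_p, method=method)[1]
    return [
        (gi, gj, float(z), float(p_adj))
        for (gi, gj, z), p_adj in zip(pairs, adj)
    ]


def kruskal_dunn(
    values_by_group: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
    permutation: int | None = None,
    seed: int | None = None,
) -> KruskalDunnResult:
    labels = list(values_by_group)
    groups = [values_by_group[k] for k in labels]
    h, p = kruskal_wallis(groups, permutation=permutation, seed=seed)
    pairwise = dunn_posthoc(groups, labels=labels, adjust=adjust)
    return KruskalDunnResult(
        h_statistic=h,
        kw_p=p,
        pairwise=pairwise,
        n_per_group={k: len(values_by_group[k]) for k in labels},
    )


def mobile_fraction_pct(n_mobile: int, n_total: int) -> float:
    """Percent of carriers that are conjugative or mobilizable, 1 decimal.

    E.g. 68 mobile carriers out of 77 -> 88.3.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_mobile / n_total, 1)


def summarize_cohort(
    profiles: Sequence[FeatureProfile],
    calls: Sequence[MobilityCall],
    plasmids: Sequence[PlasmidRecord],
    arg_class_map: Mapping[str, str] | None = None,
    adjust: str = "bonferroni",
) -> dict:
    """Cohort summary tables and group tests.

    Returns a dict with a per-plasmid table, mobility-class distributions of
    length/GC/ARG presence with Kruskal-Wallis + Dunn results, per-ARG and
    per-antibiotic-class occurrence counts (with the fraction of carriers
    that are mobile), and Inc/MOB/MPF frequency tables. Comparisons are
    skipped (with a notice) when fewer than two mobility classes are present.
    """
    arg_class_map = arg_class_map or {}
    by_id_call = {c.plasmid_id: c for c in calls}
    by_id_prof = {p.plasmid_id: p for p in profiles}
    rows = []
    for p in plasmids:
        call = by_id_call.get(p.id)
        prof = by_id_prof.get(p.id)
        if call is None or prof is None:
            raise ValueError(f"plasmid {p.id!r} missing a mobility call or profile")
        rows.append(
            {
                "plasmid_id": p.id,
                "mobility": call.mobility,
                "length_nt": p.length,
                "gc_content": p.gc_content,
                "arg_present": int(bool(prof.arg_families)),
                "n_features": prof.n_features,
                "bhr_candidate": prof.bhr_candidate,
            }
        )
    table = pd.DataFrame(rows)

    notices: list[str] = []
    tests: dict[str, KruskalDunnResult] = {}
    present = [m for m in MOBILITY_CLASSES if (table["mobility"] == m).any()]
    if len(present) < 2:
        notices.append(
            "fewer than two mobility classes present; group comparisons skipped"
        )
    else:
        for metric in ("length_nt", "gc_content", "arg_present"):
            groups = {
                m: table.loc[table["mobility"] == m, metric].to_numpy()
                for m in present
            }
            tests[metric] = kruskal_dunn(groups, adjust=adjust)

    arg_rows = []
    for family in sorted({a for p in profiles for a in p.arg_families}):
        carriers = [p.plasmid_id for p in profiles if family in p.arg_families]
        mobile = [
            pid
            for pid in carriers
            if by_id_call[pid].mobility in ("conjugative", "mobilizable")
        ]
        arg_rows.append(
            {
                "arg_family": family,
                "antibiotic_class": arg_class_map.get(family, ""),
                "n_occurrences": len(carriers),
                "n_mobile_carriers": len(mobile),
                "mobile_fraction_pct": mobile_fraction_pct(len(mobile), len(carriers)),
            }
        )
    arg_table = pd.DataFrame(
        arg_rows,
        columns=[
            "arg_family",
            "antibiotic_class",
            "n_occurrences",
            "n_mobile_carriers",
            "mobile_fraction_pct",
        ],
    )
    class_counts = (
        arg_table.groupby("antibiotic_class")["n_occurrences"].sum().to_dict()
        if not arg_table.empty
        else {}
    )

    inc_counts: dict[str, int] = {}
    mob_counts: dict[str, int] = {}
    mpf_counts: dict[str, int] = {}
    for c in calls:
        for inc in c.inc_types:
            inc_counts[inc] = inc_counts.get(inc, 0) + 1
        if c.mob_type:
            mob_counts[c.mob_type] = mob_counts.get(c.mob_type, 0) + 1
        if c.mpf_type:
            mpf_counts[c.mpf_type] = mpf_counts.get(c.mpf_type, 0) + 1

    return {
        "table": table,
        "tests": tests,
        "arg_table": arg_table,
        "arg_class_counts": class_counts,
        "inc_type_counts": inc_counts,
        "mob_type_counts": mob_counts,
        "mpf_type_counts": mpf_counts,
        "notices": notices,
    }


def _sig(x: float, digits: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{digits}g}")


def write_stats_json(path: str | Path, summary: dict) -> None:
    """Machine-readable test results, floats at 6 significant digits."""
    payload: dict = {
        "notices": summary["notices"],
        "inc_type_counts": summary["inc_type_counts"],
        "mob_type_counts": summary["mob_type_counts"],
        "mpf_type_counts": summary["mpf_type_counts"],
        "arg_class_counts": summary["arg_class_counts"],
        "tests": {},
    }
    for metric, res in summary["tests"].items():
        payload["tests"][metric] = {
            "h_statistic": _sig(res.h_statistic),
            "kw_p": _sig(res.kw_p),
            "n_per_group": res.n_per_group,
            "pairwise": [
                {"group_i": gi, "group_j": gj, "z": _sig(z), "p_adjusted": _sig(p)}
                for gi, gj, z, p in res.pairwise
            ],
        }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_summary_tsv(path: str | Path, summary: dict) -> None:
    table: pd.DataFrame = summary["table"]
    per_class = table.groupby("mobility").agg(
        n=("plasmid_id", "size"),
        median_length_nt=("length_nt", "median"),
        mean_gc=("gc_content", "mean"),
        arg_presence_rate=("arg_present", "mean"),
        n_bhr_candidates=("bhr_candidate", "sum"),
    )
    per_class.to_csv(path, sep="\t", float_format="%.6g")
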