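"""End-to-end plasmid characterization: FASTA in, profile tables out.

Composes the module chain: sequence loading -> ORF calling -> per-category
homology search -> mobility typing -> host-range feature scoring ->
(optionally) ANI dereplication of broad-host-range candidates -> cohort
statistics. Every output is re-derivable from the inputs and the run
configuration alone; a manifest records the configuration and a checksum of
each written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import ani as ani_mod
from . import features as feat_mod
from . import homology, mobility, orfs, seqio, simulate, stats

logger = logging.getLogger("plasbhr")

PANEL_PREFIX = "panel_"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run-wide settings for :func:`run_characterize`.

    ``reference_paths`` maps category names to FASTA paths; alternatively
    ``refs_dir`` is scanned for ``panel_<category>.fasta`` files. Threshold
    overrides are merged over the per-category defaults.
    """

    plasmids: str = ""
    refs_dir: str | None = None
    reference_paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "plasbhr_out"
    thresholds: dict[str, dict] = field(default_factory=dict)
    min_orf_nt: int = 90
    topology: str = "linear"
    ani_fragment_nt: int = 1000
    ani_threshold_pct: float = 95.0
    ani_linkage: str = "single"
    run_ani: bool = True
    bhr_min_features: int = 3
    mobilizable_rule: str = mobility.STRICT_PAPER
    tat_pair_mode: bool = True
    t4ss_min_genes: int = 3
    t4ss_require_atpase: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolve_reference_paths(self) -> dict[seqio.Category, Path]:
        paths: dict[seqio.Category, Path] = {}
        for key, value in self.reference_paths.items():
            paths[seqio.Category(key.upper())] = Path(value)
        if self.refs_dir:
            for fasta in sorted(Path(self.refs_dir).glob(f"{PANEL_PREFIX}*.fasta")):
                name = fasta.stem[len(PANEL_PREFIX):].upper()
                try:
                    category = seqio.Category(name)
                except ValueError:
                    logger.warning("ignoring unrecognized panel file %s", fasta)
                    continue
                paths.setdefault(category, fasta)
        if not paths:
            raise ConfigError("no reference panels given (refs_dir/reference_paths)")
        return paths

    def validate(self) -> None:
        if not self.plasmids or not Path(self.plasmids).exists():
            raise ConfigError(f"plasmid FASTA not found: {self.plasmids!r}")
        for category, path in self.resolve_reference_paths().items():
            if not path.exists():
                raise ConfigError(f"reference FASTA for {category} not found: {path}")
        if self.topology not in ("linear", "circular"):
            raise ConfigError(f"topology must be linear|circular, got {self.topology!r}")
        if self.mobilizable_rule not in (mobility.STRICT_PAPER, mobility.RELAXASE_OR_ORIT):
            raise ConfigError(f"unknown mobilizable_rule {self.mobilizable_rule!r}")
        if self.ani_linkage not in ("single", "complete"):
            raise ConfigError(f"unknown ani_linkage {self.ani_linkage!r}")

    def effective_thresholds(self) -> dict[seqio.Category, homology.HitThresholds]:
        table = dict(homology.DEFAULT_THRESHOLDS)
        for key, values in self.thresholds.items():
            category = seqio.Category(key.upper())
            base = table[category]
            table[category] = homology.HitThresholds(
                max_evalue=values.get("max_evalue", base.max_evalue),
                min_identity=values.get("min_identity", base.min_identity),
                min_ref_cover=values.get("min_ref_cover", base.min_ref_cover),
            )
        return table


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_profile_tsv(
    path: Path,
    calls: list[mobility.MobilityCall],
    profiles: list[feat_mod.FeatureProfile],
    clusters: ani_mod.ClusterAssignment | None,
) -> None:
    by_prof = {p.plasmid_id: p for p in profiles}
    sizes: dict[int, int] = {}
    if clusters:
        for cid in clusters.assignment.values():
            sizes[cid] = sizes.get(cid, 0) + 1
    with open(path, "w") as handle:
        handle.write(
            "plasmid_id\tmobility\tmob_type\tmpf_type\tinc_types\t"
            "relaxase_present\tt4ss_present\torit_present\t"
            "tat_system\tpar\tpsi\tmps\tmtase\tn_features\tbhr_candidate\t"
            "args\tvfs\tcluster_id\tcluster_size\n"
        )
        for c in sorted(calls, key=lambda c: c.plasmid_id):
            p = by_prof[c.plasmid_id]
            cid = clusters.assignment.get(c.plasmid_id) if clusters else None
            handle.write(
                f"{c.plasmid_id}\t{c.mobility}\t{c.mob_type or ''}\t"
                f"{c.mpf_type or ''}\t{','.join(sorted(c.inc_types))}\t"
                f"{c.relaxase_present}\t{c.t4ss_present}\t{c.orit_present}\t"
                f"{p.tat_system}\t{p.par}\t{p.psi}\t{p.mps}\t{p.mtase}\t"
                f"{p.n_features}\t{p.bhr_candidate}\t"
                f"{','.join(sorted(p.arg_families))}\t"
                f"{','.join(sorted(p.vf_families))}\t"
                f"{cid if cid is not None else ''}\t"
                f"{sizes.get(cid, '') if cid is not None else ''}\n"
            )


def run_characterize(config: RunConfig) -> dict:
    """Run the full characterization; returns all in-memory results.

    Writes plasmids.tsv, orfs.gff3, orfs.faa, hits.tsv, mobility.tsv,
    features.tsv, ani.tsv + clusters.tsv (when the ANI step runs),
    profile.tsv, stats.json, summary.tsv and manifest.json to ``out_dir``.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    plasmid_seqs = seqio.read_fasta(config.plasmids, "nucleotide")
    plasmids = [
        seqio.PlasmidRecord(id=pid, sequence=seq, topology=config.topology)
        for pid, seq in plasmid_seqs
    ]
    logger.info("loaded %d plasmids", len(plasmids))

    refs = seqio.load_reference_sets(config.resolve_reference_paths())
    by_cat: dict[seqio.Category, list[seqio.ReferenceEntry]] = {}
    for r in refs:
        by_cat.setdefault(r.category, []).append(r)

    all_orfs: list[orfs.OrfRecord] = []
    for p in plasmids:
        all_orfs.extend(orfs.find_orfs(p, min_length_nt=config.min_orf_nt))
    logger.info("called %d ORFs", len(all_orfs))

    thresholds = config.effective_thresholds()
    hits: list[homology.Hit] = []
    for category in sorted(by_cat, key=lambda c: c.value):
        cat_refs = by_cat[category]
        targets = (
            plasmids if category in seqio.NUCLEOTIDE_CATEGORIES else all_orfs
        )
        cat_hits = homology.search_category(
            cat_refs, targets, thresholds=thresholds[category]
        )
        logger.info("%s: %d hits", category, len(cat_hits))
        hits.extend(cat_hits)

    grouped = homology.group_hits_by_plasmid(hits)
    cognate_map = seqio.build_cognate_map(refs)
    arg_class_map = seqio.build_arg_class_map(refs)
    calls = []
    profiles = []
    for p in plasmids:
        p_hits = grouped.get(p.id, [])
        calls.append(
            mobility.call_mobility(
                p_hits,
                plasmid_id=p.id,
                rule=config.mobilizable_rule,
                t4ss_min_genes=config.t4ss_min_genes,
                t4ss_require_atpase=config.t4ss_require_atpase,
            )
        )
        profiles.append(
            feat_mod.build_profile(
                p.id,
                p_hits,
                cognate_map,
                pair_mode=config.tat_pair_mode,
                min_features=config.bhr_min_features,
            )
        )

    ani_results: list[ani_mod.AniResult] = []
    clusters: ani_mod.ClusterAssignment | None = None
    candidates = [
        p for p in plasmids
        if {pr.plasmid_id: pr for pr in profiles}[p.id].bhr_candidate
    ]
    if config.run_ani and len(candidates) >= 2:
        fragment = min(config.ani_fragment_nt, min(p.length for p in candidates))
        if fragment < config.ani_fragment_nt:
            logger.info("lowering ANI fragment size to %d nt", fragment)
        ani_results = ani_mod.all_pairs_ani(candidates, fragment_nt=fragment)
        clusters = ani_mod.cluster_at_threshold(
            ani_results,
            threshold_pct=config.ani_threshold_pct,
            ids=[p.id for p in candidates],
            linkage=config.ani_linkage,
        )
        logger.info(
            "ANI dereplication: %d candidates -> %d clusters",
            len(candidates),
            clusters.n_clusters,
        )
    elif config.run_ani:
        logger.info("fewer than two BHR candidates; ANI step skipped")

    summary = stats.summarize_cohort(profiles, calls, plasmids, arg_class_map)
    for notice in summary["notices"]:
        logger.info("%s", notice)

    seqio.write_plasmid_tsv(outdir / "plasmids.tsv", plasmids)
    orfs.write_gff3(outdir / "orfs.gff3", all_orfs)
    orfs.write_orf_fasta(outdir / "orfs.faa", all_orfs)
    homology.write_hits_tsv(outdir / "hits.tsv", hits)
    mobility.write_mobility_tsv(outdir / "mobility.tsv", calls)
    feat_mod.write_features_tsv(outdir / "features.tsv", profiles, arg_class_map)
    if clusters is not None:
        ani_mod.write_ani_tsv(outdir / "ani.tsv", ani_results)
        ani_mod.write_clusters_tsv(outdir / "clusters.tsv", clusters)
    write_profile_tsv(outdir / "profile.tsv", calls, profiles, clusters)
    stats.write_stats_json(outdir / "stats.json", summary)
    stats.write_summary_tsv(outdir / "summary.tsv", summary)

    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            f.name: _sha256(f)
            for f in sorted(outdir.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    return {
        "plasmids": plasmids,
        "orfs": all_orfs,
        "hits": hits,
        "calls": calls,
        "profiles": profiles,
        "ani": ani_results,
        "clusters": clusters,
        "summary": summary,
    }


def run_simulate(config: simulate.SimConfig, out_dir: str | Path) -> simulate.Cohort:
    """Generate a synthetic cohort and write it to ``out_dir``."""
    cohort = simulate.simulate_cohort(config)
    simulate.write_cohort(cohort, out_dir)
    return cohort
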