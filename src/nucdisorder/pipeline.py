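"""End-to-end orchestration: inputs -> consensus -> metrics -> reports.

The report bundle mirrors the shape of the study's tables and figures:
per-compartment disorder summaries with the non-nuclear control, a
co-localization multiplicity table, per-protein CH-CDF coordinates with a
per-group quadrant table, hub accounting and connectivity summaries for the
PPI-mapped sets, median disorder content for all proteins / hubs /
intra-compartment hubs, and the compartment-vs-control significance calls.
Everything is plain TSV plus a JSON manifest carrying the seed, a config
hash, and the package version; every number in every report is recomputable
from the emitted per-protein intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chcdf import chcdf_point, load_boundaries, quadrant_fractions
from .data_io import (
    COMPARTMENTS,
    StudyDatasets,
    assemble_datasets,
    read_compartments,
    read_edges,
    read_fasta,
)
from .disorder_consensus import ScoreTrack, build_consensus, read_scores
from .disorder_metrics import (
    DisorderProfile,
    group_summary,
    multiplicity_summary,
    protein_profile,
    summaries_to_frame,
)
from .enrichment_stats import StatsConfig, results_to_frame, run_all_comparisons
from .ppi_hubs import (
    annotate_hubs,
    annotate_intra_hubs,
    build_network,
    connectivity_summary,
    intra_compartment_degrees,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    fasta: str
    scores: str
    compartments: str
    outdir: str
    edges: str | None = None
    edge_format: str = "tsv"
    exclude_fragments: bool = False
    boundaries: str | None = None
    seed: int = 0
    hub_percentile: float = 20.0
    min_domain_len: int = 30
    content_threshold: float = 0.4
    binarize_threshold: float = 0.5
    cdf_track: str = "mean"  # "mean" of all tracks, or one predictor name
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stats = StatsConfig(**raw.pop("stats", {}))
        cfg = cls(stats=stats, **raw)
        for name in ("fasta", "scores", "compartments", "edges", "boundaries"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        return cfg

    def public_dict(self) -> dict:
        d = asdict(self)
        d.pop("outdir")  # the output location must not affect the config hash
        return d


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def compare_localization_subsets(
    datasets: StudyDatasets, profiles: dict[str, DisorderProfile]
) -> pd.DataFrame:
    """Side-by-side disorder summaries for the three nuclear roles.

    Lets one check that the annotated, annotated-plus-predicted, and
    PPI-mapped nuclear sets have equivalent disorder distributions.
    """
    rows = []
    for role in ("nuclear_a", "nuclear_ap", "ppi_nuclear_ap"):
        members = [profiles[p] for p in sorted(getattr(datasets, role)) if p in profiles]
        if not members:
            logger.info("role %r has no profiled proteins; row omitted", role)
            continue
        rows.append(group_summary(members, group=role))
    return summaries_to_frame(rows)


def analyze(
    datasets: StudyDatasets,
    tracks: dict[str, list[ScoreTrack]],
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage on in-memory inputs; returns named report tables."""
    ids = sorted(datasets.all_proteins)
    missing = [p for p in ids if len(tracks.get(p, [])) < 2]
    if len(missing) > len(ids) / 2:
        raise RuntimeError(
            f"score tracks missing for {len(missing)}/{len(ids)} proteins; "
            "need at least half the proteome covered"
        )
    if missing:
        logger.info("%d proteins lack >=2 score tracks and are excluded", len(missing))

    profiles: dict[str, DisorderProfile] = {}
    mean_scores: dict[str, np.ndarray] = {}
    for pid in ids:
        ptracks = tracks.get(pid, [])
        if len(ptracks) < 2:
            continue
        rec = datasets.all_proteins[pid]
        mask = build_consensus(
            ptracks, thresholds=config.binarize_threshold, expected_length=rec.length
        )
        profiles[pid] = protein_profile(mask, min_len=config.min_domain_len)
        if config.cdf_track == "mean":
            mean_scores[pid] = np.mean([t.scores for t in ptracks], axis=0)
        else:
            named = [t for t in ptracks if t.predictor_name == config.cdf_track]
            if named:
                mean_scores[pid] = named[0].scores

    reports: dict[str, pd.DataFrame] = {}

    # per-protein intermediates (everything downstream is recomputable from these)
    reports["profiles"] = pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "length": p.length,
                "content": p.content,
                "n_domains": p.n_domains,
                "domain_lengths": ",".join(map(str, p.domain_lengths)),
            }
            for _, p in sorted(profiles.items())
        ]
    )

    # compartment summaries vs the non-nuclear control
    groups = [
        group_summary(
            [profiles[p] for p in sorted(datasets.nnuclear) if p in profiles],
            group="nnuclear",
            content_threshold=config.content_threshold,
        )
    ]
    for comp in COMPARTMENTS:
        members = [
            profiles[p]
            for p in sorted(datasets.compartment_members(comp, within=datasets.nuclear_ap))
            if p in profiles
        ]
        if members:
            groups.append(
                group_summary(members, group=comp, content_threshold=config.content_threshold)
            )
    reports["group_summaries"] = summaries_to_frame(groups)

    reports["localization_subsets"] = compare_localization_subsets(datasets, profiles)

    comp_lookup = {
        pid: rec.compartments for pid, rec in datasets.all_proteins.items() if rec.is_nuclear
    }
    reports["multiplicity"] = multiplicity_summary(
        [profiles[p] for p in sorted(comp_lookup) if p in profiles], comp_lookup
    )

    # CH-CDF coordinates and quadrant tables
    ch_b, cdf_b = load_boundaries(config.boundaries)
    points = {}
    for pid in sorted(mean_scores):
        rec = datasets.all_proteins[pid]
        points[pid] = chcdf_point(pid, rec.sequence, mean_scores[pid], ch_b, cdf_b)
    reports["chcdf_points"] = pd.DataFrame(
        [
            {"protein_id": p.protein_id, "x": p.x, "y": p.y, "quadrant": p.quadrant}
            for _, p in sorted(points.items())
        ]
    )
    quad_rows = []
    group_defs = [("nnuclear", datasets.nnuclear)] + [
        (c, datasets.compartment_members(c, within=datasets.nuclear_ap))
        for c in COMPARTMENTS
    ]
    group_defs.append(("total", frozenset(datasets.all_proteins)))
    for label, members in group_defs:
        pts = [points[p] for p in sorted(members) if p in points]
        if not pts:
            continue
        row = {"group": label, "n": len(pts)}
        row.update(quadrant_fractions(pts))
        quad_rows.append(row)
    reports["chcdf_quadrants"] = pd.DataFrame(quad_rows)

    # PPI / hub accounting
    if datasets.edges:
        net = build_network(datasets.edges)
        hubs, k_star = annotate_hubs(net, config.hub_percentile)
        intra_deg = intra_compartment_degrees(net, comp_lookup)
        intra_hubs = annotate_intra_hubs(net, comp_lookup, k_star=k_star)
        hub_rows, conn_rows, content_rows = [], [], []

        def _median_content(members: list[str]) -> float:
            vals = [profiles[p].content for p in members if p in profiles]
            return float(np.median(vals)) if vals else float("nan")

        ctrl = sorted(datasets.ppi_nnuclear)
        if ctrl:
            conn = connectivity_summary(ctrl, net, hubs)
            conn_rows.append({"group": "nnuclear", **conn})
            ctrl_hubs = [p for p in ctrl if p in hubs]
            content_rows.append(
                {
                    "group": "nnuclear",
                    "median_content_all": _median_content(ctrl),
                    "median_content_hubs": _median_content(ctrl_hubs),
                    "median_content_intra_hubs": _median_content(ctrl_hubs),
                }
            )
        for comp in COMPARTMENTS:
            in_ppi = sorted(datasets.compartment_members(comp, within=datasets.ppi_nuclear_ap))
            hub_rows.append(
                {
                    "compartment": comp,
                    "n_nuclear_a": len(datasets.compartment_members(comp, within=datasets.nuclear_a)),
                    "n_nuclear_ap": len(datasets.compartment_members(comp, within=datasets.nuclear_ap)),
                    "n_ppi": len(in_ppi),
                    "n_hubs": sum(p in hubs for p in in_ppi),
                    "n_intra_hubs": len(intra_hubs.get(comp, frozenset()) & set(in_ppi)),
                }
            )
            if in_ppi:
                conn = connectivity_summary(
                    in_ppi, net, hubs, intra_deg, intra_hubs.get(comp, frozenset())
                )
                conn_rows.append({"group": comp, **conn})
                comp_hubs = [p for p in in_ppi if p in hubs]
                comp_ihubs = [p for p in in_ppi if p in intra_hubs.get(comp, frozenset())]
                content_rows.append(
                    {
                        "group": comp,
                        "median_content_all": _median_content(in_ppi),
                        "median_content_hubs": _median_content(comp_hubs),
                        "median_content_intra_hubs": _median_content(comp_ihubs),
                    }
                )
        reports["hub_table"] = pd.DataFrame(hub_rows)
        reports["connectivity"] = pd.DataFrame(conn_rows)
        reports["hub_content"] = pd.DataFrame(content_rows)

    # compartment-vs-control significance calls
    cfg = StatsConfig(**{**asdict(config.stats), "seed": config.seed})
    results = run_all_comparisons(datasets, profiles, cfg)
    reports["comparisons"] = results_to_frame(results)
    return reports


def run(config: RunConfig) -> Path:
    """Read inputs per the config, run the analysis, write the report bundle."""
    records = read_fasta(config.fasta, exclude_fragments=config.exclude_fragments)
    comp_map = read_compartments(config.compartments)
    edges = read_edges(config.edges, format=config.edge_format) if config.edges else []
    datasets = assemble_datasets(records, comp_map, edges)
    tracks = read_scores(config.scores)

    reports = analyze(datasets, tracks, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in sorted(reports.items()):
        _write(df, outdir / f"{name}.tsv")

    cfg_json = json.dumps(config.public_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.public_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_proteins": len(datasets.all_proteins),
        "n_edges": len(datasets.edges),
        "reports": sorted(reports),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
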