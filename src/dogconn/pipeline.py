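"""End-to-end orchestration: cohort → connectivity → graph → communities → hubs.

``analyze_cohort`` runs every analysis stage in memory and returns a
:class:`RunReport`; ``run_pipeline`` wraps it with file I/O (reads a fixture
directory, persists every intermediate table, writes a JSON report).
``write_cohort`` materializes a synthetic fixture directory.

Reproducibility: a single master seed deterministically spawns per-stage
child seeds (permutation test, consensus clustering, null models) via
``numpy.random.SeedSequence(master, spawn_key=(stage,))``, so any stage can
be re-run in isolation with the same stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centrality as centrality_mod
from . import communities as communities_mod
from . import connectivity as conn_mod
from . import network as network_mod
from . import parcellation as parc_mod
from . import synthetic
from .atlas import ROIMetadata
from .errors import ConfigurationError

log = logging.getLogger("dogconn")

_STAGE_SALTS = {"perm": 1, "consensus": 2, "split": 3, "null": 4}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(_STAGE_SALTS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults mirror the dog connectome analysis."""

    metadata_path: str = ""
    timeseries_dir: str = ""
    overlap_path: str = ""
    output_dir: str = "dogconn_out"
    seed_alpha: float = 0.05
    edge_alpha: float = 0.01
    resolution: float = 0.6
    n_repeats: int = 10
    n_null: int = 100
    n_perm: int = 5000
    top_k_hubs: int = 20
    edge_weight: str = "abs_t"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_alpha", "edge_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name}={v} must be in (0, 1)")
        for name in ("n_repeats", "n_null", "n_perm", "top_k_hubs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sha1(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    n_nodes: int = 0
    n_edges: int = 0
    density: float = 0.0
    triangles: int = 0
    small_world: dict = field(default_factory=dict)
    layer1_modules: int = 0
    final_modules: int = 0
    layer1_q: float = 0.0
    final_q: float = 0.0
    community_density: list = field(default_factory=list)
    homolog_symmetry: dict = field(default_factory=dict)
    top_rankings: dict = field(default_factory=dict)
    consensus_hubs: list = field(default_factory=list)
    jaccard_table: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=float)


@dataclass
class AnalysisResult:
    """Report plus the in-memory objects every stage produced."""

    report: RunReport
    stats: conn_mod.GroupEdgeStats
    edges: pd.DataFrame
    graph: object
    layer1: communities_mod.CommunityPartition | None
    final: communities_mod.CommunityPartition | None
    centralities: pd.DataFrame | None
    rankings: dict | None
    subject_matrices: list


def analyze_cohort(
    cohort: list[synthetic.ROITimeSeries],
    meta: ROIMetadata,
    cfg: PipelineConfig,
    overlap: synthetic.ParcellationOverlap | None = None,
    reference: parc_mod.NetworkAssignment | None = None,
    compute_small_world: bool = True,
) -> AnalysisResult:
    """Run connectivity, graph, community, centrality (and optionally
    parcellation-comparison) stages on an in-memory cohort."""
    report = RunReport(config=asdict(cfg))
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        log.info("stage connectivity: %d subjects", len(cohort))
        mats = [conn_mod.semipartial_matrix(ts) for ts in cohort]
        stats = conn_mod.group_edge_stats(
            mats, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "perm")
        )
        edges = conn_mod.threshold_edges(
            stats, cfg.seed_alpha, cfg.edge_alpha, weight=cfg.edge_weight
        )

        log.info("stage network_build: %d edges retained", len(edges))
        g = network_mod.build_graph(edges, meta)
        report.n_nodes = g.number_of_nodes()
        report.n_edges = g.number_of_edges()
        report.density = network_mod.density(g)
        report.triangles = network_mod.triangle_count(g)

        layer1 = final = None
        cent = rankings = None
        if g.number_of_edges() == 0:
            report.degenerate = True
            log.warning("empty graph; downstream stages skipped")
        else:
            if compute_small_world:
                try:
                    sw = network_mod.small_world(
                        g, n_null=cfg.n_null, seed=stage_seed(cfg.seed, "null")
                    )
                    report.small_world = sw.as_dict()
                except Exception as exc:  # degenerate null (e.g. triangle-free)
                    caught.append(f"small_world skipped: {exc}")
            log.info("stage communities")
            layer1 = communities_mod.consensus_partition(
                g, cfg.resolution, cfg.n_repeats, seed=stage_seed(cfg.seed, "consensus")
            )
            final = communities_mod.split_lateralized(
                g, layer1, meta, seed=stage_seed(cfg.seed, "split")
            )
            report.layer1_modules = layer1.n_modules
            report.final_modules = final.n_modules
            report.layer1_q = layer1.q
            report.final_q = final.q
            report.community_density = communities_mod.community_density(
                g, final
            ).to_dict("records")
            try:
                report.homolog_symmetry = communities_mod.homolog_symmetry(g, meta)
            except Exception as exc:  # too sparse for rank correlation
                caught.append(f"homolog_symmetry skipped: {exc}")

            log.info("stage centrality")
            cent = centrality_mod.node_centralities(g)
            rankings, hubs = centrality_mod.hub_table(cent, meta, k=cfg.top_k_hubs)
            report.top_rankings = {
                m: rk.reset_index().to_dict("records") for m, rk in rankings.items()
            }
            report.consensus_hubs = sorted(hubs)

        if overlap is not None and reference is not None:
            log.info("stage parcellation_compare")
            assign = parc_mod.allocate_rois(overlap, meta)
            jtab = parc_mod.match_networks(reference, assign)
            report.jaccard_table = jtab.to_dict("records")

    caught += [str(w.message) for w in wlist]
    report.warnings = caught
    return AnalysisResult(report, stats, edges, g, layer1, final, cent, rankings, mats)


# ---------------------------------------------------------------------------
# fixture directory I/O


def write_cohort(
    spec: synthetic.GeneratorSpec,
    meta: ROIMetadata,
    outdir,
    overlap_jitter: float = 0.2,
) -> Path:
    """Materialize a synthetic fixture: metadata, per-subject TSVs, planted
    truth labels, and an overlap table."""
    out = Path(outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    meta.to_tsv(out / "metadata.tsv")
    for ts in synthetic.generate_timeseries(meta, spec):
        ts.to_tsv(out / "timeseries" / f"{ts.subject_id}.tsv")
    truth = pd.DataFrame(
        {
            "roi": meta.names,
            "layer1": [synthetic.planted_layer1_labels(spec)[n] for n in meta.names],
            "final": [synthetic.planted_final_labels(spec)[n] for n in meta.names],
            "hub": [n in spec.hub_names for n in meta.names],
        }
    )
    truth.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    nets = synthetic.planted_networks_from_metadata(meta)
    ov = synthetic.generate_overlap_table(
        meta, nets, jitter=overlap_jitter, seed=spec.seed
    )
    ov.to_tsv(out / "overlap.tsv")
    return out


def load_cohort(fixture_dir) -> tuple[list[synthetic.ROITimeSeries], ROIMetadata]:
    fixture_dir = Path(fixture_dir)
    meta = ROIMetadata.from_tsv(fixture_dir / "metadata.tsv")
    cohort = [
        synthetic.ROITimeSeries.from_tsv(p, p.stem)
        for p in sorted((fixture_dir / "timeseries").glob("*.tsv"))
    ]
    if not cohort:
        raise ConfigurationError(f"no time-series TSVs under {fixture_dir}/timeseries")
    return cohort, meta


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """File-based end-to-end run; persists all intermediates under output_dir."""
    meta = ROIMetadata.from_tsv(cfg.metadata_path)
    tsdir = Path(cfg.timeseries_dir)
    cohort = [
        synthetic.ROITimeSeries.from_tsv(p, p.stem) for p in sorted(tsdir.glob("*.tsv"))
    ]
    if not cohort:
        raise ConfigurationError(f"no time-series TSVs under {tsdir}")
    overlap = reference = None
    if cfg.overlap_path:
        overlap = synthetic.ParcellationOverlap.from_tsv(cfg.overlap_path)
        reference = parc_mod.NetworkAssignment(
            {
                roi: net
                for net, rois in synthetic.planted_networks_from_metadata(meta).items()
                for roi in rois
            }
        )
    res = analyze_cohort(cohort, meta, cfg, overlap=overlap, reference=reference)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "subject_matrices").mkdir(exist_ok=True)
    for mat in res.subject_matrices:
        mat.to_csv(out / "subject_matrices" / f"{mat.subject_id}.csv")
    res.stats.edge_frame().to_csv(out / "edge_stats.tsv", sep="\t", index=False)
    res.stats.seed_frame().to_csv(out / "seed_stats.tsv", sep="\t", index=False)
    res.edges.to_csv(out / "thresholded_edges.tsv", sep="\t", index=False)
    network_mod.export_graphml(res.graph, out / "graph.graphml")
    network_mod.export_edgelist_csv(res.graph, out / "edges.csv")
    if res.layer1 is not None and res.final is not None:
        part = res.layer1.to_frame().rename(columns={"module": "layer1_module"})
        part["final_module"] = res.final.to_frame()["module"].to_numpy()
        part.to_csv(out / "partition.tsv", sep="\t", index=False)
        communities_mod.community_density(res.graph, res.final).to_csv(
            out / "community_density.tsv", sep="\t", index=False
        )
    if res.rankings is not None:
        for m, rk in res.rankings.items():
            rk.to_csv(out / f"top_{m.lower()}.tsv", sep="\t")
        pd.Series(sorted(res.report.consensus_hubs), name="roi_or_pair").to_csv(
            out / "consensus_hubs.tsv", sep="\t", index=False
        )
    if res.report.jaccard_table:
        pd.DataFrame(res.report.jaccard_table).to_csv(
            out / "jaccard.tsv", sep="\t", index=False
        )
    (out / "report.json").write_text(res.report.to_json())
    return res.report
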