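"""Two-layer consensus community structure of the ROI graph.

Communities are found by weighted-modularity maximization (multi-level
greedy "Louvain" moves) at a configurable resolution (default 0.6, the value
used for the dog connectome). A single stochastic run is unstable, so the
partition of record is a consensus over repeated runs: co-assignment
frequencies across repeats are thresholded at 0.5 and the surviving
agreement graph is re-clustered until the co-assignment matrix is
block-constant.

A second layer dissects lateralized communities — those with more than 70%
of members in a single hemisphere. The ``top_k`` most populous lateralized
modules are re-clustered on their induced subgraphs and the refined labels
are merged back, leaving every other module untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ROIMetadata
from .errors import DegenerateGraphError, InsufficientDataError

LATERALIZATION_FRACTION = 0.7
CONSENSUS_THRESHOLD = 0.5
MAX_CONSENSUS_ITER = 20


@dataclass(frozen=True)
class CommunityPartition:
    """Node→module labels with provenance.

    Module ids are contiguous integers from 0, ordered by decreasing module
    size (ties by smallest member name) so labellings are deterministic.
    """

    labels: dict[str, int] = field(repr=False)
    q: float
    layer: int
    resolution: float
    n_repeats: int
    seed: int

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def members(self, module: int) -> set[str]:
        return {n for n, m in self.labels.items() if m == module}

    def modules(self) -> list[set[str]]:
        return [self.members(m) for m in range(self.n_modules)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi": sorted(self.labels), "module": [self.labels[r] for r in sorted(self.labels)]}
        )


def _canonical_labels(communities: list[set[str]]) -> dict[str, int]:
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(ordered) for node in comm}


def modularity_score(g: nx.Graph, labels: dict[str, int], resolution: float) -> float:
    """Weighted modularity of a labelling, with resolution on the null term."""
    missing = set(g.nodes()) - set(labels)
    if missing:
        raise DegenerateGraphError(f"nodes without labels: {sorted(missing)[:5]}")
    comms: dict[int, set] = {}
    for n, m in labels.items():
        if n in g:
            comms.setdefault(m, set()).add(n)
    return nx.community.modularity(
        g, comms.values(), weight="weight", resolution=resolution
    )


def detect_communities(
    g: nx.Graph, resolution: float = 0.6, seed: int = 0
) -> CommunityPartition:
    """One run of greedy multi-level weighted-modularity maximization."""
    if g.number_of_edges() < 1:
        raise DegenerateGraphError("community detection needs at least one edge")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    labels = _canonical_labels([set(c) for c in comms])
    q = modularity_score(g, labels, resolution)
    return CommunityPartition(labels, q, layer=1, resolution=resolution, n_repeats=1, seed=seed)


def _child_seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(salt,))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def consensus_partition(
    g: nx.Graph, resolution: float = 0.6, n_repeats: int = 10, seed: int = 0
) -> CommunityPartition:
    """Consensus over repeated stochastic detections.

    Runs ``n_repeats`` detections with derived seeds, builds the node×node
    co-assignment frequency matrix, zeroes entries below 0.5, re-clusters the
    agreement graph, and iterates until the matrix is block-constant (all
    frequencies 0 or 1) or 20 iterations pass (then: warning, last partition).
    """
    if n_repeats < 1:
        raise DegenerateGraphError("n_repeats must be >= 1")
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    current = g
    last_parts = None
    for iteration in range(MAX_CONSENSUS_ITER):
        seeds = _child_seeds(seed, n_repeats, salt=iteration)
        parts = [detect_communities(current, resolution, s) for s in seeds]
        last_parts = parts
        if all(p.labels == parts[0].labels for p in parts[1:]):
            labels = _canonical_labels(parts[0].modules())
            return CommunityPartition(
                labels,
                modularity_score(g, labels, resolution),
                layer=1,
                resolution=resolution,
                n_repeats=n_repeats,
                seed=seed,
            )
        co = np.zeros((len(nodes), len(nodes)))
        for part in parts:
            for comm in part.modules():
                ids = [index[n] for n in comm]
                co[np.ix_(ids, ids)] += 1.0
        co /= n_repeats
        co[co < CONSENSUS_THRESHOLD] = 0.0
        off = co[~np.eye(len(nodes), dtype=bool)]
        if np.all((off == 0) | (off == 1)):
            agreement = nx.Graph()
            agreement.add_nodes_from(nodes)
            ii, jj = np.nonzero(np.triu(co, k=1))
            agreement.add_edges_from((nodes[a], nodes[b]) for a, b in zip(ii, jj))
            comms = [set(c) for c in nx.connected_components(agreement)]
            labels = _canonical_labels(comms)
            return CommunityPartition(
                labels,
                modularity_score(g, labels, resolution),
                layer=1,
                resolution=resolution,
                n_repeats=n_repeats,
                seed=seed,
            )
        nxt = nx.Graph()
        nxt.add_nodes_from(nodes)
        ii, jj = np.nonzero(np.triu(co, k=1))
        nxt.add_weighted_edges_from(
            (nodes[a], nodes[b], co[a, b]) for a, b in zip(ii, jj)
        )
        current = nxt
    warnings.warn("consensus did not converge in 20 iterations; returning last partition")
    labels = _canonical_labels(last_parts[0].modules())
    return CommunityPartition(
        labels,
        modularity_score(g, labels, resolution),
        layer=1,
        resolution=resolution,
        n_repeats=n_repeats,
        seed=seed,
    )


def _hemisphere_fraction(members: set[str], meta: ROIMetadata) -> float:
    hemis = meta.table.set_index("name")["hemisphere"]
    counts = pd.Series([hemis[m] for m in members]).value_counts()
    lateral = max(counts.get("left", 0), counts.get("right", 0))
    return lateral / len(members)


def split_lateralized(
    g: nx.Graph,
    part: CommunityPartition,
    meta: ROIMetadata,
    top_k: int = 2,
    resolution: float | None = None,
    n_repeats: int | None = None,
    seed: int | None = None,
) -> CommunityPartition:
    """Second layer: re-cluster the largest lateralized modules in isolation.

    A module qualifies as lateralized when more than 70% of its members lie
    in one hemisphere. The ``top_k`` most populous qualifying modules are
    re-run through :func:`consensus_partition` on their induced subgraphs;
    everything else keeps its membership. Fewer qualifying modules than
    ``top_k`` yields a warning and splits whatever qualifies.
    """
    if part.layer != 1:
        raise DegenerateGraphError("split_lateralized expects a layer-1 partition")
    resolution = part.resolution if resolution is None else resolution
    n_repeats = part.n_repeats if n_repeats is None else n_repeats
    seed = part.seed if seed is None else seed

    modules = part.modules()
    lateralized = [
        (m, comm)
        for m, comm in enumerate(modules)
        if len(comm) >= 2 and _hemisphere_fraction(comm, meta) > LATERALIZATION_FRACTION
    ]
    lateralized.sort(key=lambda mc: (-len(mc[1]), mc[0]))
    if len(lateralized) < top_k:
        warnings.warn(
            f"only {len(lateralized)} lateralized modules found "
            f"(requested top_k={top_k})"
        )
    chosen = lateralized[:top_k]
    chosen_ids = {m for m, _ in chosen}

    final_comms: list[set[str]] = [
        comm for m, comm in enumerate(modules) if m not in chosen_ids
    ]
    for offset, (m, comm) in enumerate(chosen):
        sub = g.subgraph(comm).copy()
        if sub.number_of_edges() == 0:
            final_comms.append(comm)
            continue
        sub_part = consensus_partition(
            sub, resolution=resolution, n_repeats=n_repeats, seed=seed + 1000 + offset
        )
        final_comms.extend(sub_part.modules())
    labels = _canonical_labels(final_comms)
    return CommunityPartition(
        labels,
        modularity_score(g, labels, resolution),
        layer=2,
        resolution=resolution,
        n_repeats=n_repeats,
        seed=seed,
    )


def community_density(g: nx.Graph, part: CommunityPartition) -> pd.DataFrame:
    """Induced-subgraph edge density per module.

    Singleton modules report density 0 with ``singleton=True`` so totals stay
    complete.
    """
    rows = []
    for m, comm in enumerate(part.modules()):
        n = len(comm)
        if n < 2:
            rows.append({"module": m, "n_nodes": n, "density": 0.0, "singleton": True})
            continue
        e = g.subgraph(comm).number_of_edges()
        rows.append(
            {
                "module": m,
                "n_nodes": n,
                "density": 2.0 * e / (n * (n - 1)),
                "singleton": False,
            }
        )
    return pd.DataFrame(rows, columns=["module", "n_nodes", "density", "singleton"])


def homolog_symmetry(g: nx.Graph, meta: ROIMetadata) -> dict:
    """Spearman correlation of left-vs-right degree and weighted degree.

    Returns ``rho_degree``, ``rho_weight`` with two-sided p-values over the
    bilateral pairs; requires at least 3 pairs with a nonzero-degree member.
    Degenerate (constant) rankings yield NaN with a warning.
    """
    deg = dict(g.degree())
    wdeg = dict(g.degree(weight="weight"))
    rows = []
    for ln, rn in meta.pairs():
        if deg.get(ln, 0) == 0 and deg.get(rn, 0) == 0:
            continue
        rows.append((deg[ln], deg[rn], wdeg[ln], wdeg[rn]))
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} bilateral pairs with nonzero degree (need >= 3)"
        )
    arr = np.asarray(rows, dtype=float)

    def _spearman(x, y):
        if np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn("constant values on one side; Spearman rho undefined")
            return float("nan"), float("nan")
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)

    rho_d, p_d = _spearman(arr[:, 0], arr[:, 1])
    rho_w, p_w = _spearman(arr[:, 2], arr[:, 3])
    return {
        "rho_degree": rho_d,
        "p_degree": p_d,
        "rho_weight": rho_w,
        "p_weight": p_w,
        "n_pairs": len(rows),
    }
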