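"""Hub metrics: weighted degree, degree, betweenness, and bilateral ranking.

Weighted degree (WD) sums incident edge weights, degree (D) counts incident
edges, and betweenness centrality (BC) is the unnormalized Brandes count of
shortest paths through a node on the binarized graph, with fractional credit
for tied shortest paths. Bilateral homologs are averaged per metric *before*
ranking, so each bilateral pair competes as one entry alongside midline ROIs,
and hubs are the regions ranked in the top k of all three metrics at once.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .atlas import ROIMetadata
from .errors import AlignmentError

METRICS = ("WD", "D", "BC")


def node_centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node WD, D and BC, indexed by ROI name."""
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    df = pd.DataFrame(
        {
            "WD": pd.Series(dict(g.degree(weight="weight")), dtype=float),
            "D": pd.Series(dict(g.degree()), dtype=float),
            "BC": pd.Series(bc, dtype=float),
        }
    )
    df.index.name = "roi"
    return df.sort_index()


def bilateral_average(tab: pd.DataFrame, meta: ROIMetadata) -> pd.DataFrame:
    """Collapse bilateral pairs to their per-metric means.

    Output has one row per bilateral pair (labelled by the shared name stem)
    and one row per midline ROI (unchanged).
    """
    rows = {}
    for ln, rn in meta.pairs():
        if ln not in tab.index or rn not in tab.index:
            raise AlignmentError(f"pair member missing from centrality table: {ln}/{rn}")
        rows[meta.pair_label(ln)] = (tab.loc[ln] + tab.loc[rn]) / 2.0
    for name in meta.midline_names():
        if name not in tab.index:
            raise AlignmentError(f"midline ROI missing from centrality table: {name}")
        rows[name] = tab.loc[name]
    out = pd.DataFrame(rows).T[list(METRICS)]
    out.index.name = "roi_or_pair"
    return out.sort_index()


def top_k(tab: pd.DataFrame, metric: str, k: int = 20) -> pd.DataFrame:
    """Top-k rows by a metric, descending; ties broken alphabetically."""
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRICS}")
    if k > len(tab):
        raise AlignmentError(f"k={k} exceeds table size {len(tab)}")
    ranked = tab.assign(_name=tab.index).sort_values(
        by=[metric, "_name"], ascending=[False, True]
    )
    out = ranked.head(k)[[metric]].copy()
    out.insert(0, "rank", range(1, len(out) + 1))
    return out


def consensus_hubs(rankings: dict[str, pd.DataFrame], k: int | None = None) -> set[str]:
    """Regions present in every provided top-k ranking (set intersection)."""
    sets = []
    for metric, ranked in rankings.items():
        labels = set(ranked.index if k is None else ranked.index[:k])
        sets.append(labels)
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def hub_table(
    tab: pd.DataFrame, meta: ROIMetadata, k: int = 20
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Bilateral-averaged top-k rankings per metric plus their intersection."""
    collapsed = bilateral_average(tab, meta)
    k = min(k, len(collapsed))
    rankings = {m: top_k(collapsed, m, k) for m in METRICS}
    return rankings, consensus_hubs(rankings)
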