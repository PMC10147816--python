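"""Mapping a voxelwise network decomposition onto the ROI atlas.

An independent decomposition of the same brain (e.g. group ICA) yields
voxelwise network masks; counting overlap voxels between each mask and each
atlas ROI gives a network × ROI table. Each ROI is allocated to the network
with the largest overlap (majority vote), averaging the counts of bilateral
pair members first so homologs always share an assignment. Two such
ROI-level parcellations are then compared network-by-network with Jaccard
set similarity, greedily pairing networks by descending score (optimal
one-to-one assignment available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .atlas import ROIMetadata
from .errors import AlignmentError, InsufficientDataError
from .synthetic import ParcellationOverlap


@dataclass(frozen=True)
class NetworkAssignment:
    """ROI → network mapping plus the set of unallocatable (zero-overlap) ROIs."""

    mapping: dict[str, str] = field(repr=False)
    unallocated: frozenset[str] = frozenset()

    def rois_of(self, network: str) -> set[str]:
        return {r for r, n in self.mapping.items() if n == network}

    def networks(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"roi": r, "network": n} for r, n in sorted(self.mapping.items())]
        rows += [{"roi": r, "network": ""} for r in sorted(self.unallocated)]
        return pd.DataFrame(rows, columns=["roi", "network"])


def allocate_rois(ov: ParcellationOverlap, meta: ROIMetadata) -> NetworkAssignment:
    """Majority-vote allocation of ROIs to networks.

    Bilateral pair counts are averaged per network before the argmax so both
    members land in the same network. Ties go to the first network in row
    order, with a warning. ROIs with zero overlap everywhere are unallocated.
    """
    tab = ov.table
    if set(tab.columns) != set(meta.names):
        raise AlignmentError("overlap table columns do not match metadata ROIs")
    mapping: dict[str, str] = {}
    unallocated: set[str] = set()

    def _assign(names: list[str], votes: pd.Series) -> None:
        if votes.sum() == 0:
            unallocated.update(names)
            return
        top = votes.max()
        winners = votes.index[votes == top]
        if len(winners) > 1:
            warnings.warn(
                f"overlap tie for {names}: {list(winners)}; keeping {winners[0]!r}"
            )
        for n in names:
            mapping[n] = winners[0]

    for ln, rn in meta.pairs():
        _assign([ln, rn], (tab[ln] + tab[rn]) / 2.0)
    for name in meta.midline_names():
        _assign([name], tab[name].astype(float))
    return NetworkAssignment(mapping, frozenset(unallocated))


def jaccard(a: set, b: set) -> float:
    """Set similarity |a∩b| / |a∪b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        raise InsufficientDataError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def match_networks(
    assign_a: NetworkAssignment,
    assign_b: NetworkAssignment,
    method: str = "greedy",
) -> pd.DataFrame:
    """Best-partner table between two ROI-level parcellations.

    Each network in A is paired one-to-one with a network in B, by greedy
    descending Jaccard (default) or optimal assignment (``method="optimal"``).
    Unmatched networks appear with an empty partner and NaN score.
    """
    universe_a = set(assign_a.mapping) | set(assign_a.unallocated)
    universe_b = set(assign_b.mapping) | set(assign_b.unallocated)
    if universe_a != universe_b:
        raise AlignmentError("assignments cover different ROI universes")
    nets_a = assign_a.networks()
    nets_b = assign_b.networks()
    scores = np.zeros((len(nets_a), len(nets_b)))
    for i, na in enumerate(nets_a):
        for j, nb in enumerate(nets_b):
            scores[i, j] = jaccard(assign_a.rois_of(na), assign_b.rois_of(nb))

    pairs: dict[int, int] = {}
    if method == "greedy":
        order = sorted(
            ((scores[i, j], i, j) for i in range(len(nets_a)) for j in range(len(nets_b))),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for s, i, j in order:
            if s <= 0 or i in used_a or j in used_b:
                continue
            pairs[i] = j
            used_a.add(i)
            used_b.add(j)
    elif method == "optimal":
        ri, ci = linear_sum_assignment(-scores)
        pairs = {int(i): int(j) for i, j in zip(ri, ci) if scores[i, j] > 0}
    else:
        raise ValueError(f"unknown matching method {method!r}")

    rows = []
    for i, na in enumerate(nets_a):
        if i in pairs:
            j = pairs[i]
            rows.append({"network_a": na, "network_b": nets_b[j], "jaccard": scores[i, j]})
        else:
            rows.append({"network_a": na, "network_b": "", "jaccard": float("nan")})
    matched_b = {pairs[i] for i in pairs}
    for j, nb in enumerate(nets_b):
        if j not in matched_b:
            rows.append({"network_a": "", "network_b": nb, "jaccard": float("nan")})
    return pd.DataFrame(rows, columns=["network_a", "network_b", "jaccard"])
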