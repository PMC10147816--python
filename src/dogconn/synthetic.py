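"""Synthetic resting-state cohorts with planted network structure.

No public dataset accompanies the dog connectome analysis this package
implements, so the generator emulates the statistical structure of denoised
ROI time series: a linear latent-factor model with block covariance
(functional modules), bilateral homolog coupling, planted hub regions with
cross-module loadings, and AR(1) temporal noise. Every planted feature is
recoverable, giving each downstream stage a ground truth.

The generative equation for ROI *i* of subject *s* is::

    x_i(t) = a_m f_m(t) + w b_q(t) + c g_p(t) + h * sum_k f_k(t) + e_i(t)

where ``f_m`` is the latent factor of the module containing *i*, ``b_q`` an
optional bridge factor shared by one matched member pair across the two
sub-blocks of a lateralized super-module (binding them into one first-layer
community), ``g_p`` a factor shared by the two members of bilateral pair *p*
with coupling ``c``, the ``f_k`` are the factors of ``hub_k`` other modules
for planted hub ROIs with loading ``h``, and ``e_i`` is AR(1) noise. Columns
are standardized to mean 0, SD 1. Pairwise couplings (bridges, homolog
pairs) rather than broad shared factors carry the structure that must
survive semi-partial estimation, which discounts any signal explained by
third regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import ROIMetadata
from .errors import ConfigurationError, StationarityError

_AR_BURN_IN = 100


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module in the metadata plan.

    A lateralized entry describes a set of bilateral pairs whose left members
    form a twin module ``<name>_L`` and right members ``<name>_R`` — the
    single-hemisphere communities that a second community-detection layer
    later dissects. Lateralized modules cannot hold midline ROIs.
    """

    name: str
    n_pairs: int
    n_midline: int = 0
    lateralized: bool = False

    @property
    def size(self) -> int:
        return 2 * self.n_pairs + self.n_midline

    def __post_init__(self) -> None:
        if self.lateralized and self.n_midline:
            raise ConfigurationError(
                f"lateralized module {self.name!r} cannot contain midline ROIs"
            )


@dataclass(frozen=True)
class FactorBlock:
    """A latent factor and the ROIs loading on it."""

    name: str
    roi_names: tuple[str, ...]
    loading: float


@dataclass(frozen=True)
class SuperModule:
    """Two sub-blocks bound into one layer-1 community by bridge couplings.

    Matched members of the two blocks (k-th of each in sorted name order)
    share a private latent factor with loading ``loading``. Pairwise bridges
    — unlike a factor shared by the whole super-module — survive semi-partial
    estimation, so the super-module coheres in the full graph yet its
    sub-blocks separate when the induced subgraph is re-clustered.
    """

    name: str
    member_blocks: tuple[str, ...]
    loading: float

    def bridge_pairs(self, block_members: Mapping[str, tuple[str, ...]]) -> list[tuple[str, str]]:
        """Deterministic matched pairs across the two member blocks."""
        if len(self.member_blocks) != 2:
            raise ConfigurationError(
                f"super-module {self.name!r} must bind exactly two blocks"
            )
        a = sorted(block_members[self.member_blocks[0]])
        b = sorted(block_members[self.member_blocks[1]])
        return list(zip(a, b))


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterization of a synthetic cohort.

    Defaults (via :func:`default_generator_spec`) emulate the study cohort:
    33 subjects, 264 time points (two runs of 132 usable volumes), 97 ROIs.
    """

    n_subjects: int
    n_timepoints: int
    modules: tuple[FactorBlock, ...]
    supermodules: tuple[SuperModule, ...] = ()
    homolog_coupling: float = 0.45
    hub_names: tuple[str, ...] = ()
    hub_loading: float = 0.35
    hub_k: int = 3
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ar_coefficient >= 1:
            raise StationarityError(
                f"ar_coefficient={self.ar_coefficient} is non-stationary (must be < 1)"
            )
        if self.ar_coefficient < 0:
            raise ConfigurationError("ar_coefficient must be in [0, 1)")
        if not 0 <= self.homolog_coupling <= 1:
            raise ConfigurationError("homolog_coupling must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for m in self.modules:
            if m.loading < 0:
                raise ConfigurationError(f"negative loading in module {m.name!r}")

    def block_of(self) -> dict[str, str]:
        """ROI name -> factor block name; errors if coverage is not a partition."""
        out: dict[str, str] = {}
        for m in self.modules:
            for roi in m.roi_names:
                if roi in out:
                    raise ConfigurationError(f"ROI {roi!r} in more than one module")
                out[roi] = m.name
        return out


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's signals: rows = time points, columns = metadata ROI order."""

    subject_id: str
    data: np.ndarray = field(repr=False)
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_names):
            raise ConfigurationError("time-series shape inconsistent with ROI names")
        if not np.isfinite(self.data).all():
            raise ConfigurationError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.data, columns=list(self.roi_names))
        df.insert(0, "t", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path, subject_id: str) -> "ROITimeSeries":
        df = pd.read_csv(path, sep="\t")
        roi_names = tuple(df.columns[1:])
        return cls(subject_id, df.iloc[:, 1:].to_numpy(float), roi_names)


# ---------------------------------------------------------------------------
# metadata


def generate_metadata(
    n_pairs: int,
    n_midline: int,
    module_plan: Sequence[ModuleSpec],
    seed: int = 0,
) -> ROIMetadata:
    """Build ROI metadata realizing a module plan.

    Bilateral pair members land in the same module, except for lateralized
    modules whose left/right members populate twin ``_L``/``_R`` groups.
    ``seed`` shuffles the roi_id assignment so planted blocks are not
    contiguous in matrix order.
    """
    plan_pairs = sum(m.n_pairs for m in module_plan)
    plan_mid = sum(m.n_midline for m in module_plan)
    if (n_pairs, n_midline) != (plan_pairs, plan_mid):
        raise ConfigurationError(
            f"requested {2 * n_pairs + n_midline} ROIs "
            f"({n_pairs} pairs + {n_midline} midline) but module plan holds "
            f"{2 * plan_pairs + plan_mid} ({plan_pairs} pairs + {plan_mid} midline)"
        )
    rows: list[dict] = []
    pair_counter = 0
    for mod in module_plan:
        for k in range(mod.n_pairs):
            stem = f"{mod.name}_p{k}"
            group_l = f"{mod.name}_L" if mod.lateralized else mod.name
            group_r = f"{mod.name}_R" if mod.lateralized else mod.name
            rows.append(
                dict(name=f"{stem}_L", hemisphere="left", pair_id=pair_counter, group=group_l)
            )
            rows.append(
                dict(name=f"{stem}_R", hemisphere="right", pair_id=pair_counter, group=group_r)
            )
            pair_counter += 1
        for k in range(mod.n_midline):
            rows.append(
                dict(name=f"{mod.name}_m{k}", hemisphere="midline", pair_id=None, group=mod.name)
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    table = pd.DataFrame(rows)
    table["roi_id"] = np.argsort(order)  # seeded permutation of ids
    return ROIMetadata(table)


def default_module_plan() -> list[ModuleSpec]:
    """The 97-ROI plan: 8 bilateral modules + 2 lateralized twin modules.

    45 bilateral pairs + 7 midline ROIs = 97. The lateralized ``sylvian``
    entry contributes twin 15-ROI single-hemisphere modules, giving a
    10-module first layer whose two largest communities are lateralized.
    """
    return [
        ModuleSpec("visual", n_pairs=5),
        ModuleSpec("hippocampal", n_pairs=2),
        ModuleSpec("ventral_post_cingulate", n_pairs=2, n_midline=1),
        ModuleSpec("dorsolateral_prefrontal", n_pairs=6),
        ModuleSpec("medial_prefrontal", n_pairs=6, n_midline=2),
        ModuleSpec("anterior_cingulate", n_pairs=2, n_midline=2),
        ModuleSpec("amygdala", n_pairs=2, n_midline=1),
        ModuleSpec("sensorimotor", n_pairs=5, n_midline=1),
        ModuleSpec("sylvian", n_pairs=15, lateralized=True),
    ]


def default_metadata(seed: int = 0) -> ROIMetadata:
    return generate_metadata(45, 7, default_module_plan(), seed=seed)


# ---------------------------------------------------------------------------
# generator spec with planted two-layer structure


def default_generator_spec(
    meta: ROIMetadata,
    n_subjects: int = 33,
    n_timepoints: int = 264,
    loading: float = 0.8,
    sub_loading: float = 0.6,
    bridge_coupling: float = 0.35,
    homolog_coupling: float = 0.2,
    hub_loading: float = 0.25,
    hub_k: int = 3,
    ar_coefficient: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> GeneratorSpec:
    """Cohort spec planting the default two-layer community structure.

    Each lateralized twin group (``sylvian_L``/``sylvian_R``) is split into
    two latent sub-blocks (8 + 7 ROIs) bound by pairwise bridge couplings,
    so the twin appears as one community at the first detection layer and
    separates into two at the second. Five bilateral pairs are planted as
    hubs with loadings onto ``hub_k`` foreign modules.
    """
    groups = meta.groups
    by_group: dict[str, list[str]] = {}
    for name in meta.names:
        by_group.setdefault(groups[name], []).append(name)

    blocks: list[FactorBlock] = []
    supers: list[SuperModule] = []
    for gname, members in sorted(by_group.items()):
        members = sorted(members)
        if gname.endswith(("_L", "_R")):
            half = (len(members) + 1) // 2
            sub_a = FactorBlock(f"{gname}_a", tuple(members[:half]), sub_loading)
            sub_b = FactorBlock(f"{gname}_b", tuple(members[half:]), sub_loading)
            blocks += [sub_a, sub_b]
            supers.append(SuperModule(gname, (sub_a.name, sub_b.name), bridge_coupling))
        else:
            blocks.append(FactorBlock(gname, tuple(members), loading))

    # hubs live in sizeable modules so their within-module degree keeps them
    # competitive in all three rankings
    hub_modules = (
        "medial_prefrontal",
        "sylvian_L",
        "visual",
        "dorsolateral_prefrontal",
        "sensorimotor",
    )
    hubs: list[str] = []
    for gname in hub_modules:
        stems = sorted({n[:-2] for n in by_group.get(gname, []) if n.endswith("_L")})
        if stems:
            hubs += [f"{stems[0]}_L", f"{stems[0]}_R"]

    return GeneratorSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        modules=tuple(blocks),
        supermodules=tuple(supers),
        homolog_coupling=homolog_coupling,
        hub_names=tuple(hubs),
        hub_loading=hub_loading,
        hub_k=hub_k,
        ar_coefficient=ar_coefficient,
        noise_sd=noise_sd,
        seed=seed,
    )


def planted_layer1_labels(spec: GeneratorSpec) -> dict[str, str]:
    """ROI -> first-layer community truth (super-modules merge their blocks)."""
    block_super = {}
    for sup in spec.supermodules:
        for b in sup.member_blocks:
            block_super[b] = sup.name
    out = {}
    for m in spec.modules:
        label = block_super.get(m.name, m.name)
        for roi in m.roi_names:
            out[roi] = label
    return out


def planted_final_labels(spec: GeneratorSpec) -> dict[str, str]:
    """ROI -> final (second-layer) community truth: the factor blocks."""
    return spec.block_of()


def planted_hub_pairs(spec: GeneratorSpec, meta: ROIMetadata) -> set[str]:
    """Collapsed pair labels of the planted hub pairs."""
    return {meta.pair_label(h) for h in spec.hub_names}


# ---------------------------------------------------------------------------
# time series


def _bridged_rois(spec: GeneratorSpec) -> set[str]:
    block_members = {m.name: m.roi_names for m in spec.modules}
    out: set[str] = set()
    for sup in spec.supermodules:
        for a, b in sup.bridge_pairs(block_members):
            out.update((a, b))
    return out


def homolog_model_correlation(spec: GeneratorSpec, left: str, right: str) -> float:
    """Model-implied marginal correlation between a bilateral pair.

    Closed form of the linear factor model for non-hub ROIs: shared variance
    is the coupled pair factor plus the module factor when both members load
    on the same one; total variance adds per-ROI factor loadings, any bridge
    coupling, and the stationary AR(1) noise variance
    ``noise_sd^2 / (1 - ar^2)``.
    """
    block = spec.block_of()
    loading = {m.name: m.loading for m in spec.modules}
    bridge_loading = {}
    for sup in spec.supermodules:
        for b in sup.member_blocks:
            bridge_loading[b] = sup.loading
    bridged = _bridged_rois(spec)

    def own_variance(name: str) -> float:
        b = block[name]
        var = loading[b] ** 2
        if name in bridged:
            var += bridge_loading[b] ** 2
        return var

    bl, br = block[left], block[right]
    shared = spec.homolog_coupling**2
    if bl == br:
        shared += loading[bl] ** 2
    noise_var = spec.noise_sd**2 / (1 - spec.ar_coefficient**2)
    c2 = spec.homolog_coupling**2
    return shared / math.sqrt(
        (own_variance(left) + c2 + noise_var) * (own_variance(right) + c2 + noise_var)
    )


def _hub_targets(spec: GeneratorSpec, meta: ROIMetadata) -> dict[str, tuple[str, ...]]:
    """Foreign factor blocks each hub loads on; pair members share targets."""
    block = spec.block_of()
    # hubs bridge only sizeable modules: bridging a small module with a
    # planted hub would fuse the two communities outright
    block_names = [m.name for m in spec.modules if len(m.roi_names) >= 8]
    if not block_names:
        block_names = [m.name for m in spec.modules]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    targets: dict[str, tuple[str, ...]] = {}
    by_label: dict[str, list[str]] = {}
    for h in spec.hub_names:
        by_label.setdefault(meta.pair_label(h), []).append(h)
    for label in sorted(by_label):
        members = by_label[label]
        own = {block[m] for m in members}
        candidates = [b for b in block_names if b not in own]
        k = min(spec.hub_k, len(candidates))
        chosen = tuple(rng.choice(candidates, size=k, replace=False))
        for m in members:
            targets[m] = chosen
    return targets


def generate_timeseries(meta: ROIMetadata, spec: GeneratorSpec) -> list[ROITimeSeries]:
    """Simulate the cohort; identical (meta, spec) gives identical output."""
    block = spec.block_of()
    missing = [n for n in meta.names if n not in block]
    if missing:
        raise ConfigurationError(f"ROIs not covered by any module: {missing[:5]}...")
    extra = set(block) - set(meta.names)
    if extra:
        raise ConfigurationError(f"module ROIs absent from metadata: {sorted(extra)[:5]}")

    loading = {m.name: m.loading for m in spec.modules}
    pair_of: dict[str, int] = {}
    for pid, (ln, rn) in enumerate(meta.pairs()):
        pair_of[ln] = pid
        pair_of[rn] = pid
    hub_targets = _hub_targets(spec, meta)

    block_members = {m.name: m.roi_names for m in spec.modules}
    bridge_of: dict[str, int] = {}
    bridge_strength: dict[str, float] = {}
    n_bridges = 0
    for sup in spec.supermodules:
        for a, b in sup.bridge_pairs(block_members):
            bridge_of[a] = bridge_of[b] = n_bridges
            bridge_strength[a] = bridge_strength[b] = sup.loading
            n_bridges += 1

    names = meta.names
    T = spec.n_timepoints
    n_ext = T + _AR_BURN_IN
    block_names = [m.name for m in spec.modules]
    n_pairs = len(meta.pairs())

    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects + 1)[1:]
    out = []
    for s_idx, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        f_block = {b: rng.standard_normal(n_ext) for b in block_names}
        f_bridge = rng.standard_normal((n_bridges, n_ext)) if n_bridges else None
        g_pair = rng.standard_normal((n_pairs, n_ext)) if n_pairs else None
        eps = rng.normal(0.0, spec.noise_sd, size=(n_ext, len(names)))
        noise = lfilter([1.0], [1.0, -spec.ar_coefficient], eps, axis=0)

        X = np.empty((n_ext, len(names)))
        for j, name in enumerate(names):
            b = block[name]
            sig = loading[b] * f_block[b]
            if name in bridge_of:
                sig = sig + bridge_strength[name] * f_bridge[bridge_of[name]]
            if name in pair_of and spec.homolog_coupling > 0:
                sig = sig + spec.homolog_coupling * g_pair[pair_of[name]]
            for tgt in hub_targets.get(name, ()):
                sig = sig + spec.hub_loading * f_block[tgt]
            X[:, j] = sig + noise[:, j]
        X = X[_AR_BURN_IN:]
        X = X - X.mean(axis=0)
        X = X / X.std(axis=0)
        out.append(ROITimeSeries(f"sub{s_idx:02d}", X, tuple(names)))
    return out


# ---------------------------------------------------------------------------
# parcellation overlap


@dataclass(frozen=True)
class ParcellationOverlap:
    """Voxel overlap counts between voxelwise networks (rows) and ROIs (cols)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ConfigurationError("overlap counts must be non-negative")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="network")

    @classmethod
    def from_tsv(cls, path) -> "ParcellationOverlap":
        return cls(pd.read_csv(path, sep="\t", index_col="network"))


def planted_networks_from_metadata(meta: ROIMetadata) -> dict[str, set[str]]:
    """Pair-closed planted networks: twin ``_L``/``_R`` groups are merged so
    every network holds both members of each of its bilateral pairs."""
    nets: dict[str, set[str]] = {}
    for name, group in meta.groups.items():
        base = group[:-2] if group.endswith(("_L", "_R")) else group
        nets.setdefault(base, set()).add(name)
    return nets


def generate_overlap_table(
    meta: ROIMetadata,
    planted_networks: Mapping[str, set[str]],
    jitter: float = 0.0,
    seed: int = 0,
    voxels_per_roi: int = 100,
) -> ParcellationOverlap:
    """Emit a network x ROI voxel-count table around planted memberships.

    Each ROI's voxels go to its planted network, except a ``jitter`` fraction
    redistributed across the other networks at random. ROIs outside every
    planted network get an all-zero column.
    """
    if not 0 <= jitter < 1:
        raise ConfigurationError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    networks = sorted(planted_networks)
    counts = pd.DataFrame(0, index=networks, columns=meta.names, dtype=int)
    owner = {}
    for net, rois in planted_networks.items():
        for r in rois:
            if r in owner:
                raise ConfigurationError(f"ROI {r!r} planted in two networks")
            owner[r] = net
    for roi in meta.names:
        if roi not in owner:
            continue
        total = int(rng.integers(int(0.8 * voxels_per_roi), int(1.2 * voxels_per_roi) + 1))
        spill = int(round(jitter * total))
        counts.loc[owner[roi], roi] = total - spill
        others = [n for n in networks if n != owner[roi]]
        if spill and others:
            alloc = rng.multinomial(spill, np.full(len(others), 1 / len(others)))
            for net, c in zip(others, alloc):
                counts.loc[net, roi] += int(c)
    return ParcellationOverlap(counts)
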