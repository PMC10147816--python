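"""ROI atlas metadata: identity, hemisphere and bilateral-homolog structure.

The pipeline operates on a fixed list of atlas regions (ROIs). Each ROI has a
stable integer id, a name, a hemisphere label (``left``/``right``/``midline``),
an optional bilateral-pair id shared by exactly the left and right instance of
the same anatomical region, and an anatomical group label. ROI order is the
single source of truth: every matrix downstream is stored in metadata order and
no name-based reordering happens at compute time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

HEMISPHERES = ("left", "right", "midline")

_COLUMNS = ["roi_id", "name", "hemisphere", "pair_id", "group"]


@dataclass(frozen=True)
class ROIMetadata:
    """Immutable table of ROI identity and bilateral-pair structure.

    Parameters
    ----------
    table
        DataFrame with columns ``roi_id, name, hemisphere, pair_id, group``;
        ``pair_id`` is a nullable integer shared by the two members of a
        bilateral homolog pair.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ConfigurationError(f"metadata missing columns: {missing}")
        t = t[_COLUMNS].reset_index(drop=True)
        ids = t["roi_id"].to_numpy()
        if sorted(ids) != list(range(len(t))):
            raise ConfigurationError(
                "roi_id values must be unique and contiguous from 0"
            )
        t = t.sort_values("roi_id").reset_index(drop=True)
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ConfigurationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].tolist()
            raise ConfigurationError(f"duplicate ROI names: {dup}")
        for pid, grp in t.dropna(subset=["pair_id"]).groupby("pair_id"):
            if len(grp) != 2 or set(grp["hemisphere"]) != {"left", "right"}:
                raise ConfigurationError(
                    f"pair_id {pid} must link exactly one left and one right ROI"
                )
        object.__setattr__(self, "table", t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        """ROI names in roi_id order."""
        return self.table["name"].tolist()

    @property
    def groups(self) -> dict[str, str]:
        """name -> anatomical group label."""
        return dict(zip(self.table["name"], self.table["group"]))

    def pairs(self) -> list[tuple[str, str]]:
        """Bilateral pairs as (left name, right name), ordered by pair_id."""
        out = []
        paired = self.table.dropna(subset=["pair_id"])
        for _, grp in paired.groupby("pair_id", sort=True):
            left = grp.loc[grp["hemisphere"] == "left", "name"].item()
            right = grp.loc[grp["hemisphere"] == "right", "name"].item()
            out.append((left, right))
        return out

    def pair_label(self, name: str) -> str:
        """Collapsed label for a ROI: the shared stem for pair members.

        Pair members are named ``<stem>_L`` / ``<stem>_R``; midline ROIs keep
        their own name.
        """
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(name)
        if pd.isna(row["pair_id"].item()):
            return name
        if name.endswith(("_L", "_R")):
            return name[:-2]
        return name

    def midline_names(self) -> list[str]:
        return self.table.loc[
            self.table["hemisphere"] == "midline", "name"
        ].tolist()

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["pair_id"] = t["pair_id"].astype("Int64")
        t.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ROIMetadata":
        t = pd.read_csv(path, sep="\t", dtype={"name": str, "group": str})
        t["pair_id"] = t["pair_id"].astype("Float64")
        return cls(t)
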