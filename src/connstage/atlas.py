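"""Region atlas for whole-brain structural connectomes.

The default parcellation is the 82-region Desikan-Killiany scheme used
throughout the package: 34 cortical regions per hemisphere plus 7
subcortical grey-matter structures per hemisphere (68 + 14 = 82 nodes).
Region indices are 0-based and contiguous; atlas files declaring 1-based
ids (``# index_base: 1`` header) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["RegionAtlas", "default_atlas", "DK_CORTICAL_LABELS", "DK_SUBCORTICAL_LABELS"]

DK_CORTICAL_LABELS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

DK_SUBCORTICAL_LABELS = [
    "thalamus", "caudate", "putamen", "pallidum",
    "accumbens", "hippocampus", "amygdala",
]

_HEMISPHERES = ("left", "right", "midline")
_TISSUES = ("cortical", "subcortical")


@dataclass(frozen=True)
class RegionAtlas:
    """Table of grey-matter regions defining the connectome node order.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``region_id`` (0-based contiguous int), ``label`` (unique
        str), ``hemisphere`` (left/right/midline) and ``tissue_class``
        (cortical/subcortical), one row per node.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_id", "label", "hemisphere", "tissue_class"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        ids = t["region_id"].to_numpy()
        if list(ids) != list(range(len(t))):
            raise ValueError("region_id must be 0-based and contiguous")
        if t["label"].duplicated().any():
            dups = t.loc[t["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate atlas labels: {dups}")
        bad_h = set(t["hemisphere"]) - set(_HEMISPHERES)
        if bad_h:
            raise ValueError(f"unknown hemisphere values: {sorted(bad_h)}")
        bad_t = set(t["tissue_class"]) - set(_TISSUES)
        if bad_t:
            raise ValueError(f"unknown tissue_class values: {sorted(bad_t)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    def index_of(self, label: str) -> int:
        hit = self.table.index[self.table["label"] == label]
        if len(hit) == 0:
            raise KeyError(f"unknown region label: {label!r}")
        return int(hit[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAtlas":
        """Read an atlas TSV; a ``# index_base: 1`` header shifts ids to 0-based."""
        path = Path(path)
        index_base = 0
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "index_base" in first:
            index_base = int(first.split(":")[1].strip())
        table = pd.read_csv(path, sep="\t", comment="#")
        if index_base:
            table = table.assign(region_id=table["region_id"] - index_base)
        return cls(table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_atlas() -> RegionAtlas:
    """The 82-region Desikan-Killiany atlas (68 cortical + 14 subcortical).

    Node order: left cortical (34), right cortical (34), left subcortical
    (7), right subcortical (7).
    """
    rows = []
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for lab in DK_CORTICAL_LABELS:
            rows.append((f"{prefix}.{lab}", hemi, "cortical"))
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for lab in DK_SUBCORTICAL_LABELS:
            rows.append((f"{prefix}.{lab}", hemi, "subcortical"))
    table = pd.DataFrame(rows, columns=["label", "hemisphere", "tissue_class"])
    table.insert(0, "region_id", range(len(table)))
    return RegionAtlas(table)
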