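"""Subject metadata table: clinical stages, covariates and scores.

Stages follow the clinical-staging model of early psychosis: HC
(healthy control), II (first psychotic episode), IIIa (incomplete
remission), IIIb (one relapse), IIIc (two or more relapses). Coarse
labels derive from the fine ones: EPP = II + III (all patients) and
III = IIIa + IIIb + IIIc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectTable", "STAGES", "STAGE_ORDER", "DEFAULT_COVARIATES"]

STAGES = ("HC", "II", "IIIa", "IIIb", "IIIc")
STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}

#: Covariates entered in every adjusted analysis: age, gender,
#: handedness and the scanner-upgrade flag.
DEFAULT_COVARIATES = ("age", "gender", "handedness", "scanner")

_CLINICAL_COLUMNS = (
    "processing_speed", "doi", "dup",
    "panss_pos", "panss_neg", "panss_gen", "panss_total",
    "gaf", "cpz",
)


@dataclass
class SubjectTable:
    """Per-subject clinical and demographic records.

    Required columns: ``subject_id``, ``group`` (one of HC/II/IIIa/IIIb/
    IIIc), ``age`` (years), ``gender`` (M/F), ``handedness`` (R/L),
    ``scanner`` (pre/post upgrade). Optional clinical columns:
    processing_speed (T-score), doi (years), dup (days), panss_*, gaf,
    cpz (mg/day); patient-only columns are NaN for controls.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"subject_id", "group", "age", "gender", "handedness", "scanner"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if t["subject_id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        bad = set(t["group"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        for col, levels in (("gender", {"M", "F"}), ("handedness", {"R", "L"}),
                            ("scanner", {"pre", "post"})):
            extra = set(t[col].dropna()) - levels
            if extra:
                raise ValueError(f"unknown {col} levels: {sorted(extra)}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def is_patient(self) -> np.ndarray:
        return (self.table["group"] != "HC").to_numpy()

    def coarse_group(self) -> pd.Series:
        """Collapse to the ordered three-level grouping HC < II < III."""
        g = self.table["group"].astype(str)
        return g.where(~g.str.startswith("III"), "III")

    def binary_group(self) -> pd.Series:
        """HC vs EPP (all patients)."""
        return self.table["group"].map(lambda s: "HC" if s == "HC" else "EPP")

    def covariate_matrix(self, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
        """Numeric covariate design (no intercept column).

        Categorical covariates are 0/1 indicators with fixed reference
        levels: gender F, handedness L, scanner pre-upgrade.
        """
        cols = {}
        t = self.table
        for cov in covariates:
            if cov == "gender":
                cols["gender_M"] = (t["gender"] == "M").astype(float)
            elif cov == "handedness":
                cols["handedness_R"] = (t["handedness"] == "R").astype(float)
            elif cov == "scanner":
                cols["scanner_post"] = (t["scanner"] == "post").astype(float)
            else:
                cols[cov] = pd.to_numeric(t[cov], errors="raise").astype(float)
        df = pd.DataFrame(cols, index=t.index)
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"missing covariate values in columns: {bad}")
        return df

    def subset(self, mask) -> "SubjectTable":
        mask = np.asarray(mask, dtype=bool)
        return SubjectTable(self.table.loc[mask].reset_index(drop=True))

    def stage_sizes(self) -> dict[str, int]:
        return {s: int((self.table["group"] == s).sum()) for s in STAGES}

    # ---- I/O ---------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubjectTable":
        t = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        return cls(t)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
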