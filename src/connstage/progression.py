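"""Ordered-progression analysis and vulnerable-subnetwork discovery.

The discovery pipeline tests whether connectivity deficits deepen along
the ordered clinical stages HC < II < III (stage III pooling IIIa/IIIb/
IIIc): a global Jonckheere-Terpstra (JT) trend analysis of whole-brain
measures, a per-region JT scan of nodal strength defining the
vulnerable node set (uncorrected p < alpha, with BH-FDR flags reported
alongside), the strength of the subnetwork spanned by those nodes, and
its coupling with processing speed and clinical variables.

All trend tests are run on covariate-residualised values by default
(age, gender, handedness, scanner); JT has no native covariate
adjustment, so adjustment happens in the residualisation step. A
raw-value mode is retained as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import CohortConnectomes
from .measures import cohort_nodal_strengths, subnetwork_strength
from .stats import (
    ancova_group_effect,
    bh_fdr,
    jonckheere_terpstra,
    pearson_correlation,
    residualize,
)
from .subjects import DEFAULT_COVARIATES, SubjectTable

__all__ = [
    "TrendScanResult",
    "global_progression",
    "nodal_jt_scan",
    "cognition_coupling",
    "clinical_correlates",
    "subject_subnetwork_strengths",
]

#: direction of the ordered alternative per global measure: connectivity
#: and microstructural coherence decrease along stages, diffusivity
#: increases.
MEASURE_DIRECTIONS = {
    "total_strength": "decreasing",
    "mean_gfa": "decreasing",
    "mean_adc": "increasing",
    "global_efficiency": "decreasing",
    "mean_clustering": "decreasing",
}

_ORDERED_COARSE = ("HC", "II", "III")


def _ordered_groups(values: np.ndarray, coarse: pd.Series):
    groups = []
    for g in _ORDERED_COARSE:
        sel = (coarse == g).to_numpy()
        if sel.sum() == 0:
            raise ValueError(f"collapsed group {g!r} is empty")
        groups.append(values[sel])
    return groups


def global_progression(
    measures: pd.DataFrame,
    subjects: SubjectTable,
    covariates=DEFAULT_COVARIATES,
    adjust: bool = True,
) -> pd.DataFrame:
    """JT trend and pairwise ANCOVA contrasts for each global measure.

    Parameters
    ----------
    measures : DataFrame
        One row per subject (aligned with ``subjects``), columns from
        ``MEASURE_DIRECTIONS`` (missing columns are skipped).
    subjects : SubjectTable
    adjust : bool
        Residualise on the covariates before testing (default).

    Returns
    -------
    DataFrame
        Tidy rows: measure, test ("JT" or a pairwise contrast),
        direction/contrast labels, n per group, statistic, p, d.
    """
    coarse = subjects.coarse_group()
    binary = subjects.binary_group()
    cov = subjects.covariate_matrix(covariates)
    contrasts = [
        ("HC_vs_EPP", binary, ("HC", "EPP")),
        ("HC_vs_II", coarse, ("HC", "II")),
        ("HC_vs_III", coarse, ("HC", "III")),
        ("II_vs_III", coarse, ("II", "III")),
    ]
    rows = []
    for measure, direction in MEASURE_DIRECTIONS.items():
        if measure not in measures.columns:
            continue
        y = measures[measure].to_numpy(dtype=float)
        if np.isnan(y).any():
            continue
        adj = residualize(y, cov) if adjust else y - y.mean()
        jt = jonckheere_terpstra(_ordered_groups(adj, coarse), direction)
        sizes = [int((coarse == g).sum()) for g in _ORDERED_COARSE]
        rows.append(
            {
                "measure": measure,
                "test": "JT",
                "contrast": "<".join(_ORDERED_COARSE),
                "direction": direction,
                "n_per_group": "/".join(map(str, sizes)),
                "statistic": jt.statistic,
                "p": jt.p_value,
                "d": float("nan"),
            }
        )
        for name, labels, pair in contrasts:
            sel = labels.isin(pair).to_numpy()
            eff = ancova_group_effect(
                y[sel], labels[sel], cov.loc[sel].reset_index(drop=True), order=list(pair)
            )
            rows.append(
                {
                    "measure": measure,
                    "test": "ANCOVA",
                    "contrast": name,
                    "direction": "two-sided",
                    "n_per_group": "/".join(map(str, eff.group_sizes)),
                    "statistic": float("nan"),
                    "p": eff.p_value,
                    "d": eff.cohens_d,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TrendScanResult:
    """Per-region JT scan outcome and the vulnerable node set."""

    node_stat: np.ndarray
    node_p: np.ndarray
    alpha: float
    vulnerable: list[int] = field(default_factory=list)
    fdr_significant: list[int] = field(default_factory=list)
    fdr_q: float = 0.05

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        n = len(self.node_p)
        df = pd.DataFrame(
            {
                "region_id": np.arange(n),
                "jt_statistic": self.node_stat,
                "jt_p": self.node_p,
                "vulnerable": np.isin(np.arange(n), self.vulnerable),
                "fdr_significant": np.isin(np.arange(n), self.fdr_significant),
            }
        )
        if labels is not None:
            df.insert(1, "label", labels)
        return df


def nodal_jt_scan(
    cohort: CohortConnectomes,
    subjects: SubjectTable,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    covariates=DEFAULT_COVARIATES,
    jt_on_residuals: bool = True,
    nodal_strengths: np.ndarray | None = None,
) -> TrendScanResult:
    """Per-region JT scan for ordered nodal-strength decrease.

    Each region's nodal strength (on the masked connectomes) is
    covariate-residualised and tested for a decreasing trend along
    HC < II < III. The vulnerable set collects regions with uncorrected
    p < alpha; BH-FDR flags at ``fdr_q`` are reported alongside but do
    not decide membership.

    ``nodal_strengths`` may be supplied precomputed (subjects x regions).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    S = (
        np.asarray(nodal_strengths, dtype=float)
        if nodal_strengths is not None
        else cohort_nodal_strengths(cohort)
    )
    if S.shape[0] != len(subjects):
        raise ValueError("strength matrix rows must match the subject table")
    coarse = subjects.coarse_group()
    cov = subjects.covariate_matrix(covariates)
    n_nodes = S.shape[1]
    stats = np.empty(n_nodes)
    pvals = np.empty(n_nodes)
    for j in range(n_nodes):
        y = S[:, j]
        adj = residualize(y, cov) if jt_on_residuals else y
        jt = jonckheere_terpstra(_ordered_groups(adj, coarse), "decreasing")
        stats[j], pvals[j] = jt.statistic, jt.p_value
    vulnerable = np.flatnonzero(pvals < alpha)
    flags, _ = bh_fdr(pvals, q=fdr_q)
    return TrendScanResult(
        node_stat=stats,
        node_p=pvals,
        alpha=alpha,
        vulnerable=vulnerable.tolist(),
        fdr_significant=np.flatnonzero(flags).tolist(),
        fdr_q=fdr_q,
    )


def subject_subnetwork_strengths(
    cohort: CohortConnectomes, nodes
) -> pd.DataFrame:
    """Per-subject strength within a node set and in the remainder.

    Cross-boundary edges count toward the remainder, so
    vulnerable + remainder = total strength for every subject.
    """
    rows = []
    for c in cohort:
        within, remainder = subnetwork_strength(c, nodes)
        rows.append(
            {
                "subject_id": c.subject_id,
                "vulnerable_strength": within,
                "remainder_strength": remainder,
                "total_strength": within + remainder,
            }
        )
    return pd.DataFrame(rows)


def cognition_coupling(
    subjects: SubjectTable,
    strengths: pd.DataFrame,
    score_column: str = "processing_speed",
) -> pd.DataFrame:
    """Correlate processing speed with total/vulnerable/remainder strength.

    Pearson r and p are computed separately within HC and within EPP.
    Groups with fewer than 3 scored subjects are skipped (NaN row).
    """
    if list(strengths["subject_id"]) != subjects.subject_ids:
        raise ValueError("strength table must align with the subject table")
    score = pd.to_numeric(subjects.table[score_column], errors="coerce").to_numpy()
    binary = subjects.binary_group()
    rows = []
    for grp in ("HC", "EPP"):
        sel = (binary == grp).to_numpy()
        for column in ("total_strength", "vulnerable_strength", "remainder_strength"):
            x = strengths[column].to_numpy(dtype=float)[sel]
            y = score[sel]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                r = p = float("nan")
            else:
                r, p = pearson_correlation(x[ok], y[ok])
            rows.append({"group": grp, "measure": column, "n": int(ok.sum()),
                         "r": r, "p": p})
    return pd.DataFrame(rows)


#: clinical variables screened against connectivity in patients.
CLINICAL_VARIABLES = (
    "doi", "dup", "panss_pos", "panss_neg", "panss_gen", "panss_total",
    "gaf", "cpz",
)


def clinical_correlates(
    subjects: SubjectTable,
    measures: pd.DataFrame,
    measure_columns=("total_strength", "vulnerable_strength", "mean_gfa", "mean_adc"),
    clinical_columns=CLINICAL_VARIABLES,
) -> pd.DataFrame:
    """Pearson screen of connectivity measures vs clinical variables.

    Patients only; missing clinical values (e.g. DUP, CPZ) are handled
    pairwise-complete, no imputation.
    """
    pat = subjects.is_patient()
    rows = []
    for m in measure_columns:
        if m not in measures.columns:
            continue
        x_all = measures[m].to_numpy(dtype=float)[pat]
        for cvar in clinical_columns:
            if cvar not in subjects.table.columns:
                continue
            y_all = pd.to_numeric(subjects.table[cvar], errors="coerce").to_numpy()[pat]
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            if ok.sum() < 3:
                r = p = float("nan")
            else:
                r, p = pearson_correlation(x_all[ok], y_all[ok])
            rows.append({"measure": m, "clinical": cvar, "n": int(ok.sum()),
                         "r": r, "p": p})
    return pd.DataFrame(rows)
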