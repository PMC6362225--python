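"""End-to-end orchestration of the staged-connectome analysis.

``run_full_analysis`` executes the whole pipeline on one cohort:
consistency mask -> per-subject network measures -> global ordered
progression -> nodal JT scan (vulnerable set) -> subnetwork strengths
and cognition coupling -> demographics comparison table -> sparse
discriminant staging of patients -> clinical correlates. Every output
is a tidy TSV (or JSON for nested results) under the configured output
directory, and the summary JSON is stamped with the config hash and
seed so reruns are verifiable.

Sensitivity subsets (scanner pre/post only, right-handed only) rerun
the same analyses on the filtered cohort; by default the consistency
mask of the full cohort is reused (``per_subset_mask`` switches to
recomputing it on the subset).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, default_atlas
from .connectome import CohortConnectomes, apply_mask_cohort, consistency_mask
from .measures import cohort_measures, cohort_nodal_strengths, hub_ranking
from .progression import (
    clinical_correlates,
    cognition_coupling,
    global_progression,
    nodal_jt_scan,
    subject_subnetwork_strengths,
)
from .slda import ldd_clinical_correlations, loocv_evaluate, SparseDiscriminantAnalysis
from .stats import chi_square_contingency, oneway_anova, logistic_domain_impairment
from .subjects import DEFAULT_COVARIATES, SubjectTable

logger = logging.getLogger("connstage")

__all__ = ["RunConfig", "run_full_analysis", "cohort_comparison_table"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (YAML/JSON loadable)."""

    connectomes_dir: str = ""
    gfa_dir: str | None = None
    adc_dir: str | None = None
    atlas_path: str | None = None
    subjects_path: str = ""
    output_dir: str = "connstage_out"
    mask_threshold: float = 0.5
    per_subset_mask: bool = False
    edge_average: str = "plain"
    covariates: tuple = DEFAULT_COVARIATES
    alpha: float = 0.05
    fdr_q: float = 0.05
    jt_enumeration_cap: int = 10**6
    jt_on_residuals: bool = True
    slda_ridge: float = 1e-3
    slda_sparsity: int = 15
    run_slda_loocv: bool = True
    include_path_measures: bool = True
    subset_scanner: str = "all"  # {pre, post, all}
    subset_handedness: str = "all"  # {R, all}
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.mask_threshold <= 1):
            raise ValueError("mask_threshold must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.subset_scanner not in ("pre", "post", "all"):
            raise ValueError("subset_scanner must be pre/post/all")
        if self.subset_handedness not in ("R", "all"):
            raise ValueError("subset_handedness must be R/all")
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------
# Demographics / clinical comparison table
# ---------------------------------------------------------------------

_CONTINUOUS = (
    "age", "gaf", "processing_speed", "doi", "dup",
    "panss_pos", "panss_neg", "panss_gen", "panss_total", "cpz",
)
_CATEGORICAL = ("gender", "handedness", "scanner")


def _contrast_groups(subjects: SubjectTable) -> list[tuple[str, list[str], pd.Series]]:
    coarse = subjects.coarse_group()
    binary = subjects.binary_group()
    fine = subjects.group
    return [
        ("HC/EPP", ["HC", "EPP"], binary),
        ("II/III", ["II", "III"], coarse),
        ("IIIa/IIIb/IIIc", ["IIIa", "IIIb", "IIIc"], fine),
    ]


def cohort_comparison_table(subjects: SubjectTable) -> pd.DataFrame:
    """Demographics table: group means (SD) or counts with test p-values.

    One-way ANOVA for continuous variables, chi-square for categorical,
    for the HC/EPP, II/III and IIIa/IIIb/IIIc contrasts. Variables
    absent from the table are skipped with a warning; groups without
    data (e.g. DOI in controls) yield NaN p for that contrast.
    """
    t = subjects.table
    rows = []
    for var in _CONTINUOUS:
        if var not in t.columns:
            warnings.warn(f"column {var!r} missing; skipped", stacklevel=2)
            continue
        vals = pd.to_numeric(t[var], errors="coerce")
        for cname, levels, labels in _contrast_groups(subjects):
            samples = [vals[(labels == g).to_numpy()].dropna().to_numpy() for g in levels]
            desc = "; ".join(
                f"{g}: {s.mean():.1f} ({s.std(ddof=1):.1f})" if len(s) > 1 else f"{g}: -"
                for g, s in zip(levels, samples)
            )
            if any(len(s) < 2 for s in samples):
                p = float("nan")
            else:
                _, p = oneway_anova(samples)
            rows.append({"variable": var, "kind": "continuous",
                         "contrast": cname, "summary": desc, "p": p})
    for var in _CATEGORICAL:
        if var not in t.columns:
            warnings.warn(f"column {var!r} missing; skipped", stacklevel=2)
            continue
        for cname, levels, labels in _contrast_groups(subjects):
            cats = sorted(t[var].dropna().unique())
            counts = np.array(
                [[int(((labels == g) & (t[var] == c)).sum()) for c in cats] for g in levels]
            )
            desc = "; ".join(
                f"{g}: " + "/".join(str(v) for v in row) for g, row in zip(levels, counts)
            )
            try:
                _, p = chi_square_contingency(counts)
            except ValueError:
                p = float("nan")
            rows.append({"variable": var, "kind": "categorical",
                         "contrast": cname, "summary": desc, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------

def _subset_mask(config: RunConfig, subjects: SubjectTable) -> np.ndarray:
    keep = np.ones(len(subjects), dtype=bool)
    if config.subset_scanner != "all":
        keep &= (subjects.table["scanner"] == config.subset_scanner).to_numpy()
    if config.subset_handedness != "all":
        keep &= (subjects.table["handedness"] == config.subset_handedness).to_numpy()
    return keep


def run_full_analysis(
    config: RunConfig,
    cohort: CohortConnectomes | None = None,
    subjects: SubjectTable | None = None,
) -> dict:
    """Execute the full analysis and write all artifacts.

    ``cohort``/``subjects`` may be passed in memory; otherwise they are
    read from the configured paths. Returns the summary dictionary
    (also written to ``<output_dir>/summary.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load_inputs"
    try:
        if cohort is None:
            atlas = (
                RegionAtlas.from_tsv(config.atlas_path)
                if config.atlas_path
                else default_atlas()
            )
            cohort = CohortConnectomes.from_directory(
                config.connectomes_dir, atlas=atlas,
                gfa_dir=config.gfa_dir, adc_dir=config.adc_dir,
            )
        if subjects is None:
            subjects = SubjectTable.from_tsv(config.subjects_path)
        if cohort.subject_ids != subjects.subject_ids:
            raise ValueError("connectome subject ids do not match the subject table")

        stage = "consistency_mask"
        full_mask = consistency_mask(cohort, config.mask_threshold)

        stage = "subset_filter"
        keep = _subset_mask(config, subjects)
        covariates = list(config.covariates)
        if keep.sum() < len(keep):
            logger.info("subset filter keeps %d/%d subjects", keep.sum(), len(keep))
            cohort = cohort.subset(keep)
            subjects = subjects.subset(keep)
            # a covariate that the subset fixes to one level is no longer
            # estimable and is dropped from the adjustment set
            if config.subset_handedness != "all" and "handedness" in covariates:
                covariates.remove("handedness")
            if config.subset_scanner != "all" and "scanner" in covariates:
                covariates.remove("scanner")
            mask = (
                consistency_mask(cohort, config.mask_threshold)
                if config.per_subset_mask
                else full_mask
            )
        else:
            mask = full_mask
        mask.to_tsv(out / "mask.tsv")
        masked = apply_mask_cohort(cohort, mask)

        stage = "network_measures"
        measures = cohort_measures(
            masked, edge_average=config.edge_average,
            include_paths=config.include_path_measures,
        )
        measures.to_csv(out / "network_measures.tsv", sep="\t", index=False)

        stage = "global_progression"
        prog = global_progression(measures, subjects, covariates)
        prog.to_csv(out / "global_progression.tsv", sep="\t", index=False)

        stage = "nodal_jt_scan"
        strengths = cohort_nodal_strengths(masked)
        scan = nodal_jt_scan(
            masked, subjects, alpha=config.alpha, fdr_q=config.fdr_q,
            covariates=covariates, jt_on_residuals=config.jt_on_residuals,
            nodal_strengths=strengths,
        )
        scan_df = scan.to_frame(cohort.atlas.labels)
        scan_df.to_csv(out / "nodal_scan.tsv", sep="\t", index=False)

        stage = "hub_ranking"
        hubs = hub_ranking(masked, reference_nodes=scan.vulnerable)
        hubs.to_csv(out / "hub_ranking.tsv", sep="\t", index=False)

        stage = "subnetwork_strengths"
        strengths_df = subject_subnetwork_strengths(masked, scan.vulnerable)
        strengths_df.to_csv(out / "subnetwork_strengths.tsv", sep="\t", index=False)

        stage = "cognition_coupling"
        coupling = cognition_coupling(subjects, strengths_df)
        coupling.to_csv(out / "cognition_coupling.tsv", sep="\t", index=False)

        stage = "cognitive_impairment"
        impair = logistic_domain_impairment(
            subjects.table[["processing_speed"]].rename(
                columns={"processing_speed": "processing_speed"}
            ),
            subjects.binary_group(),
            subjects.covariate_matrix(covariates),
        )
        impair.to_csv(out / "cognitive_impairment.tsv", sep="\t", index=False)

        stage = "comparison_table"
        table1 = cohort_comparison_table(subjects)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)

        stage = "slda"
        pat = subjects.is_patient()
        slda_summary: dict = {}
        if pat.sum() >= 8 and len(set(subjects.group[pat])) >= 2:
            X = strengths[pat]
            labels = subjects.group[pat].to_numpy()
            model = SparseDiscriminantAnalysis(
                X, labels, ridge=config.slda_ridge, sparsity=config.slda_sparsity
            )
            res = model.fit()
            res.loadings_frame(cohort.atlas.labels).to_csv(
                out / "slda_loadings.tsv", sep="\t", index=False
            )
            scores = res.training_scores()
            scores_df = pd.DataFrame(
                scores, columns=[f"LDD{q + 1}" for q in range(scores.shape[1])]
            )
            scores_df.insert(0, "subject_id", np.array(subjects.subject_ids)[pat])
            scores_df["group"] = labels
            scores_df.to_csv(out / "slda_scores.tsv", sep="\t", index=False)
            ldd_corr = ldd_clinical_correlations(
                scores, subjects.table.loc[pat].reset_index(drop=True)
            )
            ldd_corr.to_csv(out / "slda_clinical_correlations.tsv", sep="\t", index=False)
            if config.run_slda_loocv:
                ev = loocv_evaluate(
                    X, labels, ridge=config.slda_ridge, sparsity=config.slda_sparsity
                )
                slda_summary = ev.to_dict()
                with open(out / "slda_evaluation.json", "w") as fh:
                    json.dump(slda_summary, fh, indent=2)

        stage = "clinical_correlates"
        merged = measures.merge(strengths_df[["subject_id", "vulnerable_strength"]],
                                on="subject_id")
        correlates = clinical_correlates(subjects, merged)
        correlates.to_csv(out / "clinical_correlates.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(subjects),
        "stage_sizes": subjects.stage_sizes(),
        "n_retained_edges": mask.n_retained_edges,
        "n_vulnerable": len(scan.vulnerable),
        "vulnerable_nodes": list(scan.vulnerable),
        "n_fdr_significant": len(scan.fdr_significant),
        "global_jt_p": {
            row["measure"]: row["p"]
            for _, row in prog[prog["test"] == "JT"].iterrows()
        },
        "cognition_coupling": coupling.to_dict(orient="records"),
        "slda": slda_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
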