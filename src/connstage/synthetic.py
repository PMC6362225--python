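"""Synthetic staged-psychosis connectome cohorts with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a shared distance-decay edge template over 82 regions; subject
connectomes as log-normally perturbed integer streamline counts; a
planted vulnerable node set whose internal edges attenuate
multiplicatively along the ordered stages (HC < II < III); optional
class-specific profiles (IIIa distinct, IIIb/IIIc shared) carved out of
the vulnerable set for discriminant separability; diffuse per-stage
gFA/ADC shifts; demographic covariates matched to the reference cohort
marginals (76/25/17/17/12 with cohort-typical age, gender, handedness
and scanner proportions) with real covariate effects on the weights;
and a processing-speed score coupled to vulnerable-subnetwork strength.

Everything is deterministic given the seed, and the planted truth is
returned so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import default_atlas
from .connectome import CohortConnectomes, Connectome
from .subjects import SubjectTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "EdgeTemplate",
    "build_edge_template",
    "generate_cohort",
    "truth_report",
]

#: stage-severity ranks scaling the planted attenuation.
STAGE_RANKS = {"HC": 0.0, "II": 0.5, "IIIa": 1.0, "IIIb": 1.0, "IIIc": 1.0}

# reference-cohort marginals per stage (counts are proportions when the
# configured group sizes differ from the defaults)
_AGE = {"HC": (26.8, 6.1), "II": (23.5, 4.6), "IIIa": (26.0, 6.3),
        "IIIb": (26.6, 6.1), "IIIc": (30.2, 7.1)}
_MALE_FRAC = {"HC": 48 / 76, "II": 17 / 25, "IIIa": 12 / 17,
              "IIIb": 12 / 17, "IIIc": 8 / 12}
_RIGHT_FRAC = {"HC": 66 / 76, "II": 25 / 25, "IIIa": 14 / 17,
               "IIIb": 15 / 17, "IIIc": 10 / 12}
_PRE_FRAC = {"HC": 63 / 76, "II": 15 / 25, "IIIa": 10 / 17,
             "IIIb": 12 / 17, "IIIc": 9 / 12}
_DOI = {"II": (0.8, 1.0), "IIIa": (1.9, 1.6), "IIIb": (4.0, 3.3), "IIIc": (7.4, 5.9)}
_DUP = {"II": (107, 233), "IIIa": (320, 545), "IIIb": (585, 963), "IIIc": (1282, 1433)}
_GAF = {"HC": (83, 5), "II": (58, 12), "IIIa": (55, 9), "IIIb": (63, 9), "IIIc": (60, 10)}
_PANSS = {
    "panss_pos": {"II": (13, 5), "IIIa": (14, 4), "IIIb": (12, 4), "IIIc": (13, 5)},
    "panss_neg": {"II": (15, 6), "IIIa": (17, 7), "IIIb": (13, 4), "IIIc": (16, 5)},
    "panss_gen": {"II": (35, 11), "IIIa": (35, 9), "IIIb": (30, 7), "IIIc": (30, 8)},
    "panss_total": {"II": (63, 19), "IIIa": (66, 16), "IIIb": (55, 14), "IIIc": (58, 14)},
}
_CPZ = {"II": (420.5, 218.5), "IIIa": (403.6, 273.1),
        "IIIb": (452.9, 324.2), "IIIc": (367.9, 222.4)}


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions.

    ``delta_max`` is the maximal log-attenuation of vulnerable-internal
    edge weights (applied as exp(-delta_max * stage_rank) with ranks
    HC 0, II 0.5, III* 1.0); ``profile_effect`` is the extra attenuation
    on the class-profile halves of the vulnerable set. ``noise_sd`` is
    the per-edge subject-level log-normal SD. Cognition: processing
    speed = group base (53 HC / 41 patients) + cognition_beta1 *
    z(vulnerable strength) + N(0, cognition_noise_sd).
    """

    group_sizes: dict = field(default_factory=lambda: {
        "HC": 76, "II": 25, "IIIa": 17, "IIIb": 17, "IIIc": 12})
    n_regions: int = 82
    density: float = 0.30
    vulnerable_set_size: int = 22
    delta_max: float = 0.15
    stage_profiles: bool = True
    profile_effect: float = 0.30
    gfa_effect: float = 0.004
    adc_effect: float = 8.0e-6
    cognition_beta1: float = 5.0
    cognition_noise_sd: float = 9.0
    speed_base_hc: float = 53.0
    speed_base_patient: float = 41.0
    age_slope: float = -0.005
    scanner_factor: float = 1.03
    noise_sd: float = 0.25
    gfa_subject_sd: float = 0.01
    gfa_edge_sd: float = 0.01
    adc_subject_sd: float = 2.0e-5
    adc_edge_sd: float = 1.0e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        if not (0 < self.density < 1):
            raise ValueError("density must lie in (0, 1)")
        if self.delta_max < 0:
            raise ValueError("delta_max must be >= 0")
        if not (0 < self.vulnerable_set_size <= self.n_regions):
            raise ValueError("vulnerable_set_size out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    vulnerable_nodes: list[int]
    stage_profiles: dict
    cognition_rho: float
    config: SyntheticConfig

    def to_dict(self) -> dict:
        return {
            "vulnerable_nodes": list(self.vulnerable_nodes),
            "stage_profiles": {k: list(v) for k, v in self.stage_profiles.items()},
            "cognition_rho": self.cognition_rho,
            "config": asdict(self.config),
        }


@dataclass
class EdgeTemplate:
    """Cohort-shared base network: geometry, presence, base edge values."""

    positions: np.ndarray
    presence: np.ndarray
    base_weights: np.ndarray
    base_gfa: np.ndarray
    base_adc: np.ndarray


def build_edge_template(config: SyntheticConfig, seed: int | None = None) -> EdgeTemplate:
    """Distance-decay random template calibrated to the target density.

    Node positions are uniform in the unit cube; edge presence follows a
    Bernoulli with probability min(1, c * exp(-d / 0.35)), with c chosen
    by bisection so the expected density equals the target. Base weights
    are proximity-scaled log-normal counts; base gFA is truncated normal
    (0.50, 0.05) in [0, 1] and base ADC normal (8.0e-4, 0.5e-4) mm^2/s.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_regions
    pos = rng.uniform(size=(n, 3))
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(n, k=1)
    decay = np.exp(-d[iu] / 0.35)

    def mean_density(c):
        return float(np.minimum(1.0, c * decay).mean())

    lo, hi = 0.0, 1.0
    while mean_density(hi) < config.density:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("density target unreachable by calibration")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_density(mid) < config.density:
            lo = mid
        else:
            hi = mid
    prob = np.minimum(1.0, hi * decay)
    present_u = rng.uniform(size=prob.shape) < prob

    # proximity-scaled log-normal counts, heavier for short connections
    d_u = d[iu]
    mu = 2.0 + 2.5 * (1.0 - d_u / d_u.max())
    w_u = np.round(np.exp(mu + 0.9 * rng.standard_normal(prob.shape)))
    w_u = np.clip(w_u, 1, None) * present_u

    gfa_u = np.clip(0.50 + 0.05 * rng.standard_normal(prob.shape), 0.0, 1.0) * present_u
    adc_u = np.clip(8.0e-4 + 0.5e-4 * rng.standard_normal(prob.shape), 1e-5, None) * present_u

    def sym(u_vals):
        m = np.zeros((n, n))
        m[iu] = u_vals
        return m + m.T

    presence = sym(present_u.astype(float)) > 0
    return EdgeTemplate(
        positions=pos,
        presence=presence,
        base_weights=sym(w_u),
        base_gfa=sym(gfa_u),
        base_adc=sym(adc_u),
    )


def _stage_list(config: SyntheticConfig) -> list[str]:
    out = []
    for stage in ("HC", "II", "IIIa", "IIIb", "IIIc"):
        out.extend([stage] * int(config.group_sizes.get(stage, 0)))
    return out


def _exact_binary(rng, n, frac, a, b):
    """n draws with an exact count of level ``a`` (round(frac * n))."""
    k = int(round(frac * n))
    vals = np.array([a] * k + [b] * (n - k), dtype=object)
    rng.shuffle(vals)
    return vals


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[CohortConnectomes, SubjectTable, SyntheticTruth]:
    """Simulate a full cohort: connectomes, metadata and planted truth."""
    config = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    template = build_edge_template(config, seed=int(rng.integers(2**31)))
    n = config.n_regions
    iu = np.triu_indices(n, k=1)
    present_u = template.presence[iu]
    w_base_u = template.base_weights[iu]

    vulnerable = np.sort(rng.choice(n, size=config.vulnerable_set_size, replace=False))
    vuln_mask = np.zeros(n, dtype=bool)
    vuln_mask[vulnerable] = True
    vuln_edge_u = vuln_mask[iu[0]] & vuln_mask[iu[1]]

    profiles: dict[str, list[int]] = {}
    profile_edges = {}
    if config.stage_profiles:
        half = config.vulnerable_set_size // 2
        set_a = vulnerable[:half]
        set_b = vulnerable[half:]
        profiles = {"IIIa": set_a.tolist(), "IIIb": set_b.tolist(), "IIIc": set_b.tolist()}
        for cls_, nodes in profiles.items():
            m = np.zeros(n, dtype=bool)
            m[nodes] = True
            profile_edges[cls_] = m[iu[0]] & m[iu[1]]

    stages = _stage_list(config)
    n_subj = len(stages)

    # ---- covariates with reference-cohort marginals -----------------
    rows = []
    for i, stage in enumerate(stages):
        rows.append({"subject_id": f"S{i + 1:03d}", "group": stage})
    table = pd.DataFrame(rows)
    age = np.empty(n_subj)
    gender = np.empty(n_subj, dtype=object)
    hand = np.empty(n_subj, dtype=object)
    scanner = np.empty(n_subj, dtype=object)
    for stage in config.group_sizes:
        sel = np.flatnonzero(table["group"] == stage)
        m, s = _AGE[stage]
        age[sel] = np.clip(m + s * rng.standard_normal(len(sel)), 18.0, None)
        gender[sel] = _exact_binary(rng, len(sel), _MALE_FRAC[stage], "M", "F")
        hand[sel] = _exact_binary(rng, len(sel), _RIGHT_FRAC[stage], "R", "L")
        scanner[sel] = _exact_binary(rng, len(sel), _PRE_FRAC[stage], "pre", "post")
    table["age"] = np.round(age, 1)
    table["gender"] = gender
    table["handedness"] = hand
    table["scanner"] = scanner

    # ---- connectomes -------------------------------------------------
    mean_age = float(age.mean())
    conns = []
    vuln_strength = np.empty(n_subj)
    clipped = 0
    for i, stage in enumerate(stages):
        rank = STAGE_RANKS[stage]
        log_factor = np.zeros(present_u.shape)
        log_factor[vuln_edge_u] -= config.delta_max * rank
        if config.stage_profiles and stage in profile_edges:
            log_factor[profile_edges[stage]] -= config.profile_effect
        cov_factor = config.age_slope * (age[i] - mean_age)
        if scanner[i] == "post":
            cov_factor += np.log(config.scanner_factor)
        eps = config.noise_sd * rng.standard_normal(present_u.shape)
        w_u = np.round(w_base_u * np.exp(eps + log_factor + cov_factor)) * present_u
        neg = w_u < 0
        clipped += int(neg.sum())
        w_u = np.clip(w_u, 0, None)

        sup = w_u > 0
        gfa_u = (
            template.base_gfa[iu]
            - config.gfa_effect * rank
            + config.gfa_subject_sd * rng.standard_normal()
            + config.gfa_edge_sd * rng.standard_normal(present_u.shape)
        )
        gfa_u = np.clip(gfa_u, 0.0, 1.0) * sup
        adc_u = (
            template.base_adc[iu]
            + config.adc_effect * rank
            + config.adc_subject_sd * rng.standard_normal()
            + config.adc_edge_sd * rng.standard_normal(present_u.shape)
        )
        adc_u = np.clip(adc_u, 1e-6, None) * sup

        w = np.zeros((n, n))
        w[iu] = w_u
        w = w + w.T
        gfa = np.zeros((n, n))
        gfa[iu] = gfa_u
        gfa = gfa + gfa.T
        adc = np.zeros((n, n))
        adc[iu] = adc_u
        adc = adc + adc.T
        conns.append(Connectome(w, gfa=gfa, adc=adc, subject_id=f"S{i + 1:03d}"))
        vuln_strength[i] = w_u[vuln_edge_u].sum()

    # ---- cognition and clinical scores ------------------------------
    # Couple speed to the *idiosyncratic* vulnerable-subnetwork variation:
    # regress out stage, age and scanner so the planted correlation is
    # selective (the remainder network shares the covariate structure but
    # not this residual).
    stage_dummies = np.column_stack(
        [(np.array(stages) == s).astype(float) for s in ("II", "IIIa", "IIIb", "IIIc")]
    )
    design = np.column_stack(
        [np.ones(n_subj), age, (scanner == "post").astype(float), stage_dummies]
    )
    coef, *_ = np.linalg.lstsq(design, vuln_strength, rcond=None)
    resid = vuln_strength - design @ coef
    z_vuln = resid / resid.std(ddof=0)
    is_pat = np.array([s != "HC" for s in stages])
    base = np.where(is_pat, config.speed_base_patient, config.speed_base_hc)
    speed = base + config.cognition_beta1 * z_vuln \
        + config.cognition_noise_sd * rng.standard_normal(n_subj)
    table["processing_speed"] = np.round(speed, 1)

    def stage_draw(params, clip_lo=None, clip_hi=None):
        out = np.full(n_subj, np.nan)
        for stage, (m, s) in params.items():
            sel = np.flatnonzero(table["group"] == stage)
            v = m + s * rng.standard_normal(len(sel))
            if clip_lo is not None:
                v = np.clip(v, clip_lo, clip_hi)
            out[sel] = np.round(v, 2)
        return out

    table["doi"] = stage_draw(_DOI, clip_lo=0.05)
    table["dup"] = stage_draw(_DUP, clip_lo=1.0)
    table["gaf"] = stage_draw(_GAF, clip_lo=1, clip_hi=100)
    for col, params in _PANSS.items():
        table[col] = stage_draw(params, clip_lo=7 if col != "panss_total" else 30)
    table["cpz"] = stage_draw(_CPZ, clip_lo=0.0)

    # plant the reference missingness: DUP unknown for ~12/71 patients,
    # CPZ missing for unmedicated patients (~16/71)
    pat_idx = np.flatnonzero(is_pat)
    n_pat = len(pat_idx)
    miss_dup = rng.choice(pat_idx, size=min(int(round(12 * n_pat / 71)), n_pat), replace=False)
    table.loc[miss_dup, "dup"] = np.nan
    miss_cpz = rng.choice(pat_idx, size=min(int(round(16 * n_pat / 71)), n_pat), replace=False)
    table.loc[miss_cpz, "cpz"] = np.nan

    rho = config.cognition_beta1 / np.sqrt(
        config.cognition_beta1**2 + config.cognition_noise_sd**2
    )
    truth = SyntheticTruth(
        vulnerable_nodes=vulnerable.tolist(),
        stage_profiles=profiles,
        cognition_rho=float(rho),
        config=config,
    )
    cohort = CohortConnectomes(default_atlas() if n == 82 else _generic_atlas(n), conns)
    return cohort, SubjectTable(table), truth


def _generic_atlas(n: int):
    from .atlas import RegionAtlas

    table = pd.DataFrame(
        {
            "region_id": range(n),
            "label": [f"region{i:03d}" for i in range(n)],
            "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n)],
            "tissue_class": ["cortical"] * n,
        }
    )
    return RegionAtlas(table)


def truth_report(
    truth: SyntheticTruth,
    scan=None,
    model_eval=None,
    cognition=None,
) -> dict:
    """Score recovery of the planted structure.

    Parameters
    ----------
    scan : TrendScanResult, optional
        Vulnerable-set recovery -> sensitivity/specificity (NaN
        sensitivity when the planted set is empty).
    model_eval : DiscriminantEvaluation, optional
        sLDA error vs its baselines.
    cognition : DataFrame from cognition_coupling, optional
        Estimated vulnerable-subnetwork r minus the planted scale.
    """
    out: dict = {"n_vulnerable_planted": len(truth.vulnerable_nodes)}
    if scan is not None:
        n = len(scan.node_p)
        planted = set(truth.vulnerable_nodes)
        if max(planted, default=-1) >= n:
            raise ValueError("truth and scan describe different atlases")
        found = set(scan.vulnerable)
        tp = len(planted & found)
        fp = len(found - planted)
        tn = n - len(planted) - fp
        out["sensitivity"] = tp / len(planted) if planted else float("nan")
        out["specificity"] = tn / (n - len(planted)) if n > len(planted) else float("nan")
        out["n_vulnerable_found"] = len(found)
    if model_eval is not None:
        out["slda_loocv_error"] = model_eval.loocv_error
        out["slda_baseline_naive"] = model_eval.baseline_naive
        out["slda_baseline_chance"] = model_eval.baseline_chance
        out["slda_beats_naive"] = bool(
            model_eval.loocv_error < model_eval.baseline_naive
        )
    if cognition is not None:
        sel = cognition[(cognition["measure"] == "vulnerable_strength")]
        if len(sel):
            est = float(sel["r"].mean())
            out["cognition_r_estimated"] = est
            out["cognition_r_planted"] = truth.cognition_rho
            out["cognition_r_error"] = est - truth.cognition_rho
    return out
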