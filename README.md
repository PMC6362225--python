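# connstage

Analysis of structural brain connectomes across the clinical stages of
early psychosis. Patients after a first psychotic episode can be placed
on an illness continuum — stage II (first episode), IIIa (incomplete
remission), IIIb (one relapse), IIIc (multiple relapses) — and the
package asks whether white-matter connectivity deficits deepen along
that ordering, which brain regions carry the effect, and whether the
stages have distinguishable connectivity signatures.

It is written for researchers holding per-subject weighted, undirected
region-by-region connectivity matrices (streamline counts over an
82-region Desikan-Killiany parcellation, optionally with per-edge gFA
and ADC maps) plus a clinical metadata table. Because patient-level
neuroimaging cohorts of this kind are rarely shareable, the package
also ships a synthetic cohort generator that plants the relevant
structure (stage-ordered deficits on a vulnerable node set, covariate
confounds, cognition coupling) with known ground truth, so the whole
pipeline can be validated end to end.

## What it computes

1. **Consistency masking.** Edges present (w_ij > 0) in fewer than a
   fraction t of subjects (default t = 0.5) are discarded cohort-wide.
2. **Network measures.** Nodal strength s_i = Σ_j w_ij, total strength
   S = Σ_{i<j} w_ij, tract-average gFA/ADC over present edges, global
   efficiency with edge lengths 1/w_ij, Onnela weighted clustering, and
   strength-based hub ranking.
3. **Ordered-trend testing.** The Jonckheere-Terpstra (JT) statistic
   JT = Σ_{g<h} #{x∈g, y∈h : x < y} + ½·#ties over the ordered groups
   HC < II < III, applied to covariate-residualised measures (age,
   gender, handedness, scanner upgrade). Exact p by complete
   enumeration on small problems, tie-corrected normal approximation
   otherwise. ANCOVA contrasts report Cohen's d between covariate-only
   GLM residual distributions.
4. **Vulnerable subnetwork.** A per-region JT scan of nodal strength
   (decreasing alternative) defines the vulnerable set at uncorrected
   p < 0.05 with Benjamini-Hochberg flags reported alongside; the
   strength inside that set is correlated with processing speed within
   controls and patients separately.
5. **Sparse discriminant staging.** Sparse linear discriminant analysis
   by penalized optimal scoring over patients' nodal-strength profiles:
   Q = K−1 = 3 sparse discriminant directions (LDDs), each an
   elastic-net regression of optimal class scores with a budget of m
   nonzero loadings (default 15, ridge λ = 1e-3). Separability is
   quantified by leave-one-out nearest-centroid error against the
   chance (1 − 1/K) and majority-class baselines, the inter-class
   centroid distance matrix, and LDD correlations with duration of
   illness and processing speed.

## Worked example

```bash
connstage simulate --out demo --seed 7
cat > cfg.yaml <<EOF
connectomes_dir: demo/connectomes
gfa_dir: demo/gfa
adc_dir: demo/adc
atlas_path: demo/atlas.tsv
subjects_path: demo/subjects.tsv
output_dir: demo_out
seed: 7
EOF
connstage run --config cfg.yaml
```

prints

```
{
  "config_hash": "440ae926c80f5c04",
  "n_subjects": 147,
  "n_vulnerable": 23
}
```

i.e. the simulated cohort (76 controls, 71 patients staged 25/17/17/12)
yields 23 regions with a significant ordered nodal-strength decrease
(22 were planted). `demo_out/summary.json` holds the rest; on this
cohort the global JT p for total strength is 8.4e-07 (the planted
deficit deepens across stages), mean gFA decreases (p = 0.0089) and
mean ADC increases (p = 0.0030) along the ordering, and the sparse
discriminant model's LOOCV error is 0.54 versus the 0.65 naive and
0.75 chance baselines. Per-stage outputs (mask, measures, nodal scan,
subnetwork strengths, cognition correlations, demographics table,
discriminant loadings/scores/evaluation) are written as tidy TSV/JSON
under `demo_out/`.

The same pipeline runs on real data arranged in the documented layout:
one TSV matrix per subject (plus optional gFA/ADC directories), an
atlas TSV (region_id, label, hemisphere, tissue_class) and a subject
TSV (stage label, age, gender, handedness, scanner flag, clinical and
cognitive scores). Sensitivity subsets rerun everything on a filtered
cohort: `connstage run --config cfg.yaml --subset handedness=R`.

As a library, the discriminant component follows the Model/Results
convention:

```python
from connstage import SparseDiscriminantAnalysis
model = SparseDiscriminantAnalysis(nodal_strengths, stage_labels,
                                   ridge=1e-3, sparsity=15)
res = model.fit()
print(res.summary())
scores = res.project(nodal_strengths)
```

## Limitations

The package starts from connectivity matrices: tractography,
parcellation and any voxel-level processing are out of scope, as are
normalized rich-club curves and figure rendering. The synthetic
generator reproduces the statistical structure the analysis assumes,
not anatomical geometry — see `docs/methods.md` for exactly what
passing tests do and do not establish about real cohorts.
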