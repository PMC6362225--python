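# Methods

This note documents the models, conventions and numerical choices
behind `connstage`, what the synthetic cohort generator does and does
not emulate, and the design decisions taken where several reasonable
options existed.

## Data model and consistency masking

A subject's connectome is a symmetric nonnegative matrix of streamline
counts w_ij over an atlas (default: 82-region Desikan-Killiany, 68
cortical + 14 subcortical), with a zero diagonal. Optional per-edge
scalars — tract-average generalized fractional anisotropy (gFA,
unitless in [0, 1]) and apparent diffusion coefficient (ADC, mm²/s) —
are defined exactly on the support {w_ij > 0}.

Edge *presence* means a strictly positive count; that is the only
information a count matrix carries. The cohort consistency mask
retains edge (i, j) iff its presence frequency across subjects is at
least the threshold t (default 0.5), i.e. edges present in *less than*
t of subjects are discarded and ties at exactly t are kept. The mask
is computed once on the full analysis cohort (patients and controls
together); sensitivity subsets reuse it by default, with
`per_subset_mask` available to recompute per subset.

## Network measures

* Nodal strength s_i = Σ_j w_ij; total strength S = Σ_{i<j} w_ij
  (so Σ s_i = 2S exactly, a tested invariant).
* Tract-average gFA/ADC per subject: the *unweighted* mean of the
  per-edge scalar over the subject's present, retained edges. A
  streamline-count-weighted mean is available
  (`edge_average: count_weighted`); whether whole-brain tract averages
  should be count-weighted is genuinely open, so both are implemented
  and the plain mean — the simplest reading — is the default. With no
  surviving edges the averages are NaN (undefined), never zero.
* Global efficiency: edge lengths ℓ_ij = 1/w_ij on present edges;
  efficiency is the mean of 1/d_ij over ordered node pairs, where d_ij
  is the shortest ℓ-path length and unreachable pairs contribute 0.
* Weighted clustering: the Onnela geometric-mean form on weights
  normalized by the network maximum (the networkx implementation,
  cross-checked against a brute-force triangle oracle in the tests).
  Both path-measure definitions are the standard choices for
  streamline-weighted networks; binary variants are not provided.
* Hubs: nodes whose cohort-mean strength exceeds the across-node mean
  by more than one SD (factor configurable). The ranking reports the
  overlap of the hub set with any supplied reference set (count and
  fraction), e.g. the vulnerable set.

## Covariate adjustment and effect sizes

Every adjusted analysis uses the covariates age, gender, handedness
and a scanner-upgrade flag, coded as 0/1 indicators with fixed
reference levels (F, L, pre-upgrade). Adjustment is two-step:
least-squares residualisation of the measure on intercept + covariates
(no group term), then the statistic of interest on the residuals.
Cohen's d is the difference of group residual means over the pooled SD
with (n_a−1, n_b−1) weighting, first-listed group minus second —
positive d for HC-minus-patient reductions. The ANCOVA p-value is the
nested-model F-test of the group factor in y ~ group + covariates.
Rank-deficient designs abort with the collinear columns named; when a
sensitivity subset fixes a covariate to a single level (e.g.
right-handed only), that covariate is dropped from the adjustment set.

## Jonckheere-Terpstra testing

For groups in a hypothesised order, the statistic counts pairs (x in
an earlier group, y in a later group) with x < y, plus half the ties.
Decreasing alternatives reverse the group order. The null mean is
(N² − Σ n_g²)/4 and the variance uses the standard tie-corrected
formula; no continuity correction is applied. p-values are one-sided.

Exactness is decided by an enumeration cap rather than a sample-size
rule: when the multinomial count of distinct label assignments is at
most the cap (default 10⁶) the exact p is computed by complete
enumeration (so small fixtures are always exact), otherwise the normal
approximation is used. Constant data make the null SD zero; the test
then carries no information and p = 0.5 is returned by convention.

Because the JT test has no native covariate adjustment, the nodal scan
applies it to covariate-residualised nodal strengths by default
(`jt_on_residuals`, raw mode retained as a switch). The ordered
grouping collapses IIIa/IIIb/IIIc into stage III (HC < II < III); the
four-way split is reserved for the discriminant model. The vulnerable
set collects regions with uncorrected p < α (default 0.05);
Benjamini-Hochberg flags at q = 0.05 are reported alongside but do not
decide membership. The remainder network is total strength minus the
within-vulnerable sum, so edges crossing the vulnerable boundary count
as remainder.

## Sparse discriminant analysis

The staging model is discriminant analysis by penalized optimal
scoring: for q = 1..Q (Q = K−1 = 3 for the four stages), alternate
between (a) an elastic-net regression of the scored class indicator
Yθ_q on the standardized feature matrix, and (b) updating θ_q as the
normalized projection of the scores onto class indicators,
orthogonalized (in the class-proportion inner product) to the constant
vector and to previous scores. The ridge term (λ = 1e-3) is folded in
by data augmentation and the L1 end is driven along the LARS path
until the active set would exceed the sparsity budget (m = 15 nonzero
loadings per direction); with m ≥ p the closed-form ridge solution is
used, in which case the fitted subspace coincides with classical
regularized LDA (a tested generalized-eigenvalue equivalence). The
hyperparameters are package defaults, exposed in configuration; an
inner hyperparameter search is deliberately absent because the model
is exploratory, not predictive.

Numerical conventions: score vectors are initialized
deterministically from the singular vectors of the centered class-mean
matrix (no random state in the fit); convergence is a relative change
of β below 1e-6 or 200 iterations, with non-convergence warned, not
raised; each β column's largest-magnitude loading is made positive so
score signs are reproducible; constant feature columns are dropped
with a warning before z-scoring and the scaling parameters are stored
for out-of-sample projection.

Evaluation is leave-one-out: each fold re-standardizes and refits on
the remaining n−1 subjects (no leakage of scaling, sparsity pattern or
scores) and classifies the held-out subject by the Euclidean
nearest centroid in LDD space, ties breaking to the earlier class in
the fixed order II < IIIa < IIIb < IIIc. The confusion matrix is
row-normalized to percentages of true class size. Baselines: chance
error 1 − 1/K, and the majority-class rule evaluated by the same
leave-one-out machinery (which equals 1 − n_majority/n whenever the
majority is unique and stable under single deletions). Inter-class
distances are Euclidean distances between class centroids of the
full-data fit.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, plus the planted truth needed to score recovery.

Template: node positions uniform in the unit cube; edge presence
Bernoulli with probability min(1, c·exp(−d/0.35)), c calibrated by
bisection so the expected density matches the target (default 0.30);
base weights are proximity-scaled log-normal counts (location
2.0 + 2.5·proximity, log-SD 0.9, rounded, minimum 1), giving the
heavy-tailed count distributions typical of streamline tractography;
base gFA ~ N(0.50, 0.05) truncated to [0, 1]; base ADC ~ N(8.0e-4,
0.5e-4) mm²/s.

Subjects: w_ij = round(template_ij · exp(ε_ij + stage + covariate))
with ε_ij ~ N(0, 0.25²) per edge (0.25 chosen so the between-subject
variability of total strength lands in the 5–10% coefficient-of-
variation range reported for streamline-count connectomes). The stage
term is −δ·rank on edges internal to the planted 22-node vulnerable
set, with δ = 0.15 and severity ranks HC 0, II 0.5, III\* 1.0, plus an
extra −0.30 on class-profile edges: the vulnerable set is split into
two halves, one attenuated further in IIIa, the other shared by IIIb
and IIIc. Keeping the profiles inside the vulnerable set means class
structure never contaminates the specificity of the nodal scan, and
the shared IIIb/IIIc profile makes their overlap (and the IIIc→IIIb
confusion spill) a planted, recoverable property. Covariate effects:
log-weight slope −0.005 per year of age and a ×1.03 factor for
post-upgrade scans, so the covariate adjustment has real work to do.
Rounding can zero small attenuated edges, which realistically feeds
the consistency mask.

Demographics are drawn to match the reference cohort marginals exactly
in expectation (group sizes 76/25/17/17/12; per-group age means/SDs;
gender, handedness and scanner proportions as exact counts), and the
clinical scores (GAF, PANSS, DOI, DUP, CPZ, with DUP/CPZ missingness)
per-group from the published summaries. Diffuse gFA (−0.004·rank) and
ADC (+8e-6·rank) shifts ride on per-subject offsets (SD 0.01 and
2e-5), yielding stage-III effect sizes near d ≈ 0.4.

Processing speed is 53 (controls) or 41 (patients) T-points plus
β1·z + N(0, 9), where z is the standardized *idiosyncratic* component
of vulnerable-subnetwork strength — the residual after regressing out
stage, age and scanner. Coupling the raw strength instead would leak
the correlation into the remainder network through the shared
covariate factors, contradicting the selectivity the generator is
meant to plant. β1 = 5 puts the realized within-group correlation with
observed vulnerable strength near 0.4 in controls (somewhat lower in
patients, where between-stage strength variance attenuates it — the
same attenuation a real staged cohort exhibits).

What the generator does *not* emulate: anatomical geometry beyond
distance decay, tractography biases (distance-dependent false
positives, gyral-crown seeding), spatially autocorrelated edge noise,
site/batch structure beyond a scalar scanner factor, and non-Gaussian
clinical-score distributions. Passing recovery tests therefore shows
the pipeline correctly extracts the planted ordered, selective and
class-specific structure at realistic noise levels — not that real
cohorts contain such structure, nor that the method is robust to
tractography artefacts.

## Problem sizes used in validation

The test suite exercises the default study conditions (147 subjects,
82 regions): null calibration of the nodal scan over 25 cohorts (2050
node-tests), vulnerable-set recovery over 20 seeds, cognition-coupling
selectivity and discriminant LOOCV over 50 seeds. The acceptance
script reruns a compact battery (6 seeds, one LOOCV) alongside the
closed-form worked examples. Normal-approximation accuracy of the JT
test is checked against a seeded permutation oracle; exact enumeration
is verified exhaustively for all pooled sizes ≤ 8.

## Pipeline conventions

Runs are configured by a validated mapping (unknown keys rejected) and
stamped with a SHA-256 config hash and seed in the summary JSON;
reruns with the same inputs are deterministic and idempotent. A full
per-stage cache was considered and dropped: the end-to-end run is
cheap enough (~20 s at reference size excluding LOOCV) that cache
invalidation complexity is not warranted; the config hash still lets
callers detect stale outputs. All tables are tidy TSV; the only nested
outputs (discriminant evaluation, summary) are JSON.

## Known limitations

* Exact JT enumeration is factorial; the cap makes the exact path
  infeasible beyond ~12 pooled observations with 3+ groups (by
  design — the asymptotic path takes over).
* The LOOCV refits the sparsity pattern per fold, which is the
  leakage-free choice but means reported loadings come from the
  full-data fit only.
* The discriminant model assumes a shared within-class covariance
  (inherited from optimal scoring); strongly heteroscedastic classes
  would call for a different model.
* No edge-level mass-univariate scan and no permutation-based
  family-wise error control are provided (documented extensions).
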