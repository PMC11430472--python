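# Methods

`connstates` re-implements, as a tested pipeline over synthetic cohorts, a
brain-state classification analysis: 324 features per scan from three
families of resting-state fMRI descriptors, linear SVM base models and
ensembles under repeated nested cross-validation, cross-condition transfer,
and coefficient-based feature importance.  This note documents the models,
the defaults and why, the numerical choices, and what the synthetic results
do and do not show.

## Input model

The pipeline starts at *parcellated* BOLD: a T x P matrix of z-scored parcel
time courses, each of the P parcels assigned to one of seven canonical
functional networks (VIS, SMN, DAN, VAN, LIM, FPN, DMN).  Volume-level
preprocessing (motion correction, band-pass, scrubbing, smoothing) is out of
scope; global signal regression is in scope and performed at the parcel
level, with the unweighted cross-parcel mean as the global regressor (the
voxelwise global signal is unavailable after parcellation).

## Synthetic cohort generator

Each parcel follows a linear factor model

    x_p(t) = g_a * g(t) + a_net(p) * u_net(p)(t) + sigma * eps_p(t)

with a shared global factor `g`, seven network factors `u` with a
user-specified 7x7 correlation matrix ("coupling", checked for positive
semidefiniteness before sampling), and white parcel noise.  Columns are
z-scored afterwards, and the implied parcel correlation matrix is available
in closed form, so recovery tests compare empirical against analytic values
rather than against other simulations.

Time courses are white in time: every feature in the pipeline is a function
of the sample correlation matrix, which is invariant to temporal ordering,
so autocorrelation would add realism without changing what is being tested.

A *condition* is a pair of parameter sets (baseline, atypical); each subject
contributes one scan per state (paired design).  Per-subject multiplicative
log-normal jitter (sigma = 0.1) on the global and network amplitudes is drawn
once per subject and applied to both states: stable subject traits add
between-subject spread but cancel in the state contrast.  Whether real paired
scans share nuisance structure beyond the pairing is unknown; this is a
modeling choice.

Default study conditions (chosen once, desk scale):

| parameter | value | rationale |
|---|---|---|
| parcels | 98 (14 per network) | same network structure as a 400-parcel atlas at ~1/4 size; subgraph binarization still yields connected-enough graphs |
| baseline coupling | 0.30 uniform | mid-range inter-network correlation; PSD with wide margin |
| global amplitude | 0.5, network amplitude 0.8, noise SD 1.0 | within-network r ~ 0.47, between-network r ~ 0.23, typical of parcellated FC |
| planted effect | VIS-SMN coupling +0.4 (anti: -0.4) | the effect size named by the classification invariant being tested |
| cohort sizes | 40 subjects, T=300 (planted/anti); 20 subjects, T=200 (null) | the sizes the calibration claims are stated for |
| CV repetitions | 10 (library default 50) | the repetition count the calibration claims are stated for |

The generator does **not** model hemodynamics, temporal autocorrelation,
motion or scanner-site artifacts, spatial smoothness within parcels, or
heavy-tailed noise.  Passing tests therefore demonstrate that the *pipeline*
recovers planted covariance effects under its own statistical assumptions —
not that real brain states are classifiable at any particular accuracy.

## Feature families (324 = 58 + 58 + 74 + 74 + 60)

**Connectivity (58 per variant; noGSR and GSR).**  Pearson correlations over
parcels; mean and SD over 29 scopes (whole matrix, 7 within-network blocks,
21 between-network blocks).  Raw r enters the statistics (no Fisher z — none
is specified for this step); each unordered parcel pair is counted once, the
diagonal never; the SD is the population (divide-by-N) SD, since a scope is
a full enumeration of its pairs, not a sample.  Means are identical either
way and SDs identical between the once-per-pair and full-matrix conventions
once the diagonal is excluded.

**Graph metrics (74 per variant).**  Eight unweighted graphs per variant:
the whole-brain matrix binarized at 10% edge density (one global cutoff over
all pairs, ranked by signed value; ties broken by ascending (row, column)
index) and each network's own submatrix re-binarized at 10% of its own
pairs.  Negative correlations compete in the same ranking; at 10% density
the retained edges are in practice positive.  Clustering is computed on the
binary graphs — the eight graphs are constructed unweighted, and binary
clustering is the reading consistent with that construction.  Measures:

* efficiency: mean inverse geodesic distance (BFS; 1/inf := 0) over 29
  scopes of the whole-brain graph, plus the global efficiency of each
  network subgraph ("intra-efficiency") — 36 features;
* clustering: node-wise C_i = 2t_i/(k_i(k_i-1)) (C_i = 0 when k_i < 2),
  whole-brain and per-network means, plus subgraph means — 15;
* modularity: Newman Q at resolution gamma = 1 for all 8 graphs — 8;
* participation: P_i = 1 - sum_s (k_is/k_i)^2 against the Newman communities
  (P_i = 0 for isolated nodes), whole-brain and per-network means, plus
  subgraph means against each subgraph's own communities (the "intra-"
  naming is mirrored; reusing whole-brain communities would be the other
  defensible reading) — 15.

Community detection is deterministic leading-eigenvector bisection on the
(generalized) modularity matrix with Kernighan–Lin single-node fine-tuning;
zero eigenvector entries join the positive side, all tie-breaks are by node
index, and the dense symmetric eigensolver makes the partition a pure
function of the adjacency matrix.  The returned Q always equals the
modularity formula applied to the returned labels; global optimality is not
guaranteed (it never is for this family of algorithms) but is verified
against exhaustive search on the small fixtures.

**Cortical gradients (60, GSR variant only).**  Connectivity profiles are
Fisher z-transformed (r clipped to +/-(1-1e-7) first) and row-wise
sparsified to the top 10% of entries per row, *keeping* the z weights: the
source description ("z-transformed and binarized ... retaining the top 10%
of weighted connections per row") is internally contradictory, and cosine
affinity on 0/1 rows would discard all profile information, so the
weight-retaining convention of the established gradient toolboxes is used.
The normalized-angle affinity 1 - acos(cos)/pi feeds a diffusion-map
embedding with anisotropy alpha = 0.5 and multiscale (t = 0) component
weighting lambda/(1-lambda) — the standard reading of "automated diffusion
time estimation".  Three components are retained; signs are fixed by making
each component's largest-magnitude entry positive.

Embeddings are aligned by orthogonal Procrustes (rotation/reflection, no
scaling or translation) to a reference.  No external template is shipped:
the default reference is the group-mean embedding of the cohort's baseline
scans (aligned-average, iterated twice); any P x 3 TSV can be supplied
instead.  Features: per-gradient range (whole brain + 7 networks, 24),
dispersion as the *sum* (not mean — so larger networks can dominate) of
squared distances to the scope centroid (8), network eccentricity (7), and
between-network squared centroid distances (21).  Dispersion, eccentricity
and distances are invariant to joint rotation of scan and reference;
per-axis ranges are coordinates in the reference frame and rotate with it.

## Classification

Five base linear SVMs (one per family) plus a feature-integration model on
all 324 features.  Outer 10-fold / inner 3-fold nested CV, repeated (default
50, configurable; the synthetic studies use 10), with all folds grouped by
subject so a participant's paired scans never straddle train/test — the
grouping also guarantees both classes in every fold.  Standardization (mean
0, SD 1; zero-variance features clamp SD to 1 and map to 0) is fit on each
outer-training set only, and the inner loop runs on data standardized with
that outer scaler.

The hyperparameter grid is powers of ten: box constraint C in {1e-6..1e3}
(10 values) x kernel scale s in {1e-4..1e2} (7 values), features divided by
s before the linear kernel.  Selection minimizes mean inner-fold hinge loss;
ties break toward smaller C, then smaller s.  For a linear kernel the pair
(C, s) is exactly equivalent to C_eff = C/s^2 on unscaled features and the
validation hinge loss depends only on C_eff, so the search fits one model
per distinct C_eff (22 of them) per fold and maps losses back onto the
70-point grid — an exact reformulation, not a shortcut.  The winning pair is
refit on the full outer-training set.

libsvm is run at tol = 1e-7 with a 200,000-iteration cap: at the grid's
extreme effective C (1e11) the dual solver need not terminate on
inseparable data, and the cap keeps fits deterministic.

Ensembles per outer fold: feature integration (its own trained model), hard
voting (majority of the five base labels; five voters, no ties), soft voting
(sum of the five base decision scores, divided by five so the ensemble score
stays on the base-model scale for thresholding).

## Evaluation

Balanced accuracy = (sensitivity + specificity)/2 with the decision
threshold searched over [-1, +1]: 201 evenly spaced candidates plus all
midpoints of adjacent sorted scores clipped to the range; "score >= t"
predicts atypical; smallest maximizer on ties.  Because 0 is always a
candidate, the searched value never falls below the threshold-0 value; the
0.5 prevalence-blind floor additionally holds whenever the scores lie inside
the searched interval (SVM decision values are unbounded, so scores far
outside [-1, 1] can in principle evade it).  AUC is the rank-based
Mann–Whitney statistic with ties counted 1/2.

Searching the threshold on the evaluation scores themselves reproduces the
target metric but is optimistic at small n: on a null cohort the optimized
per-repetition balanced accuracy equals (1 + two-sample KS statistic)/2,
which for 20-vs-20 scores has expectation ~0.64 under the null.  The
package therefore reports two aggregations per model: the mean of
per-repetition optimized values (the target metric) and a *pooled* value in
which the outer-test scores of all repetitions enter one threshold search
(bias ~+0.04 at 10 repetitions of 20 subjects).  The pooled value is the
package's calibration metric — it is the one asserted against the
[0.40, 0.60] null band — and both are written by the drivers.  A
`threshold=` argument on `confusion_at_threshold` supports freezing a
threshold chosen elsewhere (e.g. on inner-validation scores) instead.

**Transfer.**  Every trained fold-model of the training condition scores all
scans of the test condition, using the training condition's scalers; a cell
of the transfer grid is the mean balanced accuracy / AUC over fold-models,
and diagonal cells reuse the within-condition nested-CV results.  Feature
names must match exactly between conditions.  Conditions with opposite
planted effects yield AUC below 0.5 — the decision polarity inverts.

**Importance.**  Per feature-integration model, |beta| is normalized to sum
to one (models with different margins become commensurable; the kernel scale
cancels); the table is the entrywise mean over models, with the model count
recorded (3 conditions x 10 folds x 50 repetitions = 1500 at full design;
the synthetic studies average 100 and subset 60).  A planted coupling shift
also moves correlated graph features, so recovery is asserted as: the best
planted feature exceeds the 99th percentile of non-planted importances (in
the shipped study it is in fact ranked first overall).

## Degenerate inputs and errors

Constant parcels, zero-variance global signals, all-identical parcels after
GSR, edgeless graphs, densities that retain zero edges, disconnected
affinity graphs, single-class training labels, and non-PSD couplings all
raise typed errors naming the offending object; nothing is silently
imputed.  The only silent conventions: clustering and participation of
low-degree/isolated nodes are 0, unreachable pairs contribute inverse
distance 0, and constant features standardize to 0.

## Known limitations

* The generator's effects enter through the network-factor covariance;
  effects that alter temporal dynamics without changing covariance are
  invisible to it, as they are to the feature set.
* Newman bisection is a local optimizer; Q values on large noisy graphs are
  reproducible but not certified optima.
* The gradient reference is cohort-derived, so gradient features are not
  directly comparable across cohorts unless a shared reference is supplied
  (transfer results here rest mainly on the connectivity and graph
  families).
* Balanced accuracies obtained with the threshold searched on evaluation
  scores are optimistic at small n (quantified above); the pooled
  aggregation mitigates but does not remove this.
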