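# Methods

## Elastic alignment of item trajectories

Every analysis rests on one primitive: the banded dynamic time warping
(DTW) distance between two equal-length integer score series sampled at the
same biweekly visits.  We use the symmetric step pattern with slope
constraint P = 0: a diagonal move charges twice the local cost
`c(i,j) = |x_i − y_j|`, horizontal and vertical moves charge it once, the
first cell is treated as a diagonal entry step (`g(1,1) = 2·c(1,1)`), and
both endpoints are anchored.  This pattern is symmetric in its arguments
and admits the path-length normalization `d/(N+M)`.  The warping window is
a Sakoe-Chiba band `|i − j| ≤ w` with default `w = 2`: scores may be
matched at most two visits (four weeks) apart.  Because all items of a
patient share the same visit grid, only equal-length alignment is
supported; unequal-length support is deliberately out of scope.

Two conventions are worth stating explicitly:

* The headline "DTW distance" is the **unnormalized accumulated cost**; the
  normalized variant is always computed and can be selected via
  `DTWParams(normalized=True)`.
* With side steps charging the local cost once, `d = 0` does **not** imply
  the series are identical: series whose level sets can be matched by pure
  stretching (e.g. `[0,0,1]` and `[0,1,1]`) align at zero cost.  Identical
  series always have `d = 0`.

Path recovery breaks ties preferring diagonal, then vertical, then
horizontal predecessors, making the reported path (never the distance)
deterministic.  A brute-force path enumerator with the same step weights
serves as an independent oracle in the tests; an exhaustive property test
checks equality over random short series for `w ∈ {0, 1, 2, ∞}`.

## Idiographic pipeline

Per patient we compute all `(17² − 17)/2 = 136` pairwise item distances.
Symptoms scoring 0 at every visit are excluded by default — such pairs have
distance 0 merely because both symptoms are absent — and the exclusion
provably never alters the distances among remaining items (tested).
Patients with fewer than three included items receive a report flagged
"insufficient items" rather than an error, so single degenerate patients
cannot abort a cohort run.

Clustering uses Ward.D2: dissimilarities are squared before updating,
inter-cluster criteria follow the Lance-Williams recurrence, and reported
merge heights are square roots of the criterion (original distance scale),
which makes heights monotone along the merge sequence.  We implement the
agglomeration directly (rather than delegating to a library) to guarantee a
deterministic, platform-independent tie-break: among equal-criterion pairs
the lexicographically smallest (min id, max id) pair merges first.  A naive
oracle that recomputes every inter-cluster criterion from scratch via the
centroid identity on the original squared distances verifies the recurrence
on random matrices.  Patient reports default to an illustrative k = 3 cut.

The symptom network is complete; the distance-to-weight map is not uniquely
determined by the analysis, so two transforms are provided: inverted
min-max similarity `s_ij = (d_max − d_ij)/(d_max − d_min)` (default;
invariant to affine transforms of the distances) and the inverse transform
`1/d_ij` (zero distances capped at the largest finite similarity).
Strength centrality is the sum of a node's edge weights; closeness is
defined directly as the inverse of the node's mean DTW distance to all
other symptoms (the matrix is complete, so no path search is involved).
If all pairwise distances coincide, the similarity is undefined and uniform
weights are emitted with a warning.

## Nomothetic pipeline

Per-patient matrices are averaged entrywise with weights equal to each
patient's number of assessments; each pair is averaged over the patients
whose included-item set contains it, with the supporting patient count
recorded.  Clustering a cohort matrix containing pairs supported by zero
patients is refused.

The number of dynamic symptom clusters is chosen from the scree of merge
heights `H_k` (height of the merge reducing k+1 to k clusters) by maximum
discrete curvature `c(k) = (H_{k−1} − H_k) − (H_k − H_{k+1})` over
`2 ≤ k ≤ k_max − 1` (default `k_max = 8`, ties resolved to the smallest k
with a warning); an explicit user-supplied k always overrides the
automatic choice.

Distatis corroborates the mean-matrix clustering using all per-patient
matrices: each full 17-item matrix (computed *without* the all-zero
exclusion, so every patient contributes a conformable matrix) is
double-centered (`S_p = −½ J D_p J`), normalized by its first eigenvalue,
and compared via RV coefficients; the first eigenvector of the RV matrix,
rescaled to sum 1, weights the compromise `S⁺ = Σ α_p S_p`, whose
eigendecomposition places the items in the compromise plane.  Distances are
centered as given by default, mirroring the common treatment of supplied
dissimilarities in three-way MDS software; a `square_distances` toggle
exposes the textbook alternative, under which the procedure provably
reduces to classical MDS when all inputs are proportional (tested against
an independent principal-coordinates implementation).  DTW dissimilarities
are generally non-Euclidean, so trailing negative eigenvalues can occur;
they are reported but never projected.  Tucker's congruence coefficient is
provided to compare factor configurations, e.g. from split-half analyses.

Outcomes are evaluated at the last recorded assessment: response is a
≥ 50 % reduction of the HRSD-17 sum versus baseline, remission a final sum
≤ 7.  Network density is each patient's mean pairwise DTW distance; by
default it is replaced by the residual from a single pooled OLS regression
on the number of assessments and the baseline sum (constant covariates are
dropped with a warning).  Group comparisons use the Wilcoxon **rank-sum**
(Mann-Whitney) test — responders and non-responders are independent
groups — exact for small untied samples; a paired signed-rank variant is
available for genuinely paired designs.  Per-item trajectories are
summarized by linear mixed models with a patient-level random intercept
(REML), time in 2-week intervals, and 0–2 items doubled to the common 0–4
scale; exactly collinear (no-residual-variance) inputs fall back to pooled
OLS with a flag.  Cronbach's alpha at a single visit uses unbiased sample
variances.

## Synthetic cohort generator

No patient-level data are distributed with the package, so a seeded
generator emulates the study conditions: 255 patients, biweekly visits,
2–17 assessments (shifted, truncated negative binomial tuned to mean ≈ 5.8
and median 5), baseline sum calibrated to 20.7 ± 4.6, five planted
trajectory clusters over the 17 items, zero-inflation heaviest for weight
loss and insight, ~66 % responders and ~50 % remitters, and
response-linked synchrony.

The model, per patient and visit: a latent 0–4-scale value per item
combines (i) a declining level — patient severity times a per-visit
recovery ratio raised to a cluster-specific rate exponent (core symptoms
decline fastest, somatic symptoms are most persistent); (ii) a
cluster-factor mix `λ·f_own + 0.1·Σ f_other + ε` scaled by a per-cluster
amplitude; and (iii) a patient-level shared factor.  Scores are rounded and
clipped to the catalog range; 0–2 items use half the latent level.
Responder/remitter labels are always derived from the realized sum scores
by the operational definitions, so truth labels cannot disagree with the
analysis pipeline; the planted propensity only shapes the decline.

Three design choices deserve explanation:

* **Factors start at zero at baseline.**  The baseline visit is the
  admission snapshot; divergent symptom dynamics develop during follow-up.
  Technically this decouples the baseline-sum calibration from the
  amplitude of the dynamics, which would otherwise inflate the baseline SD
  far beyond 4.6 through the eight-item cluster's correlated contribution.
* **Narrow items carry a 2× fluctuation boost.**  Halving both level and
  dynamics would leave 0–2 items quantization-flattened — almost never
  crossing a score threshold — so all narrow items would cluster together
  by quietness regardless of the planted structure.  The boost makes a 0–2
  item traverse its two thresholds as readily as a 0–4 item traverses four:
  dynamics live on the normalized severity scale, levels on the raw one.
  This matches clinical data, where insomnia items swing across their full
  range while remaining on a coarse scale.
* **Synchrony reallocates variance.**  A purely additive common factor
  cancels in pairwise item differences and would leave DTW distances
  untouched; instead, responders' idiosyncratic (item- and cluster-level)
  fluctuations are shrunk by `1/(1 + synchrony_gain)`, so a larger share of
  their variance is shared and their trajectories run more in step.  Mean
  within-patient distance is monotonically decreasing in the gain (tested
  over a gain grid).

Item levels and per-cluster amplitudes were calibrated once, by simulation,
against the prescribed targets (baseline sum 20.7 ± 4.6, assessment counts,
outcome shares, and recoverability of the planted five-cluster structure by
the elbow rule), and then frozen; they are ordinary config fields, not
per-run tuning knobs.

### What the generator does and does not emulate

It reproduces the marginal summaries above, a recoverable cluster
structure, and the response-density linkage.  It does **not** model
treatment regimes, informative dropout, graded-response measurement models,
or rater effects; items within a cluster are exchangeable up to their level
offsets.  Passing recovery tests therefore demonstrates that the pipeline
detects structure of the planted kind at realistic noise levels — not that
real cohorts contain such structure.

### A structural caveat on the density-outcome null

Because response and remission are *defined* from the same bounded score
trajectories whose pairwise distances the density analysis averages, the
two quantities are not independent even with zero planted synchrony:
responders must reach near-zero scores, and floor-censoring of their late
visits mechanically compresses their DTW distances (≈ −0.55 SD at zero
gain; the effect persists when the decline distribution is fully decoupled
from the planted responder flag).  The rank test itself is well calibrated
— under label permutation its p-values are uniform (tested at 1000
permutations) — but a "null" defined as zero synchrony gain is not a true
null for realized outcome labels.  Real analyses of this design face the
same confound, which should temper causal readings of density-outcome
associations.

## Problem sizes and numerics

Default experiment sizes: cluster-recovery runs use 10 cohorts of 255
patients; the density null experiment uses 200 cohorts; permutation
calibration uses 1000 label shuffles of an 80-patient cohort.  The
pairwise-DTW kernel vectorizes the dynamic program across all 136 item
pairs of a patient simultaneously, so a full 255-patient cohort (69,360
ordered alignments) takes well under a second.  Eigendecompositions use
symmetric solvers; compromise eigenvalues below 1e−10 are treated as null
directions; Ward and elbow ties are broken deterministically as described.
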