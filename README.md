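# symdyn — dynamic time warping analysis of depression-symptom trajectories

`symdyn` analyzes repeated clinician-rated depression assessments (the
17-item Hamilton Rating Scale for Depression, HRSD-17) as a set of per-item
time series and asks which symptoms *move together over time* — within one
patient (idiographic) and across a cohort (nomothetic).  It is aimed at
researchers working with routine-outcome-monitoring (ROM) time series who
want symptom-dynamics clusters and networks rather than cross-sectional
factor structures.

## The method

For two equal-length item-score series `x`, `y`, the elastic dissimilarity
is the banded dynamic time warping (DTW) cost

    g(i,j) = min( g(i-1,j-1) + 2·c(i,j),  g(i-1,j) + c(i,j),  g(i,j-1) + c(i,j) ),

with local cost `c(i,j) = |x_i − y_j|`, the symmetric P = 0 step pattern
(diagonal weight 2, horizontal/vertical weight 1, `g(1,1) = 2·c(1,1)`),
both endpoints anchored, and a Sakoe-Chiba band `|i − j| ≤ w` (default
`w = 2`, i.e. ±2 biweekly visits).  `d = g(N,M)` is the DTW distance;
`d/(N+M)` is its length-normalized form.

On top of this primitive the package builds:

* **Idiographic pipeline** — per patient: the `(17² − 17)/2 = 136` pairwise
  item distances (symptoms scoring 0 throughout follow-up are excluded by
  default), Ward.D2 agglomerative clustering (Lance-Williams update on
  squared dissimilarities, heights reported on the original scale), and a
  symptom network with min-max similarity edges, strength centrality
  (Σ edge weights) and closeness centrality (1 / mean DTW distance).
* **Nomothetic pipeline** — per cohort: the assessment-count-weighted mean
  distance matrix, scree/elbow selection of the number of dynamic symptom
  clusters, a Distatis compromise analysis (RV-coefficient-weighted
  three-way MDS) corroborating the clusters, per-item linear mixed models
  (random intercept; 0–2 items rescaled to 0–4), and a comparison of
  network density — each patient's average DTW distance, residualized on
  the number of assessments and baseline severity — between treatment
  responders (≥ 50 % sum reduction) / remitters (final sum ≤ 7) and the
  rest, via Wilcoxon rank-sum tests.
* **Synthetic cohort generator** — a seeded simulator of an ROM inpatient
  cohort (255 patients, biweekly visits, 2–17 assessments each, baseline
  sum ≈ 20.7 ± 4.6) with five planted dynamic symptom clusters, item-level
  zero-inflation, response-linked decline and trajectory synchrony, used as
  ground truth for recovery experiments.

## Worked example

```bash
python examples/03_cohort_clusters.py
```

prints (abridged):

```
scree heights H_1..H_8: [6.43, 4.74, 3.8, 3.2, 1.18, 0.84, 0.83, 0.77]
elbow selects k* = 5
  cluster 1: depressed_mood, work_and_interests
  cluster 2: guilt, psychic_anxiety
  cluster 3: suicide, retardation, agitation, somatic_anxiety,
             gastrointestinal, hypochondriasis, weight_loss, insight
  cluster 4: early_insomnia, middle_insomnia, late_insomnia
  cluster 5: general_somatic, genital
adjusted Rand index vs the planted structure: 1.00
```

The scree heights drop sharply between the four between-cluster merges
(H₁–H₄) and the within-cluster merges (H₅ onwards), so the elbow selects
five dynamic clusters — core symptoms, distress, inner turmoil, sleep, and
somatic symptoms — and the cut recovers the generator's planted structure
exactly.  `examples/04_density_vs_outcome.py` then shows responders'
adjusted mean DTW distances are systematically shorter (denser networks):

```
response : median residual -0.212 (yes, n=171) vs +0.234 (no, n=84); rank-sum p = 2.45e-05
remission: median residual -0.279 (yes, n=147) vs +0.261 (no, n=108); rank-sum p = 7.57e-09
```

Each script in `examples/` is a short narrative: aligning two items,
one patient's network, cohort clustering, density vs outcome, and
generator calibration.

## Command line

```bash
symdyn simulate --seed 2020 --out cohort.csv          # cohort CSV + truth JSON
symdyn patient --in cohort.csv --id P001 --plots      # per-patient report
symdyn cohort  --in cohort.csv --k 5 --out results/   # full nomothetic analysis
```

The cohort command writes `cohort_distance.csv`, `clusters.json`,
`distatis.csv`, `centrality.csv`, `density.csv`, `tests.json`, and
`trajectories.csv`.

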