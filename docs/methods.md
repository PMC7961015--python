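# Methods

This note records the models, conventions and design choices behind
`dcisprofiler`, in the spirit of the methods documentation of simulation
and statistics packages: what is assumed, what is configurable, and what
passing the test suite does and does not demonstrate.

## Data model

The unit of observation is a segmented cell from an iteratively stained
multiplexed-immunofluorescence (MxIF) tissue-microarray section.  Each
cell carries identifiers (patient, slide, field of view, core), a tissue
class, a nucleus count, compartment areas (nucleus, membrane, cytoplasm,
in pixels), per-round registration scores in [0, 1], per-round exposure
times (ms), and two raw intensity readouts per marker (median over the
nuclear mask and median over the whole cell).  The marker panel maps each
marker to its staining round, its summarisation (nuclear median for ER,
PR, p21, Ki67; whole-cell median otherwise), and its analysis role; the
clustering set is ER, HER2, cMET, SLC7A5, and EGFR is carried but excluded
from analysis.

## Quality control

Cell-level rules (all must hold): epithelial class; 1–2 nuclei; every
compartment area strictly greater than 10 px and strictly less than
1500 px (boundary values excluded — the bounds are exclusive by
definition); registration summary ≥ threshold.  The registration score of
a round is the Pearson correlation between the baseline nuclear patch and
that round's patch, clipped below at 0; a zero-variance (blank) patch
scores 0, representing complete loss of the cell.  The per-cell summary is
the **minimum** over rounds, because a usable cell must stay registered in
every round.  The default threshold is 1.0 with a float tolerance of 1e-9;
it is configurable because empirical correlations rarely equal 1 exactly,
and upstream pipelines may already binarise the score.

FOV rule: manual quality pass and DCIS fraction
%DCIS/(%DCIS + %Normal) ≥ 0.5.  The boundary (exactly 0.5) is retained;
FOVs with no evaluable tissue are excluded under their own rule name.
Cells of excluded FOVs are removed **before** patients are counted.

Patient rules (outcome analysis): ≥ 100 retained cells; non-event
patients followed at least 3 years; event patients with the event before
10 years (later events are treated as probable new primaries).

Every stage returns an audit with input = excluded + output; a cell
failing several rules is tallied under each rule but excluded once.
Filtering is conjunctive, hence idempotent and order-insensitive.

## Preprocessing

Order of operations: exposure correction → log2 → summarisation →
per-slide median centring → (clustering markers) capping and
standardisation.

* **Exposure correction** assumes linear detector response:
  `corrected = raw × reference_ms / exposure_ms`, with the per-round
  reference exposure taken from the panel file so the correction is
  deterministic rather than data-dependent.
* **log2(x + 1)**: the +1 pseudo-count keeps zero intensities finite and
  the transform monotone.
* **Slide normalisation** subtracts each slide's per-marker median and
  adds back the grand median, equalising slide medians exactly.  Median
  centring was chosen over quantile normalisation as the weakest
  correction consistent with an additive batch effect; it preserves
  within-slide rank order.  *Assumption*: slides have comparable cellular
  composition (many cores per slide).  If a slide contains few patients,
  composition differences masquerade as batch effects and centring can
  absorb real signal — visible in the generator when one patient occupies
  a whole slide.
* **Capping and standardisation**: per clustering marker, values below
  the 1st or above the 99th percentile (linear-interpolation quantiles)
  are set to the percentile, then the column is z-scored with the
  post-capping mean and population SD.  Parameters are fitted once on the
  pooled post-QC cell set and frozen for all downstream use, so held-out
  cells can be projected into the same space.  Constant columns raise an
  error rather than silently producing zeros.

## Consensus clustering and PAC

Cells are clustered with k-means (k-means++ initialisation, Lloyd
iterations, best of `restarts` by within-cluster sum of squares) in the
standardised 4-marker space; Euclidean distance is appropriate there
because standardisation removed unit effects.  For each candidate
k = 2..15, `reps` subsamples of ⌈0.8·n⌉ cells (without replacement) are
clustered and the consensus value of a cell pair is the fraction of
co-clustering among subsamples containing both cells; pairs never
co-sampled are undefined and excluded.  PAC is the fraction of defined
off-diagonal pairs with consensus strictly inside (0.1, 0.9) (entries at
the bounds count as unambiguous); the chosen k minimises PAC with ties
going to the smaller k.  Subsample fraction 0.8 and 100 repetitions (50 in
the headline re-computation) are the conventional consensus-clustering
settings; all are configurable.  Heatmap-ordered consensus matrices are
stored for small inputs so the selection can be inspected visually, but
selection itself is fully automatic.

Pair counts are accumulated as one-hot membership matrix products, so a
10,000-cell sweep over k = 2..15 runs in minutes on one CPU; the pipeline
subsamples the cohort to 10,000 cells for the sweep (a full 75k-cell pair
matrix would need tens of GB) and then fits the final k-means on all
cells.

Cluster labels are made canonical by matching fitted centroids to the six
phenotype archetypes (all-low; ER-high; SLC7A5-high/HER2-low;
ER+cMET-high; HER2+SLC7A5-high; HER2-high) with an exact assignment
solution on Euclidean distances, honouring the fitted marker order.  If k
differs from the number of archetypes the labels stay in fit order with a
warning.

## Escore

The patient cluster profile is the composition vector of that patient's
cells over the six canonical clusters.  The risk model is an unpenalised
maximum-likelihood logistic regression of the event indicator on
x₁ = %C5&6 and x₂ = %C2&4 (percentage scale 0–100 — required for the
published coefficients 1.77/−2.78 and threshold 13 to be on a sensible
scale).  A patient is high risk when the predicted probability exceeds
the cohort base rate, which on the linear scale is
`score > logit(base_rate) − intercept`; the two classifications agree by
construction for every fitted model.  The published model's intercept was
never reported, so the frozen constant reconstructs it from the base-rate
rule (`logit(0.255) − 13`); this affects probabilities, not
classifications.

Degenerate designs: constant covariates are dropped (slope 0), recovering
the intercept-only limit; complete separation raises an error with
guidance instead of silent regularisation.

Evaluation reports the confusion counts at the model threshold
(classification strictly above the cut), sensitivity, specificity, error
rate, and the rank-statistic AUC with midrank tie handling.
Leave-one-out cross-validation refits only the logistic model — the
clustering is fitted once on all cells, since re-clustering per fold would
change cluster identities and break the meaning of the fixed covariates;
non-converging folds are flagged, excluded from the held-out AUC, and
counted.  Note that held-out LOOCV probabilities are pessimistically
biased in small cohorts (removing a case weakens the evidence for its own
class), so a null cohort of ~50 patients shows LOOCV AUC well below 0.5;
the chance-level property is only recovered at larger n.  Duplicate-core
concordance scores each core of a patient separately and reports the
fraction of patients whose cores agree on the risk class.

## Survival

Disease-free interval = time from diagnosis to the event, censored at
last follow-up.  Kaplan–Meier product-limit curves per Escore group use
the standard tie convention (censored records at an event time remain in
the risk set); the two-group log-rank test uses the hypergeometric
variance and a χ² statistic with 1 df.

## Synthetic cohorts

The generator draws, per patient: the outcome (exactly 13/51 when the
product is integral, otherwise Bernoulli); the cluster profile from a
Dirichlet with mean equal to the outcome group's published composition
(clusters 2/4/5/6 as reported; the unreported clusters 1 and 3 split the
remaining mass equally) and a concentration parameter; a follow-up time
(non-BCE ~ Uniform(3, 17) years, matching the cohort's 1–17-year range
with ~9-year median; BCE ~ Weibull with shape 1.5 scaled to a 2.5-year
median and truncated below 10 years).  Each cell draws its true cluster
from the patient's profile and its 4-marker value from the archetype
Gaussian (default within-cluster SD 0.5 z-units — separable but
overlapping, matching the mixed-duct appearance of real lesions).  PR is
correlated with ER at the cell level (r = 0.8, mirroring its exclusion
from clustering for collinearity); background markers are lognormal with
patient-level shifts.

Raw intensities are synthesised by inverting the preprocessing chain
(z → log2 via an affine map, add slide offset, undo log2, undo exposure
correction with per-slide exposure jitter), so preprocessing recovers the
latent log2 values exactly (< 1e-9) on artifact-free single-slide data,
and the standardised values off the capping bounds to < 1e-6.  Artifacts
(multi-nucleate cells, out-of-range compartments, misregistered cells,
low-DCIS FOVs) are injected at configurable rates, and nuclear image
patches for registration scoring are synthesised as smoothed random
fields with pixel offsets.

**Calibrated defaults.**  Cells per patient: negative binomial with mean
2200 (dispersion 5), so ~75k epithelial cells survive QC at 51 patients.
Group-conditional profile concentration: 1.0 — strongly dispersed
profiles, which is what the published discrimination implies: with the
reported group-mean compositions, an end-to-end simulated cohort matches
the published AUC (≈0.785) and LOOCV AUC (≈0.739) only when per-patient
profiles vary this widely.  Logistic outcome mode draws profiles from the
pooled Dirichlet at concentration 1500 with intercept −11.4: this spread
was chosen by a Fisher-information analysis as the regime where the steep
published slopes are statistically identifiable at a ~25% event rate —
wider spreads saturate the logistic (outcomes become deterministic),
narrower ones leave no covariate variation.  Even at this optimum the
asymptotic SE of the %C5&6 slope at n = 2000 patients is ≈0.115, so
single-run recovery within ±0.15 is a ~1.3σ event, not a certainty.

**What the generator does not emulate**: spatial structure (ducts,
neighbourhoods), stromal/immune phenotypes beyond a stromal flag,
autofluorescence/background rounds, segmentation errors other than the
modelled artifact classes, and marker–marker correlations beyond ER–PR.
Passing tests on this data shows the pipeline's statistics are computed
correctly under the study's assumed generative structure; it cannot show
that the published coefficients generalise to new cohorts.

## Problem sizes used in the checks

Headline re-computations: consensus selection on 10,000 cells (k = 2..15,
50 reps, 80% subsampling); slope recovery on 2,000 patients; the
end-to-end discrimination band on 20 cohorts of 51 patients at the
default cell counts with k fixed at 6 (the k-sweep is exercised
separately).  Module tests use smaller cohorts chosen so the whole suite
runs in minutes.
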