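# Methods

## Problem setting

In radiotherapy for small cell lung cancer the clinical target volume (CTV)
extends the gross disease — the primary tumor (GTV) and grossly involved
nodes (GTVnd) — into the mediastinal/hilar lymph-node stations at risk of
microscopic spread. Where recurrences later appear, and how they relate to
how completely each station was covered by the delineated CTV, is the
question this package operationalizes. It works entirely on co-registered
binary masks on a shared voxel lattice: CTV, GTV, GTVnd, an optional
recurrence region, and the 16 stations of the IASLC map, indexed LN1..LN16
with labels

| LN1 | LN2 | LN3 | LN4 | LN5 | LN6 | LN7 | LN8 | LN9 | LN10 | LN11 | LN12 | LN13 | LN14 | LN15 | LN16 |
|---|---|---|---|---|---|---|---|---|---|---|---|---|---|---|---|
| 1R | 1L | 2R | 2L | 3A | 3P | 4R | 4L | 5 | 6 | 7 | 8 | 10R | 10L | 11R | 11L |

## Partition parameters

The *ideal CTV* is the union of every full station volume the delineated
CTV touches at all:

    ideaCTV = ∪ { LN_i : |CTV ∩ LN_i| > 0 },  i ∈ [1, 16].

Touching one voxel of a station pulls the whole station into the union —
the construct asks "which stations did the CTV commit to", not "how much of
them did it cover". Six ratio families follow, with G the gross-disease
mask (GTV ∪ GTVnd by default; a `gross_disease="primary_only"` switch
restricts G to the primary — the source protocol is ambiguous here and the
union keeps nodal stations from zeroing out):

    RctvLN_i  = |CTV ∩ LN_i| / |LN_i|        RIctvLN_i = |CTV ∩ LN_i| / |ideaCTV|
    RgtvLN_i  = |G ∩ LN_i| / |LN_i|          RIgtvLN_i = |G ∩ LN_i| / |ideaCTV|
    RcmgLN_i  = |(CTV−G) ∩ LN_i| / |LN_i|    RIcmgLN_i = |(CTV−G) ∩ LN_i| / |ideaCTV|

All cardinalities are voxel counts (the voxel volume cancels in every
ratio; no partial-volume weighting). Together with 14 scalars — CTV and
GTVnd volume, in-plane resolution, counts of stations involved by CTV and
GTVnd, a lung-quadrant code, seven binary station-overlap flags (4L, 4R, 5,
6, 7, 11L, 11R) and the pre-treatment tumor size — they form the canonical
110-entry feature vector. Degenerate case: a CTV touching no station gives
|ideaCTV| = 0 and all RI* ratios are defined as 0 (not NaN), with a logged
warning, so feature matrices stay numeric.

Because the stations must be pairwise disjoint for the ratios to be
well-defined (overlap would double-count), disjointness is a hard
validation error, never auto-repaired. Station ratios with an empty station
are a hard error too.

Recurrence mapping: each patient's recurrence mask produces one *event* per
station it intersects (so one mask straddling a boundary yields several
events, which is how 94 relapsing patients can produce 170 station-level
instances in the reference cohort). An event is *GTV-affected* when the
recurrence touches gross disease inside that station — any contact takes
precedence, making the GTV-affected / CTV−GTV classes mutually exclusive.
The event's `actual_over_idea` is |CTV ∩ LN_s| / |LN_s|, read as the
fraction of the ideal station volume the actual delineation covered; the
reference table's 0–1 column range and its under-coverage framing both
match this reading, which is isolated in one function should another
interpretation be preferred.

## Synthetic phantoms

No per-patient imaging is publicly available for the clinical cohort this
pipeline mirrors, so every stage is exercised on synthetic structure sets
with planted ground truth. The generator reproduces the *statistical*
structure the analysis needs, not anatomy:

* **Atlas** — 16 disjoint ellipsoidal stations in a stylized mediastinal
  arrangement (superior 1R/1L, subcarinal 7 central, hilar 10R/10L and
  interlobar 11R/11L lateral-inferior), specified in fractions of the
  lattice extent so the same layout is valid at any resolution. Default
  lattice 96³ at 1.5 mm isotropic — a desk-scale stand-in for the clinical
  512×512×5 mm planning grid; ratio geometry is resolution-independent.
  Minimum center separation 0.166·extent vs an ellipsoid diameter of
  0.11·extent guarantees disjointness; collisions under user-supplied
  geometry raise an error naming the pair.
* **Patient** — a spherical GTV with diameter drawn from a truncated normal
  (mean 4.8 cm, sd 1.8, range 1.5–11 cm, matching the cohort's near-even
  split around 5 cm) anchored in a sampled lung quadrant; per-station
  involvement drawn with hilar-dominant probabilities (10R 0.45, 10L 0.35,
  4R 0.35, 7 0.30, tapering to 0.03 for 2L/3P); GTVnd as ellipsoidal
  sub-regions confined to involved stations; CTV = (GTV ∪ GTVnd) dilated by
  8 mm (Euclidean distance transform, so anisotropic spacings are exact)
  unioned with the full masks of involved stations. The dilation margin is
  what produces partial station coverage — ratios strictly between 0 and 1 —
  in nearby uninvolved stations.
* **Outcome** — the latent relapse label is Bernoulli in
  σ(β₀ + Σ βⱼ·xⱼ) evaluated on the patient's own extracted features.
  Defaults: β₀ = −4.2 and coefficients {RctvLN13: 3.0, RctvLN14: 2.5,
  RctvLN7: 2.0, RgtvLN11: 2.5, RgtvLN13: 2.5} — hilar/subcarinal coverage
  and gross involvement drive relapse, echoing the reference cohort's
  recurrence geography. These values were calibrated once, at design time,
  so that the observed relapse fraction at the default scale is ≈ 0.56
  (reference cohort: 94/180 = 0.52) and the latent linear predictor
  separates observed labels with AUC ≈ 0.84. Event times are exponential
  with hazard 0.02/month multiplied by 2.0 for tumors ≥ 5 cm; censoring is
  exponential at 0.003/month (≈ 10% censored by 36 months) plus a 72-month
  administrative window for never-relapsing patients. The *observed*
  relapse status — what the clinical record and all downstream stages see —
  is 1 only when the event precedes censoring; with censoring switched off
  the observed and latent labels coincide exactly. Recurrence masks are
  single ellipsoids seeded in a station drawn with weights proportional to
  the reference tally, centered inside gross disease with probability 0.6.
* **Reproducibility** — one master seed; per-patient substreams derived by
  counter (`SeedSequence(seed, spawn_key=(k,))`), so cohorts are
  byte-identical across runs and generation order.

What the phantoms deliberately do not emulate: anatomically accurate IASLC
boundaries, CT intensities, deformable anatomy, multi-focal recurrence,
inter-observer delineation variability. Tests passing on phantoms therefore
certify the *arithmetic and statistical machinery* — ratio formulas,
screening, model fitting, survival estimation — not clinical performance on
real scans.

## Modelling chain

Stratified 80/20 train/validation split, then strictly on training rows:
column standardization (population-sd convention; constant columns map to
zero and are flagged), greedy correlation filtering (|Pearson r| ≥ 0.95;
within a pair the feature with the weaker point-biserial label correlation
is dropped, ties keeping the earlier schema column), recursive feature
elimination ranked by mean impurity importance across stratified 5-fold CV
fits and scored by mean held-out AUC (selected subset = AUC maximizer, ties
to the smaller subset), and a grid search over tree depth {3, 5, 7, ∞} ×
ensemble size {100, 200, 500} by stratified 5-fold CV AUC. The classifier
is a bootstrap-aggregated decision-tree ensemble with √p feature subsetting
at splits; predicted probability is the per-tree average RF(x) = (1/B)Σ
Tᵢ(x), hard labels are the majority vote — both aggregation rules are kept
side by side, averaging for scores/AUC, voting for class output. Threshold
metrics use score ≥ 0.5. Validation rows never influence any fitted
quantity; a dedicated test permutes validation labels and asserts the
fitted pipeline is bit-identical.

The correlation threshold (0.95), RFE step (1), CV scoring (AUC), grid
values and the 0.5 threshold are unspecified in the source protocol and are
exposed as configuration with those defaults. No target subset size is
hard-coded (the protocol's "27 reserved features" vs its 22-row feature
list is irreconcilable from the text); selection is data-driven, and the
published 22-feature list ships as `REFERENCE_SELECTED_FEATURES` for
comparison only.

## Survival analysis

Local control is the absence of recurrence; the "3-year local control rate"
is read as the Kaplan–Meier survival proportion at 36 months. KM and the
two-group log-rank test (hypergeometric variance, χ²₁) delegate to
lifelines. The univariate Cox model for a binary covariate is a direct
Newton–Raphson maximization of the partial likelihood — Breslow tie
handling by default, Efron via `ties="efron"`, tolerance 1e-8, at most 50
iterations, with explicit failure on monotone likelihoods — kept explicit
so the likelihood convention is testable against brute-force maximization
and against lifelines on tie-free data. 2×2 tables report the odds ratio
ad/bc with a Woolf confidence interval; the p-value is the
continuity-corrected χ² unless an expected cell drops below 5, then
Fisher's exact test. The reference study's multivariate Cox model is out of
scope: it cannot be reproduced without per-patient data.

## Numerical choices and problem sizes

* Voxel membership is binary; a voxel's mm position is origin + index ·
  spacing; ellipsoid rasterization includes voxels whose centers fall
  inside, evaluated only on the bounding box.
* Hausdorff distance is computed between boundary-voxel centers
  (6-connected erosion residue) scaled by spacing; empty masks are an
  error, identical masks give 0.
* Dice of two empty masks is defined as 1.0.
* NIfTI headers are float32, so grid spacing/origin are authoritative in
  the JSON sidecar and round-trip exactly.
* Statistical suites run at sizes chosen for desk-scale runtimes while
  keeping each check well-powered: ratio-recount equivalence on 48³
  lattices (exact integer arithmetic, scale-irrelevant); model anchor and
  null calibration on default-scale (96³) cohorts of n=500 — smaller
  lattices distort these suites, since a ~5 cm tumor fills a 72 mm extent
  and saturates the ratios; screening recovery on directly planted 400×110
  matrices with RFE step 10; survival recovery at n=1000. The model anchor
  fits the bagged ensemble at depth 7 with 300 trees after the correlation
  filter — the depth the pipeline's own grid search selects on these
  cohorts — while the full RFE + grid-search chain is exercised separately
  and in the pipeline run.

## Known limitations

* The phantom atlas is geometric, not anatomical; station adjacency
  patterns (hence which stations get clipped by the dilation margin) only
  loosely resemble the mediastinum.
* The planted logistic model generates labels from extracted features, so
  phantom cohorts are, by construction, learnable; anchor AUCs certify the
  pipeline's ability to recover a known signal, not expected clinical AUC.
* Single-ellipsoid recurrences cannot represent disseminated failure.
* The Cox implementation is univariate (scalar binary covariate) by design.
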