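# Methods

`lineage4d` reimplements, as a tested pipeline, the quantitative 4D
cell-lineage analysis used to ask whether the unequal first cleavage of the
*C. elegans* zygote is required for reliably successful embryogenesis.  The
chain is: embryo alignment in time and space → control reference model by
Generalized Procrustes Analysis (GPA) → 13 per-cell variables → group
statistics with a permutation-calibrated false-discovery threshold → a
repeated-cross-validation Lasso classifier predicting embryo death.  A
synthetic embryo generator with planted group effects exercises every stage
end to end.

## Lineage data model and nomenclature

A lineage is a forest of named cell tracks (time-stamped 3D nuclear
positions in µm, 1-based frames, parent/daughter links; 0 or exactly 2
daughters).  Somatic names follow the Sulston convention (daughters append
a/p, l/r, or d/v); the germline lineage uses an explicit table
(P0→AB,P1; P1→EMS,P2; EMS→MS,E; P2→C,P3; P3→D,P4; P4→Z2,Z3), and ectopic
germline divisions fall back to the generic a/p rule (Z2a, Z2p).  Cells
already present at recording start have no observable birth; their
StartTime is missing and flows into the imputation machinery downstream.

Classifier *stage cohorts* attribute each named cell to the canonical
4-, 8-, 15-, or 28-cell stage at which it first exists (e.g. the 15-cell
cohort holds the eight AB great-granddaughters plus MSa/MSp, Ea/Ep, Ca/Cp);
a stage's feature universe is the cumulative union of cohorts, 52 cells ×
13 features at the 28-cell stage.

Two on-disk formats are read: a native long-format TSV (one row per nucleus
observation) and the classic AceTree/StarryNite per-timepoint nuclei files
(best-effort, with a column-mapping option and mandatory pixel/plane
calibration, e.g. 0.14 µm/px and 0.75 µm/plane).

## Temporal and spatial alignment

**Pace matching.** Each embryo's linearly interpolated cell-count curve is
compared with a reference curve (the mean over control embryos) on a 1-min
grid; the pace factor is the grid value in [0.5, 2.0] (step 0.001)
maximizing the Pearson correlation.  Time zero is the ABa division
(operationalized, like all division times, as the first frame at which
daughters are tracked — "anaphase onset" at 2.5-min sampling).  Aligned
time is `(t − t₀) · scale`.

**Axes.** The A-P axis is the first principal component of all nuclear
positions within the first 100 recorded frames; D-V is the component of the
MS-lineage centroid direction orthogonal to A-P (ventral positive); L-R =
A-P × D-V (right-handed).  Signs: the AB-lineage side is anterior
(negative A-P).  One deliberate numerical choice: axis *directions* are
estimated on the raw µm cloud and the per-axis extent normalization is
applied to the *coordinates* afterwards.  Normalizing first would divide
each imaging axis by its extent, equalizing the variances and leaving the
first principal component ill-conditioned (we measured anisotropy ratios of
~1.05 on normalized clouds); estimating directions on the raw cloud keeps
the estimator exactly rotation-equivariant, which the test suite checks
under 100 random rigid motions.  A low-anisotropy warning (ratio < 1.2)
flags clouds whose A-P axis is unreliable.

**µm-equivalent coordinates.** Extent-normalized coordinates are rescaled
by the control-mean extents along the embryonic axes, so positional
features read in µm-like units while embryo size differences are removed.
Division vectors are only rotated, never extent-scaled: angles are measured
in real space, where anisotropic rescaling would distort them.

**GPA.** Landmarks are per-cell metaphase positions (the mother's last
tracked frame), matched by name; cells missing from an embryo are dropped
pairwise.  Every configuration is superposed on the current mean by
least-squares rotation + translation (Kabsch, proper rotations only), the
mean is recomputed, and iteration stops when the residual changes by less
than 1e-12 (cap 200 iterations).  Updates are synchronous, so the result is
invariant to input order.  Procrustes *scaling* is off by default — extent
normalization has already removed size — and available via a flag.

**Reference model.**  From ≥ 1 aligned controls: per-cell mean metaphase
positions, mean unit division vectors (mean of unit vectors, renormalized),
per-minute mean trajectories (each control linearly interpolated to a 1-min
aligned grid before averaging), and control mean/SD per (cell, feature)
(sample SD, n−1 throughout).  Serialized as JSON with explicit units.

## The 13 per-cell variables

StartTime, EndTime, LifeTime (aligned minutes); pAP, pDV, pLR (metaphase
position along the embryonic axes); totdis (summed frame-to-frame
displacement) and netdis (birth-to-end displacement; netdis ≤ totdis by
construction); aAP, aDV, aLR (division-vector angles versus the axes);
aMean (angle to the reference division vector); pOV (Euclidean distance of
the metaphase position from the reference mean).  The division vector runs
from the a/l/d-suffixed daughter (or the first of the P-lineage pair) to
its sister at the daughters' first common frame.  Angles are directed
(0–180°), so inverted divisions appear near 180° instead of folding back —
needed to see MSa/MSp inversions.  Before computing aMean/pOV a test
embryo's landmark set is rigidly superposed on the reference (Kabsch on ≥ 4
shared cells).

Derived phenotypes: EMS skew (aMean of EMS > 35° at anaphase onset),
MSa/MSp left-right inversion (both L-R coordinates sign-flipped versus the
reference at metaphase, gated on the reference offset exceeding 0.5 µm),
extra P4-lineage divisions (division count in the P4 subtree minus one),
AB–P1 division asynchrony (aligned minutes), and a T-arrangement proxy at
the 4-cell stage (ABa→ABp nearly parallel to A-P *and* P2–ABp distance
> 1.5× the mean adjacent-cell distance; the original scoring was visual, so
this rule is a documented, tunable stand-in).

The mean positional-deviation curve interpolates each live cell at 1-min
intervals, sums Euclidean distances to the same cell's reference
trajectory, and divides by the number of contributing cells; cells absent
from the reference are excluded from the denominator.

## Group statistics

Welch's unequal-variance t-test per feature with Benjamini–Hochberg
adjustment; multi-group comparisons by one-way ANOVA with Tukey's HSD
(statsmodels).  The screening effect size is the relative mean difference
versus the control/alive group (threshold 0.15); an absolute-difference
option exists.  The p-value cut-off is calibrated by label shuffling: for
each α on a descending grid {0.05, 0.02, 0.01, 0.008, 0.005, 0.002, 0.001},
the expected false-positive count is the mean number of features passing
(|effect| ≥ 0.15 AND p < α) over 100 seeded permutations (the same shuffle
set across the grid, for variance reduction); estimated FDR(α) =
expected / max(observed, 1); α* is the largest grid value with FDR ≤ 0.10.
Features need ≥ 5 non-missing embryos per group to be tested.  Variability
is summarized as sample SD and CV = SD/mean (CV only for positive-mean
features such as LifeTime; invariant to uniform time dilation).  The
robustness screen flags features with an unchanged mean (Welch p ≥ 0.05)
and significantly larger variance in the perturbed group (one-sided
variance-ratio F test, p < 0.05) — the test pairing is this package's
choice; a Levene option is exposed.  AB-size analyses use 2%-wide half-open
bins labelled "(56-54]" (the square bracket marks the included endpoint)
and Pearson correlations with two-sided p from the asymptotic t
approximation (n−2 df).

## Outcome prediction (Lasso)

Preprocessing, in order: drop features whose min–max-rescaled variance is
below 0.025 (a unit-free reading of the "low overall variance" rule; the
alternative ordering — filter after scaling — is equivalent here because
the filter already operates on the rescaled column); drop features with
> 25% missing values; impute the rest with the outcome-class mean (overall
mean as fallback; an `overall_mean` mode avoids the label leakage inherent
in class-mean imputation and is flagged in the API); min–max scale to
[0, 1].  Rows are never dropped.

The classifier is L1-penalized logistic regression (scikit-learn liblinear;
C = 1/(n·λ); the intercept is kept effectively unpenalized via a large
intercept scaling) along a 20-value geometric λ path from 1.5× the
gradient-bound λ_max down to λ_max/1000 — the top of the path guarantees the
intercept-only "empty model" is reachable, which dominates under null
labels.  Each of 250 repetitions draws a stratified 5-fold split
(stratification prevents empty-class folds at n ≈ 31), accumulates held-out
predicted probabilities along the path, picks the λ minimizing
cross-validated mean squared error between probability and 0/1 label
(deviance is not used; squared error mirrors the min-CV-MSE rule), refits
on all data at that λ to read the selected features, and records the
held-out accuracy at threshold 0.5.  Aggregates: accuracy mean ± SD,
model-size histogram, per-feature inclusion frequency; the *best model* is
the single repetition with the global minimum CV error, reported with its
ROC (sensitivity/specificity over sorted unique probabilities, the 0.5
operating point, and the Youden-J point).  Per-stage reports restrict to
the embryos shared across stages; embryos with a 4-cell T-arrangement or an
EMS skew are excluded from classification, matching the study design.

## The synthetic embryo generator

The generator is the test bed, not a mechanical model.  What it emulates:

* canonical topology from the 2-cell stage to ~100 cells, with a
  generation × founder clock table (near-synchronous AB rounds ~24–38 min,
  long Ea/Ep cycles, slow D and P4) and lognormal cycle noise
  (CV 5%, matching the observed 4–5% range; lognormal avoids negative
  durations);
* AB–P1 division asynchrony shrinking linearly with relative AB size
  (4.25 min at 60% down to a 0.75-min size-independent residual below 46%,
  so inverted embryos retain residual asynchrony);
* P1-lineage cell-cycle shortening of 1.2%/percentage point of AB size
  below 60%, with P4 2.5× more sensitive (~25–30% shorter at equalized
  sizes);
* positions inside an ellipsoidal eggshell (half-axes 25 × 15 × 12.5 µm,
  flattened along D-V by the compression covariate): daughters placed
  ± half a separation along a per-cell canonical division axis (a static
  name-derived table; self-consistent rather than measured, since the
  reference model is itself built from simulated controls), then 20
  iterations of pairwise soft-sphere overlap resolution with ellipsoid
  projection per frame, plus a small random walk (SD 0.35 µm/frame).  At a
  pair's birth frame the spindle-dictated direction is re-imposed on the
  relaxed midpoint — without this, relaxation rotates fresh sister pairs
  and division-angle noise triples;
* cell radii from lineage volume splits (AB:P1 set by the drawn relative
  AB size; asymmetric P-lineage splits), total cell volume 55% of the
  eggshell;
* planted dead-embryo signatures (equalized-dead and inverted groups): a
  2 µm dorsal shift of ABar and its progeny (applied to observed
  positions), 2.5× inflated Ca random motion, MS division-axis skew
  (SD 25°) and MSa/MSp inversion (p = 0.35; the canonical MS axis has a
  deliberate L-R component so inversion flips the daughters' L-R signs),
  EMS skew of 40–60° (p = 0.25 equalized-dead, 0.43 inverted), ectopic
  germline divisions (p = 0.35, recording extended to cover them), and
  1.3× inflated timing CV;
* measurement noise of 0.7 µm per observed position, 2.5-min frames, and
  truncated recordings (20% stop at the 26-cell stage).

Outcome labels are deterministic per group (equalized-dead and inverted
die), so the classifier has a learnable target.  `planted_truth` lists the
(cell, feature) pairs each signature touches.  The signature magnitudes are
calibration knobs chosen once at plausible scales, not measured values.
What the generator does **not** reproduce: real wild-type coordinates,
eggshell deformation, cytoplasmic flows, cell-contact-mediated signaling,
or gene expression — so green tests demonstrate that the *analysis chain*
recovers what was planted under realistic noise, not that it would make the
same biological calls on microscope data.  Two planted effects are
deliberately diluted en route (the ABar dorsal shift is partially absorbed
by frame inference and Procrustes superposition; Ca's net displacement is
dominated by crowding drift), which is the realistic regime for a
positional screen.

## Determinism and problem sizes

All randomness flows from one root seed through named substreams
(simulate / shuffles / folds), and every stage is a pure function of
(inputs, config, seed): rerunning the pipeline reproduces byte-identical
outputs (the provenance manifest also records wall-clock timings, which are
excluded from the comparison).  The default cohort mirrors the study's
group sizes (10 wild-type, 18 control, 21 equalized-alive, 28
equalized-dead, 7 inverted; 84 embryos).  The test suite runs scaled-down
cohorts (21–26 embryos, 10–25 CV repetitions, 20–100 shuffles) chosen so
the full suite completes in a few minutes; the acceptance script runs the
complete 84-embryo pipeline with the full 250 × 5-fold protocol.

## Known limitations

* Division timing is quantized to the 2.5-min frame interval, which caps
  the observable AB-size/asynchrony correlation well below the underlying
  latent correlation.
* The AceTree reader is best-effort over one dialect; deposited exports
  with different column layouts need the column-mapping option.
* Class-mean imputation leaks outcome information into the classifier
  features; it is retained as the primary mode for fidelity to the original
  workflow, with `overall_mean` provided for unbiased estimates.
* GPA with partial landmark overlap has no global optimality guarantee;
  with the dense overlap of early-stage cells this has not been an issue in
  practice.
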