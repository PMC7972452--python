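# lineage4d

Quantitative 4D cell-lineage analysis of early *C. elegans* embryogenesis,
built to ask a developmental question: is the physically unequal first
cleavage of the zygote — a large anterior AB cell (~60% of the embryo) and a
small posterior P₁ cell — required for reliably successful development?
When the first division is experimentally equalized, some embryos live and
some die; the analysis here quantifies how equalized embryos deviate from
normal development cell by cell, and whether an embryo's fate can be
predicted from its first few divisions.

The package is aimed at researchers analysing nucleus-tracking lineage data
(StarryNite/AceTree exports or a plain long-format table) and at anyone who
wants a fully synthetic, seeded test bed for this class of analysis.

## What it computes

1. **Alignment.** Each embryo is aligned in time (a pace-scaling factor
   maximizing the Pearson correlation between cell-count curves, with the
   ABa division as *t* = 0) and space (per-axis size normalization; A-P axis
   from the first principal component of early nuclear positions; D-V axis
   through the MS-lineage centroid; L-R = A-P × D-V).
2. **Reference model.** Control embryos are superimposed by Generalized
   Procrustes Analysis (iterative least-squares rotation + translation onto
   an evolving mean shape); the model stores per-cell mean metaphase
   positions, mean division vectors, and per-minute mean trajectories.
3. **13 features per cell.** Timing (StartTime, EndTime, LifeTime),
   position (pAP, pDV, pLR), movement (totdis, netdis), division
   orientation (aAP, aDV, aLR), and deviation from the reference: the
   angular deviation `aMean` (angle between observed and reference division
   vectors) and the positional deviation `pOV` (distance from the reference
   metaphase position). Plus derived phenotypes: EMS spindle skew > 35°,
   MSa/MSp left-right inversion, extra germline (P₄) divisions, AB–P₁
   division asynchrony.
4. **Group statistics.** Welch tests with Benjamini–Hochberg correction;
   an effect-size screen (|relative effect| ≥ 15%) whose p-value cut-off is
   calibrated to a 10% false-discovery rate by 100 label-shuffle
   permutations; SD/CV variability summaries with ANOVA + Tukey HSD; a
   robustness screen (mean unchanged, variance inflated); lethality by
   relative-AB-size bin and size–asynchrony correlations.
5. **Outcome prediction.** L1-penalized logistic regression over a
   shrinkage path inside stratified 5-fold cross-validation repeated 250
   times; per repetition the λ with minimal cross-validated MSE is chosen
   and the selected features recorded; reports accuracy distributions,
   model sizes, feature inclusion frequencies, and the ROC of the
   minimum-CV-error model, per developmental stage (4/8/15/28 cells).

A synthetic embryo generator (`lineage4d.simulate`) produces tracked
lineages from the 2-cell stage to ~100 cells inside an ellipsoidal
eggshell, with lineage-specific division clocks, AB-size-dependent
P₁-lineage acceleration, and planted dead-embryo signatures (dorsal shift
of ABar progeny, inflated Ca movement, MS/EMS division-angle defects,
ectopic germline divisions), so the whole chain is testable without
microscope data. See `docs/methods.md` for the model and every numerical
choice.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort (84 embryos, mirroring the study's group sizes):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_build_reference.py
python analysis/03_extract_features.py
python analysis/04_group_statistics.py --seed 1
python analysis/05_predict_outcome.py --seed 1
```

which prints, among other things:

```
simulated 84 embryos -> results/cohort
                  n  ab_size  dead
control          18     57.4     0
equalized_alive  21     50.8     0
equalized_dead   28     50.3    28
inverted          7     45.3     7
wild_type        10     59.6     0

reference from 18 controls: 108 cells, 108 division vectors

stage 15: 338 features x 84 embryos
phenotype flags: 9 embryos with extra P4 divisions, 13 with EMS skew

screen: alpha* = 0.002, 3 features pass; top: ['MS.aAP', 'MS.aMean', 'MSp.pAP']
mean CV of cell-cycle duration (%):
control            5.97
equalized_alive    6.36
equalized_dead     7.53
inverted           7.35
wild_type          5.85
AB-P1 asynchrony vs relative AB size: r = 0.42 (p = 0.0011, n = 56)

40 equalized embryos classified (9 excluded for T-arrangement / EMS skew)
stage  4: accuracy 52.4 ± 6.4 %, best-model sensitivity 95 % / specificity 95 %
stage  8: accuracy 74.6 ± 2.9 %, best-model sensitivity 100 % / specificity 100 %
stage 15: accuracy 72.4 ± 3.2 %, best-model sensitivity 58 % / specificity 100 %
stage 28: accuracy 79.3 ± 4.5 %, best-model sensitivity 100 % / specificity 100 %
```

Reading the output: the screen's permutation-calibrated cut-off lands at
α\* = 0.002, and the three features separating equalized-dead from
equalized-alive embryos are exactly where the generator planted its MS
division-angle defect. Cell-cycle variability (CV) rises from controls
through equalized-dead embryos, division asynchrony between AB and P₁
correlates with AB size across upshifted embryos, and a classifier trained
on later-stage features predicts death far better than one restricted to
the 4-cell stage — the planted positional signatures only become visible
once the affected cells exist.

The same chain is available as one command (`lineage4d run --out DIR --seed
1`) or via the library (`lineage4d.pipeline.run_pipeline`). All outputs are
deterministic functions of the seed; rerunning reproduces them
byte-identically.

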