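# fiberscore

Quantification of collagen-fiber architecture in second-harmonic-generation
(SHG) microscopy images, and construction and evaluation of proportional-
hazards prognostic scores built from those features.

## The problem

The arrangement of fibrillar collagen at a tumor boundary carries prognostic
information: curved fibers wrapping early tumor foci, fibers stretched
parallel to the boundary, fibers radiating perpendicular to it, reticular
networks, strongly aligned or chaotic fields, and dense or sparse packing
are recognizable architecture classes with different clinical implications.
SHG imaging shows these fibers label-free, and the macro-scale patterns have
micro-scale correlates that can be measured automatically. This package
implements the full measurement-and-modeling chain for that problem:

1. **Feature extraction.** Each 150 µm × 150 µm region of interest (ROI) is
   reduced to 142 named features: 8 morphological features of the traced
   fiber network (collagen area fraction, fiber count, mean length, mean
   width, straightness = chord/arc, crosslink density, crosslink spacing,
   orientation concentration) and 134 texture features (6 intensity-histogram
   statistics; 80 gray-level co-occurrence statistics over 5 pixel
   displacements × 4 directions; 48 Gabor-bank responses over 4 frequencies
   × 6 orientations × {mean, sd}).
2. **Patient-level scores.** Per-ROI vectors are averaged per patient and
   Z-scored with training-cohort statistics. A feature score is the linear
   combination selected by L1-penalized (LASSO) Cox regression,
   score = Σᵢ β̂ᵢ xᵢ, with the penalty chosen by cross-validated partial
   likelihood. An architecture score is a ridge-Cox fit over eight binary
   pattern indicators; a clinical score is an unpenalized Cox fit over
   clinical covariates. Combined scores weight the component scores by their
   multivariate Cox coefficients.
3. **Survival evaluation.** Cumulative/dynamic ROC at a 60-month horizon
   with inverse-probability-of-censoring weights, Youden-index cutoffs
   frozen on the training cohort, Kaplan–Meier risk stratification with
   log-rank tests and hazard ratios, time-dependent AUC and its
   event-density-weighted integral (iAUC), Harrell's C, nomogram point
   mappings and calibration.

Because real cohorts of this kind are not redistributable, the package
includes a first-class synthetic-data module: an SHG image simulator with
per-fiber ground truth (width, length, curvature, orientation, branch
points) including presets for the eight architecture archetypes, and a
Weibull proportional-hazards cohort simulator with calibrated censoring and
known linear predictor. Every stage is tested against these ground truths.

## Worked example

```bash
python analysis/01_simulate_archetypes.py --seed 1   # render + measure the 8 archetypes
python analysis/02_simulate_cohort.py     --seed 1   # image-backed survival cohort
python analysis/03_fit_scores.py          --seed 1   # LASSO / ridge / clinical / combined
python analysis/04_evaluate_models.py     --seed 1   # AUC, KM, iAUC, C-index, nomogram
```

The archetype step prints per-archetype morphology, ending with

```
lowest straightness:            archetype 5 (0.880)
highest orientation concentration: archetype 2 (0.675)
area fraction dense vs sparse:  0.174 (7) vs 0.025 (8)
highest crosslink density:      archetype 4 (4.345 per 100 um^2)
```

i.e. the dense pattern (7) covers ~7× the collagen area of the sparse one
(8), the reticular pattern (4) has the highest branch-point density, and the
aligned/stretched patterns (2, 3, 5) have the highest orientation
concentration. The evaluation step ends with the training-cohort summary

```
          score  auc_5y    hr  iauc  c_index
      cli_score   0.631 2.170 0.617    0.588
     tcmf_score   0.770 3.772 0.743    0.691
     tacs_score   0.784 4.303 0.770    0.707
tcmf_tacs_score   0.786 4.410 0.770    0.710
     full_score   0.796 5.071 0.778    0.715
```

showing the expected ordering on this simulated cohort: the clinical score
(whose covariates carry no generating signal here) discriminates weakly,
the image-derived scores recover most of the generating hazard (the true
linear predictor's C-index is ≈ 0.71 on this cohort), and the combined
scores do best. All tables land under `results/`.

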