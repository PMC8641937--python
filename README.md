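# eventscales

Event-based time-scale analysis of speech prediction: from hierarchical
recurrent language models to cortical encoding, gradient and
connectivity statistics.

## The problem

When listening to a story, the brain predicts upcoming words from
context at many time scales at once — the current phrase, the sentence,
the unfolding episode. Two candidate architectures could organise such
predictions: a *continuously updating* hierarchy, where every level of
context is refreshed with each incoming word, and a *sparsely updating*,
event-based hierarchy, where a level's context representation is held
fixed until a boundary marks the end of its event. This package
implements the full analysis chain needed to adjudicate between them
with encoding models of brain activity:

1. **Language models** (`eventscales.lm`): stacked LSTM (continuous) and
   hierarchical multiscale LSTM (HM-LSTM, sparse; COPY / UPDATE / FLUSH
   regimes with a learned binary boundary per layer), implemented in
   numpy with full backpropagation through time. The output module sums
   per-layer readouts, so zeroing one readout matrix ("masking") yields
   predictions driven by exactly one layer's time scale.
2. **Predictiveness features** (`eventscales.features`): word-level
   surprisal `-ln p(word | context)`, next-word entropy (ascribed to the
   preceding word) and prediction-target embedding dissimilarity, from
   the full and each masked model; contextual-incongruence control;
   temporal-integration-window analysis via context scrambling.
3. **Design matrices** (`eventscales.design`): double-gamma HRF
   convolution of word-locked features at TR = 0.947 s, per-run
   z-scoring, nuisance assembly, and phase-randomised surrogate features
   (amplitude spectra preserved exactly).
4. **Ridge engine** (`eventscales.ridge`): fourfold cross-validated
   ridge regression with per-fold generalized cross-validation over 100
   log-spaced penalties, fold-averaged weights, Fisher-z encoding
   accuracy, and scrambled-feature null calibration.
5. **ISC / ROI** (`eventscales.isc`): pairwise intersubject correlation,
   participant bootstrap with self-pair exclusion, FDR adjustment, and
   the 80%-of-parcel selection rule.
6. **Gradient** (`eventscales.gradient`): 1-D weight profiles along the
   inferior-superior sheet axis, robust-linear smoothing, constrained and
   unconstrained peak selection, slope fits with coordinate-shuffle
   nulls, cluster-based permutation tests, and the rotation analysis.
7. **Connectivity** (`eventscales.connectivity`): time-scale seeds,
   psychophysiological-interaction regressions, Euclidean distance to the
   neighbour-coupling hypothesis matrix with a circular-shift null, and
   top-down vs bottom-up directionality.
8. **Reading** (`eventscales.reading`): self-paced-reading exclusions,
   speed transform, lagged (−2..+5) spill-over design, and the
   scrambled-null unique contribution of predictiveness.
9. **Synthetic data** (`eventscales.synthetic`): seeded generators for
   hierarchical corpora, cohorts of sheet activity with a planted
   time-scale gradient and surprisal-gated coupling, and reading logs
   with a planted spill-over profile — every downstream statistic has a
   recoverable ground truth.

See `docs/methods.md` for models, formulas and design choices.

## Worked example

Run the end-to-end synthetic pipeline (simulation → encoding → ISC/ROI →
gradient → connectivity → reading) with a planted 8 mm-per-scale
gradient:

```bash
eventscales --seed 0 report --out report.json
```

which prints `pipeline finished in 23.3s; report at report.json`, and in
`report.json` (abridged):

```json
{
  "stages": {
    "simulate": {"n_words": 2600, "n_vertices": 1152},
    "isc":      {"median_isc_max": 0.941, "roi_vertices": 960},
    "encode":   {"mean_z_accuracy": -0.017,
                 "mean_z_accuracy_planted_vertices": 4.42},
    "gradient": {"grand_average_slope_mm": 6.4, "p": 0.002,
                 "planted_slope_mm": 8.0},
    "ppi":      {"mean_distance": 4.208, "p": 0.0164},
    "reading":  {"accuracy": 1.312, "z_accuracy": 118.6}
  }
}
```

Reading the numbers: the intersubject-correlation step selects the 960
vertices of the five parcels carrying shared stimulus-locked signal;
encoding accuracy beats the scrambled-predictiveness null exactly where
signal was planted (z ≈ 4.4 at planted vertices, z ≈ 0 elsewhere); the
constrained-peak gradient fit recovers the planted inferior-to-superior
ordering of surprisal time scales (6.4 mm per scale step against a
planted 8 mm on this small demo sheet, shuffle-null p ≈ 0.002); the PPI
matrices sit closer to the neighbour-coupling hypothesis than circularly
shifted surrogates (p ≈ 0.016); and the reading model detects the
planted spill-over of surprisal on reading speed far above its null
(Fisher-z accuracy 1.31, null z ≈ 119).

Other entry points: `eventscales simulate`, `train`, `score`,
`count-params --breakdown` (trainable-parameter accounting of the
full-scale architectures).

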