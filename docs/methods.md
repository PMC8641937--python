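# Methods

This note documents the models and statistical procedures implemented in
`eventscales`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic-data experiments do and
do not establish.

## Language models

Both language models are stacked recurrent networks over subword
embeddings, implemented directly in numpy (forward pass, full
backpropagation through time, Adam optimisation).

**Continuously updating LSTM.** Each layer updates hidden state `h` and
cell state `c` at every word: gates `i, f, o` are sigmoids and the
candidate `g` a tanh of an affine map of `[x; h_prev]`, with
`c = f⊙c_prev + i⊙g` and `h = o⊙tanh(c)`.

**Sparsely updating HM-LSTM** (simplified hierarchical multiscale
variant, no top-down connections). Each layer carries a scalar binary
boundary indicator `z` and follows one of three regimes per word:

- COPY (`z_self_prev = 0`, `z_below = 0`): `h, c` pass through unchanged
  (bit-identical, not merely approximately);
- UPDATE (`z_self_prev = 0`, `z_below = 1`): the ordinary LSTM update on
  the bottom-up input;
- FLUSH (`z_self_prev = 1`): the cell state is re-initialised from the
  input alone, `c = i⊙g`, discarding all history.

Bottom-up input to layer `l > 1` is `z_below · h_below` — information
moves up only at a boundary. The new boundary is the binarised hard
sigmoid (slope 1, threshold 0.5) of an affine function of the layer's new
hidden state; training uses a straight-through estimator whose gradient
is the hard sigmoid's own slope inside its linear band and zero outside.
The boundary detector exists on every layer including the top one (the
top indicator only drives that layer's own FLUSH).

**Output module and masking.** Per-layer readout matrices
`R_l ∈ R^{units×units}` map each hidden state into a summed combined
representation `h_r = Σ_l R_l h_l`, followed by a dense softmax over the
vocabulary. Summation (rather than concatenation) makes masking exact:
zeroing `R_l` removes exactly one layer's contribution while the
recurrent dynamics are untouched, so time-scale-specific predictions come
from a model whose internal state evolution is identical to the full
model's. The identity mask reproduces the full forward pass exactly (a
tested invariant). Embeddings are frozen by default
(`embeddings_trainable` exists for completeness).

**Parameter accounting.** At the full-scale configuration (5 layers ×
300 units, 100-d embeddings, vocabulary 91,645) the reconstruction used
here counts, per variant:

| component | LSTM | HM-LSTM |
| --- | ---: | ---: |
| recurrent stack (5 cells, single bias each) | 3,366,000 | 3,366,000 |
| boundary detectors (5 × (300 + 1)) | — | 1,505 |
| readout matrices (5 × 300 × 300) | 450,000 | 450,000 |
| softmax (300 × 91,645 + 91,645) | 27,585,145 | 27,585,145 |
| **total** | **31,401,145** | **31,402,650** |

The published totals for the corresponding full-scale models are
31,428,745 and 31,431,570 — differences of 27,600 and 28,920 (−0.088% and
−0.092%). The original output-module parameterisation is described only
in supplementary material that is not publicly specified in enough
detail to reconstruct; an exhaustive mechanized search over architecture
variants (trainable embeddings, double cell biases, input projections,
skip connections, readout biases, concatenated or gated readouts,
intermediate dense layers, boundary detectors on the joint gate kernel,
trainable initial states and slopes) found no coherent structure that
reproduces both published totals jointly. The package therefore reports
the computed totals with the per-tensor breakdown
(`eventscales.lm.parameter_accounting_report`) and states the residual
difference explicitly instead of hiding it in an opaque constant.

**Training.** Minibatches of 16 sequences (500 words at full scale;
shorter in the scaled-down runs), categorical cross-entropy, Adam, early
stopping after two epochs without validation improvement. Two choices
matter for small-scale HM-LSTM training and are exposed as parameters:
the boundary-detector bias starts at 0 (boundaries initially fire, so
upper layers receive input from the first step) and boundary parameters
use a reduced learning-rate scale (default 0.3; the bundled
integration-window experiment uses 0.005). Without these, the boundary
pre-activations race out of the straight-through band before the cells
have learned anything and the detectors freeze at one of the two
degenerate extremes (copy-forever or flush-forever). This plays the role
that slope annealing plays in large-scale training of such models, while
keeping the binarisation itself exactly as specified.

Even so, boundary learning at tiny scale is bistable across optimisation
restarts: because every layer shares the hidden state that drives its
boundary detector, the cells themselves can steer the detectors into a
collapsed regime (layer 1 hoarding all memory with the upper layers
idle). The collapsed solutions reach visibly worse validation
cross-entropy than solutions that engage the stack, so the bundled
experiment trains several restarts and keeps the one with the best
validation loss — the same selection principle used for the full-scale
hyperparameter search — with the restart seeds fixed in the test, never
chosen by the outcome of the slope analysis.

## Predictiveness features

For each word (position `p`, context truncated to the most recent 500
words; words early in a text are scored with their shorter context):

- **surprisal** = −ln of the probability assigned to the actual word
  (natural log by default, configurable to log2; zero probabilities are
  floored at 1e-10 and flagged);
- **entropy** of the next-word distribution, stored at word `p − 1`
  because everything needed to compute it is available before word `p`
  arrives;
- **dissimilarity** = 1 − Pearson correlation between the embeddings of
  the predicted (argmax, ties to the lowest token id) and actual word.

Each metric is computed for the full model and for each of the five
masked models: 18 feature columns per language model. The contextual
incongruence control correlates a word's embedding with the mean
embedding of its preceding window (2–32 words); it is computed for every
word by default with an optional function-word filter.

**Integration windows.** Context is scrambled at granularities
1–256 words (1–64 in the scaled-down experiments): for each evaluation
position, the words beyond the most recent `g` are permuted uniformly
(seeded), leaving the last `g` context words untouched. Per layer, an
ordinary least-squares line (with intercept) is fit to mean masked
surprisal against log2 granularity; a second-level line across layers
summarises whether deeper layers benefit more from longer context. The
null shuffles first-level slopes across layers (10,000 times at full
scale); between-model comparison is a Monte Carlo permutation test on the
difference of means.

## Design matrices

Word-locked features become unit impulses at word onsets (duration
ignored), convolved with a canonical double-gamma HRF (gamma shapes 6 and
16, undershoot ratio 1/6, peak near 5 s — configurable) on a 50 ms grid
and sampled at TR = 0.947 s. Columns are z-scored per run; constant
columns are dropped with a log message; entropy at each run's final word
(no successor) is imputed with the run mean and flagged. Linguistic
nuisance columns: word-presentation train (coded 1), content/function
flag (±1), Zipf frequency. Nine acoustic components enter as opaque
sample-aligned nuisance columns (the synthetic generator emits white
noise stand-ins).

**Surrogates.** Phase randomisation per run: FFT, uniform random phase
rotation with conjugate symmetry (DC and Nyquist fixed), inverse FFT —
the amplitude spectrum is preserved to machine precision while temporal
alignment is destroyed. 500 surrogate versions of the predictiveness
columns (nuisance intact) form the null family for encoding accuracy.

## Ridge engine

Runs are paired (each odd-numbered run with its successor) into four
cross-validation folds; each fold is the test set once. Within each
fold, generalized cross-validation on the training portion selects the
penalty from 100 log-spaced values in [1e−5, 1e8], using
`‖y − ŷ‖² / (n·(1 − tr(H)/n)²)` with `H` the ridge hat matrix (computed
via SVD; an exhaustive-grid test asserts the selected penalty minimises
the criterion). Weights from the optimal-penalty fits are averaged over
folds; encoding accuracy is the fold-mean correlation of predicted and
observed held-out response, Fisher z-transformed. Columns are z-scored
per run upstream and not re-standardised within folds; the response is
centred per fold with the training mean (whether the original analysis
re-centred within folds is not stated; this choice is documented rather
than guessed silently). Scrambled-design refits reuse the frozen
per-fold penalties, and the observed accuracy is z-scored against the
scrambled-accuracy distribution; a degenerate null spread yields z = 0
with a log message.

## Intersubject correlation and ROI selection

Vertex-wise Pearson correlations between all participant pairs
(concatenated runs), median group map, and a bootstrap hypothesis test
(10,000 iterations at full scale): participants are resampled with
replacement, self-pairs excluded, and the observed median is ranked
against the z-normalised, null-centred bootstrap distribution
(Hall–Wilson shift). p-values are Benjamini–Hochberg adjusted; a parcel
enters the ROI when ≥ 80% of its vertices are significant at q < 0.01.
The eligible parcel family is a configuration list (the synthetic sheet
uses six bands along the inferior-superior axis). Zero-variance vertex
series yield undefined correlations, which are excluded from the median.

## Gradient analysis

Weight maps are collapsed into 1-D profiles along the inferior-superior
axis (2 mm windows, 1 mm steps), then smoothed by a robust local linear
fit: iteratively reweighted least squares with bisquare weights, two
reweighting iterations, over a 70 mm window at full scale. The robust
estimator and iteration count are unspecified in the source analysis;
bisquare with two iterations is the documented, configurable choice. On
the synthetic 48 mm sheet the smoothing window is scaled to 12 mm — a
70 mm window would span the whole axis and flatten every profile (the
full-scale axis is 212–234 mm, so 70 mm is about a third of it; 12 mm
preserves that proportion).

Peaks are local maxima (strictly larger than both neighbours); the
highest positive one is selected. Constrained (dorsal-stream) selection
restricts scale 1 to the inferior half of the occupied axis and scales
2–5 to positions strictly superior to scale 1's peak; when no admissible
positive local maximum exists, the largest positive value in the
admissible region is used and flagged. Per-participant least-squares
slopes across the five peak coordinates are tested one-sided (positive
gradient hypothesised) against a null that shuffles each participant's
coordinates across time scales (scale 1 held fixed in constrained mode,
since it is preset there); between-model comparison permutes model
labels within participants.

Cluster inference on the sheet: one-sample t per vertex, vertices kept
if significant at α = 0.05 with at least two significant neighbours
(8-connectivity on the synthetic grid; the adjacency is pluggable for
real meshes), positive and negative clusters separately, summed t as the
cluster statistic, max-cluster null from scrambled partitions,
significance at 2.5% per sign. The rotation analysis rotates sheet
coordinates about the centroid in 5° steps, recomputes unconstrained
profiles/peaks/slopes per rotation, and clusters significant rotations
in the circular rotation domain. The encoding-accuracy contrast is a
paired cluster test whose null shuffles model labels within participants
(sign flips, n = 1000).

## Connectivity

Seeds: the inferior-superior coordinate of each time scale is the
grand-median constrained peak; the anterior-posterior coordinate is the
peak of a moving-average profile (window 2 mm along anterior-posterior ×
5 mm along inferior-superior) of that scale's weight map; a sphere of
radius 5 mm (the figure caption of the source analysis says 6 mm where
its methods say 5 mm; 5 mm is the default, 6 mm available) collects
member vertices, whose mean activity is the seed series. For each
target scale, the design stacks the physiological, psychological
(HRF-convolved surprisal) and psychophysiological-interaction (pointwise
product, formed after per-run z-scoring of both factors) regressors of
all four predictor scales jointly — 12 columns — and the target series is
fit with the shared ridge scheme. The four fold-averaged PPI weights
fill the target's row of a 5×5 matrix (diagonal empty; upper triangle
top-down, lower bottom-up).

The hypothesis matrix sets the first off-diagonals to +1 and every other
off-diagonal entry to −1. Group-mean Euclidean distance over the 20
off-diagonal entries is ranked against a null in which each
participant's target series are circularly shifted by a uniformly drawn
whole number of runs (1–7, in samples, wrapping within the concatenated
session) before refitting — autocorrelation preserved, stimulus
alignment destroyed. Directionality compares upper- and lower-triangle
means with a paired sign-flip permutation test.

## Reading model

Trials outside (0.001 s, 6 s] are excluded; times are inverted to speed;
the within-run 3-SD rule is applied to speeds iteratively to a fixpoint
(so preprocessing is idempotent — rerunning on its own output changes
nothing); retained speeds are z-scored per run; runs with fewer than
three retained trials are dropped. The practice effect across runs is
tested against a null of slopes fit to shuffled run-mean speeds.

The design holds lagged copies (−2..+5 word positions) of every
predictiveness and nuisance column (length, frequency, content flag);
trial number enters unlagged; edge trials missing a lag get zeros plus a
shared missing-lag indicator, which keeps edge trials in the design at
full rank. Folds are single runs (participants completed four runs).
The null for the unique contribution of predictiveness phase-scrambles
each base word series once and rebuilds its lagged copies, preserving
the strong correlation structure among lags — scrambling lag columns
independently would give the null more effective degrees of freedom than
the observed design and mis-calibrate the z-score.

## Synthetic data

The generator plants known structure so every downstream statistic has a
recoverable target:

- **Corpus**: a nested hierarchy of latent topic states with geometric
  event lengths; boundary sequences are nested by construction. Default
  emission regime "sequences": level-1 events are fixed token sequences
  ("words" from a small lexicon), the next word is drawn from the active
  level-2 topic, deeper topics generate topics of the level below. Within
  an event the next token is predictable from short context; across
  boundaries prediction requires coarse topics inferred from long
  context. An alternative "mixture" regime emits each token independently
  from the topic distribution of a uniformly chosen level. The sequence
  regime is the default because it creates genuine pressure toward sparse
  updating: under the mixture regime flushing always destroys useful
  state at layer 1 (the next token is exchangeable with the last), so a
  trained boundary detector rationally collapses to copy-forever and the
  hierarchy never engages.
- **Cohort**: a 40 × 60 vertex sheet at 1 mm pitch (scaled to 24 × 48 in
  the bundled experiments), TR 0.947 s, 519 samples per run at full scale
  (96 in the experiments). Vertex activity = HRF-convolved surprisal at
  the vertex's assigned scale × gain + a stimulus-locked component shared
  across participants (drives intersubject correlation) + independent
  Gaussian noise; planted couplings add
  `amplitude · z(source activity) · z(source surprisal)` to the target
  blob, realising the hypothesised interaction. Scale blobs are placed
  along the inferior-superior axis with a configurable true slope.
- **Reading logs**: log reading time = baseline + planted spill-over
  profile on z-scored surprisal (lags −2..5) + length and frequency
  effects + log-normal noise, clipped to (0, 6] s.

What the generator does **not** emulate: scanner artefacts, motion,
physiological noise spectra, spatial autocorrelation of BOLD noise,
hemodynamic variability across vertices, the acoustic masker stream, or
lexical/syntactic structure of natural language. Passing recovery tests
therefore demonstrates that the estimators are correct and calibrated
under their own generative assumptions, not that the effects are
detectable in real recordings.

## Problem sizes in the bundled experiments

The test and demonstration runs use deliberately small problem sizes
chosen to exercise every code path with stable statistics: corpora of
2,600–24,000 tokens over vocabularies of 16–48, models of 2–3 layers ×
8–32 units, cohorts of 2–6 participants × 8 runs × 96 samples on a
24 × 48 mm sheet, 20–100 surrogate designs, 200–2,000 permutations, and
7 seeds per planted-slope condition. Full-scale constants (500-word
context, 100-λ grid, 500 surrogates, 10,000 permutations, 70 mm
smoothing) remain the library defaults.

## Known limitations

- Tiny HM-LSTM training is sensitive to the boundary learning dynamics;
  the defaults documented above give reproducible hierarchies on the
  bundled corpus but are not tuned for other corpora.
- The GCV-then-freeze null (penalties selected on observed data, reused
  for surrogates) follows the source procedure; its z-scores are
  empirically near standard-normal in the bundled calibration runs, but
  the procedure has no exactness guarantee.
- The rotation analysis recomputes profiles per rotation on the
  rectangular synthetic sheet; on real flattened meshes the occupied
  region changes shape under rotation, which is handled by the same code
  path but untested against real geometry.
- The circular-shift null shifts seed series jointly per participant;
  with very few runs the shift space is small and p-values are coarse.
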