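# Methods

## The encoding and its assumptions

The pipeline assumes each input is an already-segmented, fixed-length
12-lead ECG beat: a 12×L real matrix in millivolts with a consistent,
declared lead order (I, II, III, aVR, aVL, aVF, V1–V6). No filtering,
baseline removal or R-peak alignment is performed; beats are consumed as
given.

The lead-rank transform keeps only the *ordering* of the 12 leads at each
sample. This discards absolute amplitude information by construction:
`transform(a·beat + b·1) = transform(beat)` for any positive scale `a` and
per-sample baseline `b` common to all leads. Conditions that manifest as
changes in relative lead amplitudes (axis shifts, regional infarcts
attenuating some leads) alter the encoding; global gain changes do not.

Signed amplitudes are ranked, not absolute values. Ties are resolved by the
lower lead index (stable sort on negated amplitudes); this is an
implementation convention required for determinism — continuous data has
ties with probability zero, but all-zero test blocks and flat-lined leads
need a fixed rule.

Transition counts are first-order and per-beat (no cross-beat
concatenation). Within an aligned 12-block a lead index never repeats, so
diagonal cells (a→a) can only arise across sample boundaries: their values
measure rank stability between consecutive samples. Row normalization uses
`mat[k,·]/(Σ mat[k,·] + ε)` with ε = 1e-10 by default — negligible against
counts at L = 651 but keeping all-zero rows at zero. The 144-vector is the
row-major flattening; the symbolic decoding `u → (⌈u/12⌉, ((u−1) mod 12)+1)`
is defined as its exact inverse, so "from-lead = row, to-lead = column"
holds end-to-end. (A literal reading of the published decoding arithmetic
maps index 12 to column 1; we use the mathematically consistent inverse
instead and treat the published formula as a typo.)

## Feature selection

NCA weighting uses the per-feature-weight variant with an L1 base distance:

    d_ij = Σ_f w_f²·|x_if − x_jf|,    p_ij = exp(−d_ij) / Σ_{k≠i} exp(−d_ik)
    F(w) = (1/N)·Σ_i Σ_{j≠i, y_j=y_i} p_ij − λ·Σ_f w_f²

maximized with L-BFGS-B (analytic gradient, start w = 1, default 100
iterations, ftol 1e-6). λ defaults to 1/N. The fit is deterministic; an
optional seeded jitter on the start point exists but is off by default.
Squared weights below 1e-12 of the maximum are snapped to zero before
ranking, so the heavy-regularization limit degrades gracefully to index
order under the stable tie rule (ties → lower feature index). The memory
cost is O(N²·F) for the cached per-feature distance tensor, which targets
beat counts in the hundreds to low thousands.

The iterative stage evaluates ranking prefixes j = start..stop (defaults
1..144) with a pooled out-of-fold 1-NN misclassification rate. One stratified
fold partition, drawn once from the CV seed, is reused for every prefix, so
the loss curve is comparable across sizes; L1 distances are accumulated
column-by-column, making the whole sweep one rank-ordered pass. The chosen
size is the *first* argmin of the curve (fewest features on ties).

**Selection bias, reproduced deliberately.** The default pipeline ranks and
chooses features using the labels of all beats, then cross-validates on the
same data — the selected-feature CV accuracy is therefore optimistically
biased. This mirrors the original procedure and is what `fit()` reports.
`selection.nested_evaluate` (CLI `--nested`) reruns the entire selection
inside each training fold and gives the unbiased estimate; it is off by
default to match the reference procedure.

## Classification and metrics

1-NN with cityblock distance; distance ties go to the lowest training row
index (k = 1 makes vote ties impossible). Folds are stratified and seeded;
stratification is an explicit choice because unstratified 10-fold CV is
ill-posed for strongly imbalanced corpora (minority classes smaller than the
fold count). When the smallest class has fewer members than the requested
folds, the fold count is reduced to that size with a warning. G-mean is
defined over class-wise recalls, `100·(Π_c recall_c)^{1/K}`, zero if any
class is never recovered; the alternative sensitivity/specificity definition
is not used.

## Symbolic layer

The alphabet is the fixed 12-symbol tuple
`(Ld1, Ld2, Ld3, AVR, AVL, AVF, V1S, V2S, V3A, V4A, V5L, V6L)`, one
3-character symbol per lead in conventional order. Sentences list the
(from, to) symbol pairs of the selected features in ranking order — the
selection order is the only ordering the procedure defines. Entropy is
base-2 Shannon entropy of the token distribution (range 0..log₂12 ≈ 3.5850
bits). Connectome graphs are directed, 12 fixed nodes, integer `count` edge
weights, in three modes:

- `sentence-transitions` (default): counts of consecutive token pairs in the
  sentence, including pairs spanning feature boundaries — the literal
  "transition table of the sentence";
- `feature-pairs`: one edge per selected feature, a cleaner view of *which*
  cells were selected;
- `class-aggregate`: the selected cells weighted by summed raw transition
  counts over one class's beats, connecting the explanation back to the
  signal statistics.

The two reference sentences shipped in `cardioish.reference` re-tokenize
exactly to their published frequency rows (194 and 188 tokens); their
frequency-row entropies are 3.5752 and 3.5637 bits. The published entropy
table pairs these two values with the opposite corpora; we pin tests to the
count→entropy computation and take no position on which labelling was
intended.

## Synthetic beats

A beat is Σ of five Gaussian waves (P, Q, R, S, T) on an L-sample grid
(default L = 651; centers 195/305/325/345/475, widths 18/6/9/7/30 samples,
amplitudes 0.15/−0.10/1.00/−0.25/0.35 mV — plausible for a beat centred on
the R peak), broadcast to 12 leads by per-class multiplicative gains plus
per-lead offsets, plus i.i.d. Gaussian noise. Per-beat noise streams derive
from `SeedSequence(master, spawn_key=beat_index)`, so beat sets are
byte-identical across runs.

Class structure lives in the gain ordering: `example_profiles` assigns the
gain ladder 1.4..0.7 to the leads in class-specific permutations, with a
shared offset ladder +0.25..−0.25 mV. The offsets keep adjacent-lead gaps
bounded away from zero even where the waveform is near zero — without them,
baseline samples have essentially tied leads whose ranking randomizes under
any noise, and noise calibration has a floor.

`calibrate_noise_sd` solves for the noise level at which the expected
fraction of rank-adjacent lead pairs flipped per sample hits a target
(default 10%), using the closed form `P(flip) = Φ(−gap/(σ√2))` averaged over
samples and adjacent pairs, by bisection. The closed form is validated
against direct simulation in the tests.

**What a green synthetic test establishes — and what it does not.** The
generator produces stationary, class-pure, perfectly segmented beats whose
discriminative structure is exactly the kind the encoding measures. Green
tests establish that the implementation recovers planted rank structure
under calibrated noise; they say nothing about performance on clinical ECGs,
with beat-segmentation error, inter-patient variability, or class structure
not expressible as lead-amplitude scaling.

## Numerical and degenerate-input choices

- ε = 1e-10 in both row and min-max normalization; constant feature columns
  normalize to zero rather than raising.
- All public indexes (leads, features, labels, samples in text files) are
  1-based; internal arithmetic is 0-based.
- Empty selections produce a valid zero-length sentence but entropy is
  undefined (error) on empty token lists; one-token sequences yield an empty
  transition table with a warning.
- `argmin` semantics everywhere: first minimum, hence deterministic.

## Scope limitations

- No WFDB/EDF readers: input is the delimited text pair or the `.npz`
  container; beats must be pre-segmented.
- No alternative rankings (ascending/absolute), no k-gram transition
  features, no classifiers beyond kNN, no physiological beat dynamics.
- NCA hyperparameters of the original MATLAB implementation are unknowable;
  the deterministic L-BFGS variant documented above is this package's
  definition.
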