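# Methods

## The problem

Multi-voxel fMRI decoding feeds a spatial pattern — one value per selected
voxel/channel at a single acquisition time — to a classifier.  These spatial
vectors are non-stationary "signals" over channel index, and empirical mode
decomposition (EMD) is a natural adaptive way to split them into
spatial-frequency components (intrinsic mode functions, IMFs) without a fixed
basis.  Plain EMD, however, fits its envelopes with non-periodic cubic
splines, which distorts the components near the first and last channel (the
*end effect*).  The channel sequence of a spatial pattern has no physically
meaningful start or end, so this package closes it into a ring: envelopes
become periodic cubic splines, the end effect disappears by construction, and
the decomposition becomes exactly equivariant under rotation of the channel
order.

## Circular EMD

For a ring signal `x` of length `N` (indices mod `N`):

1. Find circular strict local maxima and minima.  Plateaus are collapsed to
   their middle index (left-middle for even run length) — a deterministic,
   rotation-consistent tie-break.  Zero-valued samples are skipped when
   counting zero crossings, so a sign change across a zero run counts once
   and the circular count is always even.
2. Fit one **periodic cubic spline** through the maxima and one through the
   minima (period `N`), average them into the mean envelope `m`, and subtract:
   `h := x − m`.
3. Repeat until `h` is an IMF: its circular extrema and zero-crossing counts
   differ by at most one, and `max|m| ≤ mean_env_tol · max|h|`.  Sifting also
   stops when the Cauchy criterion `Σ(h_prev − h_new)² / Σ h_prev² <
   sd_tol` triggers or `max_sift_iters` is reached.
4. Subtract the accepted IMF from the running residual and repeat.  On a ring
   a non-constant signal cannot be monotonic, so the terminal state is:
   residual has fewer than two maxima or minima, or its peak-to-peak
   amplitude falls below `residual_amp_tol` times the input's, or
   `max_imfs` components have been extracted.

The identity `x = Σ IMF_i + residual` holds to floating-point cancellation
because every component is produced by subtraction from the running residual.

### Periodic spline system

The envelope spline's knot second derivatives (moments `M_j`) solve the
cyclic tridiagonal system

```
μ_j M_{j−1} + 2 M_j + λ_j M_{j+1} = 6 f[t_{j−1}, t_j, t_{j+1}],
μ_j = h_{j−1}/(h_{j−1}+h_j),  λ_j = h_j/(h_{j−1}+h_j),
```

with `f` the second divided difference, all indices cyclic and the wrap gap
`period − t_{m−1} + t_0`.  Envelope knots sit at extrema, so gaps are general,
not unit.  The system is solved densely (at most a few dozen knots per
envelope); tests assert the row-wise residual of the solved system stays
below `1e−10` of the data scale, and the evaluated spline is checked against
two independent oracles — a brute-force per-segment coefficient solve and
scipy's periodic `CubicSpline` — to `1e−8` and better.  `m = 2` knots remain
well-posed (the cyclic system degenerates to a nonsingular 2×2); `m = 1`
yields the constant spline.

### Sifting defaults and rationale

| parameter | default | meaning |
|---|---|---|
| `mean_env_tol` | 0.05 | relaxed zero-mean-envelope condition, fraction of peak amplitude |
| `sd_tol` | 0.2 | classical Cauchy sifting threshold |
| `max_sift_iters` | 100 | cap on subtractions per component |
| `max_imfs` | 10 | cap on extracted components |
| `residual_amp_tol` | 1e−12 | relative residual amplitude at which decomposition stops |

These are the conventional sifting settings for short signals; 200-channel
spatial vectors from the emulated study decompose into roughly 4–7 IMFs
under them, with single-digit sift counts.

### Classic baseline

`classic_emd` runs the same sifting loop with **natural** cubic splines
through the interior extrema and *no* end extension.  This deliberately keeps
the boundary pathology: beyond the outermost extrema the envelope
extrapolates, components pick up spurious end swings, and the decomposition
is not rotation-equivariant.  The baseline exists so the circular variant's
advantage (smaller end-to-end jumps `|c[0] − c[N−1]|` of the components,
exact rotation equivariance) is measurable rather than asserted.  Zero-padded
variants of the baseline exist in the literature; natural splines without
extension were chosen here as the cleanest form of the uncorrected behaviour.

## Spectral summaries

Each IMF is summarised by its FFT half-spectrum: normalised spatial
frequencies `2πk/N ∈ [0, π]`, magnitudes, total energy (equal to the
time-domain sum of squares, asserted via Parseval to `1e−8` relative), and
the dominant frequency.  The zero bin is excluded from the dominant-frequency
search whenever any oscillatory bin is non-negligible (relative magnitude
above `1e−12`), so an offset never masquerades as an oscillation.  Dominant
frequencies are expected to be non-increasing across IMF order; because
sifting is approximate this is reported as a flag and asserted statistically
(≥ 90% of random two-tone trials), not per-signal.

## Preprocessing flow

Raw input is a set of runs (volumes × channels, one condition code per
volume; 1 = rest, 2–4 = task classes).  Stages, in order:

1. **shift** (default 1 TR): pair volume `t + shift` with condition `t`
   (hemodynamic-delay compensation); trailing volumes are dropped.
2. **ROI selection**: keep channels of the requested regions, order intact.
3. **t-value channel selection**: pooled two-sample t (task vs. rest volumes
   across runs) per channel; drop below 3.2, keep the top 200 by statistic.
   The exact statistic used by the original preprocessing toolbox is not
   documented; a pooled-variance two-sample t is the conventional choice
   consistent with a 3.2 threshold.
4. **outlier clipping**: per channel per run, two passes of clipping to
   mean ± 4 SD (clipping, not deletion, keeps labels aligned).
5. **detrend**: remove the least-squares line per channel per run, keeping
   the run mean so the next stage still sees physiological levels.
6. **baseline normalisation**: percent signal change `100·(x − b)/b`
   against the run's baseline-condition mean (all conditions by default,
   i.e. the run mean).
7. **spatial z-norm**: each volume z-scored across channels, population-SD
   convention (divide by n).
8. **task-condition selection**: keep task volumes as labelled samples.

On the emulated design this yields exactly 240 samples × 200 channels,
balanced 80/80/80, and leave-one-run-out folds of 216 training / 24 test
samples.

## Classifiers

* **SVM**: one-vs-one C-SVC with Gaussian kernel
  `K(x₁,x₂) = exp(−‖x₁−x₂‖²/2σ²)`, `σ² = n_features/2` (the libsvm default
  `gamma = 1/n_features`), `C = 1`, termination tolerance `1e−3`
  (scikit-learn backend).
* **Logistic regression**: multinomial softmax minimising categorical
  cross-entropy (scikit-learn backend).
* **Neural network**: 200 → 300 → 200 → 100 → 3 feed-forward net, ReLU,
  per-feature batch normalisation and dropout (rate 0.5) on every hidden
  layer, categorical cross-entropy `−(1/n) Σ_x Σ_c y_c ln z_c`, mini-batches
  of 32, Adam at learning rate `1e−3` for 200 epochs, implemented directly
  in numpy.  Training is fully seeded and single-threaded deterministic;
  evaluation uses running batch-norm statistics with dropout off.  The
  optimiser, epoch count, learning rate and dropout rate are free choices
  (standard values); the architecture, batch size, regularisers and loss are
  fixed by the reference configuration.

Cross-validation treats each acquisition run as one fold (the only grouping
consistent with 216/24 splits on the 10-run design).  Per fold the model is
refit from scratch with a deterministic per-fold seed.  Reports contain
per-fold accuracy, the pooled true×predicted confusion matrix, and
support-weighted precision/recall/F1 computed from the confusion counts (a
never-predicted class contributes precision 0 with a warning); with balanced
classes the weighted and macro averages coincide and weighted recall equals
pooled accuracy.

Feature modes: the raw channel vector; a single IMF; a sum of chosen IMFs; or
all IMFs (the sample minus its residual trend — the configuration of interest,
since the residual carries non-oscillatory drift with no class information).
Samples whose decomposition is shorter than a requested index contribute zero
vectors, logged.

## Synthetic data

`make_circular_tones` builds sums of exact circular harmonics (integer cycle
counts, so components close the ring by construction) with optional offset
and seeded Gaussian noise — ground truth for separation and end-effect tests.

`make_emulated_study` emulates the decoding session's structure: 10 runs × 32
states (8 rest + 24 task, three balanced classes; rest interleaved one per
three task states, class order rotating with block and run so the design is
balanced), one volume per state plus a trailing rest volume, 300 channels of
which the first 250 respond to task.  Task volumes add, with a one-volume
hemodynamic delay, an activation pattern = offset (2 raw units above a
baseline of 100, i.e. 2% signal change — a realistic BOLD effect size) plus
a class-specific circular harmonic across the signal channels (amplitude 1,
frequencies 3/8/19 cycles — well-separated spatial scales, giving the IMF
features a mechanistic reason to carry class information).  Per-channel
smooth drift (linear + half-sine, amplitude 1) and Gaussian noise (SD 0.5)
are added.  The 250/300 split makes the t-selection stage meaningful: the 50
noise-only channels are rejected, and exactly 200 of the responsive channels
survive.

What the generator does **not** emulate: hemodynamic response shapes beyond a
pure delay, spatial 3-D structure and smoothness of real volumes, scanner
artefacts, inter-subject variability, and realistic overlap between class
patterns.  Passing tests therefore demonstrate that the pipeline recovers
class structure it is designed to recover and that the decomposition behaves
as specified — not that real fMRI data would reach any particular accuracy.
With the default (easy) separation the cross-validated accuracy saturates
near 1.0 for all three classifiers; with the class pattern amplitude set to
zero it sits at chance (1/3).

## Numerical choices and degenerate inputs

* Constant signals: no extrema, zero IMFs, residual = input (not an error).
* Envelopes need ≥ 2 maxima and ≥ 2 minima; below that, decomposition stops
  and the remainder stays in the residual.
* Exact zeros in crossing counts are skipped (see above); plateau tie-break
  is the run's left-middle index.
* All file I/O is headered CSV with 0-based indices and 17-significant-digit
  floats, so round trips are bit-exact.
* Determinism: logistic/SVM runs are bit-reproducible under a fixed seed;
  the numpy network is reproducible in the default single-threaded setting.

## Problem sizes

Default study conditions (10 runs, 240 samples, 200 channels) are used
throughout the tests and the acceptance script; property suites use 20–100
random signals of length 200–256.  These sizes exercise every code path at
full design scale — the only scaled-down piece is the literature-scale
accuracy comparison itself, which would require the original scanner data.

## Known limitations

* The decomposition depends on the channel ordering that defines the ring
  (the ROI concatenation order of the source data); permuting channels other
  than by rotation changes the IMFs.  This is inherent to treating the
  pattern as a 1-D ring.
* The classic baseline implements one specific uncorrected end behaviour
  (natural splines, no extension); it is a reference point, not a survey of
  end-effect fixes.
* `nu`-SVC, alternative kernels, hyperparameter search and GPU training are
  out of scope.
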