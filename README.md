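# circleemd

Circular empirical mode decomposition (EMD) and task-state decoding for
spatial channel signals.

## What this is for

Multi-voxel pattern analysis treats one fMRI acquisition as a vector of
channel (voxel) values and asks a classifier which task the subject was
performing — here, the three gestures rock / scissors / paper.  Those spatial
vectors are non-stationary over the channel index, and EMD decomposes them
adaptively into intrinsic mode functions (IMFs) of decreasing spatial
frequency.  Plain EMD suffers from the *end effect*: its cubic-spline
envelopes distort near the first and last channel.  A spatial pattern has no
meaningful first or last channel, so this package closes the channel sequence
into a ring and fits **periodic** cubic-spline envelopes.  The moments
(second derivatives) `M_j` of each envelope solve the cyclic system

    mu_j M_{j-1} + 2 M_j + lambda_j M_{j+1} = 6 f[t_{j-1}, t_j, t_{j+1}]

with cyclic indices and wrap gap `period - t_{m-1} + t_0`, so the envelope is
C² across the ring joint, there is no boundary to extrapolate at, and the
decomposition `x = Σ C_i + r_n` is exactly equivariant under rotation of the
channel order.

Around the decomposition the package provides the full decoding pipeline:

* preprocessing of raw multi-run recordings (hemodynamic shift, ROI and
  t-value channel selection, outlier clipping, detrending, percent-signal
  change, spatial z-norm, task-sample extraction);
* IMF-based feature construction (single IMF, IMF sums, all IMFs = sample
  minus residual trend);
* three classifiers under leave-one-run-out 10-fold cross-validation:
  RBF-kernel SVM, multinomial logistic regression, and a 300/200/100
  feed-forward network with dropout and batch normalisation;
* a classic (non-periodic) EMD baseline and FFT spectral summaries to
  quantify what the circular construction buys;
* a fully seeded synthetic-study generator so everything is testable without
  any data download.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
import numpy as np
from circleemd import CircularSignal, circle_emd, spectral_separation_report

i = np.arange(256)
fast, slow = np.cos(2*np.pi*8*i/256), np.cos(2*np.pi*2*i/256)
dec = circle_emd(CircularSignal(fast + slow))
print("IMFs:", dec.n_imfs)
print("IMF1 ~ fast tone r =", round(np.corrcoef(dec.imfs[0], fast)[0, 1], 4))
print("IMF2 ~ slow tone r =", round(np.corrcoef(dec.imfs[1], slow)[0, 1], 4))
print("reconstruction error:", np.max(np.abs(dec.reconstruct() - (fast+slow))))
print("dominant frequencies:", [round(f, 4) for f in
      spectral_separation_report(dec).dominant_frequencies])
```

prints

```
IMFs: 2
IMF1 ~ fast tone r = 0.9999
IMF2 ~ slow tone r = 1.0
reconstruction error: 0.0
dominant frequencies: [0.1963, 0.0491]
```

The two tones are recovered in the first two IMFs (correlation ≈ 1), the sum
of components reproduces the input exactly, and the dominant normalised
spatial frequencies 2π·8/256 ≈ 0.1963 and 2π·2/256 ≈ 0.0491 decrease across
the IMF order.

The same flow from the command line, on a simulated study:

```bash
circleemd simulate --out study/ --seed 1
circleemd pipeline --study study/ --out report/ \
    --features original --features all-imfs \
    --classifier logistic --classifier svm --classifier mlp --seed 1
```

which ends with one line per (feature, classifier) pair, e.g.
`all-imfs/mlp: mean accuracy 1.0000` on the default (easy) synthetic
conditions, and writes per-fold accuracy tables, pooled confusion matrices,
weighted precision/recall/F1 and a JSON run summary into `report/`.

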