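# Methods

## Model and assumptions

The classifier treats a heartbeat as a small image. Each beat (one window
around an annotated R peak, min–max normalized per lead) is reshaped to an
`m × n` matrix and passed through a two-stage convolutional cascade whose
kernels are not trained by gradient descent but computed in closed form from
patch statistics:

* **Two-lead (DL) mode** — one CCA per layer between the patch ("pending")
  matrices of the two leads; the first view's canonical vectors become lead
  1's filters, the second view's lead 2's.
* **Three-lead (TL) mode** — a cyclic schedule of pairwise CCAs: layer 1
  pairs (X¹,X²), (X²,X³), (X³,X¹) keeping the first view's vectors for leads
  1–3; layer 2 pairs (Y³,Y¹), (Y¹,Y²), (Y²,Y³) keeping the second view's
  vectors. Every lead thus receives filters informed by one neighbour in the
  cycle.
* **Single-view baselines** — PCA filters (top eigenvectors of `X Xᵀ`) and
  seeded unit-norm Gaussian filters, in the same cascade.

The statistical assumption that motivates CCA here: beat morphology is
common to all leads up to (possibly sign-flipped) scaling, while noise
(baseline drift, EMG-like high-frequency noise) is generated per electrode
and is nearly uncorrelated between leads. Canonical directions maximize
cross-lead correlation, so they favour the shared signal subspace and
suppress lead-specific noise. The cascade output is made scale-robust by
binary hashing (threshold at zero) and translation-robust within blocks by
histogramming.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `S1`, `S2` | samples kept left/right of the R peak | 160/200 (360 Hz protocol), 120/136 (257 Hz protocol) | windows cover one cardiac cycle at each rate |
| `m × n` | ECG-matrix shape | 18×20 (360 samples), 16×16 (256) | near-square minimizes patches straddling the padded border; any factorization of the beat length is accepted |
| `t1 × t2` | patch size (odd) | 7×7 | also the filter size `k1 × k2` |
| `L1`, `L2` | filters per layer | 9 | feature length grows as `2^{L2}`; `L ≤ t1·t2` |
| `u1 × u2` | histogram block | 7×7 | on the lead-concatenated decimal map |
| `R` | block overlap ratio | 0.5 | stride `= max(1, round_half_up(u·(1−R)))` |
| `C` | SVC penalty | 1 | liblinear L2-regularized L2-loss dual, one-vs-rest |
| `ridge` | covariance regularization | 1e-8 × trace/dim | added to `S11`, `S22` before inversion |
| `k` | cross-validation folds | 5 (10 for the 360 Hz protocol) | stratified, seeded, refit per fold |

## Numerical choices

* **CCA route.** `S11` is Cholesky-factored after ridge regularization; the
  whitened symmetric matrix `L11⁻¹S12S22⁻¹S21L11⁻ᵀ` is diagonalized
  (`eigh`), giving `a` with `aᵀS11a = 1` and S-orthogonality between
  solutions by construction. `b` comes from the stationarity condition
  `b ∝ S22⁻¹S21a`, renormalized — this keeps the pair consistently matched
  instead of solving two eigenproblems whose eigenvector phases could
  disagree. Correlations are `√λ`, clipped into `[0, 1+ε]`. Tests compare
  this route against an independent whitening+SVD implementation
  (agreement ≲ 1e-14 in practice).
* **Sign convention.** Canonical/principal vectors are flipped so the
  largest-magnitude component is positive (CCA and PCA are sign-ambiguous;
  a fixed convention makes filters reproducible bit for bit).
* **Patch extraction.** One patch per pixel with zero-padded borders, so an
  `m × n` map always yields `m·n` columns; the patch mean is removed before
  vectorization (row-major pixel order, matching the row-major reshape of
  canonical vectors into kernels). Convolution is zero-padded, same-size
  cross-correlation — the adjoint of that patch extraction.
* **Hashing.** `H(c) = 1` for `c > 0`, and `H(0) = 0`, so exactly-zero
  (degenerate) maps encode to decimal value 0.
* **Stride rounding.** `u=7, R=0.5` gives stride `round_half_up(3.5) = 4`.
  Only fully contained blocks are used, keeping each block's histogram mass
  exactly `u1·u2`.
* **Flat beats** normalize to all-zeros (with a logged warning) instead of
  raising, so batch pipelines survive pathological segments.
* **Reported tables** round half-up to the printed precision; raw values are
  kept internally. Macro averages are computed from unrounded per-class
  values; a per-class metric with a zero denominator is reported as
  undefined (not 0) and excluded from its average with a warning.
* **Folds.** Stratified assignment is done by seeded per-class shuffling and
  round-robin dealing, which warns (rather than fails) when a class has
  fewer members than folds.

## The synthetic generator

Each class is a latent beat: five Gaussian bumps (P, Q, R, S, T) with
class-specific amplitudes on a shared time base. Lead `h` observes
`gain_h · latent · (1 + jitter)` plus a baseline-wander sinusoid with random
per-lead phase and independent white Gaussian noise; `jitter` is a per-beat
scalar shared across leads. Records tile beats at a fixed RR interval so
segmentation round-trips exactly. This reproduces the two properties the
method relies on — cross-lead signal correlation equal to one (up to gain
sign) and cross-lead noise correlation tending to zero — and deliberately
omits others: no heart-rate variability or ectopic timing, no QT adaptation,
no 12-lead torso geometry, no electrode-motion artefact bursts. Passing the
synthetic end-to-end tests therefore demonstrates that the pipeline
exploits shared-morphology/independent-noise structure, not that it attains
any particular accuracy on clinical recordings.

Default study conditions: 3 classes × 150 beats, 2 leads, 256-sample beats,
noise sd 0.05, jitter sd 0.05, baseline amplitude 0.1, gains (1.0, −0.6)
(the sign flip mimics the opposite polarity of a limb and a chest lead).

The **multi-lead-advantage experiment** uses equal-magnitude,
opposite-polarity gains (1.0, −1.0) with strong noise (sd 0.5, baseline
0.3): both leads then carry the full latent signal and differ only in their
independent noise, which is the premise under which cross-lead filtering
should beat a single-lead PCA cascade. With the default asymmetric gains
the second lead's SNR is near 1 and the comparison degenerates into "does
adding an almost-pure-noise lead help" — a different (and uninformative)
question; at equal gains the two-lead cascade wins on every tested seed
(mean advantage ≈ 5 percentage points at these settings).

## Problem sizes

End-to-end experiments in the test suite and acceptance script run at
reduced settings chosen as a sensible desk-scale operating point:
`L1 = L2 = 4`, 16×16 matrices, 150 (discrimination) or 80
(multi-lead-advantage) beats per class, 5 folds, 5 seeds. The structural
identities (feature length `2^{L2}·L1·B`, histogram mass `L1·B·u1·u2`) are
additionally exercised at the full published operating point
(`L1 = L2 = 9`).

## Known limitations

* CCA modes support two or three leads only; richer lead mixing (beyond
  scalar gains in the generator, beyond pairwise CCA in the network) is out
  of scope.
* R peaks are taken from annotations; no peak detector is included, and no
  resampling between sampling rates is performed.
* The per-lead layer-2 maps are concatenated *before* hashing and
  histogramming, which keeps the feature length at `2^{L2}·L1·B` for any
  number of leads; blocks that straddle a lead boundary mix pixels of two
  leads. Histogramming each lead separately would multiply the feature
  length by the lead count and is not implemented.
* The WFDB adapter covers headers, signal formats 16 and 212, and MIT-format
  beat annotations — enough for the two target databases and for synthetic
  round-trips, not the full format family.
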