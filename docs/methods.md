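# Methods

## Interval representation

Every annotated heartbeat is reduced to intervals anchored at its ECG R
peak: the RR interval and the latency of each characteristic point of the
dZ/dt complex (columns RR, RA, RB, RE, RX1, RX2, RY, RO, RZ, all in
seconds). RR(i) is defined as the *forward* interval
r(i+1) − r(i), and each subject's last beat is dropped. The convention
matters because the point columns are later divided by the same row's RR: a
forward interval keeps every latency of beat i inside beat i's own RR
window, so all ratios lie in (0, 1) for physiological annotations. Beats of
different subjects never share a row neighborhood; no delay line crosses a
subject boundary.

Missing annotations are first replaced by the mean of the available cycles,
grouped by (subject, subtype) — the interval table is built per subtype per
volunteer, and subject-level latency structure is worth preserving — with a
same-dataset column-mean fallback when a group has no observed value.
Mean imputation happens on raw intervals, before any normalization, so the
group means are plain seconds. These placeholder values exist only to make
the normalization well defined; the forecaster later overwrites them and a
boolean mask records which cells were originally missing.

## Normalization

Two stages, both invertible and both inverted on output:

1. **RR ratio.** Each point column is divided row-wise by RR, removing
   between-subject heart-rate differences. The RR column itself is retained
   in seconds for the inversion.
2. **Sum of squares.** Each ratio column is divided by its Euclidean norm
   over the pooled rows of *all* datasets, giving unit column sums of
   squares. Different acquisition devices produce different value ranges;
   pooling lets one model serve both. The per-column scales are persisted
   with the model, and new data are scaled with the stored factors rather
   than renormalized, so a model never sees a scale it was not trained
   with (a mismatch is a hard error).

Round-trips hold to 1e−12 and are tested at that tolerance.

## The NARX network

A single-hidden-layer NARX with 8 input and 8 output channels (the eight
point-latency ratios; the exogenous line carries the same series as the
target, x ≡ y, making the model an order-2 nonlinear autoregression with
duplicated tap banks), 10 tanh hidden units, linear output, and delay taps
{1, 2} on both lines:

    y(t) = W_o · tanh(W_x·[x(t−1); x(t−2)] + W_y·[y(t−1); y(t−2)] + b_h) + b_o

418 weights in the default topology. Weights are initialized with seeded
Nguyen–Widrow scaling (uniform fallback available). Channel counts, hidden
size, delays and a linear hidden activation are all configurable; the
linear variant exists mainly so linear-autoregression fits can serve as
exact oracles in tests.

**Open loop (series-parallel).** During training the feedback taps read the
*true* recorded targets (teacher forcing). Every time step then becomes an
independent feed-forward sample, so the exact residual Jacobian is a
per-sample chain rule — no backpropagation through time — and the samples
can be shuffled and split freely. The Jacobian is verified against central
finite differences to a relative error below 1e−5.

**Closed loop (parallel).** For forecasting, the feedback taps read the
network's own previous predictions. Imputation runs a *hybrid* closed loop
along each (subject, subtype) stream: a tap reads the observed value where
the annotation exists and the prediction where it does not, because pure
free-running would discard usable observations. Observed cells are never
overwritten; imputation is forward in time only. ABEXYOZu complexes carry
no points and are skipped (flagged unforecastable), as are the first d_max
rows of each stream, whose delay lines cannot be filled.

**Delay removal.** `remove_delay` shifts every tap index by −1 (taps {1,2}
become {0,1}), leaving the weights bit-identical, so the network emits each
forecast one time step ahead of the original alignment — the forecast of
beat t+1 is available while beat t is being processed. On a fixed recorded
series the shifted taps read exactly the values the original taps read one
step later, so the forecast *values* coincide with the base alignment; the
flag changes latency of availability, not accuracy, in this implementation.
Pure tap shifting was chosen over also prepending delay-line states; the
output range is documented instead of extended.

## Training algorithms

All three trainers minimize the unweighted mean squared error over the 8
channels jointly, on teacher-forced samples randomly split 70/15/15
(row-level split by default; a subject-level split is available for
leakage-aware evaluation). Early stopping monitors the validation loss with
a patience of 6 epochs and always returns the weights of the
best-validation epoch. Defaults (1000 max epochs, μ schedule 1e−3 × 10 /
× 0.1) follow the long-standing defaults of this architecture family; every
value is a `TrainOptions` field.

- **Levenberg–Marquardt (LM):** Δw = −(JᵀJ + μI)⁻¹Jᵀe with multiplicative
  damping; a step is accepted only if the loss decreases, so the
  accepted-step loss trace is non-increasing by construction. μ exceeding
  1e10 stops training (`mu_overflow`).
- **Scaled conjugate gradient (SCG, Møller):** conjugate directions with a
  model-trust-region scale λ and a finite-difference curvature estimate
  along the search direction; only gradient products are used, never an
  explicit JᵀJ, so memory stays linear in the weight count.
- **Bayesian regularization (BR):** LM on F = β·E_D + α·E_W with MacKay
  evidence re-estimation each epoch: γ = N_w − α·tr(H⁻¹) with
  H = β·JᵀJ + α·I, then α = γ/(2E_W), β = (N − γ)/(2E_D). γ is clamped to
  [0, N_w] with a warning; tr(H⁻¹) is computed from the eigenvalues of H
  with a small floor for numerical safety, and α/β are capped to keep the
  damped system finite. Validation stopping is off by default for BR — the
  evidence framework itself controls overfitting — and can be re-enabled.
  Freezing α at 0 provably reduces BR to the LM trajectory (tested).

`compare_algorithms` trains each candidate on identical splits and ranks by
test VEcv, breaking ties by lower RMSE and then declaration order.

## X-candidate selection

Some subtypes carry two X candidates. For each scope (dataset by default)
the selector computes the RMS deviation of each candidate's RR-ratio from a
reference ratio — the candidate's own mean ratio over the typical
(ABEXYOZ0) beats of the same dataset, overridable — and picks the candidate
with the smaller deviation, ties going to X2 (the true X of typical beats).
RMS about the reference is used rather than a plain standard deviation
because a plain SD is invariant to a constant offset and would be blind to
a systematically displaced candidate. Selection is per dataset because the
true candidate can genuinely differ between acquisition devices (the
synthetic study is constructed that way).

## Evaluation

MSE, RMSE and MAE are pooled over channels; Pearson R is the standard
product-moment correlation; VEcv = 100·(1 − Σ(t−p)²/Σ(t−t̄)²) in percent
with the verbal bands very poor (≤10), poor (≤30), average (≤50), good
(≤80) and excellent (>80), upper bounds inclusive; Lin's concordance
correlation coefficient uses population (1/n) moments, following the
original definition, which guarantees |CCC| ≤ |R|. Detection rates count a
complex as detected when no forecastable point remains missing; the
*effective* rate excludes ABEXYOZu complexes from the denominator, since
they contain nothing to detect. Every metric is tested against an
independent pure-Python brute-force implementation to 1e−10 and
cross-checked against scikit-learn where an equivalent exists.

## Synthetic cohort generator

The generator emulates the statistics of beat-to-beat ICG annotation tables
that matter to a delay-2 forecaster, without attempting waveform-morphology
realism:

- **RR intervals:** stationary AR(1) around a subject mean (default
  0.85 s / 0.72 s for the two devices, SD 0.05 s, coefficient 0.6).
- **Latencies:** fraction-of-RR means ordered A < B < E < X1 < X2 < Y < O
  < Z (0.05, 0.10, 0.18, 0.30, 0.38, 0.50, 0.62, 0.75 — order-respecting
  defaults, configurable), plus a subject-level offset (SD 0.01), an AR(1)
  beat-to-beat component (SD 0.012, coefficient 0.6) and iid annotation
  jitter (SD 0.004). The AR component is what gives a delay-2 model signal
  to learn.
- **Subtypes:** drawn from a sticky Markov chain (persistence 0.8) whose
  stationary distribution equals the configured proportions, because
  morphology changes slowly in real recordings and subtype streams must
  contain genuinely adjacent beats for the delay line to be meaningful.
  The default mix is imbalanced, with the typical complex at 25 % and
  ABEXYOZu at 10 %.
- **Missingness:** per-subtype point sets, with the A/B/E and Y/O/Z groups
  masked jointly (enforced at config validation). The default map yields
  ~55 % missing X2 and ~65 % missing Y/O/Z — the heavy range reported for
  beat-to-beat annotation. ABEXYOZu masks everything.
- **True X:** one candidate per device is designated true; the other is
  offset by 0.03 RR and carries extra jitter (SD 0.02), so reference-ratio
  deviation identifies the true one.

The complete (unmasked) matrix is returned alongside the beats, so
held-out accuracy against ground truth is always measurable. What passing
tests on this generator do **not** show: robustness to annotation errors,
artifact beats, non-stationary heart rate, or morphology-driven subtype
correlation with latency shifts — none of which the generator emulates.

## Problem sizes and numerical choices

The default study is two 4-subject cohorts of 100 beats each (792 interval
rows, ~200 typical training samples); the parameter-recovery experiment
uses a 2000-step series. Training runs cap at 100–200 epochs in tests and
examples, which is past convergence for these sizes. Normalization
round-trips are asserted at 1e−12, Jacobian agreement at 1e−5 relative,
metric-oracle agreement at 1e−10. Degenerate inputs fail loudly:
non-positive RR, zero-norm columns, all-missing columns, zero-variance
metric inputs and mismatched normalization scales all raise typed errors
rather than propagating NaNs.

## Known limitations

- The exogenous line duplicates the target series (x ≡ y); a genuinely
  exogenous covariate (e.g. respiration) would need only a config change,
  but is untested.
- Gradients through the closed loop are out of scope; training is
  open-loop only, as is standard for this architecture family.
- Imputation is forward-only; a bidirectional pass could help early-stream
  rows but is not implemented.
- On a fixed recording, delay removal changes forecast availability, not
  forecast values; streaming deployments would see the latency benefit.
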