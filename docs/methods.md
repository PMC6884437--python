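# Methods

## Signal model and the load statistic

The package treats a NIRS session as a uniformly sampled multi-channel
recording (default 10 Hz) split into a resting period and a task period.
Analysis is single-channel: the long (3 cm) left channel is the default,
the other channels participate only in the PCA stage of preprocessing.

Cognitive load at step τ is the conditional entropy of the current 20-s
task window given the 20-s resting baseline,

    CL(X_τ) = H(X_τ | B) = H(X_τ) − MI(X_τ ; B),

with B fixed to the final 20 s of rest for the whole session. Conditioning
(rather than baseline subtraction) is the point of the statistic: entropy is
invariant to translation, so the residual resting activity carried into the
task period can only be discounted through the mutual-information term.

Windows are 20 s long and advance in 10-s steps; window τ ends τ·10 s after
task onset, so the first window overlaps the last 10 s of rest and a task of
T seconds yields floor(T/10) estimates (7 for a 70-s task). This
rest-borrowing makes the estimator available from 10 s after task onset,
at the cost of a first step whose window mixes rest and task signal; the
first step also has no predecessor, so its final value is its raw
conditional entropy.

### The gated update

A change in load must move MI(X;B) and D_KL(X;B) in opposite directions
(more load → less resemblance to rest → lower MI, higher divergence). Each
step after the first is therefore gated on

    (MI_τ ≤ MI_{τ−1} and D_τ > D_{τ−1})  or  (MI_τ > MI_{τ−1} and D_τ ≤ D_{τ−1}),

with the inequality directions exactly as stated (note the asymmetric
placement of the equalities). When the gate passes, the raw conditional
entropy is used; otherwise the step is treated as a spontaneous fluctuation
and smoothed:

    CL(X_τ) = α·H(X_{τ−1}|B) + β·H(X_τ|B),
    α = H(X_{τ−1}|X_τ)/VI,  β = H(X_τ|X_{τ−1})/VI,
    VI = H(X_{τ−1}|X_τ) + H(X_τ|X_{τ−1}).

Because both weights derive from one joint histogram of the two windows,
α + β = 1 holds to machine precision and the averaged value is a convex
combination of the two raw conditional entropies. Two deliberate choices:

* the averaging combines the **raw** conditional entropies, not the
  previously smoothed value — the formula is implemented as written; a
  `recursive=True` flag provides the alternative reading (smoothing the
  smoothed series), which damps fluctuations more aggressively;
* identical consecutive windows give VI = 0 with both numerators 0; the
  weights are then set to ½ by continuity.

A session is summarised by the median of its `cl_final` values — robust to
the occasional outlier step (including the rest-borrowing first step).

## Estimators

All information quantities are discrete plug-in estimates on equal-width
histograms, base-2 logarithms (bits). The plug-in estimator was chosen over
k-NN/KSG-style estimators because the update rule depends on *exact*
identities — H(X|B) = H(X) − MI(X;B) and the two forms of VI — which hold by
construction when every term is computed from one shared joint histogram,
and only approximately otherwise.

Conventions, in one place:

* **Bins**: 16 by default, sized for 200-sample windows (n/12 rule). CL
  values are bin-dependent, so the bin count is recorded in run manifests
  and trace files' provenance. The absolute CL scale is therefore
  arbitrary; only comparisons on a fixed configuration are meaningful.
* **Pairwise support**: MI, conditional entropy and VI bin both series with
  one shared set of edges spanning the pooled min–max of the two inputs (a
  common alphabet is required for joint quantities). Single-window entropy
  spans that window's own range.
* **Bin semantics**: half-open `[e_i, e_{i+1})`, last bin closed;
  out-of-range values are clipped into the terminal bins with a warning.
* **Pairing**: MI between a task window and the baseline pairs samples by
  index; the 20-s window design forces equal lengths.
* **KL divergence**: histograms on shared pooled-range edges, Jeffreys
  smoothing (+0.5 pseudo-count per bin on both sides, then renormalise);
  this keeps D_KL finite, non-negative, and zero iff the smoothed
  histograms coincide. D_KL(X;B) uses P_X as the first argument.
* **Degenerate ranges** (constant windows) get a unit-width support centred
  on the value, so entropies are 0 rather than undefined.

The plug-in estimator is biased (≈ (bins−1)²/(2n·ln2) upward for MI at
independence, ~0.08 bits at n=200, bins=16); the permutation-null test and
the documented tolerances account for this.

## Preprocessing

Three stages, in order, applied to the full recording before splitting at
the rest/task boundary:

1. **Bandpass** 0.01–0.6 Hz, first-order Butterworth, applied
   forward–backward (zero-phase) by default since the estimator is
   windowed-offline; a causal single-pass option exists for strict online
   use. Inputs shorter than 3× the longest filter time constant
   (≈48 s at the defaults) are rejected rather than padded.
2. **Linear detrending** (least squares).
3. **Skin-blood-flow attenuation**: channels are variables, time points
   observations; the first `n_sbf_components` (default 2, options 1–3)
   principal components of the *rest-period* covariance are projected out
   of the task period. Centering uses rest-period channel means for both
   segments, making the stage an affine correction fit on rest only. The
   rest segment itself is centered but *not* SBF-cleaned — the baseline is
   deliberately the raw (conditioned) resting activity. This PCA stage is
   also the motion-artifact control; no separate correction is applied.

Whether to filter rest and task jointly or separately is not constrained by
the windowed design; the package filters the whole recording once and then
splits, which avoids duplicated edge transients at the boundary. PCA removal
is per session.

## Decision boundary

Given CL sets S1 (lower condition) and S2 (higher condition), both with ≥2
elements: sort S1 descending and S2 ascending; find the smallest S1 element
inside S2's range and the largest S2 element inside S1's range (the overlap
markers); take the immediate S1 neighbour strictly below the S1 marker and
the immediate S2 neighbour strictly above the S2 marker; 𝔻 is their
midpoint. All elements in the closed overlap of the two ranges,
[min S2, max S1], are discarded from both sets; 𝔻 strictly separates the
surviving ("refined") sets, and this is asserted on every fit.

Edge cases are explicit and logged: disjoint ranges → midpoint of the
adjacent extremes, nothing discarded; a missing strict neighbour → the
set's own extreme with a warning; inputs in the wrong order → swapped (the
fit is label-agnostic) and flagged; median exactly on 𝔻 → "easy".
Fully nested or identical ranges leave one refined set empty and raise a
fit error — no boundary exists in the sense of this algorithm. Since 𝔻 is
built from extreme order statistics, it is sensitive to outliers in small
samples; this is a property of the algorithm, preserved deliberately.

Overlap-marker membership uses closed intervals (a value equal to a range
endpoint counts as "within" that range).

## Evaluation machinery

* Questionnaire scores 1–8 map to easy (≤4) / difficult (≥5); "difficult"
  is the positive class for tp/fp/fn/tn.
* Undefined ratios (e.g. precision with no positive predictions) are
  reported as absent, never as 0.
* The paired criterion counts strictly greater high-condition medians; ties
  fail.
* Rank tests report the rank-sum z statistic, the raw rank sum, and the
  effect size r = z/√N, since both conventions appear in the literature.
* Bootstraps are percentile bootstraps (the minimal reading of "bootstrap
  confidence interval"); BCa was considered out of scope. The
  correlation bootstrap's two-tailed p is the fraction of the resampled
  distribution whose |ρ| exceeds the observed |ρ| — an unusual definition
  (the bootstrap distribution is centred on the observed statistic, so p
  clusters near 0.5 for moderate correlations), implemented as stated and
  verified against exhaustive resample enumeration at n=6. Resamples with
  a constant margin (undefined ρ) contribute 0.
* The KL bootstrap resamples the two sets independently; note the smoothed
  plug-in D_KL is biased upward, so its CI lower bound sits near, not at,
  zero under the null.
* No multiple-testing correction by default; a Holm option exists in the
  underlying statistics where relevant.

## Synthetic sessions

The generator emulates a forehead total-blood-flow recording with a known
load level, for pipeline validation in the absence of public recordings.
Per channel: band-limited (0.01–0.6 Hz) Gaussian hemodynamics whose
amplitude during the task is `hemo_sigma × load` (rest amplitude
`hemo_sigma`); sinusoidal cardiac (1.1 Hz), respiratory (0.25 Hz) and Mayer
(0.10 Hz) artifacts with random per-channel phases; linear drift
(0.01 units/s); white noise (σ = 0.3). Shared across channels: two
skin-blood-flow components in the 0.1–0.35 Hz band — a dominant global
pattern (amplitude 3.0) and a weaker left–right gradient (amplitude 1.8).
Load levels "low"/"high" map to 1.0/2.0 (a 2:1 task-band amplitude ratio).

Design rationale, in decreasing order of importance:

* **Load as band-limited variance.** The estimator is variance/entropy
  sensitive, so amplitude scaling of the in-band stochastic component is
  the minimal mechanism the pipeline must detect. The hemodynamic noise is
  synthesized by filtering white noise with the same passband as the
  preprocessing filter, so the load signal survives preprocessing by
  construction.
* **Two SBF components, not one.** The preprocessing stage removes a fixed
  two principal components. If the generator injected a rank-one shared
  signal, the second removed component would point at an arbitrary
  direction of per-channel cortical signal, deleting a random fraction of
  the load signal in every session (we measured the induced spread of the
  cleaned task amplitude at up to 0.8 bits in log scale, enough to bury
  the load contrast). A two-component superficial signal is also the more
  physiologically faithful reading of a two-component removal.
* **SBF stays in the baseline.** Components are fit on rest and removed
  from the task only, so the baseline retains the superficial signal. Its
  spread therefore exceeds the cleaned task windows', which keeps the
  shared-alphabet binning in the regime where the window entropy resolves
  the task amplitude — this is what makes median CL increase with load.
  The 0.1–0.35 Hz SBF band (Mayer-wave to respiratory range) gives the
  20-s baseline window several cycles of the dominant component, keeping
  its spread stable across sessions.
* **Per-subject variability** is a log-normal coupling gain
  (σ = 0.2) multiplying *all* amplitudes — optode–skin coupling scales the
  whole measured signal — plus a normal drift perturbation
  (σ = 0.002 units/s). A coupling gain shared within subject cancels in
  the load contrast, as it does physically.

What the generator does **not** emulate: task-evoked mean shifts
(hemodynamic response functions), non-stationary artifact amplitudes,
motion spikes, heartbeat variability, optical path or geometry effects,
and any coupling between load and the artifacts. Passing end-to-end tests
therefore show that the pipeline recovers amplitude-coded load differences
under realistic noise and superficial contamination — not that it would
survive every pathology of real recordings.

## Numerical and size choices in tests

Property tests use 200-sample windows (the operational size), 1000-case
fuzz loops for identities, and seeded generators throughout. End-to-end
checks use 30 subjects per cohort (70-s tasks to fit the boundary, 180-s
sessions — the storytelling length — for classification), chosen to match
the study design the generator emulates while keeping the full suite under
a minute of CPU. Bootstrap calibration uses 500 replications of 25-sample
draws with 2000 resamples; percentile intervals at that sample size are
expected to undercover mildly (~94% observed for a nominal 95%).

## Known limitations

* The absolute CL scale depends on the bin count and window length; values
  are comparable only within a fixed configuration.
* The decision boundary is an order-statistic construction; with heavily
  overlapping populations it can fail (nested ranges) or land far from the
  optimal midpoint. That behaviour is inherited from the algorithm itself.
* The plug-in MI bias grows with bins²/n; configurations far from the
  16-bins/200-sample default shift the CL scale.
* Single-channel analysis only; no fusion across channels, and short
  (1 cm) channels are carried but unused outside the PCA stage.
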