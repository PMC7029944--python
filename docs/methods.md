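# Methods

## Problem and models

`spikeattn` asks whether a population of simultaneously recorded neurons,
presented with two stimuli (one in each hemifield), processes them in
*parallel* (attention divided across neurons) or *serially* (all neurons
locked onto the same stimulus at any instant).  The premise is
probability-mixing at the single-cell level: at any moment a neuron
responds to exactly one of the two stimuli.  Let `X_t^i ∈ {0,1}` indicate
that neuron `i` attends the contralateral stimulus during analysis interval
`t`.  The trial's 400 ms analysis window (100–500 ms after stimulus onset
by default, skipping the response latency) is cut into `I` equal intervals
within which attention is held fixed.

### Spike model

Conditional on the attended stimulus, spikes follow a discrete-time point
process at 1 ms resolution with conditional intensity

    h(s | H_s; x) = r^i(x) · exp( Σ_{j=1..10} β_j ΔN_{s−j} )

`r^i(x)` is a neuron-specific base rate in spikes/ms selected by the
attended stimulus's identity (T / NI / NC at the attended side, or a single
rate for the blank display), giving seven rate slots per neuron over the
full condition set; `β_1..β_10` are history weights shared by all neurons
(negative early lags give refractoriness).  The interval likelihood is the
exact discrete-time product `Σ_spikes log(h·u) − Σ_bins h·u` with `u = 1 ms`;
we treat the continuous point-process density on the 1 ms grid as a Riemann
sum, which is exact for piecewise-constant intensity at the recording
resolution and makes the simulator (per-bin Bernoulli draws with the same
`h`) exactly self-consistent with the likelihood.  Spike history crosses
interval boundaries and reaches 10 ms before the analysis window; those
pre-window spikes are stored data, never zero-padding.

### HMM

A three-state hidden Markov chain `C_t` (attentional regimes) has initial
distribution `λ` (shared across conditions — the first interval precedes
stimulus-identity perception) and per-condition-class transition matrix
`Γ_m`.  Given `C_t = c`, neurons attend the contralateral stimulus
independently with probability `α_c`.  Marginally the attention count is a
mixture of three binomials with weights `π_t = λΓ^{t−1}`; the derived
attention probability is `p_t = π_t·α` and the pairwise correlation
`ρ_t = (π_t·α² − p_t²)/(p_t(1−p_t))`, which is always non-negative and is
reported as undefined when `p_t ∈ {0,1}`.  Free parameters: 2 (λ) +
6 per class (Γ) + 3 (α) + 7 per neuron (rates) + 10 (β) = 15 + 6|M| + 7|N|.

### CBM

The correlated binomial model makes the attention count at each interval
CBin(n, p, ρ): a mixture of Binomial(n, p) (weight 1−ρ) and a fully
correlated component on {0, n} with mass p at n.  `ρ` is constrained to
[0, 1]; the mixture construction cannot represent negative correlation.
Interval parameters `(p_{t,m}, ρ_{t,m})` are free per interval and class
except at `t = 1`, where a single `(p_1, ρ_1)` is shared across classes via
one tied parameter (not post-hoc averaging).  Dimension: 12 + 2|M|(I−1) +
7|N|.  Because the attention-parameter count grows linearly in `I|M|`,
`fit_cbm` refuses designs beyond a budget of 128 attention parameters
(enough for all 12 condition classes at I = 5).

### Deviation statistics

`D_n = Σ_z |z − n/2| f(z) / (n/2)` maps an attention-count PMF to [0, 1]:
0 is maximally parallel (all mass at n/2), 1 fully serial (mass on {0, n}).
Closed-form large-n limits: `D* = 2 Σ_k π_k |α_k − 1/2|` for the binomial
mixture and `D* = 2(1−ρ)|p − 1/2| + ρ` for CBin.  Both are invariant under
the contra/ipsi label swap, which matters for identifiability (below).

## Fitting

Direct maximum likelihood with the latent structure marginalized
analytically (forward recursion for the HMM, two-component mixture for the
CBM).  Parameters are transformed to an unconstrained space — log rates,
raw β, softmax logits for λ and Γ rows, log-odds for α, p, ρ — and
optimized with L-BFGS-B using exact analytic gradients: the HMM gradient
uses the standard forward–backward posterior identities (state and
two-slice posteriors for λ and Γ, per-neuron responsibilities for α and the
intensity parameters); the CBM gradient uses the component
responsibilities.  Gradients are verified against finite differences in the
unit tests.  Box bounds keep log-odds within ±8 and log rates within
[−10, 2], so probabilities stay off the exact boundary during optimization;
near-boundary CBM correlation estimates are reported as flags, never
regularized away.

Multi-start (default 5 starts; the recovery harness uses 3): the first
start is deterministic — rates at pooled empirical firing rates with a
±0.3 log-rate contra/ipsi split, α = (0.9, 0.5, 0.1), uniform λ, mildly
sticky Γ, β = 0 — and the rest jitter around it with seeded noise.  The
split matters: with both rates equal the likelihood is at a saddle where
every attention parameter has zero gradient.  After fitting, hidden states
are permuted so `α_1 ≥ α_2 ≥ α_3` (the likelihood is invariant under state
relabelling); λ and Γ are permuted consistently.

Identifiability: with a single condition, the global swap `x ↦ 1−x`
combined with exchanging each neuron's two rate parameters leaves the
likelihood unchanged, so `p_t` is identified only up to `p ↦ 1−p`.  All
D-statistics are invariant under the swap; recovery claims are therefore
stated for `D_n`/`D*`, not for the sign of `p − 1/2`.

## Decoding

Smoothing posteriors (conditioning on the whole trial, not filtered).  HMM:
forward–backward gives `P(C_t | y_{1:I})` with per-step normalization; the
per-neuron attention posterior mixes the state-conditional responsibilities
over it, and the attention-count PMF is the corresponding mixture of three
Poisson binomials (computed exactly by O(n²) convolution).  CBM: each
interval's component posterior weighs a Poisson binomial (independent
per-neuron posteriors) against a modified Bernoulli on {0, n} driven by one
shared attention bit.  `D_n` of the posterior count PMF is the posterior
(per-trial) serial/parallel measure.  Decoding reports only probabilities —
no argmax labels — and by default covers trials with at least 10
simultaneously recorded neurons (below that the posterior `D_n` is too
variable to be informative); the threshold never affects fitting.

## Simulator

`simulate_trial` draws the latent structure exactly as the models define it
and then generates spikes bin-by-bin at 1 ms as Bernoulli(min(h·u, 1)) with
the running simulated history; clipping events are counted and warned
about.  Spikes are generated from 0 ms so that the history feeding the
first analysed bin is real simulated data; before 100 ms an attention-free
baseline rate applies.  The default design is the reference simulation
study: 10 neurons, 20 trials, one condition (so two rates per neuron),
100 ms intervals, I = 10 (HMM) or 5 (CBM).

Numerical values that the tabulated cases leave open were fixed once:
contralateral rate 0.05 spikes/ms vs ipsilateral 0.015 (a factor ≈3.3,
comfortably identifiable over a 100 ms interval: ~5 vs ~1.5 expected
spikes), baseline 0.02 spikes/ms, β = (−1.0, −0.4, −0.15, −0.05, 0, …)
for mild refractoriness.  The HMM presets use a transition matrix with all
rows equal to the case's state distribution, making `π_t` stationary so the
case's D* is the constant ground truth at every interval.

What the synthetic sessions do *not* emulate: neuron drop-out over a
session (the data model supports per-trial neuron subsets; the simulator
keeps the roster fixed), heterogeneous per-neuron rates, multiple
conditions per session, and any mismatch between the generative and fitted
model families.  Passing recovery tests therefore demonstrate correctness
and statistical adequacy of the estimation machinery under the model, not
robustness to real-data misspecification.

## Recovery experiments and test scale

`recovery_experiment` repeats simulate → fit → decode, recording per
replicate the prior statistics implied by the true and estimated parameters
and the median decoded `D_n` across trials, with quantile summaries
(medians, 25–75% and full ranges).  The shipped tests and the acceptance
script run 20 replicates with 3 optimizer starts — a scale chosen so a full
run completes in minutes on one CPU while the median-based checks remain
stable — and check that the median estimated D* lies within ±0.1 of the
generating value and that the median decoded `D_n` lies within ±0.15 of the
median prior `D_n` (our operationalization of the qualitative claim that
posterior medians track the encoding results).

## Numerical choices and edge cases

* All mixture likelihoods are evaluated in log space with `logaddexp`;
  forward–backward uses per-step normalization plus a per-interval max
  shift of the emission row, so trials with hundreds of spikes cannot
  underflow.  An all-zero emission row raises an error naming the interval.
* Exact zeros in user-supplied parameters (λ, Γ, α, ρ ∈ {0, 1}) are legal
  in likelihood evaluation and decoding (`log 0 = −inf` flows through
  `logaddexp` correctly); the optimizer itself stays interior via its box
  bounds.
* At most one spike per 1 ms bin is a data invariant, enforced at
  `SpikeTrain` construction.
* Degenerate inputs: silent neurons are retained (their likelihood is
  well-defined); `ρ_t` undefined at `p_t ∈ {0,1}` is flagged, not NaN;
  condition classes with no trials are dropped from fitting with a warning.
* Poisson binomial PMFs use exact iterative convolution; no DFT
  approximation is needed at population sizes of tens.

## Known limitations

* Exactly two stimuli and three hidden states; no cross-neuron history
  coupling; no standard errors on estimates (point MLE only).
* The contra/ipsi sign of `p` is unidentified in single-condition designs
  (see above); multi-condition sessions anchor it through the shared rate
  slots.
* CBM correlation estimates with few neurons pile up near 0/1; they are
  flagged (`FitReport.boundary_flags`) but deliberately not regularized.
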