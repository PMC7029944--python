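# spikeattn

Serial vs. parallel visual attention, inferred from simultaneously recorded
spike trains.

When two stimuli are shown at once (one per hemifield), does a population
of neurons split its attention across them (parallel processing) or lock
onto one stimulus at a time (serial processing)?  `spikeattn` implements
two latent-attention models that answer this from multi-neuron spike data
at 1 ms resolution, for researchers analysing simultaneously recorded
single units in attention tasks.

## The models in brief

Each neuron `i` attends exactly one stimulus at interval `t`
(`X_t^i ∈ {0,1}`, 1 = contralateral).  Conditional on the attended
stimulus, spikes follow a point process with conditional intensity

    h(s | H_s; x) = r^i(x) · exp(Σ_{j=1..10} β_j ΔN_{s−j}),

a neuron-specific base rate modulated by the previous 10 ms of its own
spiking.  Two models couple the unobserved `X_t^i` across neurons:

* **HMM** — a 3-state hidden attentional regime `C_t` with initial law `λ`
  and per-condition transition matrix `Γ_m`; given `C_t = c`, neurons
  attend independently with probability `α_c`.  Marginally the attention
  count follows a mixture of three binomials Bin3(`π_t`, `α`, n) with
  `π_t = λΓ^{t−1}`.
* **CBM** — attention counts follow the correlated binomial
  CBin(n, p, ρ) = (1−ρ)·Binomial(n, p) + ρ·(fully correlated on {0, n}),
  independently per interval.

The serial/parallel continuum is summarized by the deviation statistic

    D_n = Σ_z |z − n/2| f(z) / (n/2)   ∈ [0, 1],

where `f` is the attention-count PMF (0 = perfectly parallel, 1 = fully
serial), and its large-n limits `D* = 2Σ_k π_k|α_k − ½|` (HMM) and
`D* = 2(1−ρ)|p − ½| + ρ` (CBM).  Both models are fitted by maximum
likelihood with the latent variables marginalized out; posterior decoding
then yields per-trial attention probabilities and posterior `D_n`.

## Worked example

Simulate a session from a tabulated HMM parameter case (10 neurons, 20
trials, I = 10; generating truth p = 0.90, ρ = 0.25, D₁₀ = 0.84,
D* = 0.82), refit it, and decode:

```python
import numpy as np
from spikeattn import (FitConfig, bin3_pmf, dn, dstar_hmm, decode_session,
                       fit_hmm)
from spikeattn.hmm import hmm_moments, state_distribution
from spikeattn.simulate import hmm_preset, simulate_session

design = hmm_preset(1, seed=42)
session, truth = simulate_session(design)
params, report = fit_hmm(session, design.scheme, FitConfig(n_starts=3, seed=1))
print(f"loglik {report.loglik:.1f} converged={report.converged}")
for t in (1, 5, 10):
    mom = hmm_moments(params.lam, params.Gamma[1], params.alpha, t)
    pi = state_distribution(params.lam, params.Gamma[1], t)
    print(f"t={t:2d}  p_t={mom.p_t:.2f}  rho_t={mom.rho_t:.2f}  "
          f"D_10={dn(bin3_pmf(pi, params.alpha, 10)):.2f}  "
          f"D*={dstar_hmm(pi, params.alpha):.2f}")
res = decode_session(session, params, design.scheme, min_neurons=10)
print("median decoded D_n:", np.median([r.d_n for r in res], axis=0).round(2))
```

Output:

```
loglik -35978.8 converged=True
t= 1  p_t=0.96  rho_t=0.63  D_10=0.96  D*=0.96
t= 5  p_t=0.89  rho_t=0.46  D_10=0.86  D*=0.85
t=10  p_t=0.87  rho_t=0.46  D_10=0.85  D*=0.84
median decoded D_n: [1.   0.99 0.97 0.96 0.93 0.95 0.96 0.92 0.92 0.9 ]
```

Reading the numbers: the fitted attention probability `p_t ≈ 0.9` and
`D* ≈ 0.85` recover the strongly serial generating regime (truth 0.82)
from a single 20-trial session; the posterior (decoded) `D_n` per interval
tells the same story trial-by-trial.  Estimates from one session carry
noticeable sampling noise — the recovery experiments below quantify it
over replicates.

The same pipeline is available from the shell:

```sh
spikeattn simulate --model hmm --case 1 --seed 42 --out sess.json
spikeattn fit --model hmm --sessions sess.json --starts 5 --seed 1 --out model.json
spikeattn decode --model-file model.json --sessions sess.json --out decode.json
spikeattn stats --model-file model.json
```

## Layout

| module | contents |
| --- | --- |
| `spikeattn.session` | sessions, trials, spike trains, the 12-condition scheme, JSON/CSV I/O |
| `spikeattn.point_process` | conditional intensity and interval likelihoods |
| `spikeattn.distributions` | Bin3, CBin, Poisson binomial PMFs; D_n and D* |
| `spikeattn.hmm` / `spikeattn.cbm` | model parameters, session likelihoods, ML fitting |
| `spikeattn.decode` | forward–backward smoothing, attention posteriors, posterior D_n |
| `spikeattn.simulate` | synthetic sessions, tabulated presets, recovery experiments |
| `spikeattn.cli` | `spikeattn` command-line entry point |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
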