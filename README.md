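# telag

Transfer-entropy based detection of directed ("causal") links and their time
lags in discrete, collectively correlated time series.

## The problem

In complex systems — spin lattices near criticality, neural populations,
coupled stochastic processes — correlations often span the whole system.
Symmetric measures (covariance, mutual information) then light up everywhere
and cannot distinguish a genuine directed link from the collective
background. `telag` implements the Wiener–Granger idea information-
theoretically: a source X "causes" a target Y if knowing X's past improves
prediction of Y's next change beyond what Y's own past provides.

## The measure

The package estimates the minimally conditioned transfer entropy, in bits,

    TE(X→Y, τ) = I(Y_{t+1}; X_{t+1−τ} | Y_t)

by plug-in (maximum-likelihood) histogram estimation, scanning the probe lag
τ = 1, 2, …: for a single directed link with causal lag ω, TE peaks at τ = ω,
so `lag_scan` doubles as a causal-lag estimator.  Because the conditioning is
minimal (one past target symbol), TE(X→X, τ=1) ≡ 0 and the estimation table
stays small.  Two corrections address the known pitfalls:

* **Effective rate of change (ERC)** — the probability a series changes
  between consecutive samples.  The directionality index
  D = [TE(X→Y) − TE(Y→X)] / ERC(Y) cancels the symmetric collective
  contribution and isolates the implanted direction.
* **Null models / surrogates** — the plug-in estimator is positively biased
  (≈ df/(2n ln 2) at sample size n), so estimates are compared against
  source-permutation surrogates or subtracted against a matched independent
  null ("effective TE").

Two generative test beds with known ground truth are built in:

* **(Amended) Ising model** — 2D Metropolis dynamics with periodic
  boundaries; the amendment gates two target sites on a source site's state
  ω samples back, implanting a directed link inside genuine collective
  correlations.
* **Random Transition model (RTM)** — three M-state swap chains where the
  targets may only swap if the source was in a conditioned set (fraction λ)
  ω steps earlier.  Its transfer entropy has an exact closed form, validated
  in-package against brute-force Markov-chain enumeration, making it a
  quantitative oracle for the estimator and its finite-sample bias.

## Worked example

```python
import numpy as np
from telag.random_transition import (
    RTMParams, simulate_rtm, analytic_te_at_causal_lag,
)
from telag.infomeasures import lag_scan, transfer_entropy

# M=2 states, gate fraction lambda=1/2, swap probabilities 1/2, causal lag 3
params = RTMParams(M=2, p1=0.5, p2=0.5, conditioned_set=(0,), omega=3,
                   n=1_000_000, seed=12)
x1, x2, _ = simulate_rtm(params)

scan = lag_scan(x1, x2, tau_max=6)
print("detected lag:", scan.argmax_lag)
print("TE at peak  :", round(scan.max_value, 4), "bits")
print("analytic    :", round(analytic_te_at_causal_lag(params), 4), "bits")
print("reverse TE  :", round(transfer_entropy(x2, x1, 3).value, 6), "bits")
```

prints

```
detected lag: 3
TE at peak  : 0.3119 bits
analytic    : 0.3113 bits
reverse TE  : 0.0 bits
```

The scan recovers the implanted lag ω = 3; the estimate matches the exact
value 0.311278 bits to within finite-sample error, and the acausal
direction is zero (any residual is plug-in bias, of order df/(2n ln 2)).

The same analysis is available from the shell:

```bash
telag simulate-rtm --M 2 --omega 3 --n 1000000 --seed 12 --out rtm.tsv
telag lagscan --input rtm.tsv --source x1 --target x2 --tau-max 6 --out scan.tsv
telag simulate-amended --L 25 --T 3.0 --omega 1 --samples 50000 --out amended.tsv
telag bias-study --M-grid 2,4,8 --n-grid 1000,10000,100000 --reps 20 --out bias.tsv
```

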