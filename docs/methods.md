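# Methods

## Estimator

All information measures are plug-in (maximum-likelihood) histogram
estimates in bits (log base 2, 0·log 0 ≡ 0), with no pseudo-counts: the
finite-sample bias of the uncorrected estimator is itself an object of
study here, and regularization would obscure it.  Joint tables are built
only from time indices where every shifted variable exists — no circular
wrap-around.

Transfer entropy uses the minimally conditioned form
TE(X→Y, τ) = I(Y_{t+1}; X_{t+1−τ} | Y_t), with exactly one past target
symbol and one lagged source symbol (history lengths k = l = 1).  The lag
convention pairs the source symbol X_{t+1−τ} with the target transition
Y_t → Y_{t+1}, so τ = 1 uses the source value simultaneous with Y_t; this
makes the self-transfer entropy at τ = 1 identically zero and places the
scan maximum at the true causal lag ω of a gated link.  The exact content
of this conditioning set is a documented convention of this package (one
consistent reading of the minimal form), chosen because it reproduces both
diagnostic behaviours above; longer histories and conditioning on third
variables are out of scope.

Two algebraically identical formulations — the entropy combination
H(Y′,Y) + H(Y,X) − H(Y) − H(Y′,Y,X) and the direct log-ratio sum
Σ p log₂[p(y′|y,x)/p(y′|y)] — are both implemented and agree to 1e-12;
the log-ratio route is the default and tiny negative round-off is clipped
at zero.  `n_effective = n − max(1, τ)` transitions contribute.  Continuous
inputs can be equal-width binned into M bins (M then plays the role of the
state count everywhere, including in the bias formulas).

Ties in the lag-scan argmax go to the smallest τ (determinism).

## Significance and bias handling

The plug-in TE is positively biased, to leading order df/(2n ln 2) with
df = (M−1)²·M for this conditioning.  Three tools are provided:

* **Permutation surrogates** (`permutation_null_threshold`): the source is
  randomly permuted, destroying all temporal structure while keeping both
  marginals and the target dynamics; 19 surrogates give a one-sided 95%
  threshold as the maximum surrogate value.  Note that an estimate with no
  true coupling is *exactly* null-distributed, so a 5% exceedance rate per
  comparison is by construction; batch tests over several lags should use a
  multiple-comparison allowance.
* **Matched null model**: for the Random Transition model, three
  independent swap chains with the same (M, n, rates); `effective_te`
  subtracts the null estimate and can legitimately be negative at small n.
* **Block (batch-means) standard errors** in the tests: Markov-chain
  samples are autocorrelated, so naive binomial standard errors
  underestimate; contiguous-block means give honest uncertainty.

## Ising simulations

Single-spin-flip Metropolis with periodic boundaries; J = 1, k_B = 1.  One
sample is recorded per L² flipping considerations (each site considered
once on average per sample).  Burn-in defaults to 10⁴ samples, chosen so
lattices up to L = 50 equilibrate at all temperatures used here; it is a
parameter, not an assertion about any particular reference run.  The start
state is ordered (all +1) below T_c ≈ 2.269 and random above, shortening
equilibration; both choices sample the same stationary distribution after
burn-in.  Runs are reproducible given the seed within this implementation
(the jitted kernel consumes its own seeded RNG stream).

Susceptibility is χ = (⟨S²⟩ − ⟨S⟩²)/(L² k_B T).  For *locating* the
crossover peak on small lattices (L ≲ 10) an ⟨|S|⟩-based variant is
provided: below T_c a small lattice tunnels between ±|S|, which inflates
the plain variance and pushes the apparent peak to low T; the |S| estimator
is the standard finite-size remedy.  The L = 25 analyses use the plain
definition.

### Amended model

The gate (source site, two target sites, allowed source state, lag ω in
sample units) freezes the targets whenever the source's *sampled* state ω
samples back differs from the allowed state; the gate value is held
constant between samples so the gate clock matches the sampled chains the
estimator sees.  Default geometry: source at (L/2, L/2), targets its east
neighbour and the site two east — all configurable.  Both targets share one
gate and one ω.  Source history accumulates from the first burn-in sample
with targets frozen until ω samples exist; since burn-in ≫ ω, every
retained sample uses a fully valid gate.  The directionality index
normalizes by the ERC of the *target*, because in the gated construction
the target's change rate carries the external (gate) factor.

## Random Transition model

Source X1 swaps with probability p1 per step, uniformly over the other M−1
states.  Targets X2, X3 may attempt their swaps (p2, p3) only if X1's state
ω steps earlier lies in the conditioned set C, |C| = λM; C defaults to {0}
and any same-size subset is equivalent by symmetry.  Initial states are
independent uniform; steps with t+1−ω < 0 hold the targets frozen.  All
marginals stay uniform, giving the closed form

    TE(X1→X2, τ) = λ f(q_in) + (1−λ) f(q_out)
    f(q) = (1−q p2) log₂[(1−q p2)/(1−λ p2)] + q p2 log₂(q/λ)
    q_in = λ + (1−λ) r^Δ,  q_out = λ(1 − r^Δ),
    r = 1 − p1 M/(M−1),  Δ = |τ−ω|,

where q is the probability the gate condition held given the observed
lagged source symbol, obtained by propagating X1's kernel Δ steps (the
kernel is symmetric, so the τ < ω and τ > ω cases coincide).  Consequences:
at τ = ω the value is independent of p1; with p1 = (M−1)/M the source is
i.i.d. (r = 0) and TE vanishes at every τ ≠ ω; TE at τ = ω is strictly
increasing in p2; the argmax over τ is exactly ω whenever λ < 1, p2 > 0.
The expression was derived for this package and is validated against an
independent brute-force oracle — exact enumeration of the Markov chain on
(X1 window, X2) and direct summation over its stationary joint — to 1e-12
across M ≤ 4, a grid of rates, and lags around ω; the derived reference
value for M = 2, λ = 1/2, p2 = 1/2 at τ = ω is 0.311278 bits.

The ERC factorizes for targets as total = λ·p_i (external gate factor ×
internal swap rate); the source has external factor 1.

## What the generators do and do not emulate

The built-in models produce stationary, discrete, regularly sampled chains
with a single implanted directed link of fixed lag — the controlled setting
in which estimator behaviour can be checked against ground truth.  Real
recordings add nonstationarity, continuous amplitudes (binning choices),
multiple interacting sources, and unobserved confounders; passing tests
here demonstrate correctness of the estimator and its calibration machinery
on the stated model classes, not robustness to those complications.
Conclusions about direction on real data should always rest on the
*difference* of the two TE directions (the D index) plus a surrogate or
null-model comparison, never on raw magnitudes.

## Problem sizes and numerics

Analyses in the test suite and the reproduction script use: RTM runs of
n = 10⁵–10⁶ (the closed form makes longer runs unnecessary); lag-recovery
over 20 replicates per ω ∈ {1,2,3} at n = 10⁵; a bias grid
{M = 2,4,8} × {n = 10³,10⁴,10⁵} with 20 replicates; Ising L = 25 with
2·10⁴ samples per temperature on a T = 1.5–3.5 grid (step 0.25) and
5·10⁴ samples for the amended-model directionality at T = 3.  These sizes
give replicate-level standard errors comfortably below the effects being
measured while keeping a full run in tens of seconds.

Degenerate inputs are defined rather than fatal: D is NaN where the
target's ERC is 0; a single-replicate bias table reports SD = 0 with a
warning flag; constant series are valid inputs with zero entropy rate.

## Known limitations

* Histograms only — no Kraskov-type continuous estimator; binning of
  continuous data is equal-width and user-parameterized.
* One conditioning symbol per side; systems whose memory exceeds one sample
  at the chosen sampling rate can leak history effects into the lag scan.
* Surrogate thresholds are exchangeable-rank tests; with many lags or pairs
  the user must control the family-wise rate.
* The Metropolis kernel is single-flip: near T_c critical slowing-down makes
  the effective sample size much smaller than the nominal one, which the
  batch-SE machinery accounts for but does not eliminate.
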