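"""The Random Transition model: an analytically solvable gated swap system.

Three M-state processes evolve in discrete time.  The source X1 swaps with
probability p1 at every step (uniformly to one of the other M−1 states).
The targets X2 and X3 may attempt their swaps (probability p2, p3) only if
X1's state ω steps earlier lies in a conditioned set C of size |C| = λM;
otherwise they must stay.  All marginals remain uniform over the M states,
which makes the transfer entropy TE(X1 → X2, τ) exactly computable:

    TE(τ) = λ f(q_in) + (1 − λ) f(q_out),
    f(q)  = (1 − q p2) log2[(1 − q p2)/(1 − λ p2)] + q p2 log2(q / λ),

where q(x) = P(condition held at t+1−ω | X1_{t+1−τ} = x) takes the value
q_in = λ + (1−λ) r^Δ on C and q_out = λ(1 − r^Δ) off C, with
r = 1 − p1·M/(M−1) the second eigenvalue of X1's transition kernel and
Δ = |τ−ω|.  At τ = ω, q is the indicator of C regardless of p1; when
p1 = (M−1)/M the kernel is uniform (r = 0) and TE vanishes at every τ ≠ ω.
The closed form is validated against an exact enumeration of the joint
Markov chain (see :func:`exact_joint`) rather than trusted on its own.

The model doubles as the test bed for finite-sample bias of the plug-in
estimator: the null model (three independent swap chains, no gating) has
zero true TE in every direction, so its estimated TE is pure bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from ._kernels import rtm_run
from .infomeasures import DiscreteSeries, te_from_joint, transfer_entropy

__all__ = [
    "RTMParams",
    "simulate_rtm",
    "null_model",
    "analytic_te_at_causal_lag",
    "analytic_te_general",
    "exact_joint",
    "oracle_te",
    "erc_decomposition",
    "effective_te",
    "bias_study",
]


@dataclass(frozen=True)
class RTMParams:
    """Model parameters; λ = |C|/M is derived from the conditioned set C.

    C defaults to the single state {0} (λ = 1/M); any subset of the same
    size is equivalent by symmetry.  X2 and X3 share one gate and lag ω.
    """

    M: int = 2
    p1: float = 0.5
    p2: float = 0.5
    p3: float = 0.5
    conditioned_set: tuple[int, ...] = (0,)
    omega: int = 1
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        for name in ("p1", "p2", "p3"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        C = tuple(sorted(set(int(c) for c in self.conditioned_set)))
        if not C:
            raise ValueError("conditioned set must be nonempty")
        if C[0] < 0 or C[-1] >= self.M:
            raise ValueError("conditioned states must lie in [0, M)")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        object.__setattr__(self, "conditioned_set", C)

    @property
    def lam(self) -> float:
        """λ = |C|/M, the fraction of source states that open the gate."""
        return len(self.conditioned_set) / self.M

    def cond_mask(self) -> np.ndarray:
        mask = np.zeros(self.M, dtype=np.bool_)
        mask[list(self.conditioned_set)] = True
        return mask


def simulate_rtm(
    params: RTMParams,
) -> tuple[DiscreteSeries, DiscreteSeries, DiscreteSeries]:
    """Simulate (X1, X2, X3); initial states independent uniform.

    Early steps with t+1−ω < 0 hold the targets frozen (the gate history
    does not exist yet); negligible at the lengths used.
    """
    rng = np.random.default_rng(params.seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    x1, x2, x3 = rtm_run(
        params.M,
        params.p1,
        params.p2,
        params.p3,
        params.cond_mask(),
        params.omega,
        params.n,
        kernel_seed,
        True,
    )
    M = params.M
    return (
        DiscreteSeries(x1, M),
        DiscreteSeries(x2, M),
        DiscreteSeries(x3, M),
    )


def null_model(
    params: RTMParams, n: int | None = None, seed: int | None = None
) -> tuple[DiscreteSeries, DiscreteSeries, DiscreteSeries]:
    """Three mutually independent swap chains (gate removed); true TE = 0."""
    n = params.n if n is None else int(n)
    seed = params.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    x1, x2, x3 = rtm_run(
        params.M,
        params.p1,
        params.p2,
        params.p3,
        params.cond_mask(),
        params.omega,
        n,
        kernel_seed,
        False,
    )
    M = params.M
    return (
        DiscreteSeries(x1, M),
        DiscreteSeries(x2, M),
        DiscreteSeries(x3, M),
    )


def _f_term(q: float, lam: float, p: float) -> float:
    """Per-source-state TE contribution; handles the 0·log 0 corners."""
    out = 0.0
    stay = 1.0 - q * p
    stay_m = 1.0 - lam * p
    if stay > 0.0 and stay_m > 0.0:
        out += stay * np.log2(stay / stay_m)
    if q > 0.0 and p > 0.0 and lam > 0.0:
        out += q * p * np.log2(q / lam)
    return out


def analytic_te_general(
    params: RTMParams, tau: int, target_swap: float | None = None
) -> float:
    """Exact TE(X1 → target, τ) in bits at any probe lag τ ≥ 1.

    Propagates X1's kernel |τ−ω| steps to get q(x), the probability the
    gate condition held given the observed lagged source state, then sums
    the exact three-way joint.  ``target_swap`` defaults to p2.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    p = params.p2 if target_swap is None else float(target_swap)
    lam = params.lam
    if lam >= 1.0 or p == 0.0:
        return 0.0
    r = 1.0 - params.p1 * params.M / (params.M - 1)
    delta = abs(tau - params.omega)
    rd = r**delta  # 1.0 at tau == omega
    q_in = lam + (1.0 - lam) * rd
    q_out = lam * (1.0 - rd)
    return lam * _f_term(q_in, lam, p) + (1.0 - lam) * _f_term(q_out, lam, p)


def analytic_te_at_causal_lag(params: RTMParams, target_swap: float | None = None) -> float:
    """Exact TE(X1 → target) at the causal lag τ = ω (independent of p1)."""
    return analytic_te_general(params, params.omega, target_swap=target_swap)


def exact_joint(params: RTMParams, tau: int) -> np.ndarray:
    """Stationary joint p(X2_{t+1}, X2_t, X1_{t+1−τ}) by chain enumeration.

    Enumerates the exact Markov chain on (X1 window of depth d = max(ω, τ),
    X2), solves for its stationary distribution by power iteration from the
    uniform product measure, and accumulates the three-way joint.  This is
    the brute-force oracle the closed form is validated against; feasible
    for M ≤ 4 and small lags.
    """
    M, om, p1, p2 = params.M, params.omega, params.p1, params.p2
    if tau < 1:
        raise ValueError("tau must be >= 1")
    d = max(om, tau)
    if M**d * M > 200_000:
        raise ValueError("state space too large to enumerate")
    in_C = params.cond_mask()

    # X1 single-step kernel
    A = np.full((M, M), p1 / (M - 1))
    np.fill_diagonal(A, 1.0 - p1)

    windows = list(product(range(M), repeat=d))  # (x1_{t-d+1}, ..., x1_t)
    widx = {w: i for i, w in enumerate(windows)}
    nw = len(windows)

    # stationary distribution over (window, x2): X1 windows carry the exact
    # stationary path measure; X2 is uniform and independent of the X1 path.
    pw = np.empty(nw)
    for i, w in enumerate(windows):
        pr = 1.0 / M
        for a, b in zip(w[:-1], w[1:]):
            pr *= A[a, b]
        pw[i] = pr

    joint = np.zeros((M, M, M))  # (x2_{t+1}, x2_t, x1_{t+1-tau})
    for i, w in enumerate(windows):
        x1_obs = w[d - tau]  # X1_{t+1-tau}
        gate_state = w[d - om]  # X1_{t+1-omega}
        open_ = in_C[gate_state]
        stay = 1.0 - p2 if open_ else 1.0
        move = p2 / (M - 1) if open_ else 0.0
        for x2 in range(M):
            base = pw[i] / M
            for x2n in range(M):
                pr = stay if x2n == x2 else move
                joint[x2n, x2, x1_obs] += base * pr
    assert abs(joint.sum() - 1.0) < 1e-9
    return joint / joint.sum()


def oracle_te(params: RTMParams, tau: int) -> float:
    """TE by direct summation over the enumerated exact joint (oracle path)."""
    return te_from_joint(exact_joint(params, tau), method="log-ratio")


def erc_decomposition(params: RTMParams, process: str) -> tuple[float, float, float]:
    """(internal, external, total) effective rate of change of one process.

    For a gated target the ERC factorizes as total = external · internal =
    λ · p_i: the gate-open probability is the external influence, the swap
    probability the internal one.  The ungated source has external = 1.
    """
    if process == "x1":
        return (params.p1, 1.0, params.p1)
    if process == "x2":
        return (params.p2, params.lam, params.lam * params.p2)
    if process == "x3":
        return (params.p3, params.lam, params.lam * params.p3)
    raise ValueError("process must be 'x1', 'x2' or 'x3'")


def effective_te(
    source: DiscreteSeries,
    target: DiscreteSeries,
    tau: int,
    null_source: DiscreteSeries,
    null_target: DiscreteSeries,
) -> float:
    """Bias-corrected TE: estimate minus the matched null-model estimate.

    The null pair must match the data in alphabet size and length so the
    finite-sample biases cancel.  Can be negative at small sample sizes.
    """
    if (
        null_source.length != source.length
        or null_target.length != target.length
        or null_source.alphabet_size != source.alphabet_size
        or null_target.alphabet_size != target.alphabet_size
    ):
        raise ValueError("null series must match data in length and alphabet")
    est = transfer_entropy(source, target, tau).value
    null = transfer_entropy(null_source, null_target, tau).value
    return est - null


def bias_study(
    M_values,
    n_values,
    replicates: int,
    base_params: RTMParams | None = None,
    seed: int = 0,
    null: bool = False,
    lambda_target: float | None = None,
) -> pd.DataFrame:
    """Finite-sample bias grid: TE(X1→X2, τ=ω) per (M, n) over replicates.

    ``null=True`` measures on the ungated null model (analytic TE = 0),
    isolating pure estimator bias.  Otherwise the gated model is used with
    the conditioned-set size chosen as round(λ·M) (λ from ``lambda_target``
    or the base parameters).  Columns: M, n, mean, sd, analytic, replicates,
    warning (set when replicates == 1, where the SD is reported as 0).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = base_params or RTMParams()
    lam = base.lam if lambda_target is None else float(lambda_target)
    ss = np.random.SeedSequence(seed)
    rows = []
    for M in M_values:
        k = min(max(int(round(lam * M)), 1), M)
        C = tuple(range(k))
        for n in n_values:
            vals = np.empty(replicates)
            for rep in range(replicates):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                p = RTMParams(
                    M=int(M),
                    p1=base.p1,
                    p2=base.p2,
                    p3=base.p3,
                    conditioned_set=C,
                    omega=base.omega,
                    n=int(n),
                    seed=child,
                )
                if null:
                    x1, x2, _ = null_model(p)
                    analytic = 0.0
                else:
                    x1, x2, _ = simulate_rtm(p)
                    analytic = analytic_te_at_causal_lag(p)
                vals[rep] = transfer_entropy(x1, x2, p.omega).value
            rows.append(
                {
                    "M": int(M),
                    "n": int(n),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if replicates > 1 else 0.0,
                    "analytic": float(analytic),
                    "replicates": replicates,
                    "warning": replicates == 1,
                }
            )
    return pd.DataFrame(rows)
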