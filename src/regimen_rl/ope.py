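"""Off-policy evaluation of target policies from logged trajectories.

The headline estimator is stepwise weighted importance sampling (step-WIS,
also called per-decision WIS): at each step t the discounted rewards are
weighted by the cumulative importance ratios ρ_{0:t} = Π_{k≤t}
π_e(a_k|s_k)/π_b(a_k|s_k) and self-normalized across trajectories,

    V̂ = Σ_t  γ^t · (Σ_i ρ^i_{0:t} r^i_t) / (Σ_i ρ^i_{0:t}).

Ordinary (trajectory-wise) importance sampling is provided for comparison,
and a bootstrap over trajectories supplies uncertainty summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, CoverageError
from .mdp_builder import TrajectorySet, discounted_return
from .solvers import Policy


@dataclass(frozen=True)
class OPEEstimate:
    """A point estimate of a target policy's expected discounted return."""

    value: float
    estimator: str  # "step_wis" | "ordinary_is"
    n_trajectories: int
    effective_sample_size: float


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap distribution of the step-WIS value over resampled trajectories."""

    point: float
    mean: float
    sd: float
    percentiles: dict[float, float]
    n_boot: int


def _check_gamma(gamma: float) -> None:
    if not 0.0 <= gamma < 1.0:
        raise ConfigurationError(f"gamma must lie in [0, 1), got {gamma}")


def _weight_matrices(
    trajs: TrajectorySet, target: Policy, behavior: Policy
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Padded (n, T_max) matrices of cumulative ratios ρ_{0:t}, rewards, and
    an aliveness mask.  Trajectories shorter than t contribute ρ = r = 0."""
    if len(trajs) == 0:
        raise ValueError("at least one trajectory is required")
    t_max = max(len(t) for t in trajs)
    n = len(trajs)
    rho = np.zeros((n, t_max))
    rew = np.zeros((n, t_max))
    alive = np.zeros((n, t_max), dtype=bool)
    for i, traj in enumerate(trajs):
        T = len(traj)
        b = behavior.probs[traj.states, traj.actions]
        if np.any(b <= 0):
            k = int(np.argmax(b <= 0))
            raise CoverageError(
                f"logged action {int(traj.actions[k])} in state {int(traj.states[k])} "
                "has zero behavior probability"
            )
        e = target.probs[traj.states, traj.actions]
        rho[i, :T] = np.cumprod(e / b)
        rew[i, :T] = traj.rewards
        alive[i, :T] = True
    return rho, rew, alive


def _step_wis_value(rho: np.ndarray, rew: np.ndarray, alive: np.ndarray, gamma: float) -> float:
    """Self-normalized per-decision value from precomputed weight matrices."""
    t_max = rho.shape[1]
    gammas = np.power(gamma, np.arange(t_max))
    denom = rho.sum(axis=0)
    numer = (rho * rew).sum(axis=0)
    any_alive = alive.any(axis=0)
    ok = any_alive & (denom > 0)
    return float((gammas[ok] * numer[ok] / denom[ok]).sum())


def _ess(rho: np.ndarray) -> float:
    """Effective sample size from the first-step importance weights.

    For per-decision WIS the first step has the widest support (weights only
    shrink as the cumulative product grows), so its Kish effective size
    (Σw)²/Σw² is the least pessimistic summary of weight concentration.  A
    value of 0 signals total weight collapse: no logged trajectory starts
    with an action the target policy would take.
    """
    w = rho[:, 0]
    ssq = float((w ** 2).sum())
    if ssq == 0.0:
        return 0.0
    return float(w.sum() ** 2 / ssq)


def step_wis(
    trajs: TrajectorySet, target: Policy, behavior: Policy, gamma: float = 0.3
) -> OPEEstimate:
    """Stepwise weighted importance sampling estimate of the target's value.

    Self-normalization makes the estimate invariant to rescaling all
    importance ratios by a positive constant; with target = behavior it
    reduces exactly to the on-policy empirical value, and on a single
    trajectory with positive weights it returns that trajectory's discounted
    return.
    """
    _check_gamma(gamma)
    rho, rew, alive = _weight_matrices(trajs, target, behavior)
    return OPEEstimate(
        value=_step_wis_value(rho, rew, alive, gamma),
        estimator="step_wis",
        n_trajectories=len(trajs),
        effective_sample_size=_ess(rho),
    )


def ordinary_is(
    trajs: TrajectorySet, target: Policy, behavior: Policy, gamma: float = 0.3
) -> OPEEstimate:
    """Ordinary importance sampling: V̂ = (1/n) Σ_i ρ^i_{0:T−1} G^i.

    Unbiased but typically much higher variance than step-WIS, because the
    full-trajectory ratio multiplies the whole return.
    """
    _check_gamma(gamma)
    rho, _, alive = _weight_matrices(trajs, target, behavior)
    last = alive.sum(axis=1) - 1
    w = rho[np.arange(rho.shape[0]), last]
    returns = np.array([discounted_return(t.rewards, gamma) for t in trajs])
    return OPEEstimate(
        value=float(np.mean(w * returns)),
        estimator="ordinary_is",
        n_trajectories=len(trajs),
        effective_sample_size=_ess(rho),
    )


def bootstrap_value(
    trajs: TrajectorySet,
    target: Policy,
    behavior: Policy,
    gamma: float = 0.3,
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap (over trajectories) of the step-WIS value.

    Resamples whole trajectories with replacement ``n_boot`` times and
    re-estimates step-WIS on each replicate.  With a single replicate the
    standard deviation is reported as 0.
    """
    _check_gamma(gamma)
    if n_boot < 1:
        raise ConfigurationError("n_boot must be at least 1")
    rho, rew, alive = _weight_matrices(trajs, target, behavior)
    point = _step_wis_value(rho, rew, alive, gamma)
    rng = np.random.default_rng(seed)
    n = rho.shape[0]
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[b] = _step_wis_value(rho[idx], rew[idx], alive[idx], gamma)
    sd = float(values.std(ddof=1)) if n_boot > 1 else 0.0
    pct = {p: float(np.percentile(values, p)) for p in (2.5, 50.0, 97.5)}
    return BootstrapSummary(
        point=point, mean=float(values.mean()), sd=sd, percentiles=pct, n_boot=n_boot
    )
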