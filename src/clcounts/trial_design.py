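"""Monte-Carlo sample-size estimation for two-arm active-controlled trials.

The primary outcome is the number of new cortical lesions per patient over
the trial window, modelled as zero-inflated Poisson.  Control-arm counts are
drawn from ZIP(lambda_c, pi) and treatment-arm counts from the same
distribution with the count-component mean reduced by the assumed treatment
effect e (lambda_t = (1 - e) lambda_c, pi unchanged) — a drug acting on the
lesion *rate* rather than on the proportion of lesion-free patients.  A
mechanism raising pi instead is available for sensitivity analyses.

The per-replicate significance test is the two-sided Mann-Whitney (Wilcoxon
rank-sum) test between the simulated arms; this is the package default
because it reproduces published lesion-count sample sizes, in line with the
nonparametric resampling methodology established for MRI count outcomes.  A
model-based alternative — the Wald z-test on the treatment coefficient of a
two-arm shared-pi ZIP regression — is available via ``test="wald_zip"`` and
typically needs ~15-20% fewer patients; the disagreement is a genuine
difference between the rank-based and model-based operating characteristics
and both are reported by the sensitivity tooling.

The sample-size search starts from the closed-form two-Poisson-rates
approximation inflated by 1/(1 - pi), brackets the 90%-power point by
doubling/halving, and bisects to single-patient resolution with a fixed
number of simulated trials per evaluated n.  Every replicate has its own
seed stream derived from (root seed, n, replicate), so results are exactly
reproducible and power evaluations at different n are independent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln

from .synthetic_data import generate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "TrialDesignConfig",
    "SampleSizeResult",
    "PUBLISHED_TWO_YEAR_ZIP",
    "poisson_rates_sample_size",
    "simulate_trial",
    "estimate_power",
    "sample_size",
    "sample_size_table",
]

#: Published 2-year shared-pi ZIP regression parameters of the four-arm
#: cohort (log-mean intercept for the untreated arm, per-arm log count
#: ratios, shared extra-zeros proportion).  The 2-year patient-level
#: distribution is not reconstructable, so 2-year designs start from these.
PUBLISHED_TWO_YEAR_ZIP = {
    "intercept": 1.25,
    "coefficients": {"sc_ifn_beta1a": -1.44, "im_ifn_beta1a": -0.58, "ga": -0.84},
    "zero_prob": 0.15,
}

_TESTS = ("mannwhitney", "wald_zip")
_MECHANISMS = ("count_mean", "zero_inflation")


@dataclass(frozen=True)
class TrialDesignConfig:
    """One trial-design scenario.

    Parameters
    ----------
    control_mean : float
        Count-component mean lambda_c of the active comparator arm.
    zero_prob : float
        Shared structural-zero probability pi in [0, 1).
    effect : float
        Assumed fractional lesion reduction e in (0, 1) of the new drug
        versus the comparator.
    alpha, target_power : float
        Two-sided significance level (default 0.05) and target power
        (default 0.90).
    n_sims : int
        Simulated trials per power evaluation (default 2000; Monte-Carlo
        SE at 90% power is then ~0.7 points).
    seed : int
        Root seed; all replicate streams derive from it.
    test : str
        ``"mannwhitney"`` (default) or ``"wald_zip"``.
    effect_mechanism : str
        ``"count_mean"`` (default: lambda_t = (1-e) lambda_c) or
        ``"zero_inflation"`` (pi raised so the overall mean drops by e).
    """

    control_mean: float
    zero_prob: float
    effect: float
    alpha: float = 0.05
    target_power: float = 0.90
    n_sims: int = 2000
    seed: int = 0
    test: str = "mannwhitney"
    effect_mechanism: str = "count_mean"

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValueError("control_mean must be positive")
        if not (0.0 <= self.zero_prob < 1.0):
            raise ValueError("zero_prob must be in [0, 1)")
        if not (0.0 <= self.effect < 1.0):
            raise ValueError("effect must be in [0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.5 < self.target_power < 1.0):
            raise ValueError("target_power must be in (0.5, 1)")
        if self.test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}")
        if self.effect_mechanism not in _MECHANISMS:
            raise ValueError(f"effect_mechanism must be one of {_MECHANISMS}")

    @property
    def treatment_params(self) -> tuple[float, float]:
        """(lambda_t, pi_t) of the treated arm under the configured mechanism."""
        if self.effect_mechanism == "count_mean":
            return (1.0 - self.effect) * self.control_mean, self.zero_prob
        # overall mean (1-pi) lambda reduced by e via extra zeros, lambda fixed
        pi_t = 1.0 - (1.0 - self.effect) * (1.0 - self.zero_prob)
        return self.control_mean, pi_t

    def to_dict(self) -> dict:
        return {
            "control_mean": self.control_mean,
            "zero_prob": self.zero_prob,
            "effect": self.effect,
            "alpha": self.alpha,
            "target_power": self.target_power,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "test": self.test,
            "effect_mechanism": self.effect_mechanism,
        }


@dataclass
class SampleSizeResult:
    """Smallest per-arm n meeting the power target, with its evidence."""

    n_per_arm: int
    achieved_power: float
    mc_se: float
    config: TrialDesignConfig
    power_curve: list[tuple[int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_per_arm": self.n_per_arm,
            "achieved_power": self.achieved_power,
            "mc_se": self.mc_se,
            "config": self.config.to_dict(),
            "power_curve": self.power_curve,
        }


def poisson_rates_sample_size(
    control_mean: float,
    treatment_mean: float,
    alpha: float = 0.05,
    power: float = 0.90,
    zero_prob: float = 0.0,
) -> float:
    """Closed-form per-arm n for comparing two Poisson rates on the log scale.

    ``(z_{1-a/2} + z_{power})^2 (1/lambda_c + 1/lambda_t) / log^2(lambda_t/lambda_c)``
    inflated by ``1/(1 - pi)`` for the zero-inflated fraction.  Used as the
    starting point of the simulation search.
    """
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = (
        (za + zb) ** 2
        * (1.0 / control_mean + 1.0 / treatment_mean)
        / math.log(treatment_mean / control_mean) ** 2
    )
    return n / (1.0 - zero_prob)


# ---------------------------------------------------------------------------
# the embedded per-replicate tests
# ---------------------------------------------------------------------------

def _zip_nll_two_arm(theta, k0, w0, k1, w1):
    b0, b1, q = theta
    pi = 1.0 / (1.0 + math.exp(-q))
    out = 0.0
    for k, w, lam in ((k0, w0, math.exp(b0)), (k1, w1, math.exp(b0 + b1))):
        lp = k * math.log(lam) - lam - gammaln(k + 1.0)
        ll = np.where(
            k == 0,
            np.logaddexp(math.log(pi), math.log1p(-pi) - lam),
            math.log1p(-pi) + lp,
        )
        out -= float(np.dot(w, ll))
    return out


def _wald_zip_pvalue(y0: np.ndarray, y1: np.ndarray) -> float:
    """Two-sided Wald p on the treatment log-ratio of a shared-pi ZIP fit."""
    if y0.max(initial=0) == 0 or y1.max(initial=0) == 0:
        return 1.0  # degenerate arm: treatment effect not estimable
    k0, w0 = np.unique(y0, return_counts=True)
    k1, w1 = np.unique(y1, return_counts=True)
    w0 = w0.astype(float)
    w1 = w1.astype(float)
    b0 = math.log(max(y0.mean(), 0.05))
    b1 = math.log(max(y1.mean(), 0.05)) - b0
    res = minimize(
        _zip_nll_two_arm, np.array([b0, b1, math.log(0.15 / 0.85)]),
        args=(k0, w0, k1, w1), method="BFGS", options={"gtol": 1e-6},
    )
    x = res.x
    h = 1e-5 * (1.0 + np.abs(x))
    H = np.empty((3, 3))
    f0 = _zip_nll_two_arm(x, k0, w0, k1, w1)
    for i in range(3):
        for j in range(i, 3):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (
                    _zip_nll_two_arm(xp, k0, w0, k1, w1)
                    - 2 * f0
                    + _zip_nll_two_arm(xm, k0, w0, k1, w1)
                ) / h[i] ** 2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    xx = x.copy(); xx[i] += si * h[i]; xx[j] += sj * h[j]
                    vals.append(_zip_nll_two_arm(xx, k0, w0, k1, w1))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h[i] * h[j]
                )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return 1.0
    var = cov[1, 1]
    if not np.isfinite(var) or var <= 0:
        return 1.0
    z = x[1] / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _mannwhitney_pvalue(y0: np.ndarray, y1: np.ndarray) -> float:
    lo = min(y0.min(), y1.min())
    hi = max(y0.max(), y1.max())
    if lo == hi:
        return 1.0  # every observation tied: no ranking information
    return float(
        stats.mannwhitneyu(y0, y1, alternative="two-sided", method="asymptotic").pvalue
    )


def simulate_trial(
    config: TrialDesignConfig, n_per_arm: int, rng: np.random.Generator
) -> float:
    """Simulate one two-arm trial and return its two-sided p-value."""
    if n_per_arm < 5:
        raise ValueError("n_per_arm must be >= 5")
    lam_t, pi_t = config.treatment_params
    y0 = generate_counts(
        "zip", n_per_arm, rng, mean=config.control_mean, zero_prob=config.zero_prob
    )
    y1 = generate_counts("zip", n_per_arm, rng, mean=lam_t, zero_prob=pi_t)
    if config.test == "mannwhitney":
        return _mannwhitney_pvalue(y0, y1)
    return _wald_zip_pvalue(y0, y1)


def estimate_power(config: TrialDesignConfig, n_per_arm: int) -> tuple[float, float]:
    """Rejection rate over ``config.n_sims`` simulated trials, with its MC SE.

    Deterministic given the config seed: replicate r at sample size n uses
    the stream derived from ``(seed, n, r)``.
    """
    root = np.random.SeedSequence([config.seed & 0x7FFFFFFF, n_per_arm])
    children = root.spawn(config.n_sims)
    reject = 0
    for child in children:
        rng = np.random.default_rng(child)
        p = simulate_trial(config, n_per_arm, rng)
        if p < config.alpha:
            reject += 1
    power = reject / config.n_sims
    mc_se = math.sqrt(power * (1.0 - power) / config.n_sims)
    return power, mc_se


_N_CAP = 100_000


def sample_size(config: TrialDesignConfig) -> SampleSizeResult:
    """Smallest per-arm n whose estimated power reaches the target.

    Starts at the analytic two-Poisson-rates approximation, brackets the
    target by doubling/halving, then bisects to 1-patient resolution.  The
    returned ``power_curve`` lists every (n, power) evaluated.
    """
    if config.effect <= 0:
        raise ValueError("sample_size needs a positive effect")
    lam_t, pi_t = config.treatment_params
    if config.effect_mechanism == "count_mean":
        n0 = poisson_rates_sample_size(
            config.control_mean, lam_t, config.alpha, config.target_power,
            config.zero_prob,
        )
    else:
        # approximate via the overall means
        n0 = poisson_rates_sample_size(
            (1 - config.zero_prob) * config.control_mean,
            (1 - pi_t) * lam_t,
            config.alpha, config.target_power,
        )
    n = max(int(round(n0)), 5)
    curve: list[tuple[int, float]] = []
    evaluated: dict[int, float] = {}

    def power_at(n_: int) -> float:
        if n_ not in evaluated:
            p, _ = estimate_power(config, n_)
            evaluated[n_] = p
            curve.append((n_, p))
            logger.info("power(n=%d) = %.4f", n_, p)
        return evaluated[n_]

    # bracket [lo, hi): power(lo) < target <= power(hi)
    if power_at(n) >= config.target_power:
        hi = n
        lo = max(n // 2, 4)
        while lo > 4 and power_at(lo) >= config.target_power:
            hi = lo
            lo = max(lo // 2, 4)
        if power_at(lo) >= config.target_power:
            hi = lo
            lo = 4
    else:
        lo = n
        hi = 2 * n
        while power_at(hi) < config.target_power:
            lo = hi
            hi *= 2
            if hi > _N_CAP:
                raise RuntimeError(
                    f"power target {config.target_power} unreachable below n={_N_CAP}"
                )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= config.target_power:
            hi = mid
        else:
            lo = mid
    achieved = power_at(hi)
    mc_se = math.sqrt(achieved * (1.0 - achieved) / config.n_sims)
    return SampleSizeResult(
        n_per_arm=hi, achieved_power=achieved, mc_se=mc_se,
        config=config, power_curve=curve,
    )


def sample_size_table(
    comparators: Mapping[str, tuple[float, float]],
    effects: Sequence[float],
    label: str = "",
    **config_kwargs,
) -> pd.DataFrame:
    """Grid of per-arm sample sizes over comparator arms and effect sizes.

    ``comparators`` maps arm label -> (control count-mean lambda_c, shared
    zero probability pi), e.g. from fitted ZIP models or published
    parameters.  Returns a tidy frame with one row per (comparator, effect).
    """
    rows = []
    for arm, (lam_c, pi) in comparators.items():
        for e in effects:
            cfg = TrialDesignConfig(
                control_mean=lam_c, zero_prob=pi, effect=e, **config_kwargs
            )
            res = sample_size(cfg)
            rows.append(
                {
                    "duration": label,
                    "comparator": arm,
                    "effect": e,
                    "n_per_arm": res.n_per_arm,
                    "achieved_power": res.achieved_power,
                    "mc_se": res.mc_se,
                }
            )
    return pd.DataFrame(rows)
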