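"""Maximum-likelihood regression for four count-model families.

Fits the Poisson, Negative Binomial (NB2), zero-inflated Poisson (ZIP) and
zero-inflated Negative Binomial (ZINB) models to per-patient new-CL counts
with treatment arm as the only covariate (log link on the count-component
mean, reference arm coefficient fixed at 0).

Parameterization
----------------
* arm means: mu_arm = exp(beta_0 + beta_arm); beta_ref = 0.
* NB shape theta (variance mu + mu^2/theta) is reported as the
  *inverse dispersion* 1/theta, optimized as log(1/theta) so the Poisson
  limit 1/theta -> 0 is a free boundary, not a constraint.
* zero inflation pi (proportion of structural zeros) is optimized on the
  logit scale; by default a single pi is shared across arms, matching the
  convention that treatment acts on the count-component mean only.

Fits are deterministic: three fixed starting points (moment estimates,
moment estimates with the zero-excess pi estimate, all-zeros) are run
through a bounded quasi-Newton optimizer and the best optimum kept.
Standard errors come from the inverse observed information (central-
difference Hessian at the optimum), delta-transformed to the reporting
scale for 1/theta and pi.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .data_io import LesionCountRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "CountModelSpec",
    "FittedCountModel",
    "log_pmf",
    "fit_model",
    "predicted_frequencies",
]

FAMILIES = ("poisson", "negbin", "zip", "zinb")

# internal optimizer box; the bounds keep exp/expit finite, they are not
# statistical constraints (a fit at the box edge is a boundary fit)
_LOG_INVDISP_BOUNDS = (-12.0, 10.0)
_LOGIT_PI_BOUNDS = (-12.0, 8.0)
_BETA_BOUNDS = (-30.0, 30.0)
_FTOL = 1e-8


@dataclass(frozen=True)
class CountModelSpec:
    """Which family to fit and over which treatment arms.

    ``arms`` is the ordered arm list; the first entry is the reference arm
    unless ``reference`` says otherwise.  ``zero_inflation_shared`` selects
    a single extra-zeros probability across arms (only meaningful for
    zip/zinb); per-arm zero inflation is available for the significance
    check of that sharing.
    """

    family: str
    arms: tuple[str, ...]
    reference: str | None = None
    zero_inflation_shared: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(self.arms) == 0:
            raise ValueError("at least one arm is required")
        ref = self.reference if self.reference is not None else self.arms[0]
        if ref not in self.arms:
            raise ValueError(f"reference arm {ref!r} not in arms")
        object.__setattr__(self, "reference", ref)
        # keep reference first for a stable design matrix
        ordered = (self.reference,) + tuple(a for a in self.arms if a != self.reference)
        object.__setattr__(self, "arms", ordered)

    @property
    def has_dispersion(self) -> bool:
        return self.family in ("negbin", "zinb")

    @property
    def has_zero_inflation(self) -> bool:
        return self.family in ("zip", "zinb")

    @property
    def n_params(self) -> int:
        n = len(self.arms)
        if self.has_dispersion:
            n += 1
        if self.has_zero_inflation:
            n += 1 if self.zero_inflation_shared else len(self.arms)
        return n


@dataclass
class FittedCountModel:
    """A fitted count-model regression.

    ``beta`` maps the intercept (key ``"intercept"``, log mean count in the
    reference arm) and each non-reference arm to its log count-ratio
    coefficient.  ``zero_prob`` is the shared extra-zeros proportion (or a
    per-arm mapping when sharing is off); ``inv_dispersion`` is 1/theta.
    """

    spec: CountModelSpec
    beta: dict[str, float]
    loglik: float
    n_params: int
    aic: float
    converged: bool
    inv_dispersion: float | None = None
    zero_prob: float | dict[str, float] | None = None
    se: dict[str, float] = field(default_factory=dict)
    boundary: tuple[str, ...] = ()
    data_fingerprint: str = ""
    n_obs: int = 0

    def arm_mean(self, arm: str) -> float:
        """Count-component mean mu for one arm."""
        if arm == self.spec.reference:
            return math.exp(self.beta["intercept"])
        if arm not in self.spec.arms:
            raise ValueError(f"unknown arm {arm!r}")
        return math.exp(self.beta["intercept"] + self.beta[arm])

    def arm_zero_prob(self, arm: str) -> float:
        if self.zero_prob is None:
            return 0.0
        if isinstance(self.zero_prob, dict):
            return self.zero_prob[arm]
        return self.zero_prob

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "arms": list(self.spec.arms),
            "reference": self.spec.reference,
            "zero_inflation_shared": self.spec.zero_inflation_shared,
            "beta": self.beta,
            "inv_dispersion": self.inv_dispersion,
            "zero_prob": self.zero_prob,
            "se": self.se,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "boundary": list(self.boundary),
            "n_obs": self.n_obs,
            "data_fingerprint": self.data_fingerprint,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# log-probability mass functions
# ---------------------------------------------------------------------------

def _lgamma_ratio(k, theta):
    """log Gamma(k + theta) - log Gamma(theta) without large-theta cancellation.

    For integer k the ratio is sum_{j<k} log(theta + j), which stays accurate
    when theta is huge (the NB near its Poisson boundary); the direct gammaln
    difference is kept for moderate theta or very large counts.
    """
    k = np.asarray(k)
    kmax = int(k.max()) if k.size else 0
    if theta <= 1e4 or kmax > 100_000:
        return gammaln(k + theta) - gammaln(theta)
    steps = np.concatenate(([0.0], np.cumsum(np.log(theta + np.arange(kmax)))))
    return steps[k]


def log_pmf(family, k, mean, inv_dispersion=0.0, zero_prob=0.0):
    """Log probability mass of one family at count k (vectorized).

    Parameters
    ----------
    family : str
        One of ``poisson``, ``negbin``, ``zip``, ``zinb``.
    k : int or array of int
        Non-negative counts.
    mean : float
        Count-component mean mu > 0 (the mean of the Poisson/NB core; under
        zero inflation the marginal mean is (1 - zero_prob) * mu).
    inv_dispersion : float
        1/theta >= 0 for the NB core; 0 gives the Poisson limit.
    zero_prob : float
        Structural-zero probability pi in [0, 1).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    k = np.asarray(k)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
        if np.any(k != np.floor(k)) or np.any(k < 0):
            raise ValueError("k must be non-negative integers")
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if not (0.0 <= zero_prob < 1.0):
        raise ValueError(f"zero_prob must be in [0, 1), got {zero_prob}")
    if inv_dispersion < 0:
        raise ValueError(f"inv_dispersion must be >= 0, got {inv_dispersion}")

    if family in ("poisson", "zip") or inv_dispersion == 0.0:
        core = k * math.log(mean) - mean - gammaln(k + 1.0)
        log_p0_core = -mean
    else:
        theta = 1.0 / inv_dispersion
        log_p0_core = -theta * math.log1p(mean / theta)
        core = (
            _lgamma_ratio(k, theta)
            - gammaln(k + 1.0)
            + log_p0_core
            + k * (math.log(mean) - math.log(theta + mean))
        )

    if family in ("poisson", "negbin") or zero_prob == 0.0:
        # pi = 0 degenerates the mixture to its core family
        return core if core.ndim else float(core)
    out = np.log1p(-zero_prob) + core
    out = np.where(
        k == 0,
        np.logaddexp(math.log(zero_prob), math.log1p(-zero_prob) + log_p0_core),
        out,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _aggregate(spec: CountModelSpec, data: Sequence[LesionCountRecord]):
    """Per-arm (unique count, weight) lists; sufficient for all likelihoods."""
    by_arm: dict[str, list[int]] = {a: [] for a in spec.arms}
    for r in data:
        if r.arm not in by_arm:
            raise ValueError(f"record arm {r.arm!r} not in model spec arms")
        by_arm[r.arm].append(r.count)
    agg = []
    for a in spec.arms:
        if not by_arm[a]:
            raise ValueError(f"arm {a!r} has no observations")
        k, w = np.unique(np.array(by_arm[a], dtype=int), return_counts=True)
        agg.append((k, w.astype(float)))
    return agg


def _unpack(theta: np.ndarray, spec: CountModelSpec):
    n_arms = len(spec.arms)
    beta = theta[:n_arms]
    pos = n_arms
    invdisp = None
    if spec.has_dispersion:
        invdisp = math.exp(theta[pos])
        pos += 1
    pis = None
    if spec.has_zero_inflation:
        if spec.zero_inflation_shared:
            pis = np.full(n_arms, expit(theta[pos]))
            pos += 1
        else:
            pis = expit(theta[pos:pos + n_arms])
            pos += n_arms
    return beta, invdisp, pis


def _neg_loglik(theta: np.ndarray, spec: CountModelSpec, agg) -> float:
    beta, invdisp, pis = _unpack(theta, spec)
    eta = beta[0] + np.concatenate(([0.0], beta[1:]))  # per-arm log-mean
    total = 0.0
    for j, (k, w) in enumerate(agg):
        mu = math.exp(eta[j])
        pi = float(pis[j]) if pis is not None else 0.0
        lp = log_pmf(spec.family, k, mu, invdisp or 0.0, pi)
        total += float(np.dot(w, lp))
    return -total


def _starts(spec: CountModelSpec, agg) -> list[np.ndarray]:
    n_arms = len(spec.arms)
    means = np.array([np.dot(k, w) / w.sum() for k, w in agg])
    means = np.maximum(means, 0.05)
    variances = np.array(
        [np.dot(w, (k - m) ** 2) / max(w.sum() - 1, 1) for (k, w), m in zip(agg, means)]
    )
    beta0 = math.log(means[0])
    beta = np.concatenate(([beta0], np.log(means[1:]) - beta0))

    # pooled zero excess over the Poisson prediction
    n_tot = sum(w.sum() for _, w in agg)
    p0_obs = sum(w[k == 0].sum() for k, w in agg) / n_tot
    p0_pois = sum(w.sum() * math.exp(-m) for (_, w), m in zip(agg, means)) / n_tot
    pi_excess = np.clip((p0_obs - p0_pois) / max(1.0 - p0_pois, 1e-6), 0.02, 0.8)

    invdisp_mom = np.clip(
        np.nanmean((variances - means) / means**2), 1e-3, 50.0
    )

    def build(beta_part, invdisp_val, pi_val):
        parts = [beta_part]
        if spec.has_dispersion:
            parts.append([math.log(invdisp_val)])
        if spec.has_zero_inflation:
            reps = 1 if spec.zero_inflation_shared else n_arms
            parts.append([logit(pi_val)] * reps)
        return np.concatenate(parts)

    starts = [
        build(beta, invdisp_mom, 0.05),
        build(beta, invdisp_mom, float(pi_excess)),
        build(np.zeros(n_arms), 1.0, 0.5),  # all-zeros on the internal scale
    ]
    if spec.has_dispersion:
        # near the Poisson limit: the 1/theta -> 0 boundary is a common optimum
        starts.append(build(beta, 1e-4, float(pi_excess)))
    return starts


def _bounds(spec: CountModelSpec) -> list[tuple[float, float]]:
    n_arms = len(spec.arms)
    bounds = [_BETA_BOUNDS] * n_arms
    if spec.has_dispersion:
        bounds.append(_LOG_INVDISP_BOUNDS)
    if spec.has_zero_inflation:
        reps = 1 if spec.zero_inflation_shared else n_arms
        bounds.extend([_LOGIT_PI_BOUNDS] * reps)
    return bounds


def _numeric_hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, step 1e-5 * (1 + |x|) per coordinate."""
    p = len(x)
    h = 1e-5 * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[i] * h[j])
    return H


def _fingerprint(data: Sequence[LesionCountRecord]) -> str:
    payload = sorted((r.arm, r.count) for r in data)
    return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


def fit_model(spec: CountModelSpec, data: Sequence[LesionCountRecord]) -> FittedCountModel:
    """Fit one count-model family by maximum likelihood.

    Deterministic given the data: three fixed starts, L-BFGS-B on the
    negative log-likelihood (objective tolerance 1e-8), best optimum kept.
    An arm whose counts are all zero is fitted anyway (its coefficient runs
    to the box edge and is flagged); a dataset whose counts are *all* zero
    is refused for negbin/zinb and returns a boundary fit with a warning for
    poisson/zip.
    """
    data = list(data)
    if not data:
        raise ValueError("no data")
    agg = _aggregate(spec, data)
    counts_all = np.concatenate([k for k, _ in agg])
    weights_all = np.concatenate([w for _, w in agg])
    n_obs = int(weights_all.sum())

    if counts_all.max() == 0:
        if spec.has_dispersion:
            raise ValueError(
                f"all counts are zero: the {spec.family} dispersion is not identifiable"
            )
        warnings.warn(
            "all counts are zero; returning a boundary fit (mean at the box edge)",
            stacklevel=2,
        )
    elif len(np.unique(counts_all)) < 2:
        raise ValueError("need at least 2 distinct count values to fit")

    obj = lambda t: _neg_loglik(t, spec, agg)  # noqa: E731
    best = None
    any_success = False
    for x0 in _starts(spec, agg):
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=_bounds(spec),
            options={"ftol": _FTOL, "gtol": 1e-8, "maxiter": 2000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    # derivative-free polish: the boundary fits (pi or 1/theta at an edge)
    # leave a nearly flat direction where quasi-Newton stalls early
    lo = np.array([b[0] for b in _bounds(spec)])
    hi = np.array([b[1] for b in _bounds(spec)])
    polish = minimize(
        lambda t: obj(np.clip(t, lo, hi)), best.x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    if polish.fun < best.fun:
        best = polish
        best.x = np.clip(best.x, lo, hi)
    theta = best.x
    loglik = -float(best.fun)
    if not any_success:
        logger.warning("no optimizer start converged for %s fit", spec.family)

    beta_vec, invdisp, pis = _unpack(theta, spec)
    bounds = _bounds(spec)
    boundary = []
    names = ["intercept"] + list(spec.arms[1:])
    if spec.has_dispersion:
        names.append("inv_dispersion")
    if spec.has_zero_inflation:
        names.extend(
            ["zero_prob"] if spec.zero_inflation_shared
            else [f"zero_prob[{a}]" for a in spec.arms]
        )
    for name, val, (lo, hi) in zip(names, theta, bounds):
        if val - lo < 1e-6 or hi - val < 1e-6:
            boundary.append(name)
            if name in spec.arms[1:] or name == "intercept":
                warnings.warn(
                    f"{spec.family} fit: parameter {name!r} ran to the box edge "
                    "(arm with no events?)", stacklevel=2,
                )

    # observed information -> SEs, delta method to the reporting scale
    se = {}
    try:
        H = _numeric_hessian(obj, theta)
        free = np.array([n not in boundary for n in names])
        sd = np.full(len(theta), np.nan)
        cov = np.linalg.inv(H[np.ix_(free, free)])
        var = np.diag(cov)
        if np.any(var < 0):
            raise np.linalg.LinAlgError("negative variance")
        sd[free] = np.sqrt(var)
        for i, name in enumerate(names):
            if not free[i]:
                continue  # boundary parameter: curvature is one-sided, no SE
            if name == "inv_dispersion":
                se[name] = float(sd[i] * invdisp)  # d(1/theta)/d log(1/theta)
            elif name.startswith("zero_prob"):
                p = expit(theta[i])
                se[name] = float(sd[i] * p * (1.0 - p))
            else:
                se[name] = float(sd[i])
    except np.linalg.LinAlgError:
        logger.warning("observed information not invertible; SEs unavailable")

    beta = {"intercept": float(beta_vec[0])}
    for a, b in zip(spec.arms[1:], beta_vec[1:]):
        beta[a] = float(b)
    zero_prob: float | dict[str, float] | None = None
    if spec.has_zero_inflation:
        if spec.zero_inflation_shared:
            zero_prob = float(pis[0])
        else:
            zero_prob = {a: float(p) for a, p in zip(spec.arms, pis)}

    n_params = spec.n_params
    return FittedCountModel(
        spec=spec,
        beta=beta,
        inv_dispersion=float(invdisp) if invdisp is not None else None,
        zero_prob=zero_prob,
        se=se,
        loglik=loglik,
        n_params=n_params,
        aic=-2.0 * loglik + 2.0 * n_params,
        converged=bool(any_success),
        boundary=tuple(boundary),
        data_fingerprint=_fingerprint(data),
        n_obs=n_obs,
    )


def predicted_frequencies(
    model: FittedCountModel, arm: str, k_max: int
) -> np.ndarray:
    """Model-predicted percentage of patients with k = 0..k_max lesions.

    Returns ``100 * P(Y = k)`` under the arm's fitted parameters; the
    entries sum to at most 100 (to 100 as ``k_max`` grows).
    """
    if arm not in model.spec.arms:
        raise ValueError(f"unknown arm {arm!r}")
    if not model.converged:
        raise ValueError("model did not converge; refusing predictions")
    ks = np.arange(k_max + 1)
    lp = log_pmf(
        model.spec.family,
        ks,
        model.arm_mean(arm),
        model.inv_dispersion or 0.0,
        model.arm_zero_prob(arm),
    )
    return 100.0 * np.exp(lp)


def fit_single_arm(
    family: str, data: Iterable[LesionCountRecord], arm: str
) -> FittedCountModel:
    """Fit one family to a single arm's records (separate per-arm fit)."""
    sub = [r for r in data if r.arm == arm]
    spec = CountModelSpec(family=family, arms=(arm,))
    return fit_model(spec, sub)


__all__.append("fit_single_arm")
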