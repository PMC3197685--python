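"""Model comparison: AIC, likelihood-ratio test and the Vuong test.

The four families form a partial nesting structure: Poisson is nested in NB
(1/theta -> 0) and in ZIP (pi -> 0); ZIP and NB are nested in ZINB.  Nested
pairs are compared with the likelihood-ratio chi-square test; non-nested (or
boundary-nested) pairs with Vuong's normal test on pointwise log-likelihood
differences.  The Vuong statistic here is the uncorrected variant (no
AIC/BIC adjustment term); an adjustment is available via ``correction``.
Model ranking uses the Akaike Information Criterion, lower is better.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .count_models import (
    FAMILIES,
    CountModelSpec,
    FittedCountModel,
    fit_model,
    log_pmf,
)
from .data_io import LesionCountRecord

logger = logging.getLogger(__name__)

__all__ = [
    "aic",
    "lr_test",
    "vuong_test",
    "compare_all",
    "ModelComparisonResult",
    "PairwiseTest",
    "NESTED_PAIRS",
]

#: (null, alternative) pairs where the null is nested in the alternative
#: (pi -> 0 and 1/theta -> 0 are boundary nestings).
NESTED_PAIRS = (
    ("poisson", "negbin"),
    ("poisson", "zip"),
    ("zip", "zinb"),
    ("negbin", "zinb"),
)

#: pairs compared with the Vuong test in the whole-dataset analysis
VUONG_PAIRS = (
    ("poisson", "zip"),
    ("negbin", "zip"),
    ("negbin", "zinb"),
)


def aic(loglik: float, n_params: int) -> float:
    """Akaike Information Criterion, -2 loglik + 2 n_params."""
    return -2.0 * loglik + 2.0 * n_params


@dataclass(frozen=True)
class PairwiseTest:
    model_a: str
    model_b: str
    kind: str  # "LR" or "Vuong"
    statistic: float
    p_value: float
    df: int | None = None
    note: str = ""


def lr_test(fit_null: FittedCountModel, fit_alt: FittedCountModel):
    """Likelihood-ratio chi-square test for a nested model pair.

    Returns ``(statistic, df, p_value)`` with the statistic
    2 (loglik_alt - loglik_null) clipped at zero and df the parameter-count
    difference.  The boundary nestings (pi or 1/theta at zero) are tested
    against the plain chi-square reference, the convention used when these
    models are ranked in practice.
    """
    pair = (fit_null.spec.family, fit_alt.spec.family)
    if pair not in NESTED_PAIRS:
        raise ValueError(
            f"{pair[0]} is not nested in {pair[1]}; use vuong_test for "
            "non-nested comparisons"
        )
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("alternative must have more parameters than the null")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        warnings.warn(
            f"null {pair[0]} log-likelihood exceeds alternative {pair[1]} "
            f"by {-stat:.3g} (numerical); statistic clipped to 0",
            stacklevel=2,
        )
        stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def _pointwise_loglik(fit: FittedCountModel, data: Sequence[LesionCountRecord]) -> np.ndarray:
    out = np.empty(len(data))
    for i, r in enumerate(data):
        out[i] = log_pmf(
            fit.spec.family,
            r.count,
            fit.arm_mean(r.arm),
            fit.inv_dispersion or 0.0,
            fit.arm_zero_prob(r.arm),
        )
    return out


def vuong_test(
    fit_a: FittedCountModel,
    fit_b: FittedCountModel,
    data: Sequence[LesionCountRecord],
    correction: str | None = None,
    one_sided: bool = False,
):
    """Vuong closeness test between two fits of the same data.

    Computes per-observation log-likelihood differences
    ``m_i = log f_A(y_i) - log f_B(y_i)`` and the statistic
    ``V = sum(m_i) / (sqrt(n) * sd(m_i))``; positive V favours model A.
    Two-sided standard-normal p by default.  ``correction="aic"`` or
    ``"bic"`` subtracts the corresponding complexity penalty from
    ``sum(m_i)`` before standardizing.
    """
    data = list(data)
    n = len(data)
    if n == 0:
        raise ValueError("no data")
    m = _pointwise_loglik(fit_a, data) - _pointwise_loglik(fit_b, data)
    sd = float(np.std(m, ddof=0))
    note = ""
    if sd < 1e-12:
        return 0.0, 1.0, "identical pointwise likelihoods"
    total = float(np.sum(m))
    if correction == "aic":
        total -= fit_a.n_params - fit_b.n_params
    elif correction == "bic":
        total -= 0.5 * math.log(n) * (fit_a.n_params - fit_b.n_params)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    v = total / (np.sqrt(n) * sd)
    if one_sided:
        p = float(stats.norm.sf(v))
    else:
        p = float(2.0 * stats.norm.sf(abs(v)))
    return float(v), p, note


@dataclass
class ModelComparisonResult:
    """All four fits on one dataset plus their pairwise tests."""

    fits: dict[str, FittedCountModel]
    tests: list[PairwiseTest]
    best_model: str
    excluded: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in FAMILIES:
            if fam not in self.fits:
                continue
            f = self.fits[fam]
            rows.append(
                {
                    "family": fam,
                    "loglik": f.loglik,
                    "n_params": f.n_params,
                    "aic": f.aic,
                    "converged": f.converged,
                }
            )
        return pd.DataFrame(rows)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_a": t.model_a,
                    "model_b": t.model_b,
                    "kind": t.kind,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                }
                for t in self.tests
            ]
        )

    def format_text(self) -> str:
        """Human-readable comparison report."""
        lines = ["Model comparison (lower AIC is better)", ""]
        df = self.to_frame()
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        lines.append("")
        best = self.fits[self.best_model]
        lines.append(f"Best model by AIC: {self.best_model} (AIC = {best.aic:.1f})")
        if best.spec.has_zero_inflation and best.zero_prob is not None:
            zp = best.zero_prob
            if not isinstance(zp, dict):
                lines.append(f"  shared extra-zeros: {100 * zp:.0f}%")
        lines.append("")
        lines.append("Pairwise tests:")
        for t in self.tests:
            extra = f", df={t.df}" if t.df is not None else ""
            lines.append(
                f"  {t.model_a} vs {t.model_b} [{t.kind}]: "
                f"stat={t.statistic:.3f}{extra}, p={t.p_value:.3g}"
            )
        if self.excluded:
            lines.append(f"Excluded (non-converged): {', '.join(self.excluded)}")
        return "\n".join(lines)


def compare_all(
    data: Sequence[LesionCountRecord],
    arms: Sequence[str] | None = None,
    reference: str | None = None,
    zero_inflation_shared: bool = True,
    families: Sequence[str] = FAMILIES,
) -> ModelComparisonResult:
    """Fit all families to one dataset and assemble the comparison.

    Runs LR tests for the nested pairs and Vuong tests for
    Poisson-vs-ZIP, NB-vs-ZIP and NB-vs-ZINB; the minimum-AIC converged fit
    is declared best.
    """
    data = list(data)
    if arms is None:
        seen: list[str] = []
        for r in data:
            if r.arm not in seen:
                seen.append(r.arm)
        arms = seen
    fits: dict[str, FittedCountModel] = {}
    for fam in families:
        spec = CountModelSpec(
            family=fam,
            arms=tuple(arms),
            reference=reference,
            zero_inflation_shared=zero_inflation_shared,
        )
        fits[fam] = fit_model(spec, data)

    tests: list[PairwiseTest] = []
    for null, alt in NESTED_PAIRS:
        if null in fits and alt in fits:
            stat, df, p = lr_test(fits[null], fits[alt])
            tests.append(PairwiseTest(null, alt, "LR", stat, p, df=df))
    for a, b in VUONG_PAIRS:
        if a in fits and b in fits:
            v, p, note = vuong_test(fits[a], fits[b], data)
            tests.append(PairwiseTest(a, b, "Vuong", v, p, note=note))

    converged = {f: m for f, m in fits.items() if m.converged}
    excluded = tuple(f for f in fits if f not in converged)
    if excluded:
        warnings.warn(
            f"excluding non-converged fits from ranking: {excluded}", stacklevel=2
        )
    if not converged:
        raise RuntimeError("no model converged")
    best = min(converged, key=lambda f: converged[f].aic)
    return ModelComparisonResult(
        fits=fits, tests=tests, best_model=best, excluded=excluded
    )
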