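import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clcounts as cc
from clcounts.count_models import CountModelSpec, fit_model, log_pmf


def make_records(counts, arm="a"):
    return [
        cc.LesionCountRecord(f"p{i}", arm, 12, int(k)) for i, k in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# log_pmf
# ---------------------------------------------------------------------------

def test_poisson_zero_probability_closed_form():
    # P(0) = exp(-lambda); at the untreated-arm 1-year mean this is ~21.7%
    assert math.exp(log_pmf("poisson", 0, 1.529)) == pytest.approx(0.217, abs=0.001)


def test_zip_zero_probability_closed_form():
    val = math.exp(log_pmf("zip", 0, 1.751, zero_prob=0.13))
    assert val == pytest.approx(0.13 + 0.87 * math.exp(-1.751), rel=1e-12)
    assert val == pytest.approx(0.281, abs=0.001)


@given(lam=st.floats(0.05, 20.0), k=st.integers(0, 40))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_zip_without_inflation_is_poisson(lam, k):
    assert log_pmf("zip", k, lam, zero_prob=0.0) == pytest.approx(
        log_pmf("poisson", k, lam), rel=1e-14
    )


@given(mu=st.floats(0.05, 20.0), k=st.integers(0, 40))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_negbin_poisson_limit(mu, k):
    """As 1/theta -> 0 the NB pmf converges to the Poisson pmf."""
    assert log_pmf("negbin", k, mu, inv_dispersion=1e-12) == pytest.approx(
        log_pmf("poisson", k, mu), abs=1e-6
    )


@pytest.mark.parametrize(
    "family, kwargs",
    [
        ("poisson", {}),
        ("negbin", {"inv_dispersion": 0.7}),
        ("zip", {"zero_prob": 0.3}),
        ("zinb", {"inv_dispersion": 0.4, "zero_prob": 0.2}),
    ],
)
@pytest.mark.parametrize("mean", [0.3, 1.7, 8.0])
def test_pmf_normalizes(family, kwargs, mean):
    ks = np.arange(0, 1001)
    total = np.exp(log_pmf(family, ks, mean, **kwargs)).sum()
    assert 1.0 - 1e-9 <= total <= 1.0 + 1e-12


def test_pmf_finite_at_huge_counts():
    assert np.isfinite(log_pmf("negbin", 10**6, 2.0, inv_dispersion=0.5))
    assert np.isfinite(log_pmf("zip", 10**6, 2.0, zero_prob=0.4))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"mean": 0.0},
        {"mean": -1.0},
        {"mean": 1.0, "zero_prob": 1.0},
        {"mean": 1.0, "zero_prob": -0.1},
        {"mean": 1.0, "inv_dispersion": -0.5},
    ],
)
def test_pmf_domain_errors(kwargs):
    with pytest.raises(ValueError):
        log_pmf("zinb", 0, **kwargs)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_poisson_single_arm_mle_is_sample_mean():
    fit = fit_model(CountModelSpec("poisson", ("a",)), make_records([0, 1, 2, 3]))
    assert fit.beta["intercept"] == pytest.approx(math.log(1.5), abs=1e-6)
    assert fit.arm_mean("a") == pytest.approx(1.5, abs=1e-6)
    assert fit.converged


def test_aic_identity_for_every_family(one_year_comparison):
    for fam, fit in one_year_comparison.fits.items():
        assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.n_params
        expected_params = {"poisson": 4, "negbin": 5, "zip": 5, "zinb": 6}[fam]
        assert fit.n_params == expected_params


def test_nesting_loglik_inequalities(one_year_comparison):
    ll = {f: m.loglik for f, m in one_year_comparison.fits.items()}
    tol = 1e-6
    assert ll["zip"] >= ll["poisson"] - tol
    assert ll["negbin"] >= ll["poisson"] - tol
    assert ll["zinb"] >= ll["negbin"] - tol


def _grid_search(counts, family):
    """Dense-grid likelihood maximization: the independent oracle."""
    counts = np.asarray(counts)
    n0 = int((counts == 0).sum())
    npos = len(counts) - n0
    s = counts.sum()
    logfact = sum(math.lgamma(k + 1) for k in counts if k > 0)
    lams = np.arange(0.01, 10.0 + 1e-12, 1e-3)
    if family == "poisson":
        ll = s * np.log(lams) - len(counts) * lams - logfact
        i = int(np.argmax(ll))
        return (lams[i], 0.0), ll[i]
    pis = np.arange(0.0, 0.9 + 1e-12, 1e-3)
    # loglik(lam, pi) = n0 log(pi + (1-pi) e^-lam) + npos log(1-pi)
    #                   + s log lam - npos lam - logfact
    zero_term = n0 * np.log(
        pis[None, :] + (1 - pis[None, :]) * np.exp(-lams[:, None])
    )
    pos_term = (
        npos * np.log1p(-pis)[None, :]
        + (s * np.log(lams) - npos * lams)[:, None]
    )
    ll = zero_term + pos_term - logfact
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return (lams[i], pis[j]), ll[i, j]


@pytest.mark.parametrize(
    "counts",
    [
        [0, 0, 0, 0, 1, 1, 2, 3, 5, 0, 0, 2, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 1, 2, 2, 3],
        [1, 2, 3, 4, 5, 0, 1, 2, 0, 0],
    ],
)
@pytest.mark.parametrize("family", ["poisson", "zip"])
def test_fit_matches_dense_grid_oracle(counts, family):
    """On small single-arm data the optimizer agrees with brute-force grid
    search within one grid step in parameters and 1e-4 in log-likelihood."""
    (lam_g, pi_g), ll_g = _grid_search(counts, family)
    fit = fit_model(CountModelSpec(family, ("a",)), make_records(counts))
    assert fit.loglik >= ll_g - 1e-4
    assert fit.arm_mean("a") == pytest.approx(lam_g, abs=1.5e-3)
    if family == "zip":
        assert fit.arm_zero_prob("a") == pytest.approx(pi_g, abs=1.5e-3)


def test_zip_parameter_recovery_is_unbiased():
    """Refits of ZIP-generated data (lambda=1.5, pi=0.15, n=2000) recover the
    truth within 3 Monte-Carlo standard errors across 20 seeds."""
    lams, pis = [], []
    for seed in range(20):
        recs = cc.generate_study(
            cc.GeneratorConfig("zip", (cc.ArmSpec("a", 2000, 1.5, 0.15),), seed=seed)
        )
        fit = fit_model(CountModelSpec("zip", ("a",)), recs)
        lams.append(fit.arm_mean("a"))
        pis.append(fit.arm_zero_prob("a"))
    for est, truth in ((np.array(lams), 1.5), (np.array(pis), 0.15)):
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - truth) <= 3 * mc_se


def test_statsmodels_agrees_with_zip_fit(one_year_cohort, one_year_comparison):
    """Independent cross-check of the shared-pi ZIP regression."""
    sm = pytest.importorskip("statsmodels.api")
    from clcounts.data_io import records_to_frame

    df = records_to_frame(one_year_cohort)
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["arm"] == a).astype(float).to_numpy() for a in cc.ARM_ORDER[1:]]
    )
    ref = sm.ZeroInflatedPoisson(
        df["new_cl_count"].to_numpy(), X, exog_infl=np.ones((len(df), 1))
    ).fit(disp=0)
    ours = one_year_comparison.fits["zip"]
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)
    assert ours.beta["intercept"] == pytest.approx(ref.params[1], abs=1e-3)
    assert ours.beta["sc_ifn_beta1a"] == pytest.approx(ref.params[2], abs=1e-3)
    from scipy.special import expit

    assert ours.arm_zero_prob("no_therapy") == pytest.approx(
        expit(ref.params[0]), abs=1e-3
    )


def test_per_arm_zero_inflation_spec():
    recs = cc.generate_study(
        cc.GeneratorConfig(
            "zip",
            (cc.ArmSpec("a", 300, 2.0, 0.4), cc.ArmSpec("b", 300, 2.0, 0.05)),
            seed=3,
        )
    )
    shared = fit_model(CountModelSpec("zip", ("a", "b")), recs)
    free = fit_model(
        CountModelSpec("zip", ("a", "b"), zero_inflation_shared=False), recs
    )
    assert free.n_params == shared.n_params + 1
    assert free.loglik >= shared.loglik - 1e-6
    zp = free.zero_prob
    assert isinstance(zp, dict) and zp["a"] > zp["b"]


def test_all_zero_data_handling():
    zeros = make_records([0] * 12)
    with pytest.raises(ValueError, match="not identifiable"):
        fit_model(CountModelSpec("negbin", ("a",)), zeros)
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_model(CountModelSpec("poisson", ("a",)), zeros)
    assert fit.arm_mean("a") < 1e-6


def test_all_zero_arm_is_flagged():
    recs = make_records([0, 1, 2, 3, 1], arm="a") + make_records([0] * 5, arm="b")
    with pytest.warns(UserWarning, match="box edge"):
        fit = fit_model(CountModelSpec("poisson", ("a", "b")), recs)
    assert "b" in fit.boundary
    assert fit.arm_mean("b") < 1e-4


def test_predicted_frequencies_normalize(one_year_comparison):
    fit = one_year_comparison.fits["zip"]
    freqs = cc.predicted_frequencies(fit, "no_therapy", 200)
    assert freqs.sum() == pytest.approx(100.0, abs=1e-6)
    assert freqs.sum() <= 100.0 + 1e-9
    with pytest.raises(ValueError, match="unknown arm"):
        cc.predicted_frequencies(fit, "nope", 5)


def test_fit_serializes_to_json(one_year_comparison):
    import json

    payload = json.loads(one_year_comparison.fits["zip"].to_json())
    assert payload["family"] == "zip"
    assert payload["n_params"] == 5
    assert payload["data_fingerprint"]
    assert payload["aic"] == pytest.approx(
        -2 * payload["loglik"] + 2 * payload["n_params"]
    )
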