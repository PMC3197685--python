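import numpy as np
import pytest

import clcounts as cc
from clcounts.trial_design import (
    TrialDesignConfig,
    _wald_zip_pvalue,
    estimate_power,
    poisson_rates_sample_size,
    sample_size,
    sample_size_table,
    simulate_trial,
)


def test_type_one_error_is_calibrated():
    """With no treatment effect the rejection rate at alpha = 0.05 stays in
    [0.03, 0.07] (rank-sum test, 2000 replicates, n = 50 per arm)."""
    cfg = TrialDesignConfig(control_mean=1.377, zero_prob=0.13, effect=0.0,
                            n_sims=2000, seed=11)
    power, mc_se = estimate_power(cfg, 50)
    assert 0.03 <= power <= 0.07
    assert mc_se == pytest.approx(np.sqrt(power * (1 - power) / 2000))


def test_type_one_error_wald_smoke():
    cfg = TrialDesignConfig(control_mean=1.377, zero_prob=0.13, effect=0.0,
                            n_sims=500, seed=13, test="wald_zip")
    power, _ = estimate_power(cfg, 50)
    assert 0.02 <= power <= 0.09


def test_power_monotone_in_n():
    cfg = TrialDesignConfig(control_mean=1.3, zero_prob=0.13, effect=0.4,
                            n_sims=800, seed=5)
    powers = {}
    for n in (40, 80, 160):
        powers[n], se = estimate_power(cfg, n)
    jitter = 2 * np.sqrt(2) * np.sqrt(0.25 / 800)
    assert powers[80] >= powers[40] - jitter
    assert powers[160] >= powers[80] - jitter
    assert powers[160] > powers[40]


def test_power_monotone_in_effect():
    powers = {}
    for e in (0.2, 0.35, 0.5):
        cfg = TrialDesignConfig(control_mean=1.3, zero_prob=0.13, effect=e,
                                n_sims=800, seed=6)
        powers[e], _ = estimate_power(cfg, 80)
    jitter = 2 * np.sqrt(2) * np.sqrt(0.25 / 800)
    assert powers[0.35] >= powers[0.2] - jitter
    assert powers[0.5] >= powers[0.35] - jitter
    assert powers[0.5] > powers[0.2]


def test_overwhelming_effect_always_rejects():
    cfg = TrialDesignConfig(control_mean=1.5, zero_prob=0.1, effect=0.99,
                            n_sims=400, seed=2)
    power, _ = estimate_power(cfg, 200)
    assert power >= 0.995


def test_underpowered_limit_near_alpha():
    cfg = TrialDesignConfig(control_mean=1.0, zero_prob=0.1, effect=0.3,
                            n_sims=1000, seed=3)
    power, _ = estimate_power(cfg, 5)
    assert power < 0.2


def test_sample_size_reproducible_and_power_target_met():
    cfg = TrialDesignConfig(control_mean=1.5, zero_prob=0.1, effect=0.5,
                            n_sims=300, seed=17)
    r1 = sample_size(cfg)
    r2 = sample_size(cfg)
    assert r1.n_per_arm == r2.n_per_arm
    assert r1.power_curve == r2.power_curve
    assert r1.achieved_power >= cfg.target_power - 2 * r1.mc_se
    # one step below the returned n the estimated power was below target
    below = dict(r1.power_curve).get(r1.n_per_arm - 1)
    if below is not None:
        assert below < cfg.target_power


def test_zero_inflation_off_matches_poisson_closed_form():
    """With pi = 0 the machinery is a plain two-Poisson-rates simulation and
    the Wald-based n lands within 15% of the closed-form approximation."""
    n0 = poisson_rates_sample_size(2.0, 1.0)
    cfg = TrialDesignConfig(control_mean=2.0, zero_prob=0.0, effect=0.5,
                            n_sims=600, seed=5, test="wald_zip")
    res = sample_size(cfg)
    assert abs(res.n_per_arm - n0) <= 0.15 * n0


def test_halving_alpha_increases_n():
    base = dict(control_mean=1.5, zero_prob=0.1, effect=0.5, n_sims=400, seed=9)
    n_05 = sample_size(TrialDesignConfig(alpha=0.05, **base)).n_per_arm
    n_025 = sample_size(TrialDesignConfig(alpha=0.025, **base)).n_per_arm
    assert n_025 > n_05


def test_effect_mechanism_on_zero_inflation():
    cfg = TrialDesignConfig(control_mean=1.5, zero_prob=0.2, effect=0.4,
                            effect_mechanism="zero_inflation")
    lam_t, pi_t = cfg.treatment_params
    assert lam_t == 1.5
    # overall mean reduced by the effect
    assert (1 - pi_t) * lam_t == pytest.approx(0.6 * (1 - 0.2) * 1.5)


def test_degenerate_all_zero_arm_gives_p_one():
    assert _wald_zip_pvalue(np.zeros(20, dtype=int), np.ones(20, dtype=int)) == 1.0
    rng = np.random.default_rng(0)
    cfg = TrialDesignConfig(control_mean=0.01, zero_prob=0.5, effect=0.5)
    p = simulate_trial(cfg, 5, rng)
    assert 0.0 <= p <= 1.0


def test_simulate_trial_rejects_tiny_arms():
    cfg = TrialDesignConfig(control_mean=1.0, zero_prob=0.1, effect=0.5)
    with pytest.raises(ValueError, match=">= 5"):
        simulate_trial(cfg, 4, np.random.default_rng(0))


def test_config_validation():
    with pytest.raises(ValueError):
        TrialDesignConfig(control_mean=0.0, zero_prob=0.1, effect=0.5)
    with pytest.raises(ValueError):
        TrialDesignConfig(control_mean=1.0, zero_prob=1.0, effect=0.5)
    with pytest.raises(ValueError):
        TrialDesignConfig(control_mean=1.0, zero_prob=0.1, effect=1.0)
    with pytest.raises(ValueError):
        TrialDesignConfig(control_mean=1.0, zero_prob=0.1, effect=0.5, test="t")
    with pytest.raises(ValueError, match="positive effect"):
        sample_size(TrialDesignConfig(control_mean=1.0, zero_prob=0.1, effect=0.0))


def test_sample_size_table_single_cell_matches_sample_size():
    kwargs = dict(n_sims=300, seed=23)
    table = sample_size_table({"ctrl": (1.5, 0.1)}, effects=[0.5], **kwargs)
    direct = sample_size(
        TrialDesignConfig(control_mean=1.5, zero_prob=0.1, effect=0.5, **kwargs)
    )
    assert len(table) == 1
    assert table["n_per_arm"].iloc[0] == direct.n_per_arm


def test_sample_size_table_decreasing_in_effect():
    table = sample_size_table(
        {"ctrl": (1.4, 0.13)}, effects=[0.3, 0.4, 0.5], n_sims=400, seed=31
    )
    ns = table.sort_values("effect")["n_per_arm"].to_numpy()
    assert ns[0] > ns[1] > ns[2]
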