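import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gscaboot import (
    BootstrapDistribution,
    JackknifeDistribution,
    acceleration,
    bca_ci,
    bias_correction,
    bootstrap_distribution,
    bootstrap_se,
    bootstrap_statistic,
    critical_ratio,
    fit_gsca,
    generate_normal,
    jackknife_distribution,
    jackknife_statistic,
    percentile_ci,
    resample_indices,
    student_t_ci,
)


def make_dist(values, original=None, n=50):
    values = np.asarray(values, dtype=float).reshape(len(values), -1)
    est = pd.DataFrame(values, columns=["p"])
    orig = pd.Series([np.median(values) if original is None else original], index=["p"])
    return BootstrapDistribution(estimates=est, original=orig, n=n)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resample_indices_contract():
    idx = resample_indices(25, seed=3)
    assert idx.shape == (25,)
    assert idx.min() >= 0 and idx.max() < 25
    np.testing.assert_array_equal(idx, resample_indices(25, seed=3))
    with pytest.raises(ValueError):
        resample_indices(1, seed=0)


def test_resample_distinct_fraction():
    """E[#distinct]/n = 1 - (1 - 1/n)^n, checked over 10,000 draws."""
    n, draws = 20, 10_000
    rng = np.random.default_rng(42)
    frac = np.mean(
        [len(np.unique(resample_indices(n, rng))) / n for _ in range(draws)]
    )
    expect = 1.0 - (1.0 - 1.0 / n) ** n
    assert frac == pytest.approx(expect, abs=0.005)


# ---------------------------------------------------------------------------
# SE and critical ratio
# ---------------------------------------------------------------------------


def test_bootstrap_se_examples():
    assert bootstrap_se(make_dist([4.0] * 10), "p") == 0.0
    assert bootstrap_se(make_dist([1.0, 2.0, 3.0]), "p") == pytest.approx(1.0)


def test_bootstrap_se_of_sample_mean():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(100, 1))
    reps, _ = bootstrap_statistic(x, lambda r: np.array([r.mean()]), B=800, seed=6)
    dist = BootstrapDistribution(
        estimates=reps.set_axis(["p"], axis=1), original=pd.Series({"p": x.mean()}), n=100
    )
    assert bootstrap_se(dist, "p") == pytest.approx(x.std(ddof=0) / 10.0, rel=0.15)


def test_critical_ratio():
    assert critical_ratio(2.0, 0.5) == 4.0
    assert critical_ratio(0.0, 1.3) == 0.0
    assert np.sign(critical_ratio(-1.7, 0.2)) == -1.0
    with pytest.raises(ValueError):
        critical_ratio(1.0, 0.0)


# ---------------------------------------------------------------------------
# percentile intervals
# ---------------------------------------------------------------------------


def test_percentile_printed_example():
    """B = 1000, alpha = 0.05: endpoints are the 25th and 975th order statistics."""
    rng = np.random.default_rng(0)
    values = rng.permutation(np.arange(1.0, 1001.0))
    ci = percentile_ci(make_dist(values), "p", alpha=0.05)
    assert ci.lower == 25.0 and ci.upper == 975.0


def test_percentile_enumerated_example():
    ci = percentile_ci(make_dist(np.arange(1.0, 21.0)), "p", alpha=0.10)
    assert (ci.lower, ci.upper) == (1.0, 19.0)


def test_percentile_degenerate_and_errors():
    ci = percentile_ci(make_dist([3.0] * 40), "p", alpha=0.1)
    assert ci.lower == ci.upper == 3.0
    with pytest.raises(ValueError, match="too few"):
        percentile_ci(make_dist(np.arange(10.0)), "p", alpha=0.05)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_percentile_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    B = int(rng.integers(41, 60))
    values = rng.normal(size=B)
    alpha = 0.10
    ci = percentile_ci(make_dist(values), "p", alpha=alpha)
    ordered = sorted(values)
    j = int(np.floor(alpha / 2 * B + 0.5))
    k = int(np.floor((1 - alpha / 2) * B + 0.5))
    assert ci.lower == ordered[max(j, 1) - 1]
    assert ci.upper == ordered[min(k, B) - 1]


def test_percentile_width_monotone_in_alpha():
    values = np.random.default_rng(9).normal(size=200)
    dist = make_dist(values)
    widths = []
    for alpha in (0.32, 0.10, 0.05, 0.02):
        ci = percentile_ci(dist, "p", alpha=alpha)
        widths.append(ci.upper - ci.lower)
    assert np.all(np.diff(widths) >= 0)


# ---------------------------------------------------------------------------
# BCa ingredients
# ---------------------------------------------------------------------------


def test_bias_correction_examples():
    # exactly half the replicates below the original
    values = np.concatenate([np.full(500, -1.0), np.full(500, 1.0)])
    assert bias_correction(make_dist(values, original=0.0), "p") == 0.0
    # 975 of 1000 below: z0 = Phi^-1(0.975) = 1.96
    values = np.concatenate([np.full(975, -1.0), np.full(25, 1.0)])
    assert bias_correction(make_dist(values, original=0.0), "p") == pytest.approx(
        1.959964, abs=1e-6
    )
    # none below: clamped, finite
    z0 = bias_correction(make_dist(np.ones(100), original=0.0), "p")
    assert z0 == pytest.approx(stats.norm.ppf(0.5 / 100))


def make_jack(values):
    return JackknifeDistribution(estimates=pd.DataFrame({"p": np.asarray(values, float)}))


def test_acceleration_examples():
    assert acceleration(make_jack([2.0, 2.0, 2.0]), "p") == 0.0
    assert acceleration(make_jack([-1.0, 0.0, 1.0]), "p") == pytest.approx(0.0, abs=1e-15)
    # {0, 0, 3}: a = -6 / (6 * 6^{3/2})
    assert acceleration(make_jack([0.0, 0.0, 3.0]), "p") == pytest.approx(
        -6.0 / (6.0 * 6.0**1.5)
    )


def test_bca_reduces_to_percentile_when_unadjusted():
    # symmetric replicates with the original at the median -> z0 = 0;
    # symmetric jackknife -> a = 0
    values = np.concatenate([-np.arange(1.0, 101.0), np.arange(1.0, 101.0)])
    dist = make_dist(values, original=0.0)
    jack = make_jack(np.linspace(-1, 1, 11))
    b = bca_ci(dist, jack, "p", alpha=0.10)
    p = percentile_ci(dist, "p", alpha=0.10)
    assert b.diagnostics["z0"] == 0.0
    assert b.diagnostics["a"] == pytest.approx(0.0, abs=1e-12)
    assert (b.lower, b.upper) == (p.lower, p.upper)


def test_bca_adjusted_levels_follow_formula():
    """z0 = 1.96, a = 0: alpha1 = Phi(1.96) = 0.975, alpha2 = Phi(2*1.96 + 1.96)."""
    values = np.concatenate([np.full(975, -1.0), np.full(25, 1.0)])
    dist = make_dist(values, original=0.0, n=50)
    jack = make_jack([1.0, 2.0, 3.0, 2.0, 1.0, 2.0, 3.0, 2.0])  # symmetric -> a = 0
    b = bca_ci(dist, jack, "p", alpha=0.05)
    z0 = b.diagnostics["z0"]
    assert b.diagnostics["a"] == pytest.approx(0.0, abs=1e-12)
    assert b.diagnostics["alpha1"] == pytest.approx(stats.norm.cdf(z0 + z0 - 1.959964), abs=1e-9)
    assert b.diagnostics["alpha2"] == pytest.approx(stats.norm.cdf(z0 + z0 + 1.959964), abs=1e-9)


def test_bca_small_fixture_hand_oracle():
    """B = 10 fixture: endpoints checked against a by-hand enumeration."""
    values = np.array([0.1, 0.4, 0.2, 0.9, 0.6, 0.3, 0.8, 0.5, 0.7, 1.0])
    dist = make_dist(values, original=0.55, n=5)
    jack = make_jack([0.5, 0.52, 0.58, 0.6, 0.61])
    alpha = 0.30
    b = bca_ci(dist, jack, "p", alpha=alpha)
    # hand computation
    z0 = stats.norm.ppf(np.sum(values < 0.55) / 10)  # 5/10 -> 0
    d = np.mean(jack.estimates["p"]) - jack.estimates["p"].to_numpy()
    a = np.sum(d**3) / (6 * np.sum(d**2) ** 1.5)
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
    a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
    ordered = np.sort(values)
    j = min(max(int(np.floor(a1 * 10 + 0.5)), 1), 10)
    k = min(max(int(np.floor(a2 * 10 + 0.5)), 1), 10)
    assert b.lower == ordered[j - 1]
    assert b.upper == ordered[k - 1]


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------


def test_student_t_examples():
    ci = student_t_ci(2.0, 0.5, n=10, alpha=0.05)
    assert ci.lower == pytest.approx(2 - 2.262157 * 0.5, abs=1e-4)
    assert ci.upper == pytest.approx(2 + 2.262157 * 0.5, abs=1e-4)
    degenerate = student_t_ci(1.5, 0.0, n=10, alpha=0.05)
    assert degenerate.lower == degenerate.upper == 1.5
    wide = student_t_ci(0.0, 1.0, n=10_001, alpha=0.05)
    assert wide.upper == pytest.approx(1.9602, abs=5e-4)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def test_jackknife_mean_closed_form():
    """theta(-i) = (n xbar - x_i) / (n - 1), against the generic refit path."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=(12, 1))
    jk = jackknife_statistic(x, lambda rows: np.array([rows.mean()]))
    n = 12
    expect = (n * x.mean() - x[:, 0]) / (n - 1)
    np.testing.assert_allclose(jk.iloc[:, 0].to_numpy(), expect, atol=1e-12)


def test_jackknife_identical_rows():
    x = np.tile([[1.0, 2.0]], (8, 1)) + 1e-12
    jk = jackknife_statistic(x, lambda rows: np.array([rows[:, 0].mean()]))
    assert jk.iloc[:, 0].nunique() == 1


# ---------------------------------------------------------------------------
# GSCA-specific resampling
# ---------------------------------------------------------------------------


def test_gsca_bootstrap_contract(pop_model):
    data = generate_normal(pop_model, 40, 1)
    original = fit_gsca(data, pop_model.spec)
    dist = bootstrap_distribution(data, pop_model.spec, original, B=25, seed=4)
    assert dist.B == 25 and dist.n == 40
    assert list(dist.estimates.columns) == list(original.theta.index)
    again = bootstrap_distribution(data, pop_model.spec, original, B=25, seed=4)
    pd.testing.assert_frame_equal(dist.estimates, again.estimates)


def test_gsca_jackknife_contract(pop_model):
    data = generate_normal(pop_model, 25, 2)
    original = fit_gsca(data, pop_model.spec)
    jack = jackknife_distribution(data, pop_model.spec, original)
    assert len(jack.estimates) == 25
    pd.testing.assert_series_equal(
        jack.means, jack.estimates.mean(axis=0), check_names=False
    )


def test_inadmissible_resamples_redrawn_not_dropped():
    """Replicates that raise the inadmissibility error are redrawn, so exactly
    B rows come back, with the failure count reported."""
    from gscaboot import InadmissibleSampleError

    x = np.arange(20.0).reshape(-1, 1)
    calls = {"n": 0}

    def stat(rows):
        calls["n"] += 1
        if calls["n"] % 15 == 0:
            raise InadmissibleSampleError("synthetic failure")
        return np.array([rows.mean()])

    reps, n_failed = bootstrap_statistic(x, stat, B=30, seed=1)
    assert len(reps) == 30
    assert n_failed == calls["n"] - 30 > 0


def test_bootstrap_aborts_on_degenerate_data():
    from gscaboot import InadmissibleSampleError

    def stat(rows):
        raise InadmissibleSampleError("always fails")

    with pytest.raises(InadmissibleSampleError, match="degenerate"):
        bootstrap_statistic(np.arange(10.0).reshape(-1, 1), stat, B=20, seed=0)
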