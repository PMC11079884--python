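import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidiff.overabundance import (
    DEFAULT_ALPHA_GRID,
    benjamini_hochberg,
    expected_counts,
    fdr_estimate,
    format_fdr,
    make_overabundance_curve,
    observed_counts,
    simulate_null_band,
)


def test_observed_counts_strict_inequality():
    assert observed_counts([1, 1, 1], [0.05]).tolist() == [0]
    assert observed_counts([0.01, 0.04, 0.2], [0.05]).tolist() == [2]
    assert observed_counts([0.05, 0.049], [0.05]).tolist() == [1]  # strict <
    with pytest.raises(ValueError):
        observed_counts([1.2], [0.05])


def test_expected_counts_uniform_null():
    assert expected_counts(168, [0.05])[0] == pytest.approx(8.4)
    assert expected_counts(100, [0.0])[0] == 0.0
    assert expected_counts(100, [1.0])[0] == 100.0


@pytest.mark.parametrize(
    "alpha,k,display",
    [
        (0.05, 18, "0.47"),
        (0.01, 6, "0.28"),
        (0.001, 2, "0.08"),
        (0.05, 17, "0.49"),
        (0.01, 6, "0.28"),
        (0.001, 4, "0.04"),
        (0.05, 9, "0.93"),
    ],
)
def test_fdr_estimates_at_reported_thresholds(alpha, k, display):
    """N*alpha/k reproduces the expected two-decimal displays for N=168."""
    value = fdr_estimate(168, alpha, k)
    assert value == pytest.approx(168 * alpha / k)
    assert format_fdr(value) == display


def test_fdr_boundary_and_no_discoveries():
    assert fdr_estimate(100, 0.2, 20) == 1.0  # k = N*alpha caps at 1
    assert fdr_estimate(100, 0.5, 10) == 1.0  # cap
    assert math.isnan(fdr_estimate(100, 0.05, 0))
    assert format_fdr(float("nan")) == "NA"
    with pytest.raises(ValueError):
        fdr_estimate(100, 1.5, 3)


def test_format_fdr_rounds_half_up():
    assert format_fdr(0.045) == "0.05"
    assert format_fdr(0.084) == "0.08"
    assert format_fdr(0.125) == "0.13"


@settings(derandomize=True, max_examples=50)
@given(st.integers(1, 500), st.floats(0.001, 0.999), st.integers(1, 500), st.integers(2, 5))
def test_fdr_monotone_and_homogeneous(n, alpha, k, c):
    """Strictly decreasing in k (below the cap); invariant to scaling N and k."""
    f1, f2 = fdr_estimate(n, alpha, k), fdr_estimate(n, alpha, k + 1)
    assert f2 <= f1
    if f1 < 1.0:
        assert f2 < f1
    assert fdr_estimate(c * n, alpha, c * k) == pytest.approx(fdr_estimate(n, alpha, k))


def test_null_band_matches_binomial_moments():
    """Mean/variance of simulated null counts agree with Binomial(N, alpha)."""
    n, alpha, reps = 168, 0.05, 2000
    rng = np.random.default_rng(123)
    u = rng.random((reps, n))
    counts = (u < alpha).sum(axis=1)
    mean_se = math.sqrt(n * alpha * (1 - alpha) / reps)
    assert counts.mean() == pytest.approx(n * alpha, abs=4 * mean_se)
    # the band itself must bracket the expectation and be reproducible
    lo, hi = simulate_null_band(n, [alpha], n_replicates=reps, seed=9)
    lo2, hi2 = simulate_null_band(n, [alpha], n_replicates=reps, seed=9)
    assert (lo == lo2).all() and (hi == hi2).all()
    assert lo[0] <= n * alpha <= hi[0]


def test_null_band_degenerate_cases():
    lo, hi = simulate_null_band(10, [0.5], n_replicates=1, seed=0)
    assert lo[0] == hi[0]  # single replicate: degenerate band
    lo, hi = simulate_null_band(10, [1.0], n_replicates=50, seed=0)
    assert lo[0] == hi[0] == 10  # every p < 1


def test_curve_uniform_pvalues_inside_envelope():
    """Seeded uniform p-values stay inside the 99% envelope nearly everywhere."""
    rng = np.random.default_rng(2024)
    inside = total = 0
    for _ in range(20):
        p = rng.random(168)
        res = make_overabundance_curve(p, n_null_replicates=500, seed=7)
        inside += int(((res.null_lo <= res.observed_k) & (res.observed_k <= res.null_hi)).sum())
        total += res.alphas.size
    assert inside / total >= 0.95


def test_curve_all_tiny_pvalues():
    res = make_overabundance_curve([1e-6] * 10, n_null_replicates=100, seed=0)
    assert (res.observed_k == 10).all()
    for a, f in zip(res.alphas, res.fdr_estimates):
        assert f <= min(1.0, 10 * a / 10) + 1e-12


def test_curve_planted_effects_escape_envelope():
    """Strong planted signal pushes the observed count above the null band."""
    rng = np.random.default_rng(5)
    p = np.concatenate([rng.random(148), np.full(20, 1e-4)])
    res = make_overabundance_curve(p, n_null_replicates=2000, seed=11)
    i05 = int(np.argmin(np.abs(res.alphas - 0.05)))
    assert res.observed_k[i05] > res.null_hi[i05]


def test_curve_defaults_and_fields():
    res = make_overabundance_curve(np.linspace(0.001, 0.999, 168), seed=1)
    assert res.n_compounds == 168
    assert set((0.001, 0.01, 0.05)) <= set(res.alphas.tolist())
    assert tuple(res.alphas.tolist()) == tuple(sorted(DEFAULT_ALPHA_GRID))
    assert np.all(np.diff(res.observed_k) >= 0)
    np.testing.assert_allclose(res.expected_k, 168 * res.alphas)


def test_benjamini_hochberg_reference():
    from scipy.stats import false_discovery_control

    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
    np.testing.assert_allclose(benjamini_hochberg(p), false_discovery_control(p))
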