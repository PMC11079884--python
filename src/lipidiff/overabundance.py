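"""Overabundance analysis of p-value collections with empirical FDR.

With N features tested at threshold alpha, a null experiment (no feature
truly differential, independent tests) yields p-values uniform on (0,1),
so the expected count of p < alpha is N*alpha. Overabundance analysis
compares the observed count k(alpha) against this expectation and against
a Monte-Carlo envelope of same-size null experiments; an observed curve
escaping the envelope indicates genuine signal despite the multiplicity
of tests.

The FDR estimate at a threshold is the expected number of null
discoveries over the number actually observed,

    FDR(alpha) = min(1, N * alpha / k),

reported rounded half-up to two decimals for display while the full
precision value is retained. With no discoveries (k = 0) the ratio is
undefined and flagged as NaN rather than given a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "OverabundanceResult",
    "DEFAULT_ALPHA_GRID",
    "observed_counts",
    "expected_counts",
    "fdr_estimate",
    "format_fdr",
    "simulate_null_band",
    "make_overabundance_curve",
    "benjamini_hochberg",
]

#: Default threshold grid; includes the conventional reporting points
#: 1e-3, 1e-2 and 0.05 plus a coarse log-spaced fill.
DEFAULT_ALPHA_GRID = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class OverabundanceResult:
    """Observed/expected discovery counts and FDR estimates over a grid."""

    n_compounds: int
    alphas: np.ndarray
    observed_k: np.ndarray
    expected_k: np.ndarray
    fdr_estimates: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    n_null_replicates: int
    seed: int

    def __post_init__(self):
        k = self.observed_k
        if np.any(np.diff(k) < 0):
            raise ValueError("observed counts must be non-decreasing in alpha")
        if np.any((k < 0) | (k > self.n_compounds)):
            raise ValueError("observed counts outside [0, N]")


def _validate_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def observed_counts(p_values, alphas) -> np.ndarray:
    """Count of p-values strictly below each threshold."""
    p = _validate_pvalues(p_values)
    alphas = np.asarray(alphas, dtype=float)
    return (p[None, :] < alphas[:, None]).sum(axis=1)


def expected_counts(n_compounds: int, alphas) -> np.ndarray:
    """Uniform-null expectation N*alpha per threshold."""
    if n_compounds < 1:
        raise ValueError("need at least one compound")
    return n_compounds * np.asarray(alphas, dtype=float)


def fdr_estimate(n_compounds: int, alpha: float, observed_k: int) -> float:
    """Expected-over-observed discoveries FDR, capped at 1.

    Returns NaN (the "no discoveries" flag) when ``observed_k`` is 0.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if observed_k < 0:
        raise ValueError("observed count cannot be negative")
    if observed_k == 0:
        return float("nan")
    return min(1.0, n_compounds * alpha / observed_k)


def format_fdr(value: float) -> str:
    """Two-decimal display rounding, half-up (0.4667 -> '0.47', 0.045 -> '0.05')."""
    value = float(value)
    if np.isnan(value):
        return "NA"
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def simulate_null_band(
    n_compounds: int,
    alphas,
    n_replicates: int = 2000,
    seed: int = 0,
    band: tuple[float, float] = (0.005, 0.995),
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo envelope of null discovery counts.

    Draws ``n_replicates`` experiments of ``n_compounds`` independent
    uniform(0,1) p-values and returns the per-threshold empirical
    ``band`` quantiles of the counts (default: central 99% envelope).
    Reproducible given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one null replicate")
    alphas = np.asarray(alphas, dtype=float)
    rng = np.random.default_rng(seed)
    # counts per replicate per alpha: Binomial(N, alpha) draws, but computed
    # from actual uniforms so the replicate curves are internally consistent
    u = rng.random((n_replicates, n_compounds))
    counts = (u[:, None, :] < alphas[None, :, None]).sum(axis=2)
    lo = np.quantile(counts, band[0], axis=0)
    hi = np.quantile(counts, band[1], axis=0)
    return lo, hi


def make_overabundance_curve(
    p_values,
    n_compounds: int | None = None,
    *,
    alphas=DEFAULT_ALPHA_GRID,
    n_null_replicates: int = 2000,
    seed: int = 0,
    band: tuple[float, float] = (0.005, 0.995),
) -> OverabundanceResult:
    """Assemble the full overabundance analysis for one comparison.

    Parameters
    ----------
    p_values:
        The per-feature p-values of one comparison.
    n_compounds:
        Number of features tested; defaults to ``len(p_values)``. The
        null model uses the same number of compounds as the tested set.
    """
    p = _validate_pvalues(p_values)
    n = int(n_compounds) if n_compounds is not None else p.size
    alphas = np.asarray(sorted(alphas), dtype=float)
    obs = observed_counts(p, alphas)
    exp = expected_counts(n, alphas)
    fdr = np.array(
        [
            fdr_estimate(n, a, k) if 0 < a < 1 else (np.nan if k == 0 else min(1.0, n * a / k))
            for a, k in zip(alphas, obs)
        ]
    )
    lo, hi = simulate_null_band(n, alphas, n_null_replicates, seed, band)
    return OverabundanceResult(
        n_compounds=n,
        alphas=alphas,
        observed_k=obs,
        expected_k=exp,
        fdr_estimates=fdr,
        null_lo=lo,
        null_hi=hi,
        n_null_replicates=n_null_replicates,
        seed=seed,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (optional extra, not the primary path).

    The primary multiplicity handling here is the overabundance FDR
    estimate above; BH q-values are offered as an extra, clearly
    separate column for users who want the standard procedure.
    """
    p = _validate_pvalues(p_values)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
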