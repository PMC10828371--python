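"""Power analysis for the difference-in-slope score test.

For a one-breakpoint segmented model with a standard-normal covariate, the
pseudo-score statistic for a slope change ``d`` at breakpoint ``psi`` is
asymptotically normal with unit variance and noncentrality

    ncp = sqrt(n) * d / sigma * Cov_r(u_psi, w) / sd_r(w),

where u_a = (X - a)_+ is the working covariate at breakpoint a, ``w`` is
the covariate the test actually uses, and Cov_r / sd_r denote covariance
and standard deviation after projecting out the intercept and linear term.
With the test evaluated at the true breakpoint (w = u_psi) this reduces to
ncp = sqrt(n) * d / sigma * sd_r(u_psi).  All first and second moments of
(X - a)_+ under the standard normal have closed forms in the normal pdf and
cdf, so power and its inverse (the minimal detectable slope difference) are
analytic.

Two-sided power at level alpha:  Phi(-z_{a/2} + |ncp|) + Phi(-z_{a/2} - |ncp|),
which equals alpha exactly at d = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "PowerSpec",
    "segmented_power",
    "min_detectable_slope_diff",
    "select_replication_subset",
    "simulated_power",
]


@dataclass
class PowerSpec:
    """Replication power scenario.

    ``n`` is the per-group analysis sample size; ``sigma`` the response
    (health-instrument) standard deviation; ``psi_std`` the breakpoint on
    the standardized covariate scale; ``slope_diff`` the difference in
    slopes on the same scale.  The covariate is assumed standard normal.
    """

    n: int
    sigma: float
    psi_std: float
    slope_diff: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _m1(a: float) -> float:
    """E[(X - a)_+] for X ~ N(0, 1)."""
    return float(norm.pdf(a) - a * norm.sf(a))


def _mx(a: float) -> float:
    """E[X (X - a)_+] = 1 - Phi(a)."""
    return float(norm.sf(a))


def _m2(a: float, b: float) -> float:
    """E[(X - a)_+ (X - b)_+]."""
    a, b = min(a, b), max(a, b)
    return float((1.0 + a * b) * norm.sf(b) - a * norm.pdf(b))


def _cov_r(a: float, b: float) -> float:
    """Cov of (X-a)_+ and (X-b)_+ after partialling out 1 and X."""
    return _m2(a, b) - _m1(a) * _m1(b) - _mx(a) * _mx(b)


def _noncentrality(n: int, slope_diff: float, sigma: float, psi: float,
                   k_eval: int | None) -> float:
    if k_eval is None:
        var_r = _cov_r(psi, psi)
        return np.sqrt(n) * slope_diff / sigma * np.sqrt(max(var_r, 0.0))
    levels = np.arange(1, k_eval + 1) / (k_eval + 1)
    pts = norm.ppf(levels)
    cov = np.mean([_cov_r(psi, p) for p in pts])
    var = np.mean([[_cov_r(p, q) for q in pts] for p in pts])
    return np.sqrt(n) * slope_diff / sigma * cov / np.sqrt(max(var, 1e-300))


def segmented_power(spec: PowerSpec, k_eval: int | None = None) -> float:
    """Rejection probability of the two-sided slope-change score test.

    With ``k_eval=None`` (default) the test is assumed evaluated at the
    true breakpoint (the classical score-statistic approximation); with an
    integer ``k_eval`` the noncentrality matches a test that averages
    working covariates over that many fixed interior normal quantiles,
    mirroring :func:`sweetspot.segmented.score_test_slope_change`.
    """
    ncp = _noncentrality(spec.n, spec.slope_diff, spec.sigma, spec.psi_std,
                         k_eval)
    z = norm.isf(spec.alpha / 2.0)
    return float(norm.cdf(-z + abs(ncp)) + norm.cdf(-z - abs(ncp)))


def min_detectable_slope_diff(n: int, sigma: float, psi_std: float,
                              alpha: float = 0.05,
                              target_power: float = 0.8,
                              k_eval: int | None = None,
                              tol: float = 1e-5) -> float:
    """Smallest slope difference reaching ``target_power`` at level alpha.

    Root-finds ``segmented_power(delta) = target_power``; power is strictly
    increasing in the slope difference so the root is unique.
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")

    def gap(d: float) -> float:
        return segmented_power(
            PowerSpec(n=n, sigma=sigma, psi_std=psi_std, slope_diff=d,
                      alpha=alpha), k_eval) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no root: power never reaches target")
    return float(brentq(gap, 0.0, hi, xtol=tol))


def select_replication_subset(primary_fits: pd.DataFrame, n_replication: int,
                              sigma: float, psi_std: float,
                              alpha: float = 0.05,
                              target_power: float = 0.8,
                              phenotype_sd: dict[str, float] | None = None,
                              k_eval: int | None = None,
                              ) -> tuple[list[str], float]:
    """Phenotypes whose primary slope difference is detectable on replication.

    For each phenotype the largest absolute slope difference across
    instruments and sexes (standardized by the phenotype's sample standard
    deviation when ``phenotype_sd`` is given) is compared with the minimal
    detectable slope difference at the replication sample size.  Returns
    ``(selected phenotypes, threshold)``.
    """
    threshold = min_detectable_slope_diff(
        n_replication, sigma, psi_std, alpha, target_power, k_eval)
    if primary_fits.empty:
        return [], threshold
    selected = []
    for phen, grp in primary_fits.groupby("phenotype", sort=False):
        deltas = grp["delta"].abs()
        if phenotype_sd is not None:
            deltas = deltas * phenotype_sd.get(phen, 1.0)
        if deltas.max() > threshold:
            selected.append(phen)
    return selected, threshold


def simulated_power(n: int, slope_diff: float, sigma: float, psi_std: float,
                    alpha: float = 0.05, n_sims: int = 2000,
                    k_eval: int = 10,
                    rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo rejection rate of the actual pseudo-score test.

    Draws a standard-normal covariate and a segmented mean response with
    slope difference ``slope_diff`` at ``psi_std``, then applies
    :func:`sweetspot.segmented.score_test_slope_change`.  Used to validate
    the analytic power approximation.
    """
    from .segmented import score_test_slope_change

    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        y = slope_diff * np.clip(x - psi_std, 0.0, None) \
            + rng.normal(0.0, sigma, n)
        if score_test_slope_change(x, y, k_eval=k_eval) < alpha:
            hits += 1
    return hits / n_sims
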