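"""One-breakpoint segmented regression and sweet-spot classification.

The model for an age-residualized health-deficit score y against a
phenotype x is a broken line

    y = b0 + b1 * x + d * (x - psi)_+ + e,

with left slope ``b1``, slope difference ``d`` (right slope = b1 + d) and
an unknown breakpoint ``psi``.  The breakpoint is estimated by iterative
linearization: at a working value psi_t the model is expanded with the
working covariates (x - psi_t)_+ and the negative gap indicator
-1{x > psi_t}; the coefficient ``g`` of the gap term measures the
first-order mismatch and drives the update psi_{t+1} = psi_t + g / d.  At a
fixed point g = 0.  A quantile grid search (exact OLS at each candidate
breakpoint) backs up the iteration and guarantees the reported fit is never
worse than the best grid solution.

A breakpoint qualifies as a *sweet spot* when (1) the two slopes have
opposite signs, (2) both slope 95% confidence intervals exclude zero, and
(3) the slope difference is significant by a two-sided pseudo-score test
after Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "SegmentedFit",
    "residualize_age",
    "residualize",
    "fit_segmented",
    "score_test_slope_change",
    "classify_relationship",
    "scan_bonferroni_denominator",
    "sweet_spot_scan",
    "adjustment_concordance",
]

RELATIONSHIP_SWEET_SPOT = "nonmonotonic_sweet_spot"
RELATIONSHIP_NONSIG = "nonmonotonic_nonsignificant"


@dataclass
class SegmentedFit:
    """Parameters of a fitted one-breakpoint model.

    Slope standard errors and confidence intervals condition on the
    estimated breakpoint; the breakpoint's own standard error comes from
    the delta method on the gap coefficient, se(psi) = se(g) / |d|.
    """

    beta0: float
    beta1: float                  # left slope
    delta: float                  # difference in slope (right - left)
    psi: float                    # breakpoint
    se_beta1: float
    se_right: float               # se of beta1 + delta
    se_psi: float
    ci_beta1: tuple[float, float]
    ci_right: tuple[float, float]
    ci_psi: tuple[float, float]
    n: int
    sse: float
    sse_line: float               # straight-line benchmark
    converged: bool               # iterative scheme reached |g| < tol
    iterations: int
    method: str                   # "iterative" or "grid"

    @property
    def right_slope(self) -> float:
        return self.beta1 + self.delta


def residualize(y, design: np.ndarray) -> np.ndarray:
    """OLS residuals of y on a design matrix, NaN-propagating.

    Rows with a missing response or any missing design entry get missing
    residuals; the fit uses complete rows only.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    mask = np.isfinite(y) & np.isfinite(design).all(axis=1)
    if mask.sum() < design.shape[1] + 1:
        raise ValueError("too few complete rows to residualize")
    beta, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
    out = np.full(y.shape, np.nan)
    out[mask] = y[mask] - design[mask] @ beta
    return out


def residualize_age(scores, age) -> np.ndarray:
    """Residuals of instrument scores after a linear regression on age."""
    age = np.asarray(age, dtype=float)
    mask = np.isfinite(age) & np.isfinite(np.asarray(scores, dtype=float))
    if mask.any() and np.ptp(age[mask]) == 0:
        raise ValueError("age is constant: degenerate design")
    design = np.column_stack([np.ones_like(age), age])
    return residualize(scores, design)


def _ols_segmented(x: np.ndarray, y: np.ndarray, psi: float,
                   with_gap: bool):
    """OLS at a fixed breakpoint; returns (coef, sse, XtX_inv, sigma2)."""
    u = np.clip(x - psi, 0.0, None)
    cols = [np.ones_like(x), x, u]
    if with_gap:
        cols.append(-(x > psi).astype(float))
    design = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    dof = len(x) - 4  # intercept, two slopes, breakpoint
    sigma2 = sse / max(dof, 1)
    try:
        xtx_inv = np.linalg.inv(design.T @ design)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(design.T @ design)
    return coef, sse, xtx_inv, sigma2


def _grid_fit(x: np.ndarray, y: np.ndarray,
              interior: tuple[float, float],
              n_grid: int = 501) -> tuple[float, float]:
    """Best breakpoint among x-quantile candidates by exact OLS SSE."""
    candidates = np.unique(
        np.quantile(x, np.linspace(interior[0], interior[1], n_grid)))
    if candidates.size == 0:
        candidates = np.array([np.median(x)])
    best_psi, best_sse = candidates[0], np.inf
    ones = np.ones_like(x)
    for psi in candidates:
        u = np.clip(x - psi, 0.0, None)
        design = np.column_stack([ones, x, u])
        g = design.T @ design
        b = design.T @ y
        try:
            coef = np.linalg.solve(g, b)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        if sse < best_sse - 1e-12:
            best_sse, best_psi = sse, float(psi)
    return best_psi, best_sse


def _iterate(x: np.ndarray, y: np.ndarray, psi0: float, lo: float, hi: float,
             tol: float, max_iter: int) -> tuple[float, bool, int]:
    psi = float(np.clip(psi0, lo, hi))
    for it in range(1, max_iter + 1):
        coef, _, _, _ = _ols_segmented(x, y, psi, with_gap=True)
        delta, gamma = coef[2], coef[3]
        if abs(gamma) < tol:
            return psi, True, it
        if delta == 0 or not np.isfinite(delta) or not np.isfinite(gamma):
            return psi, False, it
        psi_new = float(np.clip(psi + gamma / delta, lo, hi))
        if psi_new == psi:
            # stuck on the constraint boundary with a non-zero gap
            return psi, False, it
        psi = psi_new
    return psi, False, max_iter


def fit_segmented(x, y, *, tol: float = 1e-8, max_iter: int = 50,
                  interior: tuple[float, float] = (0.02, 0.98),
                  n_grid: int = 501, alpha: float = 0.05,
                  min_n: int = 20) -> SegmentedFit:
    """Fit the one-breakpoint model y = b0 + b1*x + d*(x - psi)_+ + e.

    The iterative linearization starts from the median of x with restarts
    from alternative quantiles, with the breakpoint constrained to the
    interior quantile range of x.  A quantile grid search (exact OLS at
    each of ``n_grid`` candidate breakpoints) always runs as a safety net;
    if it beats the iterative solution the grid answer is reported and the
    fit is flagged as non-converged for the iterative scheme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < min_n:
        raise ValueError(f"fit_segmented: need >= {min_n} complete pairs, "
                         f"got {n}")
    if np.ptp(x) == 0:
        raise ValueError("fit_segmented: x is constant")
    lo, hi = np.quantile(x, interior)
    if lo == hi:
        raise ValueError("fit_segmented: interior quantile range of x is "
                         "degenerate")

    # straight-line benchmark
    line_design = np.column_stack([np.ones_like(x), x])
    line_coef, *_ = np.linalg.lstsq(line_design, y, rcond=None)
    line_resid = y - line_design @ line_coef
    sse_line = float(line_resid @ line_resid)

    starts = [float(np.median(x))] + list(
        np.quantile(x, [0.1, 0.3, 0.7, 0.9, 0.5]))
    best = None  # (sse, psi, converged, iterations)
    total_iter = 0
    for psi0 in starts:
        psi, ok, its = _iterate(x, y, psi0, lo, hi, tol, max_iter)
        total_iter += its
        _, sse, _, _ = _ols_segmented(x, y, psi, with_gap=False)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, psi, ok, its)
        if ok:
            break
    sse_it, psi_it, converged, _ = best

    psi_grid, sse_grid = _grid_fit(x, y, interior, n_grid)
    if converged and sse_it <= sse_grid + 1e-9:
        psi_hat, method = psi_it, "iterative"
    else:
        if sse_grid < sse_it - 1e-9:
            psi_hat, method, converged = psi_grid, "grid", False
        else:
            psi_hat, method = psi_it, ("iterative" if converged else "grid")

    coef3, sse, xtx_inv3, sigma2 = _ols_segmented(x, y, psi_hat,
                                                  with_gap=False)
    beta0, beta1, delta = (float(c) for c in coef3)
    se_beta1 = float(np.sqrt(sigma2 * xtx_inv3[1, 1]))
    var_right = sigma2 * (xtx_inv3[1, 1] + xtx_inv3[2, 2]
                          + 2.0 * xtx_inv3[1, 2])
    se_right = float(np.sqrt(max(var_right, 0.0)))

    coef4, _, xtx_inv4, sigma2_4 = _ols_segmented(x, y, psi_hat,
                                                  with_gap=True)
    se_gamma = float(np.sqrt(max(sigma2_4 * xtx_inv4[3, 3], 0.0)))
    delta4 = float(coef4[2])
    se_psi = se_gamma / abs(delta4) if delta4 != 0 else float("inf")

    tq = float(t_dist.ppf(1 - alpha / 2, max(n - 4, 1)))
    right = beta1 + delta
    fit = SegmentedFit(
        beta0=beta0, beta1=beta1, delta=delta, psi=float(psi_hat),
        se_beta1=se_beta1, se_right=se_right, se_psi=se_psi,
        ci_beta1=(beta1 - tq * se_beta1, beta1 + tq * se_beta1),
        ci_right=(right - tq * se_right, right + tq * se_right),
        ci_psi=(psi_hat - tq * se_psi, psi_hat + tq * se_psi),
        n=n, sse=float(min(sse, sse_line)), sse_line=sse_line,
        converged=bool(converged), iterations=total_iter, method=method)
    return fit


def score_test_slope_change(x, y, k_eval: int = 10) -> float:
    """Two-sided pseudo-score test of no change in slope.

    Under H0 the relationship is a straight line.  The test augments the
    straight-line model with the mean of the working covariates
    (x - psi_k)_+ over ``k_eval`` fixed candidate breakpoints placed at
    equally spaced interior quantiles of x, and refers the studentized
    coefficient of that covariate to t with n - 3 degrees of freedom.
    Because the candidate breakpoints depend on x only, the null
    distribution is exact for Gaussian errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 20:
        raise ValueError("score_test_slope_change: need >= 20 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("score_test_slope_change: x is constant")
    levels = np.arange(1, k_eval + 1) / (k_eval + 1)
    psis = np.quantile(x, levels)
    w = np.clip(x[:, None] - psis[None, :], 0.0, None).mean(axis=1)
    design = np.column_stack([np.ones_like(x), x, w])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    dof = n - 3
    sigma2 = sse / dof
    try:
        xtx_inv = np.linalg.inv(design.T @ design)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(design.T @ design)
    se_w = np.sqrt(max(sigma2 * xtx_inv[2, 2], 0.0))
    if se_w == 0:
        return 1.0
    t_stat = coef[2] / se_w
    return float(2.0 * t_dist.sf(abs(t_stat), dof))


def _ci_excludes_zero(ci: tuple[float, float]) -> bool:
    lo, hi = ci
    return (lo > 0) or (hi < 0)


def classify_relationship(fit: SegmentedFit | None, p_bonferroni: float,
                          alpha: float = 0.05,
                          line_slope_ci: tuple[float, float] | None = None,
                          ) -> dict:
    """Classify a fitted phenotype-instrument relationship.

    Sweet spot: opposite-sign slopes, both slope CIs excluding zero, and a
    Bonferroni-adjusted score-test p below ``alpha``.  Same-sign slopes
    with both CIs excluding zero give a monotone class; an opposite-sign
    shape failing the criteria is nonmonotonic but non-significant;
    anything else is flat.  When no segmented fit is available
    (``fit is None``) the straight-line slope CI decides between monotone
    and flat.
    """
    if fit is None:
        if line_slope_ci is not None and _ci_excludes_zero(line_slope_ci):
            rel = "increasing" if line_slope_ci[0] > 0 else "decreasing"
        else:
            rel = "flat"
        return {"relationship": rel, "psi": np.nan,
                "psi_lo": np.nan, "psi_hi": np.nan}
    left, right = fit.beta1, fit.right_slope
    left_sig = _ci_excludes_zero(fit.ci_beta1)
    right_sig = _ci_excludes_zero(fit.ci_right)
    opposite = left * right < 0
    if opposite and left_sig and right_sig and p_bonferroni < alpha:
        rel = RELATIONSHIP_SWEET_SPOT
        return {"relationship": rel, "psi": fit.psi,
                "psi_lo": fit.ci_psi[0], "psi_hi": fit.ci_psi[1]}
    if left_sig and right_sig and not opposite:
        rel = "increasing" if left > 0 else "decreasing"
    elif opposite:
        rel = RELATIONSHIP_NONSIG
    else:
        rel = "flat"
    return {"relationship": rel, "psi": np.nan,
            "psi_lo": np.nan, "psi_hi": np.nan}


def scan_bonferroni_denominator(n_phenotypes: int, n_sexes: int = 2,
                                n_instruments: int = 5) -> int:
    """Fixed-product multiple-testing denominator for the sweet-spot scan
    (#selected measures x #sexes x #instruments)."""
    return n_phenotypes * n_sexes * n_instruments


def _covariate_design(sub: pd.DataFrame, covariates: list[str] | None,
                      ) -> np.ndarray:
    cols = [np.ones(len(sub)), sub["age"].to_numpy(dtype=float)]
    if covariates:
        for cov in covariates:
            series = sub[cov]
            if series.dtype == object or isinstance(
                    series.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(series, drop_first=True,
                                         dtype=float)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy())
            else:
                cols.append(series.to_numpy(dtype=float))
    return np.column_stack(cols)


def sweet_spot_scan(cohort: pd.DataFrame, scores: pd.DataFrame,
                    phenotypes: list[str],
                    instruments: tuple[str, ...] = ("I", "II", "III",
                                                    "IV", "V"),
                    covariates: list[str] | None = None,
                    row_filter: str | None = None,
                    alpha: float = 0.05, k_eval: int = 10,
                    min_n: int = 20,
                    m_tests: int | None = None) -> pd.DataFrame:
    """Sweet-spot scan over sex x instrument x phenotype.

    Per sex, each instrument score is residualized on age (and on the
    one-hot coded covariate design when ``covariates`` is given, reference
    level = first category), then regressed on each selected phenotype with
    the one-breakpoint model; the slope change is tested with the
    pseudo-score test and Bonferroni-corrected with the fixed denominator
    #phenotypes x #sexes x #instruments.  ``row_filter`` accepts a pandas
    query expression for sensitivity re-runs (e.g. excluding medicated
    participants).  An empty phenotype list returns an empty table.
    """
    if not phenotypes:
        return pd.DataFrame(columns=_SCAN_COLUMNS)
    df = cohort.merge(scores, on="participant_id", how="inner")
    if row_filter:
        df = df.query(row_filter)
    m = (m_tests if m_tests is not None
         else scan_bonferroni_denominator(len(phenotypes), 2,
                                          len(instruments)))
    rows = []
    for sex in ("F", "M"):
        sub = df[df["sex"] == sex]
        if not len(sub):
            continue
        design = _covariate_design(sub, covariates)
        for inst in instruments:
            score = sub[f"score_{inst}"].to_numpy(dtype=float)
            try:
                resid = residualize(score, design)
            except ValueError:
                continue
            for phen in phenotypes:
                x = sub[phen].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(resid)
                row = {"phenotype": phen, "instrument": inst, "sex": sex,
                       "n": int(ok.sum()), "m_tests": m}
                if ok.sum() < min_n:
                    row.update({"relationship": "insufficient_data",
                                "psi": np.nan, "psi_lo": np.nan,
                                "psi_hi": np.nan, "beta1": np.nan,
                                "right_slope": np.nan, "delta": np.nan,
                                "p_score_raw": np.nan,
                                "p_score_bonferroni": np.nan,
                                "converged": False, "method": "none"})
                    rows.append(row)
                    continue
                try:
                    fit = fit_segmented(x[ok], resid[ok], alpha=alpha,
                                        min_n=min_n)
                except ValueError:
                    fit = None
                p_raw = (score_test_slope_change(x[ok], resid[ok], k_eval)
                         if fit is not None else np.nan)
                p_bonf = (min(1.0, p_raw * m) if np.isfinite(p_raw)
                          else np.nan)
                cls = classify_relationship(fit, p_bonf, alpha)
                row.update(cls)
                row.update({
                    "beta1": fit.beta1 if fit else np.nan,
                    "right_slope": fit.right_slope if fit else np.nan,
                    "delta": fit.delta if fit else np.nan,
                    "p_score_raw": p_raw, "p_score_bonferroni": p_bonf,
                    "converged": fit.converged if fit else False,
                    "method": fit.method if fit else "none"})
                rows.append(row)
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


_SCAN_COLUMNS = ["phenotype", "instrument", "sex", "relationship", "psi",
                 "psi_lo", "psi_hi", "beta1", "right_slope", "delta",
                 "p_score_raw", "p_score_bonferroni", "n", "converged",
                 "method", "m_tests"]


def adjustment_concordance(unadjusted: pd.DataFrame,
                           adjusted: pd.DataFrame) -> float:
    """Squared Pearson correlation between breakpoint estimates of two runs.

    Compares sweet-spot breakpoints over (phenotype, instrument, sex)
    combinations classified as sweet spots in *both* scans — the summary
    used to judge how resistant optima are to covariate adjustment.
    Returns NaN with fewer than two common sweet spots.
    """
    keys = ["phenotype", "instrument", "sex"]
    a = unadjusted[unadjusted["relationship"] == RELATIONSHIP_SWEET_SPOT]
    b = adjusted[adjusted["relationship"] == RELATIONSHIP_SWEET_SPOT]
    merged = a.merge(b, on=keys, suffixes=("_unadj", "_adj"))
    if len(merged) < 2:
        return float("nan")
    r = np.corrcoef(merged["psi_unadj"], merged["psi_adj"])[0, 1]
    return float(r ** 2)


def plot_fit(x, y, fit: SegmentedFit, ax=None):
    """Simple diagnostic plot of data and the fitted broken line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    ax.plot(x[ok], y[ok], ".", alpha=0.2, ms=2)
    xs = np.linspace(np.nanmin(x), np.nanmax(x), 200)
    ys = fit.beta0 + fit.beta1 * xs + fit.delta * np.clip(xs - fit.psi,
                                                          0, None)
    ax.plot(xs, ys, "r-", lw=1.5)
    ax.axvline(fit.psi, color="r", ls="--", lw=0.8)
    ax.set_xlabel("phenotype")
    ax.set_ylabel("residualized deficit score")
    return ax
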