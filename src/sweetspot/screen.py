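"""Variance-heterogeneity screen for health-related phenotypes.

Phenotypes likely to be under homeostatic control show lower variance in
healthier people.  The screen pre-filters the phenotype panel (missingness
and pairwise correlation), then compares each phenotype's variance between
the healthiest and least-healthy instrument groups with the Brown-Forsythe
test, separately per instrument, sex and age stratum, under a fixed-product
Bonferroni correction.  A phenotype is selected as health-related when at
least one comparison is significant after correction *and* the healthiest
group has the lower variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .instruments import INSTRUMENTS, LEVEL_HEALTHIEST, LEVEL_LEAST_HEALTHY

__all__ = [
    "AGE_STRATA",
    "AgeStratum",
    "prefilter_phenotypes",
    "brown_forsythe",
    "bonferroni_denominator",
    "run_screen",
    "select_health_related",
]


@dataclass(frozen=True)
class AgeStratum:
    label: str
    lo: float  # inclusive
    hi: float  # exclusive


AGE_STRATA = (
    AgeStratum("<55", 45.0, 55.0),
    AgeStratum("55-64", 55.0, 65.0),
    AgeStratum("65-74", 65.0, 75.0),
    AgeStratum(">=75", 75.0, np.inf),
)

SEXES = ("F", "M")


def prefilter_phenotypes(cohort: pd.DataFrame, phenotypes: list[str],
                         r_max: float = 0.9, miss_max: float = 0.24,
                         exempt: tuple[str, ...] = (),
                         ) -> tuple[list[str], pd.DataFrame]:
    """Drop phenotypes by missingness, then prune correlated pairs.

    A phenotype with missingness above ``miss_max`` is dropped unless
    listed in ``exempt`` (e.g. scarce inflammatory biomarkers retained for
    their known relevance).  Among surviving phenotypes, for every pair with
    pairwise-complete Pearson ``|r| > r_max`` the later column in input
    order is dropped.

    Returns the kept list and a log frame with one row per drop
    (``phenotype``, ``reason``, ``value``).
    """
    missing = [p for p in phenotypes if p not in cohort.columns]
    if missing:
        raise KeyError(f"phenotypes not in cohort table: {missing}")
    drops: list[tuple[str, str, float]] = []
    kept: list[str] = []
    for p in phenotypes:
        frac = float(cohort[p].isna().mean())
        if frac > miss_max and p not in exempt:
            drops.append((p, "missingness", frac))
        else:
            kept.append(p)
    if kept:
        corr = cohort[kept].corr(method="pearson")  # pairwise complete
        dropped: set[str] = set()
        final: list[str] = []
        for i, p in enumerate(kept):
            if p in dropped:
                continue
            final.append(p)
            for q in kept[i + 1:]:
                if q in dropped:
                    continue
                r = corr.loc[p, q]
                if np.isfinite(r) and abs(r) > r_max:
                    dropped.add(q)
                    drops.append((q, "correlation", float(r)))
        kept = final
    log = pd.DataFrame(drops, columns=["phenotype", "reason", "value"])
    return kept, log


def brown_forsythe(group_a, group_b) -> tuple[float, float]:
    """Two-group Brown-Forsythe test of variance homogeneity.

    Levene's test with median centering: z_ij = |x_ij - median_j|, then the
    one-way ANOVA F statistic on the z values, referred to F(1, N - 2).
    Median centering keeps the test honest for skewed data and unequal
    group sizes.  Degenerate all-equal spreads give (W, p) = (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("brown_forsythe: each group needs >= 2 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    na, nb = len(za), len(zb)
    n_tot = na + nb
    mean_a, mean_b = za.mean(), zb.mean()
    grand = (za.sum() + zb.sum()) / n_tot
    num = na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2
    den = ((za - mean_a) ** 2).sum() + ((zb - mean_b) ** 2).sum()
    if den <= 0:
        if num <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    w = (n_tot - 2) * num / den
    p = float(f_dist.sf(w, 1, n_tot - 2))
    return float(w), p


def bonferroni_denominator(n_phenotypes: int, n_instruments: int = 5,
                           n_sexes: int = 2, n_strata: int = 4) -> int:
    """Fixed-product multiple-testing denominator for the variance screen.

    The planned product (#measures x #instruments x #sexes x #age strata)
    is used even when individual strata are skipped for small group sizes,
    so the correction is conservative and auditable.
    """
    return n_phenotypes * n_instruments * n_sexes * n_strata


def run_screen(cohort: pd.DataFrame, scores: pd.DataFrame,
               phenotypes: list[str], alpha: float = 0.05,
               min_group_size: int = 30,
               instruments: tuple[str, ...] = INSTRUMENTS,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Brown-Forsythe screen over phenotype x instrument x sex x age stratum.

    For each combination, participants are restricted to complete cases
    (non-missing phenotype and non-missing instrument score — the score is
    already missing when too many of its components are), split into the
    healthiest and least-healthy levels, and tested; combinations where
    either group has fewer than ``min_group_size`` members are skipped but
    still counted in the Bonferroni denominator.

    Returns ``(records, skipped)``: one row per performed test with the raw
    and Bonferroni-adjusted p-value and the variance direction, and a log
    of skipped combinations with reasons.
    """
    missing = [p for p in phenotypes if p not in cohort.columns]
    if missing:
        raise KeyError(f"phenotypes not in cohort table: {missing}")
    df = cohort.merge(scores, on="participant_id", how="inner")
    m = bonferroni_denominator(len(phenotypes), len(instruments),
                               len(SEXES), len(AGE_STRATA))
    recs, skipped = [], []
    for phen in phenotypes:
        for inst in instruments:
            lvl = df[f"level_{inst}"]
            sc = df[f"score_{inst}"]
            for sex in SEXES:
                for stratum in AGE_STRATA:
                    sel = ((df["sex"] == sex)
                           & (df["age"] >= stratum.lo)
                           & (df["age"] < stratum.hi)
                           & df[phen].notna() & sc.notna())
                    x_h = df.loc[sel & (lvl == LEVEL_HEALTHIEST), phen]
                    x_l = df.loc[sel & (lvl == LEVEL_LEAST_HEALTHY), phen]
                    if len(x_h) < min_group_size or len(x_l) < min_group_size:
                        skipped.append({
                            "phenotype": phen, "instrument": inst,
                            "sex": sex, "stratum": stratum.label,
                            "n_healthiest": len(x_h), "n_least": len(x_l),
                            "reason": f"group below {min_group_size}"})
                        continue
                    var_h = float(x_h.var(ddof=1))
                    var_l = float(x_l.var(ddof=1))
                    w, p_raw = brown_forsythe(x_h, x_l)
                    recs.append({
                        "phenotype": phen, "instrument": inst, "sex": sex,
                        "stratum": stratum.label,
                        "n_healthiest": len(x_h), "n_least": len(x_l),
                        "var_healthiest": var_h, "var_least": var_l,
                        "W": w, "p_raw": p_raw,
                        "p_bonferroni": min(1.0, p_raw * m),
                        "healthiest_lower": var_h < var_l,
                        "m_tests": m})
    columns = ["phenotype", "instrument", "sex", "stratum", "n_healthiest",
               "n_least", "var_healthiest", "var_least", "W", "p_raw",
               "p_bonferroni", "healthiest_lower", "m_tests"]
    records = pd.DataFrame(recs, columns=columns)
    skipped_df = pd.DataFrame(
        skipped, columns=["phenotype", "instrument", "sex", "stratum",
                          "n_healthiest", "n_least", "reason"])
    return records, skipped_df


def select_health_related(records: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-phenotype selection summary from screen records.

    A phenotype is selected when at least one of its records is significant
    after Bonferroni correction with the healthiest group showing the lower
    variance.  The summary reports the minimum adjusted p across all of the
    phenotype's records (at most #instruments x #sexes x #strata of them).
    """
    rows = []
    for phen, grp in records.groupby("phenotype", sort=False):
        hit = grp[(grp["p_bonferroni"] < alpha) & grp["healthiest_lower"]]
        rows.append({
            "phenotype": phen,
            "n_tests": len(grp),
            "n_significant_lower": len(hit),
            "min_p_bonferroni": float(grp["p_bonferroni"].min())
            if len(grp) else np.nan,
            "selected": bool(len(hit)),
        })
    return pd.DataFrame(
        rows, columns=["phenotype", "n_tests", "n_significant_lower",
                       "min_p_bonferroni", "selected"])
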