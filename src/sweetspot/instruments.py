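"""Health-deficit instruments on the unit interval.

Five instruments summarise a participant's health, all oriented so that
*higher = less healthy*:

I.   Frailty index — normalised sum of binary/graded health deficits.
II.  Five-disease count — cancer, cardiovascular disease, major pulmonary
     disease, dementia, diabetes; medication or treatment for a disease
     confirms its status.
III. Other chronic-condition count — clinician-diagnosed conditions not
     used for instrument II.
IV.  Composite cognitive score — mean of cognitive-domain means of
     rank-normalised test scores (risk direction harmonised first).
V.   Physical-function composite — mean of rank-normalised physical test
     scores.

Continuous instruments (I, III, IV, V) are cut at pooled cohort quartiles
into four ordinal health levels (1 = healthiest ... 4 = least healthy); the
five-disease instrument uses the categorical rule 0 diseases = healthiest,
>= 2 = least healthy, exactly 1 = intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

__all__ = [
    "TestSpec",
    "InstrumentMetadata",
    "QuartileCutoffs",
    "invert_risk_direction",
    "rank_normalize",
    "frailty_index",
    "disease_instrument",
    "composite_instrument",
    "quartile_cutoffs",
    "assign_health_levels",
    "compute_instruments",
]

INSTRUMENTS = ("I", "II", "III", "IV", "V")

LEVEL_HEALTHIEST = 1
LEVEL_GOOD = 2
LEVEL_FAIR = 3
LEVEL_LEAST_HEALTHY = 4

_DIRECTIONS = ("risk_increases", "risk_decreases")


@dataclass(frozen=True)
class TestSpec:
    column: str
    direction: str
    domain: str = "default"

    __test__ = False  # an assessment test, not a pytest case

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"test {self.column!r}: unknown direction {self.direction!r} "
                f"(expected one of {_DIRECTIONS})")


@dataclass
class InstrumentMetadata:
    """Column-role metadata binding a cohort table to the five instruments."""

    deficit_columns: list[str]
    disease_pairs: list[tuple[str, str | None]]
    chronic_columns: list[str]
    cognitive_tests: list[TestSpec]
    physical_tests: list[TestSpec]
    min_deficit_fraction: float = 0.8

    def __post_init__(self):
        if len(self.disease_pairs) != 5:
            raise ValueError("the five-disease instrument needs exactly 5 "
                             "disease/medication pairs")
        if not 0 < self.min_deficit_fraction <= 1:
            raise ValueError("min_deficit_fraction must be in (0, 1]")

    @classmethod
    def for_synthetic_cohort(cls, n_deficits: int = 51,
                             n_chronic: int = 28) -> "InstrumentMetadata":
        from . import simulate as sim
        return cls(
            deficit_columns=[f"deficit_{j:02d}" for j in
                             range(1, n_deficits + 1)],
            disease_pairs=list(sim.DISEASE_MED_PAIRS),
            chronic_columns=[f"chronic_{j:02d}" for j in
                             range(1, n_chronic + 1)],
            cognitive_tests=[TestSpec(c, d, domain=dom)
                             for c, dom, d in sim.COGNITIVE_TESTS],
            physical_tests=[TestSpec(c, d) for c, d in sim.PHYSICAL_TESTS],
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "deficit_columns": self.deficit_columns,
            "disease_pairs": [[d, m] for d, m in self.disease_pairs],
            "chronic_columns": self.chronic_columns,
            "cognitive_tests": [
                {"column": t.column, "domain": t.domain,
                 "direction": t.direction} for t in self.cognitive_tests],
            "physical_tests": [
                {"column": t.column, "direction": t.direction}
                for t in self.physical_tests],
            "min_deficit_fraction": self.min_deficit_fraction,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InstrumentMetadata":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            deficit_columns=list(doc["deficit_columns"]),
            disease_pairs=[(d, m) for d, m in doc["disease_pairs"]],
            chronic_columns=list(doc["chronic_columns"]),
            cognitive_tests=[TestSpec(t["column"], t["direction"],
                                      domain=t.get("domain", "default"))
                             for t in doc["cognitive_tests"]],
            physical_tests=[TestSpec(t["column"], t["direction"])
                            for t in doc["physical_tests"]],
            min_deficit_fraction=doc.get("min_deficit_fraction", 0.8),
        )


@dataclass(frozen=True)
class QuartileCutoffs:
    instrument: str
    q1: float
    q2: float
    q3: float

    def __post_init__(self):
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartile cutoffs must be non-decreasing")


def invert_risk_direction(values, direction: str):
    """Orient a test score so that larger values mean greater decline.

    Inversion is negation; downstream rank normalisation makes the choice
    of monotone inversion immaterial.
    """
    if direction == "risk_increases":
        return np.asarray(values, dtype=float)
    if direction == "risk_decreases":
        return -np.asarray(values, dtype=float)
    raise ValueError(f"unknown direction of risk: {direction!r}")


def rank_normalize(values) -> np.ndarray:
    """Map values to (0, 1) by average ranks: (rank - 0.5) / n.

    Ranks are computed among non-missing entries; missing entries remain
    missing.  Raises on an all-missing vector.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if not mask.any():
        raise ValueError("rank_normalize: all values missing")
    out = np.full(x.shape, np.nan)
    ranks = rankdata(x[mask], method="average")
    out[mask] = (ranks - 0.5) / mask.sum()
    return out


def frailty_index(deficits: pd.DataFrame,
                  min_fraction: float = 0.8) -> pd.Series:
    """Mean of non-missing deficit indicators per participant.

    Each deficit must lie in [0, 1] (graded deficits allowed).  A
    participant with fewer than ``min_fraction`` of deficits observed gets a
    missing score.
    """
    vals = deficits.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    bad = finite & ((vals < 0) | (vals > 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"deficit value {vals[i, j]} outside [0, 1] at row "
            f"{deficits.index[i]}, column {deficits.columns[j]!r}")
    n_obs = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.where(n_obs > 0,
                         np.nansum(vals, axis=1) / np.maximum(n_obs, 1),
                         np.nan)
    score = np.where(n_obs >= min_fraction * deficits.shape[1], score, np.nan)
    return pd.Series(score, index=deficits.index)


def disease_instrument(cohort: pd.DataFrame,
                       pairs: list[tuple[str, str | None]],
                       ) -> tuple[pd.Series, pd.Series]:
    """Five-disease score and categorical health level.

    A disease is confirmed if its flag is set *or* the paired medication /
    treatment flag is set.  Score = confirmed count / 5.  Level: 0 diseases
    -> healthiest, exactly 1 -> intermediate (good health), >= 2 -> least
    healthy.  The score is missing if any effective flag is undetermined.
    """
    effective = []
    for dis, med in pairs:
        d = cohort[dis].astype(float)
        if med is not None and med in cohort.columns:
            m = cohort[med].astype(float)
            e = pd.Series(np.where((d == 1) | (m == 1), 1.0,
                                   np.where(d.notna() & m.notna(), 0.0,
                                            np.nan)),
                          index=cohort.index)
        else:
            e = d
        effective.append(e)
    eff = pd.concat(effective, axis=1)
    count = eff.sum(axis=1, skipna=False)
    score = count / 5.0
    level = pd.Series(np.nan, index=cohort.index)
    level[count == 0] = LEVEL_HEALTHIEST
    level[count == 1] = LEVEL_GOOD
    level[count >= 2] = LEVEL_LEAST_HEALTHY
    return score, level


def composite_instrument(cohort: pd.DataFrame,
                         tests: list[TestSpec]) -> pd.Series:
    """Mean of domain means of rank-normalised, risk-oriented test scores.

    Each test is oriented by its declared direction of risk, rank-normalised
    over the cohort, averaged within its domain over the participant's
    observed tests, and domain means are averaged with equal weight per
    domain.  The composite is missing for a participant with no observed
    test in some domain.
    """
    domains: dict[str, list[np.ndarray]] = {}
    for t in tests:
        if t.column not in cohort.columns:
            raise KeyError(f"test column {t.column!r} not in cohort table")
        rn = rank_normalize(invert_risk_direction(cohort[t.column],
                                                  t.direction))
        domains.setdefault(t.domain, []).append(rn)
    domain_means = []
    for cols in domains.values():
        stacked = np.vstack(cols)
        n_obs = (~np.isnan(stacked)).sum(axis=0)
        dm = np.where(n_obs > 0,  # mean of observed tests in the domain
                      np.nansum(stacked, axis=0) / np.maximum(n_obs, 1),
                      np.nan)
        domain_means.append(dm)
    dm = np.vstack(domain_means)
    out = dm.mean(axis=0)  # NaN if any domain missing
    return pd.Series(out, index=cohort.index)


def quartile_cutoffs(scores, instrument: str = "") -> QuartileCutoffs:
    """Pooled-cohort quartiles (inclusive linear interpolation)."""
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no non-missing scores for quartile cutoffs")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return QuartileCutoffs(instrument, float(q1), float(q2), float(q3))


def assign_health_levels(scores, cutoffs: QuartileCutoffs) -> pd.Series:
    """Quartile health levels with half-open boundaries.

    score < q1 -> healthiest; q1 <= score < q2 -> good; q2 <= score < q3 ->
    fair; score >= q3 -> least healthy.  Ties at a cutoff go to the
    less-healthy side except below q1 (matching a strict "< q1" healthiest
    rule).  Missing scores get missing levels.
    """
    index = scores.index if isinstance(scores, pd.Series) else None
    x = pd.Series(np.asarray(scores, dtype=float), index=index)
    level = pd.Series(np.nan, index=x.index)
    level[x < cutoffs.q1] = LEVEL_HEALTHIEST
    level[(x >= cutoffs.q1) & (x < cutoffs.q2)] = LEVEL_GOOD
    level[(x >= cutoffs.q2) & (x < cutoffs.q3)] = LEVEL_FAIR
    level[x >= cutoffs.q3] = LEVEL_LEAST_HEALTHY
    return level


def compute_instruments(cohort: pd.DataFrame, meta: InstrumentMetadata,
                        ) -> tuple[pd.DataFrame, dict[str, QuartileCutoffs]]:
    """All five instrument scores and health levels for a cohort table.

    Returns a frame with ``participant_id``, ``score_I`` .. ``score_V`` and
    ``level_I`` .. ``level_V``, plus the quartile cutoffs used for the
    continuous instruments.
    """
    scores: dict[str, pd.Series] = {}
    scores["I"] = frailty_index(cohort[meta.deficit_columns],
                                meta.min_deficit_fraction)
    score_ii, level_ii = disease_instrument(cohort, meta.disease_pairs)
    scores["II"] = score_ii
    scores["III"] = frailty_index(cohort[meta.chronic_columns],
                                  meta.min_deficit_fraction)
    scores["IV"] = composite_instrument(cohort, meta.cognitive_tests)
    scores["V"] = composite_instrument(cohort, meta.physical_tests)

    out = pd.DataFrame({"participant_id": cohort["participant_id"]})
    cutoffs: dict[str, QuartileCutoffs] = {}
    for inst in INSTRUMENTS:
        out[f"score_{inst}"] = scores[inst]
    for inst in ("I", "III", "IV", "V"):
        cut = quartile_cutoffs(scores[inst], inst)
        cutoffs[inst] = cut
        out[f"level_{inst}"] = assign_health_levels(scores[inst], cut)
    out["level_II"] = level_ii
    return out, cutoffs
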