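"""Synthetic aging-cohort generator with planted ground truth.

Emulates the structure of a community-dwelling cohort of adults aged 45-85:
binary health deficits driven by a latent health-deficit load, five major
disease flags with medication confirmation, a larger set of chronic-condition
flags, cognitive and physical test scores with declared directions of risk,
continuous phenotypes with planted relationships to latent health
(increasing / decreasing / V-shaped / null), and categorical lifestyle
covariates.

The generator plants three kinds of truth that downstream stages must
recover:

* relationship type and breakpoint per phenotype (per sex when requested);
* variance heterogeneity: residual noise standard deviation that is larger
  for participants with a higher latent health-deficit load;
* right-skewed deficit-style instrument scores that increase with age.

The latent model: each participant carries a latent health-deficit load

    load = a0 + a_age * (age - 45) / 40 + a_resid * (u - 1/2)

clipped to (0, 1), where ``u`` is an age-independent uniform latent
health-deficit percentile (0 = healthiest residual health).  Deficits,
disease flags, chronic flags and test scores are drawn conditionally on the
load; phenotypes are generated from ``u`` by the inverse of the planted
phenotype -> deficit relationship, plus Gaussian noise whose standard
deviation interpolates between ``base_sd`` (healthiest latent tertile) and
``base_sd * heteroskedasticity_factor`` (least-healthy tertile).

Missingness is applied completely at random, per column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeSpec",
    "CohortConfig",
    "default_phenotype_specs",
    "default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortIOError",
]

_RELATIONSHIPS = ("increasing", "decreasing", "nonmonotonic", "null")

# latent health-deficit load coefficients (see module docstring)
_A0 = 0.18
_A_AGE = 0.20
_A_RESID = 0.30

# mean per-deficit susceptibility by sex, calibrated so that the frailty
# index mean matches a typical community cohort (females ~0.092, males ~0.081)
_DEFICIT_SUSCEPT = {"F": 0.33, "M": 0.29}
_DISEASE_SUSCEPT = {"F": 0.42, "M": 0.52}
_CHRONIC_SUSCEPT = {"F": 0.43, "M": 0.30}

DISEASE_COLUMNS = [
    "disease_cancer",
    "disease_cvd",
    "disease_pulmonary",
    "disease_dementia",
    "disease_diabetes",
]
# (disease column, medication/treatment column) pairs; None = no med proxy
DISEASE_MED_PAIRS = [
    ("disease_cancer", "med_cancer_treatment"),
    ("disease_cvd", "med_heart"),
    ("disease_pulmonary", None),
    ("disease_dementia", None),
    ("disease_diabetes", "med_diabetes"),
]

COGNITIVE_TESTS = [
    # (column, domain, direction of risk)
    ("cog_memory_recall", "memory", "risk_decreases"),
    ("cog_exec_alternation", "executive", "risk_decreases"),
    ("cog_exec_fluency", "executive", "risk_decreases"),
    ("cog_exec_word_assoc", "executive", "risk_decreases"),
    ("cog_exec_stroop_time", "executive", "risk_increases"),
    ("cog_exec_prospective", "executive", "risk_decreases"),
    ("cog_speed_reaction_time", "psychomotor", "risk_increases"),
]

PHYSICAL_TESTS = [
    ("phys_walk_time", "risk_increases"),
    ("phys_tug_time", "risk_increases"),
    ("phys_balance_time", "risk_decreases"),
    ("phys_chair_rise_time", "risk_increases"),
    ("phys_grip_strength", "risk_decreases"),
]

COVARIATE_LEVELS = {
    "smoking": (["never", "occasional", "current", "current_heavy"],
                [0.55, 0.15, 0.20, 0.10]),
    "alcohol": (["never", "light_moderate", "heavy"], [0.25, 0.60, 0.15]),
    "education": (["less_than_secondary", "secondary", "diploma", "university"],
                  [0.10, 0.25, 0.30, 0.35]),
    "income": (["lt20k", "20_50k", "50_100k", "100_150k", "gt150k"],
               [0.08, 0.25, 0.35, 0.20, 0.12]),
    "nutrition_risk": (["low", "high"], [0.65, 0.35]),
}

STRING_COLUMNS = ["sex", "ancestry"] + list(COVARIATE_LEVELS)


@dataclass
class PhenotypeSpec:
    """Planted phenotype -> health-deficit relationship.

    ``left_slope`` / ``right_slope`` are on the latent-percentile scale:
    the latent health-deficit percentile changes by ``slope`` per phenotype
    unit, so a slope of 0.1 means the phenotype spans ten units across the
    full latent range on that side of the breakpoint.  For monotone
    relationships only ``left_slope`` is used.  ``location`` anchors the
    phenotype value of the healthiest participants (monotone and null).
    """

    name: str
    relationship: str
    breakpoint: float | None = None
    left_slope: float | None = None
    right_slope: float | None = None
    base_sd: float = 1.0
    heteroskedasticity_factor: float = 1.0
    sex_specific: bool = False
    location: float = 0.0

    def __post_init__(self) -> None:
        if self.relationship not in _RELATIONSHIPS:
            raise ValueError(
                f"{self.name}: unknown relationship {self.relationship!r}")
        if self.base_sd <= 0:
            raise ValueError(f"{self.name}: base_sd must be positive")
        if self.heteroskedasticity_factor < 1:
            raise ValueError(
                f"{self.name}: heteroskedasticity_factor must be >= 1 "
                "(1 = homoskedastic; larger = lower variance when healthiest)")
        if self.relationship == "nonmonotonic":
            if self.breakpoint is None:
                raise ValueError(f"{self.name}: nonmonotonic needs a breakpoint")
            if self.left_slope is None or self.right_slope is None:
                raise ValueError(f"{self.name}: nonmonotonic needs both slopes")
            if self.left_slope * self.right_slope >= 0:
                raise ValueError(
                    f"{self.name}: nonmonotonic slopes must have opposite signs")
        elif self.relationship == "increasing":
            if not self.left_slope or self.left_slope <= 0:
                raise ValueError(f"{self.name}: increasing needs left_slope > 0")
        elif self.relationship == "decreasing":
            if not self.left_slope or self.left_slope >= 0:
                raise ValueError(f"{self.name}: decreasing needs left_slope < 0")

    def breakpoint_for_sex(self, sex: str) -> float | None:
        """Planted breakpoint for one sex.

        When ``sex_specific`` the male breakpoint is shifted right by 5% of
        the phenotype's planted support width, mimicking sex-dependent
        optima (e.g. hemoglobin).
        """
        if self.relationship != "nonmonotonic":
            return None
        if not self.sex_specific or sex == "F":
            return self.breakpoint
        width = 1.0 / abs(self.left_slope) + 1.0 / abs(self.right_slope)
        return self.breakpoint + 0.05 * width


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """Planted panel: 6 V-shaped, 3 increasing, 3 decreasing, 6 null."""
    v = PhenotypeSpec
    return [
        v("sweet1", "nonmonotonic", breakpoint=2.0, left_slope=-0.08,
          right_slope=0.12, base_sd=0.25, heteroskedasticity_factor=2.0),
        v("sweet2", "nonmonotonic", breakpoint=5.5, left_slope=-0.10,
          right_slope=0.10, base_sd=0.30, heteroskedasticity_factor=1.8),
        v("sweet3", "nonmonotonic", breakpoint=-1.0, left_slope=-0.12,
          right_slope=0.08, base_sd=0.25, heteroskedasticity_factor=2.2),
        v("sweet4", "nonmonotonic", breakpoint=40.0, left_slope=-0.09,
          right_slope=0.11, base_sd=0.35, heteroskedasticity_factor=2.0),
        v("sweet5", "nonmonotonic", breakpoint=95.0, left_slope=-0.10,
          right_slope=0.12, base_sd=0.30, heteroskedasticity_factor=1.6),
        v("sweet6", "nonmonotonic", breakpoint=14.5, left_slope=-0.11,
          right_slope=0.09, base_sd=0.25, heteroskedasticity_factor=2.0,
          sex_specific=True),
        # monotone phenotype noise is sized at ~45% of the latent-driven
        # spread so that measures sharing the latent driver correlate near
        # 0.8, as in a real panel, rather than collapsing into the
        # correlation prefilter
        v("inc1", "increasing", left_slope=0.08, location=5.0,
          base_sd=1.6, heteroskedasticity_factor=1.8),
        v("inc2", "increasing", left_slope=0.10, location=0.0,
          base_sd=1.3, heteroskedasticity_factor=1.8),
        v("inc3", "increasing", left_slope=0.12, location=27.0,
          base_sd=1.1, heteroskedasticity_factor=1.8),
        v("dec1", "decreasing", left_slope=-0.08, location=70.0,
          base_sd=1.6, heteroskedasticity_factor=1.8),
        v("dec2", "decreasing", left_slope=-0.10, location=1.3,
          base_sd=1.3, heteroskedasticity_factor=1.8),
        v("dec3", "decreasing", left_slope=-0.12, location=0.0,
          base_sd=1.1, heteroskedasticity_factor=1.8),
        v("null1", "null", location=0.0, base_sd=1.0),
        v("null2", "null", location=10.0, base_sd=2.0),
        v("null3", "null", location=100.0, base_sd=15.0),
        v("null4", "null", location=5.0, base_sd=0.5),
        v("null5", "null", location=50.0, base_sd=5.0),
        v("null6", "null", location=7.0, base_sd=1.0),
    ]


@dataclass
class CohortConfig:
    n_participants: int = 10_000
    age_range: tuple[float, float] = (45.0, 85.0)
    sex_ratio: float = 0.523          # fraction female
    n_deficits: int = 51
    n_disease_flags: int = 5          # fixed by the five-disease instrument
    n_chronic_flags: int = 28
    phenotype_specs: list[PhenotypeSpec] = field(
        default_factory=default_phenotype_specs)
    missingness_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_deficits <= 0 or self.n_chronic_flags <= 0:
            raise ValueError("deficit/chronic counts must be positive")
        if self.n_disease_flags != 5:
            raise ValueError("the five-disease instrument requires exactly "
                             "5 disease flags")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if not 0 <= self.missingness_rate <= 1:
            raise ValueError("missingness_rate must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        names = [s.name for s in self.phenotype_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names")


def default_config(**overrides) -> CohortConfig:
    return CohortConfig(**overrides)


def _het_profile(u: np.ndarray, factor: float) -> np.ndarray:
    """Noise-sd multiplier as a function of latent percentile ``u``.

    Constant 1 on the healthiest tertile, constant ``factor`` on the
    least-healthy tertile, linear in between — so the planted
    tertile-to-tertile residual-sd ratio is exactly ``factor``.
    """
    t = np.clip((u - 1.0 / 3.0) * 3.0, 0.0, 1.0)
    return 1.0 + (factor - 1.0) * t


def _generate_phenotype(spec: PhenotypeSpec, u: np.ndarray, sex: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    n = len(u)
    noise = rng.normal(0.0, spec.base_sd, n)
    if spec.relationship == "null":
        return spec.location + noise  # independent of health, homoskedastic
    noise = noise * _het_profile(u, spec.heteroskedasticity_factor)
    if spec.relationship in ("increasing", "decreasing"):
        return spec.location + u / spec.left_slope + noise
    # nonmonotonic: each participant falls on one side of the vertex; the
    # healthiest (u ~ 0) sit at the breakpoint on either side
    side_right = rng.random(n) < 0.5
    slope = np.where(side_right, spec.right_slope, spec.left_slope)
    psi = np.where(sex == "M",
                   spec.breakpoint_for_sex("M"),
                   spec.breakpoint_for_sex("F"))
    return psi + u / slope + noise


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a participant table and its truth registry.

    Returns ``(table, registry)``.  The registry maps each phenotype name to
    per-sex planted truth (relationship, breakpoint, slopes,
    heteroskedasticity factor) plus generator provenance.  The table
    includes a ``latent_u`` column holding the age-independent latent
    health-deficit percentile (ground truth; not a measured variable).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range

    age = rng.uniform(lo, hi, n)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    ancestry = rng.choice(
        ["white", "asian", "black", "other"], size=n,
        p=[0.94, 0.02, 0.007, 0.033])
    u = rng.random(n)  # latent health-deficit percentile, age-independent
    load = np.clip(
        _A0 + _A_AGE * (age - 45.0) / 40.0 + _A_RESID * (u - 0.5),
        0.005, 0.995)

    data: dict[str, np.ndarray] = {
        "participant_id": np.arange(1, n + 1),
        "age": age,
        "sex": sex,
        "ancestry": ancestry,
        "latent_u": u,
    }

    suscept = np.where(sex == "F", _DEFICIT_SUSCEPT["F"], _DEFICIT_SUSCEPT["M"])
    weights = np.linspace(0.4, 1.6, config.n_deficits)  # heterogeneous deficits
    for j in range(config.n_deficits):
        p = np.clip(load * suscept * weights[j], 0.0, 1.0)
        data[f"deficit_{j + 1:02d}"] = (rng.random(n) < p).astype(float)

    dis_suscept = np.where(sex == "F", _DISEASE_SUSCEPT["F"],
                           _DISEASE_SUSCEPT["M"])
    for col in DISEASE_COLUMNS:
        p = np.clip(load * dis_suscept * 0.9, 0.0, 1.0)
        data[col] = (rng.random(n) < p).astype(float)
    for dis, med in DISEASE_MED_PAIRS:
        if med is None:
            continue
        has = data[dis] == 1
        p_med = np.where(has, 0.5, 0.02)  # meds occasionally without diagnosis
        data[med] = (rng.random(n) < p_med).astype(float)

    chr_suscept = np.where(sex == "F", _CHRONIC_SUSCEPT["F"],
                           _CHRONIC_SUSCEPT["M"])
    cweights = np.linspace(0.5, 1.5, config.n_chronic_flags)
    for j in range(config.n_chronic_flags):
        p = np.clip(load * chr_suscept * cweights[j], 0.0, 1.0)
        data[f"chronic_{j + 1:02d}"] = (rng.random(n) < p).astype(float)

    # cognitive / physical tests: raw scores monotone in the latent load,
    # oriented per declared direction of risk
    for col, _domain, direction in COGNITIVE_TESTS:
        signal = load + rng.normal(0.0, 0.12, n)
        if direction == "risk_increases":
            data[col] = 20.0 + 30.0 * signal
        else:
            data[col] = 15.0 - 10.0 * signal
    for col, direction in PHYSICAL_TESTS:
        signal = load + rng.normal(0.0, 0.12, n)
        if direction == "risk_increases":
            data[col] = 5.0 + 10.0 * signal
        else:
            data[col] = 40.0 - 25.0 * signal

    for spec in config.phenotype_specs:
        data[spec.name] = _generate_phenotype(spec, u, sex, rng)

    for name, (levels, probs) in COVARIATE_LEVELS.items():
        data[name] = rng.choice(levels, size=n, p=probs)

    table = pd.DataFrame(data)

    if config.missingness_rate > 0:
        protected = {"participant_id", "age", "sex", "ancestry", "latent_u"}
        maskable = [c for c in table.columns if c not in protected
                    and c not in COVARIATE_LEVELS]
        for col in maskable:
            mask = rng.random(n) < config.missingness_rate
            table.loc[mask, col] = np.nan

    registry = {
        "phenotypes": {
            spec.name: {
                sx: {
                    "relationship": spec.relationship,
                    "breakpoint": spec.breakpoint_for_sex(sx),
                    "left_slope": spec.left_slope,
                    "right_slope": (spec.right_slope
                                    if spec.relationship == "nonmonotonic"
                                    else spec.left_slope),
                    "heteroskedasticity_factor":
                        spec.heteroskedasticity_factor,
                    "base_sd": spec.base_sd,
                }
                for sx in ("F", "M")
            }
            for spec in config.phenotype_specs
        },
        "config": {
            "n_participants": config.n_participants,
            "age_range": list(config.age_range),
            "sex_ratio": config.sex_ratio,
            "n_deficits": config.n_deficits,
            "n_chronic_flags": config.n_chronic_flags,
            "missingness_rate": config.missingness_rate,
            "seed": config.seed,
        },
        "string_columns": STRING_COLUMNS,
    }
    return table, registry


class CohortIOError(ValueError):
    """Raised when a cohort file cannot be parsed."""


def write_cohort(table: pd.DataFrame, registry: dict, path: str | Path) -> None:
    """Write ``cohort.csv`` and ``truth.json`` into directory ``path``.

    Missing values are serialized as empty cells; floats round-trip at full
    precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    table.to_csv(path / "cohort.csv", index=False, na_rep="",
                 float_format="%.17g")
    with open(path / "truth.json", "w") as fh:
        json.dump(registry, fh, indent=1)


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a cohort directory written by :func:`write_cohort`.

    Empty cells become NaN (missing), never zero.  A non-numeric entry in a
    numeric column raises :class:`CohortIOError` naming the row and column.
    """
    path = Path(path)
    csv = path / "cohort.csv"
    if not csv.exists():
        raise CohortIOError(f"no cohort.csv under {path}")
    with open(path / "truth.json") as fh:
        registry = json.load(fh)
    table = pd.read_csv(csv, dtype=str, keep_default_na=False)
    string_cols = set(registry.get("string_columns", STRING_COLUMNS))
    out = {}
    for col in table.columns:
        raw = table[col]
        if col in string_cols:
            out[col] = raw.where(raw != "", other=pd.NA)
            continue
        vals = raw.replace("", np.nan)
        try:
            converted = vals.astype(float)  # correctly-rounded parser
        except (ValueError, TypeError):
            coerced = pd.to_numeric(vals, errors="coerce")
            bad = coerced.isna() & vals.notna()
            row = int(bad.idxmax())
            raise CohortIOError(
                f"non-numeric value {vals[row]!r} in column {col!r}, "
                f"row {row + 2} of {csv}") from None
        out[col] = converted
    frame = pd.DataFrame(out)
    if "participant_id" in frame.columns and len(frame):
        frame["participant_id"] = frame["participant_id"].astype(int)
    return frame, registry
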