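"""The 0-7 point FOBT prioritization score.

Five additive components: age class (0-2), male gender (0-1), current
smoking (0-1), BMI class with a gender-specific overweight rule (0-1), and
number of comorbidities among type-2 diabetes, dyslipidemia and
hypertension, capped at two points (0-2). Totals are grouped into risk
bands — four bands (0-3, 4, 5, >=6) or the collapsed three bands
low/medium/high — each associated with an empirical positive-FOBT rate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import MIN_SCORING_AGE, Gender, PatientRecord

__all__ = [
    "BMICategory",
    "BandScheme",
    "ScoreBreakdown",
    "classify_bmi",
    "age_points",
    "gender_points",
    "smoking_points",
    "bmi_points",
    "comorbidity_points",
    "compute_score",
    "assign_band",
    "score_dataframe",
    "FOBTRiskScorer",
]


class BMICategory(str, enum.Enum):
    """WHO-style BMI classes with half-open [lower, upper) bins."""

    UNDERWEIGHT = "underweight"  # < 18.50
    NORMAL = "normal"  # 18.50-24.99
    OVERWEIGHT = "overweight"  # 25.00-29.99
    OBESE_I = "obese_I"  # 30.00-34.99
    OBESE_II = "obese_II"  # 35.00-39.99
    OBESE_III = "obese_III"  # >= 40


#: Left edges of the BMI bins, in kg/m^2; each bin is [edge, next_edge).
_BMI_EDGES: list[tuple[float, BMICategory]] = [
    (40.0, BMICategory.OBESE_III),
    (35.0, BMICategory.OBESE_II),
    (30.0, BMICategory.OBESE_I),
    (25.0, BMICategory.OVERWEIGHT),
    (18.5, BMICategory.NORMAL),
    (0.0, BMICategory.UNDERWEIGHT),
]


class BandScheme(str, enum.Enum):
    FOUR_BAND = "four_band"
    THREE_BAND = "three_band"


#: Band labels in ascending risk order per scheme.
FOUR_BAND_LABELS = ("0-3", "4", "5", ">=6")
THREE_BAND_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ScoreBreakdown:
    """The five point components of the score and their total."""

    age_points: int
    gender_points: int
    smoking_points: int
    bmi_points: int
    comorbidity_points: int

    @property
    def total(self) -> int:
        return (
            self.age_points
            + self.gender_points
            + self.smoking_points
            + self.bmi_points
            + self.comorbidity_points
        )


def classify_bmi(bmi: float) -> BMICategory:
    """Assign a BMI value (kg/m^2) to its half-open class.

    18.50 is normal, 25.00 overweight, 30.00 obese class I; "29.99"-style
    published upper bounds are read as "up to but not including the next
    edge".
    """
    if not (isinstance(bmi, (int, float)) and math.isfinite(bmi) and bmi > 0):
        raise ValueError(f"bmi must be finite and positive, got {bmi!r}")
    for edge, category in _BMI_EDGES:
        if bmi >= edge:
            return category
    raise AssertionError("unreachable: bins cover (0, inf)")


def age_points(age: int) -> int:
    """Age component: 40-49 -> 0, 50-59 -> 1, >=60 -> 2.

    The risk of colorectal cancer roughly doubles after 60, hence the second
    point at that threshold. Undefined (raises) below 40.
    """
    if age < MIN_SCORING_AGE:
        raise ValueError(
            f"age {age} is below the minimum scoring age of {MIN_SCORING_AGE}"
        )
    if age < 50:
        return 0
    if age < 60:
        return 1
    return 2


def gender_points(gender: Gender) -> int:
    """Gender component: male 1, female 0."""
    return 1 if Gender(gender) is Gender.MALE else 0


def smoking_points(current_smoker: bool) -> int:
    """Smoking component: 1 for current smokers; former smokers score 0."""
    return 1 if current_smoker else 0


def bmi_points(bmi: float, gender: Gender) -> int:
    """BMI component: <25 -> 0; >=30 -> 1; overweight scores 1 only for women.

    The gender-specific overweight rule reflects the observed excess of
    positive tests among overweight women in the derivation cohort.
    Underweight scores 0 (no separate rule below 25).
    """
    category = classify_bmi(bmi)
    if category in (BMICategory.UNDERWEIGHT, BMICategory.NORMAL):
        return 0
    if category is BMICategory.OVERWEIGHT:
        return 1 if Gender(gender) is Gender.FEMALE else 0
    return 1


def comorbidity_points(dm: bool, dysl: bool, hta: bool) -> int:
    """Comorbidity component: none 0, exactly one 1, two or three 2."""
    n = int(dm) + int(dysl) + int(hta)
    return min(n, 2)


def compute_score(record: PatientRecord) -> ScoreBreakdown:
    """Full score breakdown for one patient record."""
    return ScoreBreakdown(
        age_points=age_points(record.age),
        gender_points=gender_points(record.gender),
        smoking_points=smoking_points(record.current_smoker),
        bmi_points=bmi_points(record.bmi, record.gender),
        comorbidity_points=comorbidity_points(record.dm, record.dysl, record.hta),
    )


def assign_band(total: int, scheme: BandScheme | str = BandScheme.FOUR_BAND) -> str:
    """Map a total score 0-7 to its risk band label.

    four_band: "0-3", "4", "5", ">=6"; three_band: "low" (0-3),
    "medium" (4-5), "high" (6-7).
    """
    if not 0 <= total <= 7:
        raise ValueError(f"total score must be in [0, 7], got {total}")
    scheme = BandScheme(scheme)
    if scheme is BandScheme.FOUR_BAND:
        if total <= 3:
            return "0-3"
        if total == 4:
            return "4"
        if total == 5:
            return "5"
        return ">=6"
    if total <= 3:
        return "low"
    if total <= 5:
        return "medium"
    return "high"


def band_labels(scheme: BandScheme | str) -> tuple[str, ...]:
    """Band labels of a scheme in ascending risk order."""
    scheme = BandScheme(scheme)
    return FOUR_BAND_LABELS if scheme is BandScheme.FOUR_BAND else THREE_BAND_LABELS


# -- vectorized dataframe interface ------------------------------------------

#: Columns the dataframe scorer requires.
REQUIRED_COLUMNS = ("gender", "age", "bmi", "current_smoker", "dm", "dysl", "hta")


def _validate_frame(X: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    age = pd.to_numeric(X["age"], errors="raise")
    if (age < MIN_SCORING_AGE).any():
        bad = X.index[age < MIN_SCORING_AGE].tolist()
        raise ValueError(
            f"age below the minimum scoring age of {MIN_SCORING_AGE} "
            f"at row(s) {bad[:10]}"
        )
    bmi = pd.to_numeric(X["bmi"], errors="raise")
    if (~np.isfinite(bmi) | (bmi <= 0)).any():
        raise ValueError("bmi must be finite and positive for every row")


def score_dataframe(
    X: pd.DataFrame, scheme: BandScheme | str = BandScheme.FOUR_BAND
) -> pd.DataFrame:
    """Score every row of a patient dataframe.

    Returns a copy of ``X`` with the five component columns, ``total`` and
    ``band`` appended. Expects the columns in :data:`REQUIRED_COLUMNS`, with
    ``gender`` as "male"/"female" and the flags as booleans or 0/1.
    """
    _validate_frame(X)
    out = X.copy()
    age = pd.to_numeric(out["age"]).to_numpy()
    bmi = pd.to_numeric(out["bmi"]).to_numpy(dtype=float)
    male = out["gender"].map(lambda g: Gender(g) is Gender.MALE).to_numpy()
    smoker = out["current_smoker"].astype(bool).to_numpy()
    ncom = (
        out["dm"].astype(bool).astype(int)
        + out["dysl"].astype(bool).astype(int)
        + out["hta"].astype(bool).astype(int)
    ).to_numpy()

    out["age_points"] = np.select([age < 50, age < 60], [0, 1], default=2)
    out["gender_points"] = male.astype(int)
    out["smoking_points"] = smoker.astype(int)
    out["bmi_points"] = np.where(
        bmi >= 30, 1, np.where((bmi >= 25) & ~male, 1, 0)
    )
    out["comorbidity_points"] = np.minimum(ncom, 2)
    out["total"] = (
        out["age_points"]
        + out["gender_points"]
        + out["smoking_points"]
        + out["bmi_points"]
        + out["comorbidity_points"]
    )
    out["band"] = [assign_band(t, scheme) for t in out["total"]]
    return out


class FOBTRiskScorer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer applying the prioritization score.

    ``transform`` appends the component columns, ``total`` and ``band`` to a
    patient dataframe; ``fit`` only validates the input (the scoring rule has
    no fitted state), so the transformer composes with sklearn pipelines.

    Parameters
    ----------
    scheme : {"four_band", "three_band"}
        Risk-band grouping appended as the ``band`` column.
    """

    def __init__(self, scheme: str = "four_band"):
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None) -> "FOBTRiskScorer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("FOBTRiskScorer expects a pandas DataFrame")
        BandScheme(self.scheme)
        _validate_frame(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_features_in_"):
            raise ValueError("FOBTRiskScorer is not fitted; call fit first")
        return score_dataframe(X, scheme=self.scheme)

    def get_feature_names_out(self, input_features=None):
        base = (
            list(input_features)
            if input_features is not None
            else list(self.feature_names_in_)
        )
        return np.asarray(
            base
            + [
                "age_points",
                "gender_points",
                "smoking_points",
                "bmi_points",
                "comorbidity_points",
                "total",
                "band",
            ],
            dtype=object,
        )
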