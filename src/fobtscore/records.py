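"""Patient-level domain types for the FOBT prioritization score.

The score applies to adults aged 40 or older screened opportunistically for
colorectal cancer; each record carries the five scored risk factors (age,
gender, current smoking, BMI, and the three comorbidity flags) plus the
optional FOBT outcome and a descriptive urban/rural residence field.
"""

from __future__ import annotations

import enum
import math

from pydantic import BaseModel, ConfigDict, field_validator


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class FOBTResult(str, enum.Enum):
    """Fecal occult blood test outcome; MISSING when no test was performed."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class Residence(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"
    UNKNOWN = "unknown"


#: Minimum age for the score to be defined (study inclusion threshold).
MIN_SCORING_AGE = 40


class PatientRecord(BaseModel):
    """One screened individual's risk-factor profile and optional FOBT outcome.

    Parameters
    ----------
    id : str
        Opaque identifier.
    gender : Gender
    age : int
        Age in completed years; must be >= 40 (the score is undefined below
        the screening inclusion age and such records are rejected).
    bmi : float
        Body mass index in kg/m^2; must be finite and positive.
    current_smoker : bool
        True only for current smokers; never-smokers and former smokers are
        pooled as non-smokers.
    dm, dysl, hta : bool
        Diagnosis flags for type-2 diabetes, dyslipidemia and hypertension
        (each operationalized as being on the corresponding treatment).
    fobt : FOBTResult
        Test outcome, MISSING if untested. Scoring does not require it.
    residence : Residence
        Descriptive only; not scored.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    gender: Gender
    age: int
    bmi: float
    current_smoker: bool
    dm: bool
    dysl: bool
    hta: bool
    fobt: FOBTResult = FOBTResult.MISSING
    residence: Residence = Residence.UNKNOWN

    @field_validator("age")
    @classmethod
    def _age_in_scoring_range(cls, v: int) -> int:
        if v < MIN_SCORING_AGE:
            raise ValueError(
                f"age {v} is below the minimum scoring age of {MIN_SCORING_AGE}; "
                "the score is undefined for younger patients"
            )
        return v

    @field_validator("bmi")
    @classmethod
    def _bmi_positive_finite(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"bmi must be finite and positive, got {v!r}")
        return v

    @property
    def n_comorbidities(self) -> int:
        """Number of the three scored comorbidities present (0-3)."""
        return int(self.dm) + int(self.dysl) + int(self.hta)


def bmi_from_height_weight(height_m: float, weight_kg: float) -> float:
    """BMI in kg/m^2 from height in metres and weight in kilograms.

    Convenience helper for inputs recorded as raw anthropometry.
    """
    if not (math.isfinite(height_m) and height_m > 0):
        raise ValueError(f"height_m must be finite and positive, got {height_m!r}")
    if not (math.isfinite(weight_kg) and weight_kg > 0):
        raise ValueError(f"weight_kg must be finite and positive, got {weight_kg!r}")
    return weight_kg / height_m**2
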