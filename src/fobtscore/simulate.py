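"""Synthetic screening-cohort generator.

Emulates the statistical structure the score's derivation cohort exhibits:
a gender split, age-class mixture with uniform integer ages within class,
truncated-normal BMI, Bernoulli smoking, a trivariate Bernoulli for the
three comorbidities with a common pairwise odds-ratio association, and a
FOBT outcome drawn from the risk band's positivity rate (band-conditional
Bernoulli; a per-point logistic alternative is available as a labelled
extension). Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import optimize, stats

from .records import FOBTResult, Gender, PatientRecord
from .scoring import FOUR_BAND_LABELS, BandScheme, assign_band, compute_score

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "generate",
    "calibrate_association",
    "trivariate_bernoulli_table",
    "spec_from_yaml",
    "spec_to_yaml",
]

#: Integer age ranges (inclusive) of the four age classes.
AGE_CLASS_RANGES = {
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    ">=70": (70, 88),
}


class CohortSpec(BaseModel):
    """Generative parameters for a synthetic screening cohort.

    Defaults (see :func:`default_cohort_spec`) reproduce the derivation
    cohort's published marginals: 112 patients, 54.46% female, the
    published age-class mix, BMI ~ TruncNormal(28.46, 4.66) on
    [17.60, 41.20] kg/m^2, 17.9% current smokers, comorbidity prevalences
    22.3% / 68.8% / 69.6% (DM / DYSL / HTA) with a pairwise odds-ratio
    association calibrated so that 19/112 of patients are expected to have
    no comorbidity, and band positivity rates 3/31, 2/20, 7/41, 8/20.
    """

    model_config = ConfigDict(frozen=True)

    n: int = 112
    p_female: float = 61 / 112
    #: probabilities of the classes 40-49, 50-59, 60-69, >=70
    age_class_probs: tuple[float, float, float, float] = (
        8 / 112, 26 / 112, 38 / 112, 40 / 112
    )
    bmi_mean: float = 28.46
    bmi_sd: float = 4.66
    bmi_min: float = 17.60
    bmi_max: float = 41.20
    p_smoker: float = 20 / 112
    p_dm: float = 25 / 112
    p_dysl: float = 77 / 112
    p_hta: float = 78 / 112
    #: common pairwise odds ratio of the comorbidity model; 1 = independent,
    #: None = calibrate to ``p_no_comorbidity``
    comorbidity_association: Optional[float] = None
    #: target probability of zero comorbidities used when
    #: ``comorbidity_association`` is None
    p_no_comorbidity: float = 19 / 112
    #: four-band positivity probabilities ("0-3", "4", "5", ">=6")
    band_pos_rates: tuple[float, float, float, float] = (
        3 / 31, 2 / 20, 7 / 41, 8 / 20
    )
    #: "band" draws FOBT from the band rate; "logistic" is an extension that
    #: uses P(pos) = sigmoid(intercept + slope * total score)
    fobt_model: Literal["band", "logistic"] = "band"
    logistic_intercept: float = -3.7
    logistic_slope: float = 0.45
    seed: int = 0

    @field_validator(
        "p_female", "p_smoker", "p_dm", "p_dysl", "p_hta", "p_no_comorbidity"
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {v}")
        return v

    @field_validator("band_pos_rates", "age_class_probs")
    @classmethod
    def _prob_vec(cls, v):
        if any(not 0.0 <= p <= 1.0 for p in v):
            raise ValueError(f"probabilities out of [0, 1]: {v}")
        return v

    @field_validator("comorbidity_association")
    @classmethod
    def _assoc(cls, v):
        if v is not None and v < 0:
            raise ValueError("comorbidity_association must be >= 0")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "CohortSpec":
        if abs(sum(self.age_class_probs) - 1.0) > 1e-9:
            raise ValueError("age_class_probs must sum to 1")
        if not self.bmi_min < self.bmi_mean < self.bmi_max:
            raise ValueError("need bmi_min < bmi_mean < bmi_max")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        return self


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study-condition spec: the derivation cohort's published marginals."""
    return CohortSpec(**overrides)


# -- correlated comorbidities ------------------------------------------------

_PATTERNS = tuple(itertools.product((0, 1), repeat=3))


def trivariate_bernoulli_table(
    p1: float, p2: float, p3: float, theta: float
) -> np.ndarray:
    """Joint pmf over the 8 comorbidity patterns (dm, dysl, hta).

    Log-linear construction: p(x) proportional to
    exp(sum_i alpha_i x_i + log(theta) * sum_{i<j} x_i x_j), with the main
    effects alpha solved so the three marginals match exactly. ``theta`` is
    the common pairwise odds ratio (1 = independence). ``theta = 0`` makes
    the comorbidities mutually exclusive, which is only feasible when
    p1 + p2 + p3 <= 1 (the Frechet lower bound on the empty cell).
    """
    p = np.array([p1, p2, p3], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("marginal probabilities must lie in [0, 1]")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0.0:
        if p.sum() > 1.0 + 1e-12:
            raise ValueError(
                "infeasible marginals for theta = 0: p1 + p2 + p3 = "
                f"{p.sum():.4f} > 1 violates the Frechet bound on the "
                "zero-comorbidity cell"
            )
        table = np.zeros(8)
        table[0] = 1.0 - p.sum()
        for i, pi in enumerate(p):
            table[1 << (2 - i)] = pi  # patterns are (dm, dysl, hta) bits
        return table
    # degenerate marginals short-circuit the solve
    if np.any(p == 0) or np.any(p == 1):
        fixed = p.copy()
        free = (p > 0) & (p < 1)
        if not free.any():
            table = np.zeros(8)
            idx = sum((1 << (2 - i)) for i in range(3) if p[i] == 1.0)
            table[idx] = 1.0
            return table
        # fall through with clipped values; solver tolerates near-degenerate
        p = np.clip(fixed, 1e-12, 1 - 1e-12)

    log_theta = math.log(theta)
    patterns = np.array(_PATTERNS, dtype=float)
    n_pairs = np.array([x[0] * x[1] + x[0] * x[2] + x[1] * x[2] for x in _PATTERNS])

    def table_for(alpha: np.ndarray) -> np.ndarray:
        logw = patterns @ alpha + log_theta * n_pairs
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def residual(alpha: np.ndarray) -> np.ndarray:
        t = table_for(alpha)
        return patterns.T @ t - p

    # coordinate-wise solve: each marginal is strictly increasing in its own
    # main effect, so 1-d bracketing converges for any theta > 0
    alpha = np.log(p / (1 - p))
    lo, hi = -60.0, 60.0
    for _ in range(500):
        r = residual(alpha)
        if np.max(np.abs(r)) < 1e-13:
            break
        for j in range(3):
            def res_j(aj: float, j=j) -> float:
                trial = alpha.copy()
                trial[j] = aj
                return float(residual(trial)[j])

            alpha[j] = optimize.brentq(res_j, lo, hi, xtol=1e-14)
    if np.max(np.abs(residual(alpha))) > 1e-9:
        raise ValueError(
            f"could not match comorbidity marginals {p.tolist()} with "
            f"pairwise odds ratio {theta}"
        )
    return table_for(alpha)


def calibrate_association(
    p1: float, p2: float, p3: float, p_none: float
) -> float:
    """Pairwise odds ratio giving P(no comorbidity) = ``p_none``.

    Solved by bisection on log(theta); raises if the target is outside the
    range attainable for the given marginals.
    """

    def none_prob(log_theta: float) -> float:
        return float(trivariate_bernoulli_table(p1, p2, p3, math.exp(log_theta))[0])

    lo, hi = -12.0, 12.0
    f_lo, f_hi = none_prob(lo) - p_none, none_prob(hi) - p_none
    if f_lo * f_hi > 0:
        raise ValueError(
            f"P(no comorbidity) = {p_none} unattainable for marginals "
            f"({p1:.3f}, {p2:.3f}, {p3:.3f}); attainable range is "
            f"[{min(none_prob(lo), none_prob(hi)):.4f}, "
            f"{max(none_prob(lo), none_prob(hi)):.4f}]"
        )
    log_theta = optimize.brentq(lambda lt: none_prob(lt) - p_none, lo, hi, xtol=1e-12)
    return math.exp(log_theta)


# -- generation --------------------------------------------------------------


def generate(
    spec: CohortSpec, seed: Optional[int] = None
) -> list[PatientRecord]:
    """Draw a synthetic cohort of ``spec.n`` patient records.

    ``seed`` overrides ``spec.seed`` when given. Identical spec + seed
    yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    female = rng.random(n) < spec.p_female
    age_cls = rng.choice(4, size=n, p=np.asarray(spec.age_class_probs))
    lohi = np.array([AGE_CLASS_RANGES[k] for k in ("40-49", "50-59", "60-69", ">=70")])
    ages = rng.integers(lohi[age_cls, 0], lohi[age_cls, 1] + 1)

    a = (spec.bmi_min - spec.bmi_mean) / spec.bmi_sd
    b = (spec.bmi_max - spec.bmi_mean) / spec.bmi_sd
    bmi = stats.truncnorm.rvs(
        a, b, loc=spec.bmi_mean, scale=spec.bmi_sd, size=n, random_state=rng
    )
    smoker = rng.random(n) < spec.p_smoker

    theta = spec.comorbidity_association
    if theta is None:
        theta = calibrate_association(
            spec.p_dm, spec.p_dysl, spec.p_hta, spec.p_no_comorbidity
        )
    table = trivariate_bernoulli_table(spec.p_dm, spec.p_dysl, spec.p_hta, theta)
    pattern_idx = rng.choice(8, size=n, p=table)
    patterns = np.array(_PATTERNS)[pattern_idx]

    u_fobt = rng.random(n)
    band_rate = dict(zip(FOUR_BAND_LABELS, spec.band_pos_rates))

    records: list[PatientRecord] = []
    for i in range(n):
        rec = PatientRecord(
            id=f"S{i + 1:06d}",
            gender=Gender.FEMALE if female[i] else Gender.MALE,
            age=int(ages[i]),
            bmi=float(round(bmi[i], 2)),
            current_smoker=bool(smoker[i]),
            dm=bool(patterns[i, 0]),
            dysl=bool(patterns[i, 1]),
            hta=bool(patterns[i, 2]),
        )
        total = compute_score(rec).total
        if spec.fobt_model == "band":
            p_pos = band_rate[assign_band(total, BandScheme.FOUR_BAND)]
        else:
            p_pos = 1.0 / (1.0 + math.exp(-(spec.logistic_intercept
                                            + spec.logistic_slope * total)))
        fobt = FOBTResult.POSITIVE if u_fobt[i] < p_pos else FOBTResult.NEGATIVE
        records.append(rec.model_copy(update={"fobt": fobt}))
    return records


# -- YAML round-trip ---------------------------------------------------------


def spec_from_yaml(path) -> CohortSpec:
    """Load a :class:`CohortSpec` from a YAML mapping of field names."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return CohortSpec(**data)


def spec_to_yaml(spec: CohortSpec, path) -> None:
    data = spec.model_dump()
    data["age_class_probs"] = list(data["age_class_probs"])
    data["band_pos_rates"] = list(data["band_pos_rates"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
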