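"""Deterministic reconstruction of the 112-patient derivation cohort.

The original per-patient data were never published, but the printed summary
tables pin the cohort down tightly: risk-band x FOBT counts, BMI-class x
FOBT counts, gender x comorbidity-count x FOBT counts, the three
comorbidity marginals, and two finer breakdowns (positives by age/BMI/
gender; comorbidity flags by BMI/FOBT/gender). This module builds one
individual-level pseudo-cohort exactly consistent with the hard constraints
and as close as possible to the finer (soft) breakdowns, by solving a small
integer program over joint category-cell counts.

The result is one member of the equivalence class of cohorts consistent
with the printed tables — not a recovery of the true records.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from . import reference as ref
from .records import FOBTResult, Gender, PatientRecord, Residence
from .scoring import BandScheme, assign_band

__all__ = ["reconstruct_reference_cohort", "reconstruction_report", "ReconstructionError"]


class ReconstructionError(RuntimeError):
    """The embedded table constraints admit no integer cohort."""


_GENDERS = ("male", "female")
_FOBT = ("positive", "negative")
_BMI_CATS = ("underweight", "normal", "overweight", "obese_I", "obese_II", "obese_III")
_AGE_CLASSES = ("40-49", "50-59", "60-69", ">=70")
#: (dm, dysl, hta) comorbidity patterns.
_PATTERNS = tuple(itertools.product((0, 1), repeat=3))

_AGE_PTS = {"40-49": 0, "50-59": 1, "60-69": 2, ">=70": 2}


def _bmi_pts(bmi_cat: str, gender: str) -> int:
    if bmi_cat in ("underweight", "normal"):
        return 0
    if bmi_cat == "overweight":
        return 1 if gender == "female" else 0
    return 1


def _cell_score(g: str, p: tuple[int, int, int], b: str, a: str, s: int) -> int:
    return (
        _AGE_PTS[a]
        + (1 if g == "male" else 0)
        + s
        + _bmi_pts(b, g)
        + min(sum(p), 2)
    )


def _solve_cell_counts() -> dict[tuple, int]:
    """Integer-program the joint category-cell counts of the pseudo-cohort.

    Hard constraints are the published band/BMI/comorbidity-count tables and
    comorbidity marginals; the finer published breakdowns enter as weighted
    L1 soft terms. Raises :class:`ReconstructionError` if the hard system is
    infeasible.
    """
    cells = [
        (g, p, f, b, a, s)
        for g in _GENDERS
        for p in _PATTERNS
        for f in _FOBT
        for b in _BMI_CATS
        for a in _AGE_CLASSES
        for s in (0, 1)
    ]
    index = {cell: i for i, cell in enumerate(cells)}
    nx = len(cells)

    hard: list[tuple[dict[int, float], float]] = []
    soft: list[tuple[dict[int, float], float, float]] = []  # coeffs, target, weight

    def select(pred) -> dict[int, float]:
        return {index[c]: 1.0 for c in cells if pred(*c)}

    # gender x comorbidity-count x FOBT (published cross-tabulation)
    for (g0, k0), (npos, nneg) in ref.GENDER_COMORBIDITY_FOBT_COUNTS.items():
        for f0, target in (("positive", npos), ("negative", nneg)):
            hard.append(
                (select(lambda g, p, f, b, a, s: g == g0 and sum(p) == k0 and f == f0),
                 float(target))
            )
    # BMI class x FOBT
    for b0, (npos, nneg) in ref.BMI_FOBT_COUNTS.items():
        for f0, target in (("positive", npos), ("negative", nneg)):
            hard.append(
                (select(lambda g, p, f, b, a, s: b == b0 and f == f0), float(target))
            )
    # risk band x FOBT
    for band0, (npos, nneg) in ref.BAND_FOBT_COUNTS.items():
        for f0, target in (("positive", npos), ("negative", nneg)):
            hard.append(
                (select(
                    lambda g, p, f, b, a, s: f == f0
                    and assign_band(_cell_score(g, p, b, a, s), BandScheme.FOUR_BAND)
                    == band0
                ), float(target))
            )
    # comorbidity marginals
    for ci, cname in enumerate(("dm", "dysl", "hta")):
        hard.append(
            (select(lambda g, p, f, b, a, s: p[ci] == 1),
             float(ref.COMORBIDITY_TOTALS[cname]))
        )

    # soft: cohort age-class counts
    for a0, target in ref.AGE_CLASS_COUNTS.items():
        soft.append(
            (select(lambda g, p, f, b, a, s: a == a0), float(target), 10.0)
        )
    # soft: smokers by gender
    for g0, target in zip(_GENDERS, ref.SMOKERS_BY_GENDER):
        soft.append(
            (select(lambda g, p, f, b, a, s: g == g0 and s == 1), float(target), 10.0)
        )
    # soft: comorbidity by gender
    for ci, cname in enumerate(("dm", "dysl", "hta")):
        for gi, g0 in enumerate(_GENDERS):
            soft.append(
                (select(lambda g, p, f, b, a, s: g == g0 and p[ci] == 1),
                 float(ref.COMORBIDITY_BY_GENDER[cname][gi]), 5.0)
            )
    # soft: positives by age class x BMI class x gender
    for a0 in _AGE_CLASSES:
        for b0 in _BMI_CATS:
            for g0 in _GENDERS:
                target = ref.POSITIVES_BY_AGE_BMI_GENDER.get((a0, b0, g0), 0)
                soft.append(
                    (select(
                        lambda g, p, f, b, a, s: f == "positive"
                        and a == a0 and b == b0 and g == g0
                    ), float(target), 2.0)
                )
    # soft: per-comorbidity counts by BMI class x FOBT x gender
    for b0 in _BMI_CATS:
        for ci, cname in enumerate(("dm", "dysl", "hta")):
            for f0 in _FOBT:
                for g0 in _GENDERS:
                    target = ref.COMORBIDITY_BY_BMI_FOBT_GENDER.get(
                        (b0, cname, f0, g0), 0
                    )
                    soft.append(
                        (select(
                            lambda g, p, f, b, a, s: b == b0 and f == f0
                            and g == g0 and p[ci] == 1
                        ), float(target), 2.0)
                    )

    nslack = 2 * len(soft)
    nvar = nx + nslack
    n_rows = len(hard) + len(soft)
    A = np.zeros((n_rows, nvar))
    rhs = np.zeros(n_rows)
    cost = np.zeros(nvar)
    for r, (coeffs, target) in enumerate(hard):
        for i, v in coeffs.items():
            A[r, i] = v
        rhs[r] = target
    for j, (coeffs, target, weight) in enumerate(soft):
        r = len(hard) + j
        for i, v in coeffs.items():
            A[r, i] = v
        # expr + u - v = target  ->  |expr - target| = u + v at optimum
        A[r, nx + 2 * j] = 1.0
        A[r, nx + 2 * j + 1] = -1.0
        rhs[r] = target
        cost[nx + 2 * j] = weight
        cost[nx + 2 * j + 1] = weight

    integrality = np.concatenate([np.ones(nx), np.zeros(nslack)])
    lb = np.zeros(nvar)
    ub = np.concatenate([np.full(nx, float(ref.COHORT_N)), np.full(nslack, np.inf)])
    res = milp(
        c=cost,
        constraints=LinearConstraint(A, rhs, rhs),
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status != 0 or res.x is None:
        raise ReconstructionError(
            "the published band/BMI/comorbidity tables admit no integer "
            f"cohort (solver status: {res.message})"
        )
    x = np.round(res.x[:nx]).astype(int)
    counts = {cells[i]: int(x[i]) for i in range(nx) if x[i] > 0}
    if sum(counts.values()) != ref.COHORT_N:
        raise ReconstructionError(
            f"reconstructed cohort has {sum(counts.values())} records, "
            f"expected {ref.COHORT_N}"
        )
    return counts


#: Deterministic within-class representative values, cycled in order.
_AGE_REPS = {
    "40-49": (45, 42, 47, 40, 44, 48, 43, 46, 41, 49),
    "50-59": (55, 52, 57, 50, 54, 58, 51, 56, 53, 59),
    "60-69": (65, 67, 62, 60, 64, 67, 68, 61, 66, 63, 69),
    ">=70": (75, 72, 77, 70, 88, 78, 71, 76, 74, 79, 73, 80, 82, 85),
}
_BMI_REPS = {
    "underweight": (17.60,),
    "normal": (22.40, 23.10, 19.80, 24.50, 21.30, 18.90),
    "overweight": (27.90, 26.30, 28.50, 25.40, 29.10, 26.30),
    "obese_I": (31.20, 33.40, 30.50, 32.70, 34.10),
    "obese_II": (36.20, 38.50, 35.40, 37.80, 39.20),
    "obese_III": (41.20, 40.50, 40.10),
}


@lru_cache(maxsize=1)
def _reconstruct_cached() -> tuple[PatientRecord, ...]:
    counts = _solve_cell_counts()
    age_cycles = {a: itertools.cycle(reps) for a, reps in _AGE_REPS.items()}
    bmi_cycles = {b: itertools.cycle(reps) for b, reps in _BMI_REPS.items()}
    records: list[PatientRecord] = []
    # fixed iteration order keeps the expansion byte-identical across runs
    for cell in sorted(counts, key=str):
        g, p, f, b, a, s = cell
        for _ in range(counts[cell]):
            i = len(records) + 1
            records.append(
                PatientRecord(
                    id=f"R{i:03d}",
                    gender=Gender(g),
                    age=next(age_cycles[a]),
                    bmi=next(bmi_cycles[b]),
                    current_smoker=bool(s),
                    dm=bool(p[0]),
                    dysl=bool(p[1]),
                    hta=bool(p[2]),
                    fobt=FOBTResult(f),
                    # published split: 106 urban / 6 rural (descriptive only)
                    residence=Residence.RURAL if i > ref.COHORT_N - 6 else Residence.URBAN,
                )
            )
    return tuple(records)


def reconstruct_reference_cohort() -> list[PatientRecord]:
    """Return the deterministic 112-record pseudo-cohort.

    Satisfies, exactly: the band x FOBT table, the BMI-class x FOBT table,
    the gender x comorbidity-count x FOBT table, gender split 51 M / 61 F,
    comorbidity marginals DM 25 / DYSL 77 / HTA 78, and 19 records with no
    comorbidity. The finer published breakdowns are matched as closely as
    those constraints permit (see :func:`reconstruction_report`).
    """
    return list(_reconstruct_cached())


def reconstruction_report(records: list[PatientRecord] | None = None) -> dict:
    """Achieved-versus-published comparison for the reconstruction.

    Returns a dict with per-table cell deviations for the soft constraints
    and booleans for the hard ones; total_soft_deviation is the summed
    absolute cell difference across the soft tables.
    """
    from .analytics import cohort_frame

    if records is None:
        records = reconstruct_reference_cohort()
    frame = cohort_frame(records)

    def count(mask) -> int:
        return int(mask.sum())

    report: dict = {"hard": {}, "soft": {}}
    hard_ok = True

    band = frame["total"].map(lambda t: assign_band(t, BandScheme.FOUR_BAND))
    for band0, (npos, nneg) in ref.BAND_FOBT_COUNTS.items():
        got = (
            count((band == band0) & (frame["fobt"] == "positive")),
            count((band == band0) & (frame["fobt"] == "negative")),
        )
        report["hard"][f"band {band0} pos/neg"] = {
            "published": (npos, nneg), "achieved": got, "ok": got == (npos, nneg)
        }
        hard_ok &= got == (npos, nneg)
    for b0, (npos, nneg) in ref.BMI_FOBT_COUNTS.items():
        got = (
            count((frame["bmi_category"] == b0) & (frame["fobt"] == "positive")),
            count((frame["bmi_category"] == b0) & (frame["fobt"] == "negative")),
        )
        report["hard"][f"bmi {b0} pos/neg"] = {
            "published": (npos, nneg), "achieved": got, "ok": got == (npos, nneg)
        }
        hard_ok &= got == (npos, nneg)
    for (g0, k0), (npos, nneg) in ref.GENDER_COMORBIDITY_FOBT_COUNTS.items():
        got = (
            count((frame["gender"] == g0) & (frame["n_comorbidities"] == k0)
                  & (frame["fobt"] == "positive")),
            count((frame["gender"] == g0) & (frame["n_comorbidities"] == k0)
                  & (frame["fobt"] == "negative")),
        )
        report["hard"][f"{g0} x {k0} comorbidities pos/neg"] = {
            "published": (npos, nneg), "achieved": got, "ok": got == (npos, nneg)
        }
        hard_ok &= got == (npos, nneg)
    for cname, target in ref.COMORBIDITY_TOTALS.items():
        got = count(frame[cname])
        report["hard"][f"{cname} total"] = {
            "published": target, "achieved": got, "ok": got == target
        }
        hard_ok &= got == target
    report["hard_all_ok"] = bool(hard_ok)

    total_dev = 0
    devs: dict[str, dict] = {}
    for a0, target in ref.AGE_CLASS_COUNTS.items():
        got = count(frame["age_class"] == a0)
        if got != target:
            devs[f"age class {a0}"] = {"published": target, "achieved": got}
        total_dev += abs(got - target)
    for gi, g0 in enumerate(_GENDERS):
        target = ref.SMOKERS_BY_GENDER[gi]
        got = count((frame["gender"] == g0) & frame["current_smoker"])
        if got != target:
            devs[f"smokers {g0}"] = {"published": target, "achieved": got}
        total_dev += abs(got - target)
    for cname in ("dm", "dysl", "hta"):
        for gi, g0 in enumerate(_GENDERS):
            target = ref.COMORBIDITY_BY_GENDER[cname][gi]
            got = count((frame["gender"] == g0) & frame[cname])
            if got != target:
                devs[f"{cname} {g0}"] = {"published": target, "achieved": got}
            total_dev += abs(got - target)
    for a0 in _AGE_CLASSES:
        for b0 in _BMI_CATS:
            for g0 in _GENDERS:
                target = ref.POSITIVES_BY_AGE_BMI_GENDER.get((a0, b0, g0), 0)
                got = count(
                    (frame["fobt"] == "positive") & (frame["age_class"] == a0)
                    & (frame["bmi_category"] == b0) & (frame["gender"] == g0)
                )
                if got != target:
                    devs[f"positives {a0}/{b0}/{g0}"] = {
                        "published": target, "achieved": got
                    }
                total_dev += abs(got - target)
    for (b0, cname, f0, g0), target in _iter_comorbidity_breakdown():
        got = count(
            (frame["bmi_category"] == b0) & (frame["fobt"] == f0)
            & (frame["gender"] == g0) & frame[cname]
        )
        if got != target:
            devs[f"{cname} {b0}/{f0}/{g0}"] = {"published": target, "achieved": got}
        total_dev += abs(got - target)

    report["soft"] = devs
    report["total_soft_deviation"] = int(total_dev)
    return report


def _iter_comorbidity_breakdown():
    for b0 in _BMI_CATS:
        for cname in ("dm", "dysl", "hta"):
            for f0 in _FOBT:
                for g0 in _GENDERS:
                    yield (b0, cname, f0, g0), ref.COMORBIDITY_BY_BMI_FOBT_GENDER.get(
                        (b0, cname, f0, g0), 0
                    )
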