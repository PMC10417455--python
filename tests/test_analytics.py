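"""Unit, oracle and property tests for the cohort analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fobtscore import (
    BandScheme,
    FOBTResult,
    Gender,
    PatientRecord,
    band_summary,
    crosstab,
    descriptive_stats,
    pooled_two_sample_t,
    risk_estimates,
)


# -- independent oracles (direct formula evaluation) -------------------------

def oracle_descriptives(values):
    """Spreadsheet-replica formulas, evaluated directly."""
    x = sorted(values)
    n = len(x)
    mean = sum(x) / n
    med = x[n // 2] if n % 2 else (x[n // 2 - 1] + x[n // 2]) / 2
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    skew = n / ((n - 1) * (n - 2)) * sum(((v - mean) / sd) ** 3 for v in x)
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)
    ci = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return dict(mean=mean, median=med, mode=mode, sd=sd, skewness=skew,
                range=x[-1] - x[0], minimum=x[0], maximum=x[-1], count=n,
                confidence_level_95=ci)


def oracle_pooled_t(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def oracle_clopper_pearson(k, n):
    lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
    return lo, hi


# A fixed 30-value synthetic age vector (ages 40-88 with repeats).
AGE_VECTOR = [
    40, 44, 47, 51, 52, 55, 55, 58, 60, 61, 62, 63, 64, 65, 65,
    66, 67, 67, 67, 68, 70, 71, 72, 74, 75, 77, 79, 81, 84, 88,
]


class TestDescriptiveStats:
    def test_symmetric_sample(self):
        d = descriptive_stats([1, 2, 3, 4, 5])
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.median == 3 and d.mean == 3

    def test_unique_mode(self):
        d = descriptive_stats([2, 2, 3])
        assert d.mode == 2 and d.mean == pytest.approx(7 / 3)
        assert not d.multimodal

    def test_mode_tie_reports_smallest_and_flags(self):
        d = descriptive_stats([1, 1, 2, 2, 5])
        assert d.mode == 1 and d.multimodal

    def test_matches_spreadsheet_oracle_on_fixed_vector(self):
        d = descriptive_stats(AGE_VECTOR)
        o = oracle_descriptives(AGE_VECTOR)
        for field, expected in o.items():
            assert getattr(d, field) == pytest.approx(expected, abs=1e-9), field

    def test_skewness_matches_adjusted_fisher_pearson_reference(self):
        # library cross-check: scipy's bias-corrected skewness is the same
        # adjusted Fisher-Pearson coefficient
        d = descriptive_stats(AGE_VECTOR)
        assert d.skewness == pytest.approx(
            float(stats.skew(AGE_VECTOR, bias=False)), abs=1e-12
        )

    def test_degenerate_constant_sample(self):
        d = descriptive_stats([4.0, 4.0, 4.0])
        assert d.sd == 0.0 and d.skewness is None

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            descriptive_stats([1.0])

    @given(
        values=st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=40
        ),
        shift=st.floats(min_value=-100, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariance_and_location_equivariance(
        self, values, shift, seed
    ):
        base = descriptive_stats(values)
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(values))
        permuted = descriptive_stats(perm)
        # invariant up to floating-point summation order
        for field in ("mean", "median", "mode", "sd", "range",
                      "minimum", "maximum", "confidence_level_95"):
            assert getattr(permuted, field) == pytest.approx(
                getattr(base, field), abs=1e-9, rel=1e-9
            ), field
        assert permuted.count == base.count
        if base.skewness is not None:
            assert permuted.skewness == pytest.approx(
                base.skewness, abs=1e-9, rel=1e-9
            )
        shifted = descriptive_stats([v + shift for v in values])
        assert shifted.mean == pytest.approx(base.mean + shift, abs=1e-6)
        assert shifted.median == pytest.approx(base.median + shift, abs=1e-6)
        assert shifted.minimum == pytest.approx(base.minimum + shift, abs=1e-6)
        assert shifted.maximum == pytest.approx(base.maximum + shift, abs=1e-6)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-6)
        assert shifted.range == pytest.approx(base.range, abs=1e-6)


class TestPooledT:
    def test_reference_band_counts(self):
        res = pooled_two_sample_t([3, 2, 7, 8], [28, 18, 34, 12])
        assert res.t == pytest.approx(-3.49663, abs=5e-6)
        assert res.df == 6
        assert res.p_two_tailed == pytest.approx(2 * res.p_one_tailed)

    def test_identical_samples_give_zero_t(self):
        res = pooled_two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_degenerate_variance(self):
        res = pooled_two_sample_t([2, 2], [2, 2])
        assert res.t == 0.0 and res.p_two_tailed == 1.0
        with pytest.raises(ValueError, match="zero pooled variance"):
            pooled_two_sample_t([2, 2], [3, 3])

    def test_small_sample_matches_textbook_oracle(self):
        res = pooled_two_sample_t([1, 2], [3, 4])
        t, df = oracle_pooled_t([1, 2], [3, 4])
        assert res.t == pytest.approx(t, abs=1e-9) and res.df == df

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_oracle_equivalence_and_sign_symmetry(self, a, b):
        va = sum((v - sum(a) / len(a)) ** 2 for v in a)
        vb = sum((v - sum(b) / len(b)) ** 2 for v in b)
        if va + vb == 0:  # degenerate handled separately
            return
        res = pooled_two_sample_t(a, b)
        t, df = oracle_pooled_t(a, b)
        assert res.t == pytest.approx(t, abs=1e-9, rel=1e-9)
        assert res.df == df
        swapped = pooled_two_sample_t(b, a)
        assert swapped.t == pytest.approx(-res.t, abs=1e-9, rel=1e-9)
        assert swapped.p_two_tailed == pytest.approx(res.p_two_tailed, rel=1e-9)


def _tiny_cohort():
    def rec(i, gender, age, bmi, smoker, dm, fobt):
        return PatientRecord(
            id=f"t{i}", gender=gender, age=age, bmi=bmi, current_smoker=smoker,
            dm=dm, dysl=False, hta=False, fobt=fobt,
        )

    return [
        rec(1, Gender.MALE, 67, 31.0, True, True, FOBTResult.POSITIVE),
        rec(2, Gender.FEMALE, 45, 22.0, False, False, FOBTResult.NEGATIVE),
        rec(3, Gender.FEMALE, 62, 27.0, False, True, FOBTResult.NEGATIVE),
        rec(4, Gender.MALE, 55, 26.0, False, False, FOBTResult.NEGATIVE),
    ]


class TestBandSummary:
    def test_single_positive_max_score(self):
        rec = PatientRecord(
            id="p", gender=Gender.MALE, age=70, bmi=32.0, current_smoker=True,
            dm=True, dysl=True, hta=True, fobt=FOBTResult.POSITIVE,
        )
        bs = band_summary([rec], BandScheme.FOUR_BAND)
        assert bs.bands[">=6"].pos_rate == 100.0
        assert bs.bands["0-3"].pos_rate is None  # empty band undefined

    def test_counts_conserved(self):
        bs = band_summary(_tiny_cohort(), BandScheme.THREE_BAND)
        assert bs.n == 4 and bs.total_positives == 1

    def test_missing_fobt_rejected(self):
        rec = PatientRecord(
            id="m", gender=Gender.MALE, age=70, bmi=32.0, current_smoker=False,
            dm=False, dysl=False, hta=False,
        )
        with pytest.raises(ValueError, match="no FOBT result"):
            band_summary([rec])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            band_summary([])


class TestRiskEstimates:
    def test_point_rates_match_band_summary(self):
        bs = band_summary(_tiny_cohort(), BandScheme.FOUR_BAND)
        est = risk_estimates(bs)
        for lab, bc in bs.bands.items():
            if bc.n:
                assert est[lab].rate == pytest.approx(bc.pos_rate)
            else:
                assert est[lab].rate is None

    @pytest.mark.parametrize("k,n", [(8, 20), (0, 15), (15, 15), (3, 31)])
    def test_clopper_pearson_matches_beta_quantile_oracle(self, k, n):
        from fobtscore.analytics import BandCounts, BandSummary

        bs = BandSummary(
            scheme=BandScheme.FOUR_BAND,
            bands={"0-3": BandCounts(n_pos=k, n_neg=n - k)},
        )
        est = risk_estimates(bs)["0-3"]
        lo, hi = oracle_clopper_pearson(k, n)
        assert est.ci_low == pytest.approx(100 * lo, abs=1e-9)
        assert est.ci_high == pytest.approx(100 * hi, abs=1e-9)
        if k == 0:
            assert est.ci_low == 0.0


class TestCrosstab:
    def test_single_record_margins(self):
        cohort = _tiny_cohort()[:1]
        table = crosstab(cohort, "gender", "fobt")
        assert table.to_numpy().sum() == 1

    def test_grand_total_equals_cohort_size(self, reference_cohort):
        for rows, cols in [
            ("bmi_category", "fobt"),
            (["n_comorbidities", "gender"], "fobt"),
            ("age_class", ["gender", "fobt"]),
        ]:
            table = crosstab(reference_cohort, rows, cols)
            assert table.to_numpy().sum() == len(reference_cohort)

    def test_cohort_percent_convention(self, reference_cohort):
        pct = crosstab(reference_cohort, "bmi_category", "fobt", percent="cohort")
        assert pct.to_numpy().sum() == pytest.approx(100.0)
        # published convention: overweight cell is 48.21% of the cohort
        assert pct.loc["overweight"].sum() == pytest.approx(48.21, abs=0.005)

    def test_row_percent_convention(self, reference_cohort):
        pct = crosstab(reference_cohort, "bmi_category", "fobt", percent="row")
        sums = pct.sum(axis=1).dropna()
        assert np.allclose(sums, 100.0)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            crosstab(_tiny_cohort(), "eye_colour", "fobt")
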