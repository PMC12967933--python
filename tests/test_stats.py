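"""ROR arithmetic, signal criteria, logistic adjustment, baseline table."""
import math

import numpy as np
import pandas as pd
import pytest

from ddisignal.cohort import build_cohort
from ddisignal.events import code_frame
from ddisignal.stats import (ContingencyTable, add_age_band, baseline_table,
                             evaluate_signal_values, fit_logistic, make_table,
                             ror)
from tests.conftest import make_reports


def oracle_ror(a, b, c, d):
    """Independent transcription of the closed-form ROR / SE / Wald CI."""
    if min(a, b, c, d) == 0:
        return None
    estimate = (a / b) / (c / d)
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    return (estimate, se,
            math.exp(math.log(estimate) - 1.96 * se),
            math.exp(math.log(estimate) + 1.96 * se))


class TestRor:
    def test_symmetric_table_has_unit_ror_and_no_signal(self):
        res = ror(ContingencyTable(5, 5, 5, 5))
        assert res.ror == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high
        assert not res.signal

    def test_worked_example_matches_independent_evaluation(self):
        res = ror(ContingencyTable(10, 90, 50, 950))
        est, se, lo, hi = oracle_ror(10, 90, 50, 950)
        assert res.ror == pytest.approx(est, rel=1e-12)
        assert res.ror == pytest.approx(19 / 9)  # 2.1111...
        assert res.se_ln_ror == pytest.approx(se, rel=1e-12)
        assert (res.ci_low, res.ci_high) == pytest.approx((lo, hi), rel=1e-12)
        assert (round(res.ci_low, 4), round(res.ci_high, 4)) == \
            (1.0353, 4.3049)
        assert res.signal

    def test_zero_cell_is_undefined_not_an_error(self):
        res = ror(ContingencyTable(0, 10, 5, 5))
        assert math.isnan(res.ror) and math.isnan(res.ci_low)
        assert not res.signal

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_swapping_rows_inverts_the_estimate_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            fwd = ror(ContingencyTable(a, b, c, d))
            rev = ror(ContingencyTable(c, d, a, b))
            assert rev.ror == pytest.approx(1.0 / fwd.ror, rel=1e-12)

    def test_scaling_all_cells_preserves_ror_and_narrows_ci(self):
        base = ror(ContingencyTable(10, 90, 50, 950))
        scaled = ror(ContingencyTable(50, 450, 250, 4750))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        assert scaled.ci_high / scaled.ci_low < base.ci_high / base.ci_low


class TestSignalCriterion:
    @pytest.mark.parametrize("a,ci_low,expected", [
        (3, 1.01, True),
        (2, 5.0, False),       # below the case-count threshold
        (100, 1.0, False),     # strict inequality on the CI bound
        (3, math.nan, False),
    ])
    def test_threshold(self, a, ci_low, expected):
        assert evaluate_signal_values(a, ci_low) is expected


def _records_from_2x2(a, b, c, d, **extra_cols):
    rows = ([{"outcome": 1, "exposure": 1}] * a
            + [{"outcome": 0, "exposure": 1}] * b
            + [{"outcome": 1, "exposure": 0}] * c
            + [{"outcome": 0, "exposure": 0}] * d)
    df = pd.DataFrame(rows)
    for name, value in extra_cols.items():
        df[name] = value
    return df


class TestFitLogistic:
    def test_saturated_fit_recovers_the_sample_odds_ratio(self):
        rec = _records_from_2x2(10, 90, 50, 950)
        res = fit_logistic(rec)
        assert res.converged
        assert res.aor == pytest.approx(19 / 9, rel=1e-6)

    def test_constant_covariate_dropped_without_changing_the_estimate(self):
        rec = _records_from_2x2(10, 90, 50, 950, site="A")
        with pytest.warns(UserWarning, match="constant"):
            res = fit_logistic(rec, covariates=["site"])
        assert res.aor == pytest.approx(19 / 9, rel=1e-6)

    def test_perfect_separation_reported_not_raised(self):
        rec = _records_from_2x2(20, 0, 0, 20)
        res = fit_logistic(rec)
        assert not res.converged
        assert res.message

    def test_constant_outcome_is_an_error(self):
        rec = _records_from_2x2(0, 10, 0, 10)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(rec)

    def test_single_arm_is_an_error(self):
        rec = _records_from_2x2(5, 5, 0, 0)
        with pytest.raises(ValueError, match="arm"):
            fit_logistic(rec)

    def test_missing_covariate_level_is_explicit_not_dropped(self):
        rec = _records_from_2x2(20, 80, 30, 170)
        sexes = ["F", "M", None] * (len(rec) // 3) + ["F"] * (len(rec) % 3)
        rec["sex"] = sexes
        res = fit_logistic(rec, covariates=["sex"])
        assert res.converged
        assert res.n_used == len(rec)  # no complete-case deletion


def _coded_cohort(dictionary, hem, ns, rows):
    cohort = build_cohort(make_reports(rows), dictionary)
    cohort.data = add_age_band(code_frame(cohort.data, hem, ns))
    return cohort


class TestMakeTable:
    def test_counts_match_hand_enumeration(self, dictionary, hem_terms,
                                           ns_terms):
        rows = (
            [{"drugs": ("apixaban", "sertraline"),
              "reactions": ("Epistaxis",)}] * 3
            + [{"drugs": ("apixaban", "sertraline"),
                "reactions": ("Nausea",)}] * 2
            + [{"drugs": ("apixaban",), "reactions": ("Epistaxis",)}] * 4
            + [{"drugs": ("apixaban",), "reactions": ("Nausea",)}] * 6
        )
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms, rows)
        t = make_table(cohort, {}, "any_hemorrhage", {})
        assert (t.a, t.b, t.c, t.d) == (3, 2, 4, 6)

    def test_empty_exposure_stratum_gives_zero_cells(self, dictionary,
                                                     hem_terms, ns_terms):
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms,
                               [{"drugs": ("apixaban",),
                                 "reactions": ("Epistaxis",)}])
        t = make_table(cohort, {"doac": "edoxaban"}, "any_hemorrhage", {})
        assert (t.a, t.b) == (0, 0)

    def test_pair_stratum_exposed_total_is_the_stratum_size(
            self, dictionary, hem_terms, ns_terms):
        rows = ([{"drugs": ("apixaban", "paroxetine"),
                  "reactions": ("Epistaxis",)}] * 5
                + [{"drugs": ("rivaroxaban", "paroxetine"),
                    "reactions": ("Nausea",)}] * 2
                + [{"drugs": ("apixaban",), "reactions": ("Nausea",)}] * 3)
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms, rows)
        t = make_table(cohort, {"doac": "apixaban",
                                "antidepressant": "paroxetine"},
                       "any_hemorrhage", {"doac": "apixaban"})
        assert t.n_exposed == 5
        assert t.n_comparator == 3


class TestBaselineTable:
    def _rows(self, n_inter, n_mono, inter_age=80.0, mono_age=70.0):
        rows = []
        for i in range(n_inter):
            rows.append({"drugs": ("apixaban", "sertraline"),
                         "age_years": inter_age + (i % 3),
                         "sex": "F" if i % 2 else "M"})
        for i in range(n_mono):
            rows.append({"drugs": ("apixaban",),
                         "age_years": mono_age + (i % 3),
                         "sex": "F" if i % 2 else "M"})
        return rows

    def test_identical_distributions_give_p_one(self, dictionary, hem_terms,
                                                ns_terms):
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms,
                               self._rows(8, 8, inter_age=70.0))
        base = baseline_table(cohort)
        assert base.pvalues["sex"] == pytest.approx(1.0)
        assert base.pvalues["age_band"] == pytest.approx(1.0)

    def test_older_interaction_group_shows_higher_median(
            self, dictionary, hem_terms, ns_terms):
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms,
                               self._rows(10, 10))
        base = baseline_table(cohort)
        med = base.continuous.set_index("group")["median"]
        assert med["interaction"] > med["non_interaction"]

    def test_age_band_counts_plus_missing_partition_each_group(
            self, dictionary, hem_terms, ns_terms):
        rows = self._rows(6, 9)
        rows[0]["age_years"] = float("nan")
        rows[8]["age_years"] = float("nan")
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms, rows)
        base = baseline_table(cohort)
        bands = base.categorical[base.categorical["variable"] == "age_band"]
        for group, expected in (("interaction", 6), ("non_interaction", 9)):
            assert bands[f"n_{group}"].sum() == expected

    def test_empty_group_is_an_error(self, dictionary, hem_terms, ns_terms):
        cohort = _coded_cohort(dictionary, hem_terms, ns_terms,
                               [{"drugs": ("apixaban",)}])
        with pytest.raises(ValueError, match="interaction"):
            baseline_table(cohort)
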