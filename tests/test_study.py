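"""Full study grid, PT breakdown, export and configuration round trip."""
import json
import math

import numpy as np
import pytest

from ddisignal.drugs import ANTIDEPRESSANTS
from ddisignal.simulate import (SimulationConfig, default_interaction_log_or,
                                simulate_reports)
from ddisignal.study import (InteractionSignalStudy, StudyConfig, pt_breakdown,
                             run_study)
from tests.conftest import make_reports


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(n_reports=30_000, ad_given_doac_prob=0.05)
    reports, truth = simulate_reports(cfg, seed=11)
    model = InteractionSignalStudy(reports)
    return model, model.fit(), truth


class TestGrid:
    def test_pair_a_cells_sum_to_overall_a_cell(self, fitted):
        _, results, _ = fitted
        sig = results.signals
        for outcome in ("any_hemorrhage", "ns_hemorrhage"):
            sub = sig[sig["outcome"] == outcome]
            overall_a = sub.loc[sub["level"] == "overall", "a"].item()
            assert sub.loc[sub["level"] == "pair", "a"].sum() == overall_a
            assert sub.loc[sub["level"] == "ad_class", "a"].sum() == overall_a
            assert sub.loc[sub["level"] == "antidepressant", "a"].sum() \
                == overall_a

    def test_every_ns_case_is_also_an_any_hemorrhage_case(self, fitted):
        model, _, _ = fitted
        df = model.cohort.data
        assert (df.loc[df["ns_hemorrhage"], "any_hemorrhage"]).all()

    def test_rows_below_three_cases_never_flag(self, fitted):
        _, results, _ = fitted
        sparse = results.signals[results.signals["a"] < 3]
        assert not sparse["signal"].any()

    def test_comparator_policy_changes_pair_rows_only(self):
        cfg = SimulationConfig(n_reports=8_000, ad_given_doac_prob=0.05)
        reports, _ = simulate_reports(cfg, seed=5)
        model = InteractionSignalStudy(reports)
        same = model.fit(comparator_policy="same_doac_monotherapy",
                         adjusted="none").signals
        pooled = model.fit(comparator_policy="all_doac_monotherapy",
                           adjusted="none").signals
        for level in ("overall", "ad_class", "antidepressant"):
            left = same[same["level"] == level].reset_index(drop=True)
            right = pooled[pooled["level"] == level].reset_index(drop=True)
            assert left.equals(right)
        pair_same = same[same["level"] == "pair"]
        pair_pooled = pooled[pooled["level"] == "pair"]
        assert not pair_same[["c", "d"]].equals(pair_pooled[["c", "d"]])

    def test_injected_pair_effect_dominates_pair_rors(self):
        theta = {k: 0.0 for k in default_interaction_log_or()}
        theta[("apixaban", "paroxetine")] = math.log(8.0)
        cfg = SimulationConfig(
            n_reports=40_000, ad_given_doac_prob=0.10,
            interaction_log_or=theta, other_drug_prob=0.0)
        reports, _ = simulate_reports(cfg, seed=21)
        results = InteractionSignalStudy(reports).fit(
            adjusted="none", outcomes=("any_hemorrhage",), levels=("pair",))
        pairs = results.signals.dropna(subset=["ror"])
        best = pairs.loc[pairs["ror"].idxmax()]
        assert (best["doac"], best["antidepressant"]) == \
            ("apixaban", "paroxetine")
        assert best["signal"]

    def test_zero_report_input_yields_empty_grids_with_warning(self):
        reports, _ = simulate_reports(SimulationConfig(n_reports=0), seed=0)
        with pytest.warns(UserWarning, match="interaction group is empty"):
            model = InteractionSignalStudy(reports)
        results = model.fit(adjusted="none")
        assert (results.signals["a"] == 0).all()
        assert not results.signals["signal"].any()
        assert results.baseline is None


class TestPtBreakdown:
    CASE_MIX = [("Cerebral hemorrhage", 23), ("Haemorrhagic stroke", 13),
                ("Hemorrhage intracranial", 10), ("Cerebral haematoma", 7),
                ("Central nervous system hemorrhage", 4),
                ("Subarachnoid hemorrhage", 2), ("Cerebellar haematoma", 2)]

    def _cohort(self, dictionary, hem, ns, rows):
        from ddisignal.cohort import build_cohort
        from ddisignal.events import code_frame
        from ddisignal.stats import add_age_band
        cohort = build_cohort(make_reports(rows), dictionary)
        cohort.data = add_age_band(code_frame(cohort.data, hem, ns))
        return cohort

    def test_sixty_one_case_mix_percentages(self, dictionary, hem_terms,
                                            ns_terms):
        rows = []
        for pt, k in self.CASE_MIX:
            rows += [{"drugs": ("apixaban", "sertraline"),
                      "reactions": (pt,)}] * k
        cohort = self._cohort(dictionary, hem_terms, ns_terms, rows)
        table = pt_breakdown(cohort, ns_terms)
        assert table.attrs["case_total"] == 61
        top = table.set_index("pt")
        assert top.loc["Cerebral hemorrhage", "n"] == 23
        assert top.loc["Cerebral hemorrhage", "pct"] == pytest.approx(
            37.7, abs=0.05)
        assert top.loc["Haemorrhagic stroke", "pct"] == pytest.approx(
            21.3, abs=0.05)

    def test_no_ns_cases_gives_empty_table(self, dictionary, hem_terms,
                                           ns_terms):
        cohort = self._cohort(dictionary, hem_terms, ns_terms,
                              [{"drugs": ("apixaban", "sertraline"),
                                "reactions": ("Epistaxis",)}])
        table = pt_breakdown(cohort, ns_terms)
        assert len(table) == 0 and table.attrs["case_total"] == 0

    def test_two_distinct_ns_terms_count_one_case(self, dictionary, hem_terms,
                                                  ns_terms):
        cohort = self._cohort(dictionary, hem_terms, ns_terms, [
            {"drugs": ("apixaban", "sertraline"),
             "reactions": ("Cerebral hemorrhage", "Subarachnoid hemorrhage")}])
        table = pt_breakdown(cohort, ns_terms)
        assert table.attrs["case_total"] == 1
        assert set(table["n"]) == {1} and len(table) == 2


class TestExport:
    def test_rerun_with_identical_config_is_byte_identical(self, fitted,
                                                           tmp_path):
        _, results, _ = fitted
        first = results.save(tmp_path / "a")
        second = results.save(tmp_path / "b")
        for key in first:
            assert first[key].read_bytes() == second[key].read_bytes()

    def test_metadata_round_trips_the_config(self, tmp_path):
        reports, _ = simulate_reports(
            SimulationConfig(n_reports=3_000, ad_given_doac_prob=0.05), seed=2)
        cfg = StudyConfig(out_dir=str(tmp_path / "out"), adjusted="none")
        run_study(cfg, reports=reports)
        meta = json.loads((tmp_path / "out" / "run_metadata.json").read_text())
        assert meta["config"] == cfg.to_dict()
        for name in ("baseline.csv", "signals_overall.csv", "signals_ns.csv",
                     "pt_breakdown.csv"):
            assert (tmp_path / "out" / name).exists()

    def test_forest_plot_returns_axes(self, fitted):
        _, results, _ = fitted
        import matplotlib
        matplotlib.use("Agg")
        ax = results.plot_forest(outcome="any_hemorrhage", level="ad_class")
        assert ax.get_xscale() == "log"

    def test_invalid_comparator_policy_rejected(self):
        with pytest.raises(ValueError, match="comparator_policy"):
            StudyConfig(comparator_policy="nonsense")
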