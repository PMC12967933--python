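"""Generator determinism, duplicate/dedup truth, estimand consistency."""
import math

import numpy as np
import pandas as pd
import pytest

from ddisignal.cohort import build_cohort
from ddisignal.dedup import deduplicate
from ddisignal.simulate import (SimulationConfig, default_interaction_log_or,
                                generate, recovery_report, simulate_reports)
from ddisignal.study import InteractionSignalStudy


def flat_covariates():
    """Covariate model with no outcome effects and no exposure shift."""
    base = SimulationConfig()
    return dict(
        age_band_probs_exposed=dict(base.age_band_probs),
        sex_female_prob_exposed=base.sex_female_prob,
        reporter_probs_exposed=dict(base.reporter_probs),
        covariate_log_odds={"age_band": {}, "sex": {}, "reporter_type": {}},
    )


class TestDeterminism:
    def test_identical_config_and_seed_give_byte_identical_files(self,
                                                                 tmp_path):
        cfg = SimulationConfig(n_reports=500)
        paths_a, _ = generate(cfg, seed=9, out_dir=tmp_path / "a")
        paths_b, _ = generate(cfg, seed=9, out_dir=tmp_path / "b")
        for name in ("demo", "drug", "reac", "truth"):
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        cfg = SimulationConfig(n_reports=500)
        paths_a, _ = generate(cfg, seed=1, out_dir=tmp_path / "a")
        paths_b, _ = generate(cfg, seed=2, out_dir=tmp_path / "b")
        assert paths_a["demo"].read_bytes() != paths_b["demo"].read_bytes()

    def test_zero_reports_gives_header_only_files_and_empty_truth(self,
                                                                  tmp_path):
        paths, truth = generate(SimulationConfig(n_reports=0), seed=0,
                                out_dir=tmp_path)
        assert truth.empty
        for name in ("demo", "drug", "reac"):
            assert len(paths[name].read_text().splitlines()) == 1


class TestDuplicates:
    def test_duplicate_rate_expectation_and_dedup_cardinality(self):
        cfg = SimulationConfig(n_reports=1_000, duplicate_rate=0.2)
        reports, truth = simulate_reports(cfg, seed=4)
        assert truth["caseid"].nunique() == 1_000
        n_extra = len(reports) - 1_000
        sd = math.sqrt(1_000 * 0.2 * 0.8)
        assert abs(n_extra - 200) < 4 * sd
        deduped = deduplicate(reports)
        assert len(deduped) == 1_000
        assert deduped["caseid"].is_unique

    def test_surviving_primaryid_matches_generator_truth(self):
        cfg = SimulationConfig(n_reports=2_000, duplicate_rate=0.4,
                               duplicate_tie_rate=0.5)
        reports, truth = simulate_reports(cfg, seed=8)
        deduped = deduplicate(reports)
        assert set(deduped["primaryid"]) == set(truth["primaryid"])


class TestTruthConsistency:
    def test_cohort_assignment_recovers_generator_group_labels(self,
                                                               dictionary):
        cfg = SimulationConfig(n_reports=5_000, ad_given_doac_prob=0.05)
        reports, truth = simulate_reports(cfg, seed=13)
        cohort = build_cohort(deduplicate(reports), dictionary)
        got = cohort.data.set_index("caseid")["group"]
        want = truth.set_index("caseid")["group"]
        kept = want[want != "excluded"]
        assert len(got) == len(kept)
        assert (got.loc[kept.index] == kept).all()
        assert cohort.exclusions.get("other_concomitant", 0) == \
            (want == "excluded").sum()

    def test_empirical_odds_ratio_converges_to_configured_value(self):
        theta = {k: math.log(2.5) for k in default_interaction_log_or()}
        cfg = SimulationConfig(
            n_reports=60_000, ad_given_doac_prob=0.3, other_drug_prob=0.0,
            interaction_log_or=theta, **flat_covariates())
        _, truth = simulate_reports(cfg, seed=17)
        inter = truth[truth["group"] == "interaction"]
        mono = truth[truth["group"] == "non_interaction"]
        a = inter["bleed"].sum()
        b = len(inter) - a
        c = mono["bleed"].sum()
        d = len(mono) - c
        est = (a * d) / (b * c)
        assert abs(math.log(est) - math.log(2.5)) < 0.1

    def test_null_generator_gives_near_unit_overall_ror(self):
        cfg = SimulationConfig(
            n_reports=200_000, ad_given_doac_prob=0.05,
            interaction_log_or={k: 0.0 for k in default_interaction_log_or()},
            **flat_covariates())
        reports, _ = simulate_reports(cfg, seed=19)
        results = InteractionSignalStudy(reports).fit(
            adjusted="none", outcomes=("any_hemorrhage",), levels=("overall",))
        row = results.signals.iloc[0]
        assert abs(math.log(row["ror"])) < 0.1


class TestValidation:
    @pytest.mark.parametrize("bad,match", [
        ({"doac_probs": {"rivaroxaban": 0.7, "apixaban": 0.7,
                         "edoxaban": 0.0, "dabigatran": 0.0}}, "doac_probs"),
        ({"duplicate_rate": 1.5}, "duplicate_rate"),
        ({"ad_given_doac_prob": -0.1}, "ad_given_doac_prob"),
        ({"interaction_log_or": {("apixaban", "paroxetine"): math.inf}},
         "interaction_log_or"),
    ])
    def test_invalid_config_raises_with_field_name(self, bad, match):
        with pytest.raises(ValueError, match=match):
            SimulationConfig(**bad).validate()

    def test_recovery_report_requires_pair_strata_in_grid(self):
        cfg = SimulationConfig(n_reports=4_000, ad_given_doac_prob=0.1)
        reports, truth = simulate_reports(cfg, seed=3)
        results = InteractionSignalStudy(reports).fit(
            adjusted="none", levels=("overall",))
        with pytest.raises(ValueError, match="stratum mismatch"):
            recovery_report(results.signals, truth)
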