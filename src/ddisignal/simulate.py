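"""Synthetic FAERS-style spontaneous-report generator with known ground truth.

Every report is drawn from an explicit generative model so each pipeline
stage can be checked against truth without downloading FAERS:

1. covariates (age band and age, sex, reporter type, report year, country)
   are drawn from configurable categorical distributions, with a separate
   distribution for antidepressant-exposed reports so the exposed group can
   be older / more physician-reported, as in real spontaneous data;
2. drugs: every report gets one DOAC; with probability ``ad_given_doac_prob``
   it also lists one of the 14 study antidepressants; with probability
   ``other_drug_prob`` an additional non-study drug (which makes the report
   an exclusion downstream);
3. the bleeding outcome is Bernoulli under a logistic model: per-DOAC
   intercept + the configured (DOAC, antidepressant) interaction log-OR +
   covariate effects — so the configured odds multiplier IS the estimand the
   pipeline should recover;
4. nervous-system bleeding is nested within bleeding (per-stratum
   probability), and preferred terms are drawn from the packaged term
   fixtures (nervous-system PTs with a realistic frequency mix) plus nuisance
   PTs, so event coding sees both signal and noise terms;
5. field-level missingness masks are applied to the recorded demographics
   (the true values still drive the outcome);
6. a configurable fraction of cases is emitted twice (same CASEID, earlier
   FDA_DT and lower PRIMARYID for the superseded version, with optional
   exact-date ties) to exercise the deduplication rule; truth records which
   row must survive.

Default parameter values reproduce the scale and mix of the published DOAC /
antidepressant interaction cohort: DOAC market shares and per-DOAC bleeding
and nervous-system rates, an interaction-group frequency of ~0.26 %%, Table-
style covariate distributions, ~48 %% age missingness, and class-level
interaction odds multipliers of 1.78 (SSRI), 1.12 (SNRI) and 0.67 (other
antidepressants).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as fio
from .drugs import (ANTIDEPRESSANTS, DOACS, SSRIS, SNRIS, OTHER_ADS,
                    load_dictionary)
from .stats import AGE_BAND_LABELS

log = logging.getLogger(__name__)

_AGE_BAND_RANGES = {"0-17": (1, 18), "18-59": (18, 60),
                    "60-74": (60, 75), ">=75": (75, 96)}

REPORTER_TYPES = ("physician", "pharmacist", "lawyer", "consumer",
                  "other_health_professional")

#: Nervous-system PT frequency mix used for NS bleeding draws
#: (term -> weight); mirrors a realistic intracranial-bleed case mix.
NS_PT_WEIGHTS = {
    "Cerebral hemorrhage": 23,
    "Haemorrhagic stroke": 13,
    "Hemorrhage intracranial": 10,
    "Cerebral haematoma": 7,
    "Central nervous system hemorrhage": 4,
    "Subarachnoid hemorrhage": 2,
    "Cerebellar haematoma": 2,
}

OTHER_BLEED_PTS = (
    "Gastrointestinal haemorrhage", "Epistaxis", "Rectal haemorrhage",
    "Haematuria", "Contusion", "Melaena", "Haematemesis", "Haemoptysis",
    "Vaginal haemorrhage", "Gingival bleeding",
)

NUISANCE_PTS = (
    "Nausea", "Dizziness", "Headache", "Fatigue", "Rash", "Vomiting",
    "Diarrhoea", "Insomnia", "Pruritus", "Dyspnoea", "Arthralgia", "Asthenia",
)

#: Non-study concomitant drugs (trigger the other_concomitant exclusion).
OTHER_DRUGS = ("ASPIRIN", "METFORMIN", "ATORVASTATIN", "OMEPRAZOLE",
               "LISINOPRIL", "AMLODIPINE", "IBUPROFEN", "PARACETAMOL")


def _class_of(ad: str) -> str:
    if ad in SSRIS:
        return "SSRI"
    if ad in SNRIS:
        return "SNRI"
    return "OTHER_AD"


def default_interaction_log_or() -> dict[tuple[str, str], float]:
    """Class-level default odds multipliers expanded to every (DOAC, AD) pair."""
    class_or = {"SSRI": 1.78, "SNRI": 1.12, "OTHER_AD": 0.67}
    return {(d, ad): math.log(class_or[_class_of(ad)])
            for d in DOACS for ad in ANTIDEPRESSANTS}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class SimulationConfig:
    """Ground-truth generative parameters; defaults emulate the study cohort."""

    n_reports: int = 200_000
    doac_probs: dict[str, float] = field(default_factory=lambda: {
        "rivaroxaban": 0.350, "apixaban": 0.469,
        "edoxaban": 0.015, "dabigatran": 0.166})
    #: probability an exposed (DOAC) report also lists one antidepressant
    ad_given_doac_prob: float = 0.00255
    ad_probs: dict[str, float] = field(default_factory=lambda: {
        ad: 1.0 / len(ANTIDEPRESSANTS) for ad in ANTIDEPRESSANTS})
    #: probability of an extra non-study drug (-> excluded downstream)
    other_drug_prob: float = 0.05
    #: per-DOAC bleeding intercept on the logit scale
    baseline_bleed_logit: dict[str, float] = field(default_factory=lambda: {
        "rivaroxaban": _logit(0.4773), "apixaban": _logit(0.1650),
        "edoxaban": _logit(0.2920), "dabigatran": _logit(0.3691)})
    #: (doac, antidepressant) -> log odds multiplier — the signal theta
    interaction_log_or: dict[tuple[str, str], float] = field(
        default_factory=default_interaction_log_or)
    #: probability a bleeding monotherapy report is nervous-system type
    ns_given_bleed_prob: dict[str, float] = field(default_factory=lambda: {
        "rivaroxaban": 0.1160, "apixaban": 0.1474,
        "edoxaban": 0.0933, "dabigatran": 0.1376})
    #: same, for antidepressant-exposed reports
    ns_given_bleed_interaction: dict[str, float] = field(
        default_factory=lambda: {
            "rivaroxaban": 0.2421, "apixaban": 0.1528,
            "edoxaban": 0.3333, "dabigatran": 0.1500})
    #: optional per-pair override of the interaction NS probability
    ns_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    # covariate model --------------------------------------------------------
    age_band_probs: dict[str, float] = field(default_factory=lambda: {
        "0-17": 0.039, "18-59": 0.156, "60-74": 0.313, ">=75": 0.492})
    age_band_probs_exposed: dict[str, float] = field(default_factory=lambda: {
        "0-17": 0.013, "18-59": 0.215, "60-74": 0.194, ">=75": 0.578})
    sex_female_prob: float = 0.511
    sex_female_prob_exposed: float = 0.592
    reporter_probs: dict[str, float] = field(default_factory=lambda: {
        "physician": 0.275, "pharmacist": 0.068, "lawyer": 0.002,
        "consumer": 0.551, "other_health_professional": 0.104})
    reporter_probs_exposed: dict[str, float] = field(default_factory=lambda: {
        "physician": 0.345, "pharmacist": 0.144, "lawyer": 0.0,
        "consumer": 0.333, "other_health_professional": 0.178})
    year_probs: dict[int, float] = field(default_factory=lambda: {
        2010: 216, 2011: 6295, 2012: 6802, 2013: 7551, 2014: 9139,
        2015: 18013, 2016: 17932, 2017: 18868, 2018: 18060, 2019: 20203,
        2020: 22254, 2021: 19774, 2022: 16362, 2023: 11929, 2024: 11913,
        2025: 2219})
    country_probs: dict[str, float] = field(default_factory=lambda: {
        "US": 0.753, "DE": 0.037, "JP": 0.034, "FR": 0.030, "GB": 0.025,
        "CA": 0.020, "IT": 0.015, "ES": 0.015, "OTHER": 0.071})
    #: covariate -> level -> additive log-odds on bleeding (centred so the
    #: marginal rates stay close to the per-DOAC intercepts)
    covariate_log_odds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "age_band": {"0-17": -0.45, "18-59": -0.25,
                         "60-74": -0.05, ">=75": 0.15},
            "sex": {"F": 0.0, "M": 0.0},
            "reporter_type": {"physician": 0.12, "pharmacist": 0.12,
                              "lawyer": -0.08, "consumer": -0.08,
                              "other_health_professional": 0.02},
        })

    # data-quality model -----------------------------------------------------
    duplicate_rate: float = 0.10
    #: fraction of duplicates whose superseded row shares the exact FDA_DT
    duplicate_tie_rate: float = 0.25
    missing_rates: dict[str, float] = field(default_factory=lambda: {
        "age": 0.482, "sex": 0.152, "reporter_type": 0.005, "country": 0.02})
    nuisance_pts: tuple[str, ...] = NUISANCE_PTS

    def validate(self) -> None:
        def check_probs(name, probs):
            vals = list(probs.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError(
                    f"{name}: probabilities must be nonnegative and sum to 1 "
                    f"(sum={sum(vals):.6f})")
        if self.n_reports < 0:
            raise ValueError("n_reports: must be nonnegative")
        check_probs("doac_probs", self.doac_probs)
        check_probs("ad_probs", self.ad_probs)
        check_probs("age_band_probs", self.age_band_probs)
        check_probs("age_band_probs_exposed", self.age_band_probs_exposed)
        check_probs("reporter_probs", self.reporter_probs)
        check_probs("reporter_probs_exposed", self.reporter_probs_exposed)
        check_probs("country_probs", self.country_probs)
        for name in ("ad_given_doac_prob", "other_drug_prob",
                     "sex_female_prob", "sex_female_prob_exposed",
                     "duplicate_rate", "duplicate_tie_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: rate {v} outside [0, 1]")
        for key, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing_rates[{key}]: rate {v} outside [0, 1]")
        for key, v in self.interaction_log_or.items():
            if not math.isfinite(v):
                raise ValueError(f"interaction_log_or[{key}]: not finite")
        for d, v in self.baseline_bleed_logit.items():
            if not math.isfinite(v):
                raise ValueError(f"baseline_bleed_logit[{d}]: not finite")

    def true_or(self, doac: str, antidepressant: str) -> float:
        """Configured conditional odds ratio for one (DOAC, AD) pair."""
        return math.exp(self.interaction_log_or.get((doac, antidepressant), 0.0))

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["interaction_log_or"] = {
            f"{d}|{ad}": v for (d, ad), v in self.interaction_log_or.items()}
        out["ns_overrides"] = {
            f"{d}|{ad}": v for (d, ad), v in self.ns_overrides.items()}
        return out


def _choice(rng: np.random.Generator, probs: Mapping, n: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array([probs[k] for k in probs], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), size=n, p=p)]


def simulate_reports(config: SimulationConfig, seed: int,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic report set; return (reports, truth).

    ``reports`` is an analysis-ready report frame (including superseded
    duplicate rows, so deduplication is exercised); ``truth`` has one row per
    case with the generator's group label, outcome flags and the surviving
    primaryid, and carries the configured per-pair odds ratios in
    ``truth.attrs['true_or']``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_reports

    empty_reports = pd.DataFrame(columns=list(fio.REPORT_COLUMNS))
    empty_truth = pd.DataFrame(columns=[
        "caseid", "primaryid", "group", "doac", "antidepressant", "ad_class",
        "bleed", "ns_bleed"])
    empty_truth.attrs["true_or"] = {
        f"{d}|{ad}": config.true_or(d, ad)
        for d in DOACS for ad in ANTIDEPRESSANTS}
    if n == 0:
        return empty_reports, empty_truth

    doac = _choice(rng, config.doac_probs, n)
    has_ad = rng.random(n) < config.ad_given_doac_prob
    ad = _choice(rng, config.ad_probs, n)
    has_other = rng.random(n) < config.other_drug_prob
    other_name = rng.choice(np.array(OTHER_DRUGS, dtype=object), size=n)

    band_base = _choice(rng, config.age_band_probs, n)
    band_exp = _choice(rng, config.age_band_probs_exposed, n)
    band = np.where(has_ad, band_exp, band_base)
    u = rng.random(n)
    band_s = pd.Series(band)
    lo = band_s.map({k: v[0] for k, v in _AGE_BAND_RANGES.items()}).to_numpy(float)
    hi = band_s.map({k: v[1] for k, v in _AGE_BAND_RANGES.items()}).to_numpy(float)
    age = np.floor(lo + u * (hi - lo))

    p_f = np.where(has_ad, config.sex_female_prob_exposed,
                   config.sex_female_prob)
    sex = np.where(rng.random(n) < p_f, "F", "M").astype(object)

    rep_base = _choice(rng, config.reporter_probs, n)
    rep_exp = _choice(rng, config.reporter_probs_exposed, n)
    reporter = np.where(has_ad, rep_exp, rep_base)
    year = _choice(rng, config.year_probs, n).astype(int)
    country = _choice(rng, config.country_probs, n)

    # outcome model
    doac_s = pd.Series(doac)
    logit = doac_s.map(config.baseline_bleed_logit).to_numpy(float)
    theta = np.zeros(n)
    for i in np.flatnonzero(has_ad):
        theta[i] = config.interaction_log_or.get((doac[i], ad[i]), 0.0)
    logit = logit + theta
    eff = config.covariate_log_odds
    logit += band_s.map(eff.get("age_band", {})).fillna(0.0).to_numpy(float)
    logit += pd.Series(sex).map(eff.get("sex", {})).fillna(0.0).to_numpy(float)
    logit += pd.Series(reporter).map(
        eff.get("reporter_type", {})).fillna(0.0).to_numpy(float)
    bleed = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    ns_p = np.where(
        has_ad,
        doac_s.map(config.ns_given_bleed_interaction).to_numpy(float),
        doac_s.map(config.ns_given_bleed_prob).to_numpy(float))
    for key, p in config.ns_overrides.items():
        d0, a0 = key
        ns_p[has_ad & (doac == d0) & (ad == a0)] = p
    ns = bleed & (rng.random(n) < ns_p)

    # preferred terms
    ns_terms = np.array(list(NS_PT_WEIGHTS.keys()), dtype=object)
    ns_w = np.array(list(NS_PT_WEIGHTS.values()), dtype=float)
    ns_w /= ns_w.sum()
    ns_pick = ns_terms[rng.choice(len(ns_terms), size=n, p=ns_w)]
    other_pick = rng.choice(np.array(OTHER_BLEED_PTS, dtype=object), size=n)
    nuis = np.array(config.nuisance_pts, dtype=object)
    n_extra = rng.choice([0, 1, 2], size=n, p=[0.50, 0.35, 0.15])
    extra_idx = rng.integers(0, len(nuis), size=(n, 2))
    reactions = []
    for i in range(n):
        pts: list[str] = []
        if ns[i]:
            pts.append(ns_pick[i])
        elif bleed[i]:
            pts.append(other_pick[i])
        k = n_extra[i] if bleed[i] else 1 + n_extra[i]
        for j in range(k):
            pt = nuis[extra_idx[i, j % 2]] if j < 2 else nuis[extra_idx[i, 0]]
            if pt not in pts:
                pts.append(pt)
        reactions.append(tuple(pts))

    # missingness (recorded fields only; the true values drove the outcome)
    age_rec = age.copy()
    age_rec[rng.random(n) < config.missing_rates.get("age", 0.0)] = np.nan
    sex_rec = sex.copy()
    sex_rec[rng.random(n) < config.missing_rates.get("sex", 0.0)] = None
    rep_rec = reporter.copy()
    rep_rec[rng.random(n) < config.missing_rates.get("reporter_type", 0.0)] = None
    ctry_rec = country.copy()
    ctry_rec[rng.random(n) < config.missing_rates.get("country", 0.0)] = None

    # identifiers and dates
    caseid_num = 10_000_000 + np.arange(n, dtype=np.int64)
    is_dup = rng.random(n) < config.duplicate_rate
    version = np.where(is_dup, 2, 1)
    primaryid_num = caseid_num * 100 + version
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    fda_dt = np.char.mod("%08d", year * 10000 + month * 100 + day
                         ).astype(object)

    drugs = []
    for i in range(n):
        row = [doac[i]]
        if has_ad[i]:
            row.append(ad[i])
        if has_other[i]:
            row.append(other_name[i])
        drugs.append(tuple(row))

    reports = pd.DataFrame({
        "primaryid": primaryid_num.astype(str),
        "caseid": caseid_num.astype(str),
        "fda_dt": fda_dt,
        "report_year": year,
        "age_years": age_rec,
        "sex": sex_rec,
        "reporter_type": rep_rec,
        "country": ctry_rec,
        "drugs": drugs,
        "reactions": reactions,
    })

    # superseded duplicate submissions: same caseid, lower primaryid,
    # earlier FDA_DT (or an exact tie, exercising the primaryid tie-break)
    dup_idx = np.flatnonzero(is_dup)
    if len(dup_idx):
        pred = reports.iloc[dup_idx].copy()
        pred["primaryid"] = (caseid_num[dup_idx] * 100 + 1).astype(str)
        tie = rng.random(len(dup_idx)) < config.duplicate_tie_rate
        back = rng.integers(10, 60, size=len(dup_idx))
        dt = pd.to_datetime(pred["fda_dt"], format="%Y%m%d")
        dt = dt - pd.to_timedelta(np.where(tie, 0, back), unit="D")
        pred["fda_dt"] = dt.dt.strftime("%Y%m%d").to_numpy(dtype=object)
        pred["report_year"] = dt.dt.year.to_numpy()
        reports = pd.concat([reports, pred], ignore_index=True)

    group = np.where(has_other, "excluded",
                     np.where(has_ad, "interaction", "non_interaction"))
    truth = pd.DataFrame({
        "caseid": caseid_num.astype(str),
        "primaryid": primaryid_num.astype(str),
        "group": group.astype(object),
        "doac": doac,
        "antidepressant": np.where(has_ad, ad, None),
        "ad_class": np.where(has_ad, [_class_of(a) for a in ad], None),
        "bleed": bleed,
        "ns_bleed": ns,
    })
    truth.attrs["true_or"] = dict(empty_truth.attrs["true_or"])
    return reports, truth


# styling pools used when emitting raw FAERS-dialect files
_STYLE_SUFFIXES = ("", " 10 MG", " 20 MG TABLET", " 5 MG")


def _brand_pools() -> dict[str, list[str]]:
    dictionary = load_dictionary()
    brands: dict[str, list[str]] = {}
    for syn, ing in sorted(dictionary.synonym_map.items()):
        brands.setdefault(ing, []).append(syn)
    return brands


def _styled_names(rng: np.random.Generator, ingredients: tuple,
                  brands: dict[str, list[str]]) -> list[str]:
    """Render ingredient identifiers as messy FAERS drug-row text."""
    out = []
    for ing in ingredients:
        pool = brands.get(ing, [str(ing).upper()])
        name = pool[rng.integers(0, len(pool))]
        out.append(name + _STYLE_SUFFIXES[rng.integers(0, len(_STYLE_SUFFIXES))])
    return out


def generate(config: SimulationConfig, seed: int, out_dir: str | Path,
             dialect: Optional[fio.FaersDialect] = None,
             ) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write a synthetic quarterly file set plus its truth export.

    DEMO/DRUG/REAC are emitted in the FAERS ASCII dialect with realistic
    name noise (brand synonyms, dose suffixes) on the study drugs, so the
    normalization stage is exercised on read-back.  Returns the written
    paths (including ``truth.csv`` and ``sim_metadata.json``) and the truth
    frame.
    """
    dialect = dialect or fio.FaersDialect()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports, truth = simulate_reports(config, seed)

    style_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    brands = _brand_pools()
    demo_rows = []
    drug_rows = []
    reac_rows = []
    for r in reports.itertuples(index=False):
        occp = fio.REPORTER_TO_OCCP.get(r.reporter_type, "") if isinstance(
            r.reporter_type, str) else ""
        age = "" if pd.isna(r.age_years) else str(int(r.age_years))
        demo_rows.append((r.primaryid, r.caseid, r.fda_dt, age,
                          "YR" if age else "", r.sex or "", occp,
                          r.country or ""))
        names = _styled_names(style_rng, r.drugs, brands) if r.drugs else []
        for seq, name in enumerate(names, start=1):
            drug_rows.append((r.primaryid, seq, "PS" if seq == 1 else "C", name))
        for pt in r.reactions:
            reac_rows.append((r.primaryid, pt))

    paths = {
        "demo": out_dir / "DEMO.txt",
        "drug": out_dir / "DRUG.txt",
        "reac": out_dir / "REAC.txt",
        "truth": out_dir / "truth.csv",
        "metadata": out_dir / "sim_metadata.json",
    }
    fio._write_dollar(paths["demo"],
                      ("primaryid", "caseid", "fda_dt", "age", "age_cod",
                       "sex", "occp_cod", "reporter_country"),
                      demo_rows, dialect)
    fio._write_dollar(paths["drug"],
                      ("primaryid", "drug_seq", "role_cod", "drugname"),
                      drug_rows, dialect)
    fio._write_dollar(paths["reac"], ("primaryid", "pt"), reac_rows, dialect)
    truth.to_csv(paths["truth"], index=False)
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        json.dump({"seed": seed, "config": config.to_jsonable(),
                   "true_or": truth.attrs["true_or"]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote synthetic study (%d demo rows) to %s", len(reports), out_dir)
    return paths, truth


def recovery_report(signals: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Compare estimated pair-level RORs with the generator's true odds ratios.

    ``signals`` is the signal grid of a fitted study (``StudyResults.signals``)
    and ``truth`` the truth frame from :func:`simulate_reports`.  For every
    (DOAC, antidepressant) pair row with the bleeding outcome and a defined
    estimate, reports the log-scale bias, whether the Wald CI covers the true
    value, and whether the signal flag agrees with truth > 1.

    Raises
    ------
    ValueError
        If the truth references a pair absent from the signal grid.
    """
    true_or = truth.attrs.get("true_or", {})
    pairs = signals[(signals["level"] == "pair")
                    & (signals["outcome"] == "any_hemorrhage")]
    grid_pairs = {(r.doac, r.antidepressant) for r in pairs.itertuples()}
    observed = {(d, a) for d, a in zip(
        truth.loc[truth["group"] == "interaction", "doac"],
        truth.loc[truth["group"] == "interaction", "antidepressant"])}
    missing = observed - grid_pairs
    if missing:
        raise ValueError(f"stratum mismatch: truth pairs absent from grid: {missing}")
    rows = []
    for r in pairs.itertuples():
        key = f"{r.doac}|{r.antidepressant}"
        if key not in true_or or not np.isfinite(r.ror):
            continue
        t = true_or[key]
        rows.append({
            "doac": r.doac, "antidepressant": r.antidepressant,
            "true_or": t, "ror": r.ror,
            "bias_ln": math.log(r.ror) - math.log(t),
            "ci_covered": bool(r.ci_low <= t <= r.ci_high),
            "signal_correct": bool(r.signal == (t > 1.0)),
        })
    return pd.DataFrame(rows, columns=["doac", "antidepressant", "true_or",
                                       "ror", "bias_ln", "ci_covered",
                                       "signal_correct"])
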