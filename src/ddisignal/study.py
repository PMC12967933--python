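"""The full study: model object, fitted results, configuration and export.

:class:`InteractionSignalStudy` is built from a report frame (or directly
from FAERS quarterly files); construction runs deduplication, drug
normalization, cohort assignment and outcome coding.  :meth:`fit` evaluates
the signal grid — overall, by antidepressant class, by antidepressant, and
by DOAC x antidepressant pair, for both the any-haemorrhage and the
nervous-system-haemorrhage outcome — and returns a :class:`StudyResults`
carrying crude RORs with Wald CIs, signal flags, adjusted odds ratios,
the baseline-characteristics table and the nervous-system PT breakdown.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import io as fio
from .cohort import Cohort, build_cohort
from .dedup import deduplicate
from .drugs import (ANTIDEPRESSANTS, DOACS, AD_CLASSES, DrugDictionary,
                    load_dictionary)
from .events import (TermSet, code_frame, default_hemorrhage_terms,
                     default_ns_terms, load_term_set, normalize_term)
from .stats import (DEFAULT_COVARIATES, BaselineTable, add_age_band,
                    baseline_table, fit_logistic, make_table, ror)

log = logging.getLogger(__name__)

OUTCOMES = ("any_hemorrhage", "ns_hemorrhage")
LEVELS = ("overall", "ad_class", "antidepressant", "pair")
COMPARATOR_POLICIES = ("same_doac_monotherapy", "all_doac_monotherapy")

SIGNAL_COLUMNS = ["outcome", "level", "doac", "antidepressant", "ad_class",
                  "a", "b", "c", "d", "ror", "se_ln_ror", "ci_low", "ci_high",
                  "signal", "aor", "aor_ci_low", "aor_ci_high",
                  "aor_converged", "aor_message"]


@dataclass
class StudyConfig:
    """Configuration of a full study run (YAML-serializable)."""

    input_paths: list[str] = field(default_factory=list)
    dictionary_path: Optional[str] = None
    hemorrhage_terms_path: Optional[str] = None
    ns_terms_path: Optional[str] = None
    comparator_policy: str = "same_doac_monotherapy"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    adjusted: str = "signals"  # 'signals' | 'all' | 'none'
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.comparator_policy not in COMPARATOR_POLICIES:
            raise ValueError(
                f"comparator_policy must be one of {COMPARATOR_POLICIES}, "
                f"got {self.comparator_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class InteractionSignalStudy:
    """Case/non-case disproportionality study of DOAC-antidepressant reports.

    Parameters
    ----------
    reports
        Report-level frame (see :mod:`ddisignal.io` for the schema), e.g.
        from :func:`ddisignal.io.assemble_reports` or the synthetic
        generator.
    dictionary, hemorrhage_terms, ns_terms
        Drug dictionary and outcome term sets; packaged defaults when None.
    dedupe
        Apply the one-report-per-case rule before cohort assignment
        (default True; disable only for already-deduplicated input).

    Examples
    --------
    >>> from ddisignal import InteractionSignalStudy, SimulationConfig
    >>> from ddisignal.simulate import simulate_reports
    >>> reports, truth = simulate_reports(SimulationConfig(n_reports=5000), 7)
    >>> results = InteractionSignalStudy(reports).fit()
    >>> print(results.summary())                        # doctest: +SKIP
    """

    def __init__(self, reports: pd.DataFrame,
                 dictionary: Optional[DrugDictionary] = None,
                 hemorrhage_terms: Optional[TermSet] = None,
                 ns_terms: Optional[TermSet] = None,
                 dedupe: bool = True):
        self.dictionary = dictionary if dictionary is not None else load_dictionary()
        self.hemorrhage_terms = hemorrhage_terms if hemorrhage_terms is not None \
            else default_hemorrhage_terms()
        self.ns_terms = ns_terms if ns_terms is not None else default_ns_terms()
        self.n_input = len(reports)
        deduped = deduplicate(reports) if dedupe else reports
        self.reports = deduped
        cohort = build_cohort(deduped, self.dictionary)
        cohort.data = add_age_band(
            code_frame(cohort.data, self.hemorrhage_terms, self.ns_terms))
        self.cohort = cohort
        if cohort.n_interaction == 0:
            warnings.warn("interaction group is empty; the signal grid will "
                          "carry only undefined estimates")

    @classmethod
    def from_faers(cls, quarter_paths: Sequence[str | Path],
                   dictionary: Optional[DrugDictionary] = None,
                   hemorrhage_terms: Optional[TermSet] = None,
                   ns_terms: Optional[TermSet] = None,
                   dialect: Optional[fio.FaersDialect] = None,
                   ) -> "InteractionSignalStudy":
        """Build the study straight from FAERS quarterly ASCII files."""
        dictionary = dictionary if dictionary is not None else load_dictionary()
        raw = fio.read_tables(quarter_paths, dialect=dialect)
        reports = fio.assemble_reports(raw, dictionary)
        return cls(reports, dictionary=dictionary,
                   hemorrhage_terms=hemorrhage_terms, ns_terms=ns_terms)

    # ------------------------------------------------------------------
    def _grid(self, comparator_policy: str, levels: Sequence[str]):
        for level in levels:
            if level == "overall":
                yield level, {}, {}, {"doac": "all", "antidepressant": "all",
                                      "ad_class": "all"}
            elif level == "ad_class":
                for klass in AD_CLASSES:
                    yield level, {"ad_class": klass}, {}, \
                        {"doac": "all", "antidepressant": "all",
                         "ad_class": klass}
            elif level == "antidepressant":
                for ad in ANTIDEPRESSANTS:
                    yield level, {"antidepressant": ad}, {}, \
                        {"doac": "all", "antidepressant": ad,
                         "ad_class": None}
            elif level == "pair":
                for doac in DOACS:
                    comp = {"doac": doac} \
                        if comparator_policy == "same_doac_monotherapy" else {}
                    for ad in ANTIDEPRESSANTS:
                        yield level, {"doac": doac, "antidepressant": ad}, \
                            comp, {"doac": doac, "antidepressant": ad,
                                   "ad_class": None}
            else:
                raise ValueError(f"unknown grid level {level!r}")

    def fit(self, comparator_policy: str = "same_doac_monotherapy",
            covariates: Sequence[str] = DEFAULT_COVARIATES,
            adjusted: str = "signals",
            outcomes: Sequence[str] = OUTCOMES,
            levels: Sequence[str] = LEVELS) -> "StudyResults":
        """Evaluate the signal grid and return the fitted results.

        Parameters
        ----------
        comparator_policy
            Comparator for pair-level strata: monotherapy reports of the
            same DOAC (default) or of all DOACs.  Overall/class/drug strata
            always compare against all DOAC monotherapy.
        covariates
            Report-level covariates for the adjusted logistic model.
        adjusted
            'signals' (default) refines only strata flagged by the crude
            criterion, 'all' fits every stratum, 'none' skips adjustment.
        outcomes, levels
            Subsets of the grid to evaluate.
        """
        if comparator_policy not in COMPARATOR_POLICIES:
            raise ValueError(
                f"comparator_policy must be one of {COMPARATOR_POLICIES}")
        if adjusted not in ("signals", "all", "none"):
            raise ValueError("adjusted must be 'signals', 'all' or 'none'")
        df = self.cohort.data
        is_interaction = (df["group"] == "interaction").to_numpy()
        is_comparator = (df["group"] == "non_interaction").to_numpy()

        rows = []
        for outcome in outcomes:
            flags = df[outcome].to_numpy(dtype=bool) if len(df) else \
                np.zeros(0, dtype=bool)
            for level, expo, comp, labels in self._grid(comparator_policy,
                                                        levels):
                table = make_table(self.cohort, expo, outcome, comp)
                res = ror(table)
                row = {"outcome": outcome, "level": level, **labels,
                       "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                       "ror": res.ror, "se_ln_ror": res.se_ln_ror,
                       "ci_low": res.ci_low, "ci_high": res.ci_high,
                       "signal": res.signal,
                       "aor": math.nan, "aor_ci_low": math.nan,
                       "aor_ci_high": math.nan, "aor_converged": False,
                       "aor_message": ""}
                want_adj = adjusted == "all" or (adjusted == "signals"
                                                and res.signal)
                if want_adj and table.n_exposed and table.n_comparator:
                    emask = is_interaction.copy()
                    cmask = is_comparator.copy()
                    for key, value in expo.items():
                        emask &= (df[key] == value).to_numpy()
                    for key, value in comp.items():
                        cmask &= (df[key] == value).to_numpy()
                    sel = emask | cmask
                    rec = df.loc[sel, list(covariates)].copy()
                    rec["outcome"] = flags[sel].astype(int)
                    rec["exposure"] = emask[sel].astype(int)
                    try:
                        adj = fit_logistic(rec, covariates=covariates)
                        row.update(aor=adj.aor, aor_ci_low=adj.ci_low,
                                   aor_ci_high=adj.ci_high,
                                   aor_converged=adj.converged,
                                   aor_message=adj.message)
                    except ValueError as exc:
                        row["aor_message"] = str(exc)
                rows.append(row)
        signals = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
        metadata = {
            "package_version": _pkg_version,
            "comparator_policy": comparator_policy,
            "covariates": list(covariates),
            "adjusted": adjusted,
            "outcomes": list(outcomes),
            "levels": list(levels),
            "hemorrhage_term_set": self.hemorrhage_terms.name,
            "ns_term_set": self.ns_terms.name,
            "n_reports_input": int(self.n_input),
            "n_reports_deduplicated": int(len(self.reports)),
            "n_interaction": int(self.cohort.n_interaction),
            "n_non_interaction": int(self.cohort.n_non_interaction),
            "exclusions": dict(self.cohort.exclusions),
        }
        return StudyResults(signals=signals, cohort=self.cohort,
                            ns_terms=self.ns_terms, metadata=metadata)


def pt_breakdown(cohort: Cohort, ns: TermSet) -> pd.DataFrame:
    """Nervous-system PT frequency table over interaction-group reports.

    Each report contributes every distinct matched PT once; percentages are
    of the number of reports with at least one matched PT (the case total),
    so they can sum above 100 when reports carry several NS terms.
    """
    inter = cohort.data[cohort.data["group"] == "interaction"]
    counts: dict[str, int] = {}
    case_total = 0
    for reactions in inter["reactions"]:
        matched = {normalize_term(pt) for pt in reactions} & ns.terms
        if matched:
            case_total += 1
            for key in matched:
                counts[key] = counts.get(key, 0) + 1
    rows = [{"pt": ns.display.get(key, key), "n": n,
             "pct": 100.0 * n / case_total}
            for key, n in counts.items()]
    out = pd.DataFrame(rows, columns=["pt", "n", "pct"])
    if len(out):
        out = out.sort_values(["n", "pt"], ascending=[False, True],
                              ignore_index=True)
    out.attrs["case_total"] = case_total
    return out


@dataclass
class StudyResults:
    """Fitted signal grid plus derived tables.

    Attributes
    ----------
    signals
        One row per (outcome, stratum): 2x2 counts, crude ROR with Wald CI
        and signal flag, and (where fitted) the adjusted odds ratio.
    cohort
        The underlying cohort with group labels and outcome flags.
    """

    signals: pd.DataFrame
    cohort: Cohort
    ns_terms: TermSet
    metadata: dict
    _baseline: Optional[BaselineTable] = field(default=None, repr=False)
    _pt_breakdown: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def baseline(self) -> Optional[BaselineTable]:
        """Baseline table; None when either analysis group is empty."""
        if self._baseline is None:
            try:
                self._baseline = baseline_table(self.cohort)
            except ValueError as exc:
                warnings.warn(f"baseline table unavailable: {exc}")
                return None
        return self._baseline

    def pt_breakdown(self) -> pd.DataFrame:
        if self._pt_breakdown is None:
            self._pt_breakdown = pt_breakdown(self.cohort, self.ns_terms)
        return self._pt_breakdown

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "DOAC-antidepressant interaction signal study",
            "=" * 60,
            f"reports in: {md['n_reports_input']:>10,}   "
            f"after dedup: {md['n_reports_deduplicated']:,}",
            f"interaction group:     {md['n_interaction']:>10,}",
            f"non-interaction group: {md['n_non_interaction']:>10,}",
            f"excluded: {sum(md['exclusions'].values()):,} {md['exclusions']}",
            f"comparator policy: {md['comparator_policy']}   "
            f"adjusted: {md['adjusted']}",
            "",
        ]
        flagged = self.signals[self.signals["signal"]]
        if flagged.empty:
            lines.append("no strata meet the signal criterion "
                         "(a >= 3 and CI lower bound > 1)")
        else:
            lines.append(f"strata meeting the signal criterion "
                         f"(a >= 3, CI low > 1): {len(flagged)}")
            show = flagged.sort_values("ror", ascending=False).head(15)
            cols = ["outcome", "level", "doac", "antidepressant", "a",
                    "ror", "ci_low", "ci_high", "aor"]
            with pd.option_context("display.width", 120):
                lines.append(show[cols].to_string(
                    index=False, float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Export all tables and run metadata; deterministic byte-for-byte."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "baseline": out_dir / "baseline.csv",
            "signals_overall": out_dir / "signals_overall.csv",
            "signals_ns": out_dir / "signals_ns.csv",
            "pt_breakdown": out_dir / "pt_breakdown.csv",
            "cohort": out_dir / "cohort.csv",
            "metadata": out_dir / "run_metadata.json",
        }
        self.cohort.summary_frame().to_csv(paths["cohort"], index=False)
        base = self.baseline
        if base is not None:
            base.to_frame().to_csv(paths["baseline"], index=False)
        else:
            pd.DataFrame(columns=["variable", "level", "interaction",
                                  "non_interaction", "p"]
                         ).to_csv(paths["baseline"], index=False)
        for outcome, key in (("any_hemorrhage", "signals_overall"),
                             ("ns_hemorrhage", "signals_ns")):
            sub = self.signals[self.signals["outcome"] == outcome]
            sub.to_csv(paths[key], index=False)
        self.pt_breakdown().to_csv(paths["pt_breakdown"], index=False)
        with open(paths["metadata"], "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def plot_forest(self, outcome: str = "any_hemorrhage",
                    level: str = "antidepressant", ax=None):
        """Simple forest-style plot of RORs with CIs for one grid level."""
        import matplotlib.pyplot as plt

        sub = self.signals[(self.signals["outcome"] == outcome)
                           & (self.signals["level"] == level)]
        sub = sub[np.isfinite(sub["ror"])]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(sub) + 1)))
        labels = [
            " + ".join(x for x in (r.doac, r.antidepressant, r.ad_class)
                       if x not in (None, "all")) or "overall"
            for r in sub.itertuples()]
        y = np.arange(len(sub))
        ax.errorbar(sub["ror"], y,
                    xerr=[sub["ror"] - sub["ci_low"],
                          sub["ci_high"] - sub["ror"]],
                    fmt="o", color="k", ecolor="gray", capsize=2)
        ax.axvline(1.0, color="firebrick", lw=1, ls="--")
        ax.set_yticks(y, labels)
        ax.set_xscale("log")
        ax.set_xlabel("reporting odds ratio (95% CI)")
        ax.set_title(f"{outcome} — {level} strata")
        ax.figure.tight_layout()
        return ax


def run_study(config: StudyConfig,
              reports: Optional[pd.DataFrame] = None) -> StudyResults:
    """Execute a configured study end to end and export its outputs.

    ``reports`` may be passed directly (e.g. a synthetic frame); otherwise
    the FAERS files under ``config.input_paths`` are read.
    """
    logging.basicConfig(level=config.log_level)
    dictionary = load_dictionary(config.dictionary_path)
    hem = (load_term_set(config.hemorrhage_terms_path)
           if config.hemorrhage_terms_path else default_hemorrhage_terms())
    ns = (load_term_set(config.ns_terms_path)
          if config.ns_terms_path else default_ns_terms())
    if reports is None:
        raw = fio.read_tables(config.input_paths)
        reports = fio.assemble_reports(raw, dictionary)
    model = InteractionSignalStudy(reports, dictionary=dictionary,
                                   hemorrhage_terms=hem, ns_terms=ns)
    results = model.fit(comparator_policy=config.comparator_policy,
                        covariates=config.covariates,
                        adjusted=config.adjusted)
    results.metadata["config"] = config.to_dict()
    if config.out_dir:
        results.save(config.out_dir)
    return results
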