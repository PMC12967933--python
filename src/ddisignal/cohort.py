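"""Case/non-case cohort construction.

Each deduplicated report is assigned, from ALL of its drug rows (suspect and
concomitant alike), to exactly one of:

* ``interaction``     — exactly one DOAC plus exactly one study
  antidepressant, and nothing else;
* ``non_interaction`` — exactly one DOAC and no other drug at all;
* ``excluded``        — everything else, with a reason.

Counting is over distinct ingredients (FAERS repeats drug rows across dose
changes) and ignores role codes.  When several exclusion reasons apply the
most informative one is reported, in the order multiple_doacs >
multiple_antidepressants > other_concomitant > no_doac; reports that would
otherwise qualify but carry no coded reaction are excluded as no_reactions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .drugs import DrugDictionary, AD_CLASSES

log = logging.getLogger(__name__)

GROUPS = ("interaction", "non_interaction", "excluded")
EXCLUSION_REASONS = ("multiple_doacs", "multiple_antidepressants",
                     "other_concomitant", "no_doac", "no_reactions")


@dataclass(frozen=True)
class GroupAssignment:
    group: str
    doac: Optional[str] = None
    antidepressant: Optional[str] = None
    ad_class: Optional[str] = None
    exclusion_reason: Optional[str] = None


def _assign(drugs: Sequence[str], has_reactions: bool,
            doacs: frozenset[str], ads: frozenset[str],
            class_map: dict[str, str]) -> GroupAssignment:
    d: list[str] = []
    s: list[str] = []
    o = 0
    for ing in set(drugs):
        if ing in doacs:
            d.append(ing)
        elif ing in ads:
            s.append(ing)
        else:
            o += 1
    if len(d) >= 2:
        return GroupAssignment("excluded", exclusion_reason="multiple_doacs")
    if len(s) >= 2:
        return GroupAssignment("excluded",
                               exclusion_reason="multiple_antidepressants")
    if o >= 1:
        return GroupAssignment("excluded", exclusion_reason="other_concomitant")
    if len(d) == 0:
        return GroupAssignment("excluded", exclusion_reason="no_doac")
    if not has_reactions:
        return GroupAssignment("excluded", exclusion_reason="no_reactions")
    if len(s) == 1:
        return GroupAssignment("interaction", doac=d[0], antidepressant=s[0],
                               ad_class=class_map[s[0]])
    return GroupAssignment("non_interaction", doac=d[0])


def assign_group(report, dictionary: DrugDictionary) -> GroupAssignment:
    """Assign one report (any object with .drugs and .reactions) to a group."""
    return _assign(report.drugs, len(report.reactions) > 0,
                   dictionary.doacs, dictionary.antidepressants,
                   dictionary.class_map)


@dataclass
class Cohort:
    """The two analysis groups plus the exclusion tally.

    ``data`` holds one row per retained report: the report columns plus
    ``group``, ``doac``, ``antidepressant`` and ``ad_class``.
    """

    data: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)
    n_input: int = 0

    @property
    def n_interaction(self) -> int:
        return int((self.data["group"] == "interaction").sum())

    @property
    def n_non_interaction(self) -> int:
        return int((self.data["group"] == "non_interaction").sum())

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())

    def counts(self, by: str = "group") -> pd.Series:
        """Tally retained reports by 'group', 'doac', 'antidepressant' or 'ad_class'."""
        return self.data.groupby(by, dropna=False).size()

    def summary_frame(self) -> pd.DataFrame:
        """Long-format (group, doac, antidepressant, ad_class, n) table."""
        if self.data.empty:
            return pd.DataFrame(
                columns=["group", "doac", "antidepressant", "ad_class", "n"])
        return (self.data
                .groupby(["group", "doac", "antidepressant", "ad_class"],
                         dropna=False)
                .size().rename("n").reset_index())


def build_cohort(reports: pd.DataFrame, dictionary: DrugDictionary) -> Cohort:
    """Assign every deduplicated report to a group and tally exclusions."""
    doacs = dictionary.doacs
    ads = dictionary.antidepressants
    cmap = dictionary.class_map
    n = len(reports)

    groups = []
    doac_col = []
    ad_col = []
    cls_col = []
    excl = dict.fromkeys(EXCLUSION_REASONS, 0)
    keep = []
    drugs_arr = reports["drugs"].to_numpy() if n else []
    reac_arr = reports["reactions"].to_numpy() if n else []
    for i in range(n):
        a = _assign(drugs_arr[i], len(reac_arr[i]) > 0, doacs, ads, cmap)
        if a.group == "excluded":
            excl[a.exclusion_reason] += 1
        else:
            keep.append(i)
            groups.append(a.group)
            doac_col.append(a.doac)
            ad_col.append(a.antidepressant)
            cls_col.append(a.ad_class)

    data = reports.iloc[keep].reset_index(drop=True) if n else reports.copy()
    data["group"] = pd.array(groups, dtype=object) if keep else \
        pd.Series([], dtype=object)
    data["doac"] = pd.array(doac_col, dtype=object) if keep else \
        pd.Series([], dtype=object)
    data["antidepressant"] = pd.array(ad_col, dtype=object) if keep else \
        pd.Series([], dtype=object)
    data["ad_class"] = pd.array(cls_col, dtype=object) if keep else \
        pd.Series([], dtype=object)
    exclusions = {k: v for k, v in excl.items() if v}
    log.info("cohort: %d interaction, %d non-interaction, %d excluded %s",
             (data["group"] == "interaction").sum(),
             (data["group"] == "non_interaction").sum(),
             sum(exclusions.values()), exclusions or "")
    return Cohort(data=data, exclusions=exclusions, n_input=n)
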