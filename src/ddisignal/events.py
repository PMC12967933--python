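"""Outcome coding from MedDRA preferred terms.

Two configurable term sets drive the analysis: a haemorrhage set (standing in
for the haemorrhage SMQ) and a nervous-system haemorrhage set (standing in
for the haemorrhagic PTs under the CNS-vascular-disorders HLGT).  The
licensed MedDRA dictionary cannot be redistributed, so the packaged lists are
curated stand-ins; licensed SMQ/HLGT exports drop in via configuration.

Matching is exact on the normalized PT string (casefolded, trimmed,
whitespace-collapsed) — PTs are controlled vocabulary, so substring matching
would only invite false positives.  The unit of analysis is the report: a
report with three bleeding PTs counts once.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

_WS_RE = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    return _WS_RE.sub(" ", str(term).strip()).casefold()


@dataclass(frozen=True)
class TermSet:
    """A named set of preferred terms, matched case-insensitively."""

    name: str
    terms: frozenset[str]
    #: normalized term -> first-seen display form (for breakdown tables)
    display: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def issubset(self, other: "TermSet") -> bool:
        return self.terms <= other.terms


@dataclass(frozen=True)
class OutcomeFlags:
    any_hemorrhage: bool
    ns_hemorrhage: bool
    matched_terms: tuple[str, ...] = ()


def make_term_set(name: str, terms: Iterable[str]) -> TermSet:
    normalized: set[str] = set()
    display: dict[str, str] = {}
    for t in terms:
        t = str(t).strip()
        if not t or t.startswith("#"):
            continue
        key = normalize_term(t)
        normalized.add(key)
        display.setdefault(key, t)
    return TermSet(name=name, terms=frozenset(normalized), display=display)


def load_term_set(path: str | Path, name: str | None = None) -> TermSet:
    """Load a term set from a plain-text file, one PT per line, '#' comments.

    Raises ``ValueError`` on an empty set — an analysis run with no outcome
    terms is meaningless.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        ts = make_term_set(name or path.stem, fh)
    if not ts.terms:
        raise ValueError(f"term set {path} is empty")
    return ts


def _packaged(filename: str, name: str) -> TermSet:
    ref = resources.files("ddisignal.data") / filename
    with resources.as_file(ref) as p:
        return load_term_set(p, name=name)


def default_hemorrhage_terms() -> TermSet:
    """Packaged stand-in for the haemorrhage SMQ term list."""
    return _packaged("hemorrhage_pts.txt", "haemorrhage_smq")


def default_ns_terms() -> TermSet:
    """Packaged stand-in for the CNS-vascular haemorrhagic PT list."""
    return _packaged("ns_hemorrhage_pts.txt", "cns_vascular_hlgt_bleeding")


def code_outcomes(report, hem: TermSet, ns: TermSet) -> OutcomeFlags:
    """Flag one report (any object with .reactions)."""
    matched = []
    any_h = False
    ns_h = False
    for pt in report.reactions:
        key = normalize_term(pt)
        if key in hem.terms or key in ns.terms:
            matched.append(pt)
            any_h = any_h or key in hem.terms
            ns_h = ns_h or key in ns.terms
    return OutcomeFlags(any_hemorrhage=any_h, ns_hemorrhage=ns_h,
                        matched_terms=tuple(matched))


def code_frame(reports: pd.DataFrame, hem: TermSet, ns: TermSet) -> pd.DataFrame:
    """Add boolean ``any_hemorrhage`` / ``ns_hemorrhage`` columns to a frame."""
    hem_terms = hem.terms
    ns_terms = ns.terms
    memo: dict[str, str] = {}
    any_col = []
    ns_col = []
    for reactions in reports["reactions"].to_numpy():
        a = False
        s = False
        for pt in reactions:
            key = memo.get(pt)
            if key is None:
                key = normalize_term(pt)
                memo[pt] = key
            if key in hem_terms:
                a = True
            if key in ns_terms:
                s = True
        any_col.append(a)
        ns_col.append(s)
    out = reports.copy()
    out["any_hemorrhage"] = any_col
    out["ns_hemorrhage"] = ns_col
    return out
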