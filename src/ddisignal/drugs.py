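"""Drug-name normalization and study-class assignment.

FAERS drug rows carry free-text names (brand or generic, often with dose or
formulation suffixes).  A :class:`DrugDictionary` maps cleaned synonyms to
canonical ingredient identifiers and assigns each ingredient to one of the
study classes: the four direct oral anticoagulants (DOAC), and antidepressants
grouped by mechanism into SSRI, SNRI and OTHER_AD.  Anything unmatched is
classed OTHER.

Matching is exact after normalization (uppercase, trimmed, trailing dose and
formulation tokens stripped); no fuzzy matching is attempted, so results are
reproducible and any recall gap is closed by extending the synonym list.
"""
from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger(__name__)

DOAC_CLASS = "DOAC"
SSRI = "SSRI"
SNRI = "SNRI"
OTHER_AD = "OTHER_AD"
OTHER = "OTHER"

AD_CLASSES = (SSRI, SNRI, OTHER_AD)
VALID_CLASSES = (DOAC_CLASS, SSRI, SNRI, OTHER_AD, OTHER)

#: The four direct oral anticoagulants under study.
DOACS = ("rivaroxaban", "apixaban", "edoxaban", "dabigatran")

#: The 14 pre-specified antidepressants, by mechanism class.
SSRIS = ("fluoxetine", "paroxetine", "fluvoxamine", "sertraline",
         "citalopram", "escitalopram")
SNRIS = ("venlafaxine", "desvenlafaxine", "duloxetine")
OTHER_ADS = ("bupropion", "mirtazapine", "agomelatine", "trazodone",
             "vortioxetine")
ANTIDEPRESSANTS = SSRIS + SNRIS + OTHER_ADS

# Trailing tokens stripped before lookup: doses, units and common
# formulation/route words.  Numeric tokens are always stripped from the tail.
_UNIT_TOKENS = {
    "MG", "MCG", "UG", "G", "ML", "MG/ML", "IU",
    "TABLET", "TABLETS", "TAB", "TABS", "CAPSULE", "CAPSULES", "CAP", "CAPS",
    "ORAL", "SOLUTION", "SUSPENSION", "INJECTION", "FILM", "COATED",
    "XR", "ER", "SR", "CR", "LA",
}
_NUMERIC_RE = re.compile(r"^[\d.,]+$")
_WS_RE = re.compile(r"\s+")


def clean_name(raw: str) -> str:
    """Uppercase, trim, collapse whitespace, strip trailing dose tokens."""
    text = _WS_RE.sub(" ", str(raw).upper().strip())
    tokens = text.split(" ")
    while tokens and (_NUMERIC_RE.match(tokens[-1]) or tokens[-1] in _UNIT_TOKENS):
        tokens.pop()
    return " ".join(tokens)


@dataclass(frozen=True)
class DrugDictionary:
    """Synonym -> ingredient and ingredient -> class maps."""

    synonym_map: dict[str, str] = field(default_factory=dict)
    class_map: dict[str, str] = field(default_factory=dict)

    @property
    def doacs(self) -> frozenset[str]:
        return frozenset(i for i, c in self.class_map.items() if c == DOAC_CLASS)

    @property
    def antidepressants(self) -> frozenset[str]:
        return frozenset(i for i, c in self.class_map.items() if c in AD_CLASSES)


def load_dictionary(path: str | Path | None = None) -> DrugDictionary:
    """Load a drug dictionary from a CSV with columns synonym, ingredient, class.

    With ``path=None`` the packaged default (4 DOACs + 14 antidepressants with
    common brand synonyms) is returned.

    Raises
    ------
    ValueError
        If a synonym maps to two different ingredients, an entry carries an
        unknown class label, or one ingredient is assigned two classes.
    """
    if path is None:
        ref = resources.files("ddisignal.data") / "drug_dictionary.csv"
        with resources.as_file(ref) as p:
            return load_dictionary(p)
    path = Path(path)
    synonym_map: dict[str, str] = {}
    class_map: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        log.warning("drug dictionary %s is empty", path)
        return DrugDictionary()
    for i, row in enumerate(rows, start=2):
        syn = clean_name(row["synonym"])
        ingredient = row["ingredient"].strip().lower()
        klass = row["class"].strip().upper()
        if klass not in VALID_CLASSES:
            raise ValueError(
                f"{path}:{i}: unknown class {klass!r} (expected one of {VALID_CLASSES})")
        if syn in synonym_map and synonym_map[syn] != ingredient:
            raise ValueError(
                f"{path}:{i}: synonym {syn!r} maps to both "
                f"{synonym_map[syn]!r} and {ingredient!r}")
        if ingredient in class_map and class_map[ingredient] != klass:
            raise ValueError(
                f"{path}:{i}: ingredient {ingredient!r} assigned classes "
                f"{class_map[ingredient]!r} and {klass!r}")
        synonym_map[syn] = ingredient
        class_map[ingredient] = klass
    missing = [i for i in set(synonym_map.values()) if i not in class_map]
    if missing:
        raise ValueError(f"{path}: ingredients without a class entry: {missing}")
    return DrugDictionary(synonym_map=synonym_map, class_map=class_map)


def normalize_name(raw: str, dictionary: DrugDictionary) -> Optional[str]:
    """Map one free-text drug name to its ingredient, or None if unmatched."""
    return dictionary.synonym_map.get(clean_name(raw))


_COMBO_RE = re.compile(r"[/+]")


def resolve_row(raw: str, dictionary: DrugDictionary) -> tuple[str, ...]:
    """Resolve a drug-row text to ingredient identifiers.

    Combination products are split on "/" and "+" before lookup.  Matched
    parts yield their canonical ingredient; unmatched parts yield their
    cleaned text (so they still count as "other" drugs downstream).
    Duplicates are collapsed preserving first appearance.
    """
    out: list[str] = []
    for part in _COMBO_RE.split(str(raw)):
        cleaned = clean_name(part)
        if not cleaned:
            continue
        ident = dictionary.synonym_map.get(cleaned, cleaned)
        if ident not in out:
            out.append(ident)
    return tuple(out)


def classify(ingredient: Optional[str], dictionary: DrugDictionary) -> str:
    """Class of an ingredient; None or unknown ingredients are OTHER."""
    if ingredient is None:
        return OTHER
    return dictionary.class_map.get(ingredient, OTHER)


def validate_study_dictionary(dictionary: DrugDictionary) -> list[str]:
    """Check a dictionary covers the study drugs; return problem descriptions."""
    problems = []
    for d in DOACS:
        if dictionary.class_map.get(d) != DOAC_CLASS:
            problems.append(f"DOAC {d!r} missing or misclassified")
    for name, klass in [(n, SSRI) for n in SSRIS] + [(n, SNRI) for n in SNRIS] \
            + [(n, OTHER_AD) for n in OTHER_ADS]:
        if dictionary.class_map.get(name) != klass:
            problems.append(f"antidepressant {name!r} missing or not {klass}")
    return problems
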