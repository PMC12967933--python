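"""Reading and writing FAERS quarterly ASCII tables.

The public FAERS extracts are distributed as $-delimited text tables with one
header row.  Seven tables exist per quarter — DEMO (demographics), DRUG,
REAC (reactions), OUTC, THER, RPSR, INDI — keyed by PRIMARYID.  Only DEMO,
DRUG and REAC are analyzed; the rest are carried through when present.

Assembled reports are held in a pandas DataFrame (one row per report) with
columns::

    primaryid, caseid, fda_dt      str    identifiers; fda_dt is YYYYMMDD
    report_year                    int    derived from fda_dt
    age_years                      float  NaN when missing
    sex                            str    'F' / 'M' / NaN
    reporter_type                  str    physician / pharmacist / lawyer /
                                          consumer / other_health_professional
                                          / NaN
    country                        str    free text or NaN
    drugs                          tuple  normalized ingredient identifiers
                                          (unmatched names kept as cleaned
                                          text), deduplicated
    reactions                      tuple  MedDRA preferred-term strings
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .drugs import DrugDictionary, resolve_row

log = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther", "rpsr", "indi")
MANDATORY_TABLES = ("demo", "drug", "reac")

REQUIRED_COLUMNS = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drugname"),
    "reac": ("primaryid", "pt"),
}

#: FAERS age-unit codes -> factor converting the stated value to years.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}

#: FAERS occupation codes -> reporter-type labels.
OCCP_TO_REPORTER = {
    "MD": "physician",
    "PH": "pharmacist",
    "LW": "lawyer",
    "CN": "consumer",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
}
REPORTER_TO_OCCP = {
    "physician": "MD",
    "pharmacist": "PH",
    "lawyer": "LW",
    "consumer": "CN",
    "other_health_professional": "OT",
}

REPORT_COLUMNS = ("primaryid", "caseid", "fda_dt", "report_year", "age_years",
                  "sex", "reporter_type", "country", "drugs", "reactions")

_FDA_DT_RE = re.compile(r"^\d{8}$")


@dataclass(frozen=True)
class FaersDialect:
    """Format options for the FAERS ASCII dialect."""

    delimiter: str = "$"
    encoding: str = "utf-8"
    #: On write, replace delimiter characters inside text fields by a space
    #: so the round trip stays exact on the sanitized value.
    strip_delimiter: bool = True


@dataclass
class RawTables:
    """Column-typed FAERS tables plus per-table dropped-row counts."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame = field(default_factory=pd.DataFrame)
    ther: pd.DataFrame = field(default_factory=pd.DataFrame)
    rpsr: pd.DataFrame = field(default_factory=pd.DataFrame)
    indi: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped: dict[str, int] = field(default_factory=dict)


def _table_of(path: Path) -> str | None:
    stem = path.name.lower()
    for name in TABLE_NAMES:
        if stem.startswith(name):
            return name
    return None


def _collect_files(quarter_paths: Sequence[str | Path]) -> dict[str, list[Path]]:
    found: dict[str, list[Path]] = {name: [] for name in TABLE_NAMES}
    for qp in quarter_paths:
        qp = Path(qp)
        if qp.is_dir():
            candidates = sorted(p for p in qp.iterdir() if p.is_file())
        elif qp.exists():
            candidates = [qp]
        else:
            raise FileNotFoundError(f"input path does not exist: {qp}")
        for p in candidates:
            name = _table_of(p)
            if name is not None:
                found[name].append(p)
    return found


def _read_one(path: Path, dialect: FaersDialect) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        encoding=dialect.encoding,
        keep_default_na=False,
        na_values=[""],
        engine="c",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_tables(quarter_paths: Sequence[str | Path],
                dialect: FaersDialect | None = None) -> RawTables:
    """Read FAERS quarterly tables from files and/or quarter directories.

    Each path may be a single $-delimited file (table identified by filename
    prefix, e.g. ``DEMO24Q1.txt``) or a directory containing such files.
    Multiple files for one table are concatenated.

    Rows with a missing primaryid/caseid, or (DEMO) an fda_dt that is not a
    valid 8-digit YYYYMMDD date, are dropped and counted in ``dropped``.

    Raises
    ------
    FileNotFoundError
        If a mandatory table (DEMO, DRUG, REAC) has no file.
    ValueError
        If a table's header lacks required columns.
    """
    dialect = dialect or FaersDialect()
    files = _collect_files(quarter_paths)
    for name in MANDATORY_TABLES:
        if not files[name]:
            raise FileNotFoundError(
                f"mandatory FAERS table {name.upper()!r} not found in {list(map(str, quarter_paths))}")

    frames: dict[str, pd.DataFrame] = {}
    dropped: dict[str, int] = {}
    for name in TABLE_NAMES:
        if not files[name]:
            frames[name] = pd.DataFrame()
            continue
        parts = [_read_one(p, dialect) for p in files[name]]
        df = pd.concat(parts, ignore_index=True) if len(parts) > 1 else parts[0]
        required = REQUIRED_COLUMNS.get(name, ("primaryid",))
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"table {name.upper()}: header mismatch — expected columns "
                f"{list(required)}, found {list(df.columns)}")
        n0 = len(df)
        keep = df["primaryid"].notna()
        if name == "demo":
            keep &= df["caseid"].notna()
            ok_dt = df["fda_dt"].fillna("").str.match(_FDA_DT_RE)
            ok_dt &= pd.to_datetime(df["fda_dt"], format="%Y%m%d",
                                    errors="coerce").notna()
            keep &= ok_dt
        df = df.loc[keep].reset_index(drop=True)
        dropped[name] = n0 - len(df)
        frames[name] = df
    if any(dropped.values()):
        log.info("dropped rows with unparseable keys: %s",
                 {k: v for k, v in dropped.items() if v})
    return RawTables(demo=frames["demo"], drug=frames["drug"],
                     reac=frames["reac"], outc=frames["outc"],
                     ther=frames["ther"], rpsr=frames["rpsr"],
                     indi=frames["indi"], dropped=dropped)


def convert_age_to_years(value, unit) -> float:
    """Convert a FAERS age value + unit code to years; unknown units -> NaN."""
    v = pd.to_numeric(value, errors="coerce")
    if pd.isna(v) or v < 0:
        return np.nan
    factor = AGE_UNIT_TO_YEARS.get(str(unit).strip().upper() if unit is not None
                                   and not pd.isna(unit) else "")
    if factor is None:
        return np.nan
    return float(v) * factor


def assemble_reports(raw: RawTables, dictionary: DrugDictionary) -> pd.DataFrame:
    """Join the raw tables into one report-level row per DEMO row.

    Drug names are normalized through the dictionary (unmatched names kept as
    cleaned text) and deduplicated per report; ages are converted to years;
    reports without reaction rows get an empty ``reactions`` tuple (they are
    excluded later, at the cohort stage).  Drug/reaction rows whose primaryid
    has no DEMO row are counted in ``frame.attrs['unjoined']`` and skipped.
    """
    demo = raw.demo
    n = len(demo)
    out = pd.DataFrame({
        "primaryid": demo["primaryid"].astype(str).to_numpy() if n else
        np.array([], dtype=object),
        "caseid": demo["caseid"].astype(str).to_numpy() if n else
        np.array([], dtype=object),
        "fda_dt": demo["fda_dt"].astype(str).to_numpy() if n else
        np.array([], dtype=object),
    })
    out["report_year"] = (out["fda_dt"].str[:4].astype(int) if n
                          else pd.Series([], dtype=int))

    if n and "age" in demo.columns:
        unit = demo["age_cod"] if "age_cod" in demo.columns else pd.Series(
            [None] * n, index=demo.index)
        out["age_years"] = [convert_age_to_years(v, u)
                            for v, u in zip(demo["age"], unit)]
    else:
        out["age_years"] = np.nan

    if n and "sex" in demo.columns:
        sex = demo["sex"].astype("string").str.strip().str.upper()
        out["sex"] = sex.where(sex.isin(["F", "M"])).astype(object)
    else:
        out["sex"] = None

    if n and "occp_cod" in demo.columns:
        occ = demo["occp_cod"].astype("string").str.strip().str.upper()
        out["reporter_type"] = occ.map(OCCP_TO_REPORTER).astype(object)
    else:
        out["reporter_type"] = None

    if n and "reporter_country" in demo.columns:
        out["country"] = demo["reporter_country"].astype(object).to_numpy()
    else:
        out["country"] = None

    known = set(out["primaryid"])
    unjoined = {"drug": 0, "reac": 0}

    drugs_by_id: dict[str, list[str]] = {}
    if len(raw.drug):
        cache: dict[str, tuple[str, ...]] = {}
        pai = (raw.drug["prod_ai"].to_numpy()
               if "prod_ai" in raw.drug.columns else None)
        for i, (pid, name) in enumerate(zip(raw.drug["primaryid"].astype(str),
                                            raw.drug["drugname"])):
            if pid not in known:
                unjoined["drug"] += 1
                continue
            key = name if isinstance(name, str) else ""
            resolved = cache.get(key)
            if resolved is None:
                resolved = resolve_row(key, dictionary) if key else ()
                cache[key] = resolved
            # fall back to the active-ingredient column when the free-text
            # name matched nothing in the dictionary
            if pai is not None and not any(r in dictionary.class_map
                                           for r in resolved):
                alt = pai[i]
                if isinstance(alt, str) and alt.strip():
                    alt_resolved = resolve_row(alt, dictionary)
                    if any(r in dictionary.class_map for r in alt_resolved):
                        resolved = alt_resolved
            bucket = drugs_by_id.setdefault(pid, [])
            for ing in resolved:
                if ing not in bucket:
                    bucket.append(ing)

    reac_by_id: dict[str, list[str]] = {}
    if len(raw.reac):
        for pid, pt in zip(raw.reac["primaryid"].astype(str), raw.reac["pt"]):
            if pid not in known:
                unjoined["reac"] += 1
                continue
            if not isinstance(pt, str) or not pt.strip():
                continue
            bucket = reac_by_id.setdefault(pid, [])
            term = pt.strip()
            if term not in bucket:
                bucket.append(term)

    out["drugs"] = [tuple(drugs_by_id.get(pid, ())) for pid in out["primaryid"]]
    out["reactions"] = [tuple(reac_by_id.get(pid, ()))
                        for pid in out["primaryid"]]
    out.attrs["unjoined"] = unjoined
    out.attrs["dropped"] = dict(raw.dropped)
    if any(unjoined.values()):
        log.info("unjoinable rows skipped: %s", unjoined)
    return out


def _sanitize(value, dialect: FaersDialect) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    text = str(value)
    if dialect.strip_delimiter and dialect.delimiter in text:
        text = text.replace(dialect.delimiter, " ").strip()
    return text


def _format_age(age_years) -> str:
    if age_years is None or pd.isna(age_years):
        return ""
    v = float(age_years)
    return str(int(v)) if v == int(v) else repr(v)


def _write_dollar(path: Path, header: Sequence[str],
                  rows: Iterable[Sequence], dialect: FaersDialect) -> None:
    sep = dialect.delimiter
    with open(path, "w", encoding=dialect.encoding, newline="\n") as fh:
        fh.write(sep.join(header) + "\n")
        for row in rows:
            fh.write(sep.join(_sanitize(v, dialect) for v in row) + "\n")


def write_tables(reports: pd.DataFrame, out_dir: str | Path,
                 dialect: FaersDialect | None = None) -> dict[str, Path]:
    """Write a report frame back out as DEMO/DRUG/REAC FAERS ASCII files.

    Drug names are written as the normalized ingredient identifiers, so
    ``read_tables`` + ``assemble_reports`` (with a dictionary containing
    identity synonyms, such as the packaged default) round-trips all
    analyzed fields exactly.
    """
    dialect = dialect or FaersDialect()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    demo_rows = []
    drug_rows = []
    reac_rows = []
    for r in reports.itertuples(index=False):
        occp = REPORTER_TO_OCCP.get(r.reporter_type, "") if isinstance(
            r.reporter_type, str) else ""
        age = _format_age(r.age_years)
        demo_rows.append((r.primaryid, r.caseid, r.fda_dt, age,
                          "YR" if age else "", r.sex or "", occp,
                          r.country or ""))
        for seq, drug in enumerate(r.drugs, start=1):
            drug_rows.append((r.primaryid, seq, "PS" if seq == 1 else "C", drug))
        for pt in r.reactions:
            reac_rows.append((r.primaryid, pt))

    paths = {
        "demo": out_dir / "DEMO.txt",
        "drug": out_dir / "DRUG.txt",
        "reac": out_dir / "REAC.txt",
    }
    _write_dollar(paths["demo"],
                  ("primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
                   "occp_cod", "reporter_country"), demo_rows, dialect)
    _write_dollar(paths["drug"],
                  ("primaryid", "drug_seq", "role_cod", "drugname"),
                  drug_rows, dialect)
    _write_dollar(paths["reac"], ("primaryid", "pt"), reac_rows, dialect)
    return paths
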