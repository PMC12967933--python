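"""FDA-recommended deduplication of spontaneous reports.

FAERS cases are resubmitted as follow-ups; all versions share a CASEID but
carry distinct PRIMARYIDs and FDA receipt dates.  The recommended rule keeps,
for each CASEID, the report with the most recent FDA_DT, breaking ties by the
highest PRIMARYID.  PRIMARYIDs are compared numerically when they parse as
integers (the FAERS convention) with a lexicographic fallback; a numeric id
outranks a non-numeric one so the order stays total.
"""
from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Retain one report per caseid: latest fda_dt, ties -> highest primaryid.

    The result is sorted by (caseid, fda_dt, primaryid).  The operation is
    idempotent and invariant to the input row order.  A summary of input
    rows, distinct cases and removed rows is logged and attached as
    ``frame.attrs['dedup']``.
    """
    if reports.empty:
        out = reports.copy()
        out.attrs["dedup"] = {"n_in": 0, "n_out": 0, "n_removed": 0}
        return out
    df = reports.copy()
    pid = df["primaryid"].astype(str)
    pid_num = pd.to_numeric(pid, errors="coerce")
    order = pd.DataFrame({
        "caseid": df["caseid"].astype(str),
        "fda_dt": df["fda_dt"].astype(str),  # YYYYMMDD sorts chronologically
        "pid_num": pid_num,
        "pid_str": pid,
    }, index=df.index)
    idx = order.sort_values(
        ["caseid", "fda_dt", "pid_num", "pid_str"],
        na_position="first", kind="mergesort").index
    df = df.loc[idx]
    out = df.drop_duplicates(subset="caseid", keep="last").reset_index(drop=True)
    summary = {"n_in": len(reports), "n_out": len(out),
               "n_removed": len(reports) - len(out)}
    out.attrs = dict(reports.attrs)
    out.attrs["dedup"] = summary
    log.info("deduplication: %s", summary)
    return out
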