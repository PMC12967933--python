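import pandas as pd
import pytest

from ddisignal.drugs import load_dictionary
from ddisignal.events import default_hemorrhage_terms, default_ns_terms


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture(scope="session")
def hem_terms():
    return default_hemorrhage_terms()


@pytest.fixture(scope="session")
def ns_terms():
    return default_ns_terms()


def make_reports(rows):
    """Build a report frame from compact dicts (defaults filled in)."""
    defaults = {
        "primaryid": None, "caseid": None, "fda_dt": "20220115",
        "age_years": 70.0, "sex": "F", "reporter_type": "physician",
        "country": "US", "drugs": (), "reactions": ("Nausea",),
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, **row)
        if r["primaryid"] is None:
            r["primaryid"] = str(1000 + i)
        if r["caseid"] is None:
            r["caseid"] = str(500 + i)
        r["report_year"] = int(r["fda_dt"][:4])
        out.append(r)
    return pd.DataFrame(out, columns=[
        "primaryid", "caseid", "fda_dt", "report_year", "age_years", "sex",
        "reporter_type", "country", "drugs", "reactions"])


@pytest.fixture
def reports_factory():
    return make_reports
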