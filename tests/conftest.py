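import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from streetprice.records import PriceReport, reports_to_frame
from streetprice.synthetic import benchmark_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DRUG_ORDER = (
    "hydromorphone",
    "buprenorphine",
    "oxymorphone",
    "methadone",
    "oxycodone",
    "hydrocodone",
    "morphine",
    "tramadol",
)


def make_report(**kw) -> PriceReport:
    """A valid crowdsourced report with overridable fields."""
    defaults = dict(
        report_id="r1",
        source="crowdsourced",
        drug="oxycodone",
        formulation="tablet",
        strength_mg=30.0,
        quantity_units=1,
        total_price_usd=30.0,
        transaction_date=dt.date(2012, 3, 1),
        country="US",
        submitted_at=dt.datetime(2012, 3, 1, 12, 0, 0),
        ip_token=None,  # set explicitly in dedup-focused tests
    )
    defaults.update(kw)
    return PriceReport(**defaults)


def frame_of(reports) -> pd.DataFrame:
    return reports_to_frame(reports)


@pytest.fixture(scope="session")
def table1():
    """The published per-(drug, source) summary estimates."""
    return benchmark_table()


@pytest.fixture(scope="session")
def table1_wide(table1):
    wide = table1.pivot(index="drug", columns="source", values="gm_price_per_mg")
    return wide.loc[list(DRUG_ORDER)]


@pytest.fixture(scope="session")
def table1_summaries(table1):
    """The published table shaped like a summarize() output."""
    out = table1.rename(columns={})
    out = out.assign(ci_defined=True)[
        ["drug", "source", "n", "gm_price_per_mg", "ci_low", "ci_high", "ci_defined"]
    ]
    return out
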