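"""Ingestion of the three source dialects into normalized price reports.

Three report streams feed the analysis:

* ``crowdsourced`` — anonymous site submissions (drug, formulation, dose
  strength, price paid, a 5-point price rating, hashed submitter IP,
  submission timestamp, source attribution, bulk-purchase flag);
* ``law_enforcement`` — quarterly officer survey rows (drug, the most
  common dosage strength encountered, price paid, quarter);
* ``marketplace`` — anonymous online marketplace listings priced in
  Bitcoin, converted to US$ at the daily weighted-average exchange rate on
  the posting date.

Each dialect has a documented CSV header (RFC-4180, UTF-8). Rows whose
mandatory fields cannot be parsed are emitted to a rejects table with a
reason — never silently dropped — so parsed + rejected always equals the
input row count.

Dialect column schemas
----------------------
crowdsourced:    report_id, drug, formulation, strength_mg, quantity,
                 price_usd, rating, attribution, ip_hash, submitted_at,
                 transaction_date, country, region, bulk
law_enforcement: report_id, drug, strength_mg, price_usd, quarter[, country]
marketplace:     listing_id, drug, strength_mg, quantity, price_btc,
                 posted_date, ship_origin
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, DomainError, ExchangeRateError
from .records import REPORT_COLUMNS, coerce_frame, price_per_mg, round_money
from .registry import normalize_drug

DIALECTS = ("crowdsourced", "law_enforcement", "marketplace")

REJECT_COLUMNS = ("row_number", "reason", "raw")


class ExchangeRateTable:
    """Daily USD-per-BTC weighted-average exchange rates.

    A missing date is an error by design: each sale is converted at the
    rate of the day it was posted, with no interpolation.
    """

    def __init__(self, rates: pd.Series):
        if (rates <= 0).any():
            raise DomainError("exchange rates must be positive")
        idx = pd.to_datetime(rates.index)
        if idx.duplicated().any():
            raise DomainError("exchange-rate dates must be unique")
        self._rates = pd.Series(rates.to_numpy(dtype=float), index=idx).sort_index()

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExchangeRateTable":
        """Read a 2-column CSV (ISO-8601 date, usd_per_btc)."""
        frame = pd.read_csv(path)
        if frame.shape[1] < 2:
            raise ConfigurationError(f"exchange-rate file {path} needs 2 columns")
        date_col, rate_col = frame.columns[:2]
        return cls(pd.Series(frame[rate_col].to_numpy(), index=frame[date_col]))

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {"date": self._rates.index.strftime("%Y-%m-%d"), "usd_per_btc": self._rates.to_numpy()}
        )
        out.to_csv(path, index=False)

    def usd_per_btc(self, date: dt.date | str | pd.Timestamp) -> float:
        key = pd.Timestamp(date).normalize()
        try:
            return float(self._rates.loc[key])
        except KeyError:
            raise ExchangeRateError(f"no exchange rate for {key.date().isoformat()}") from None

    def __len__(self) -> int:
        return len(self._rates)


def convert_currency(amount_btc: float, date, rates: ExchangeRateTable) -> float:
    """Convert a BTC amount to US$ at the posting-date rate.

    Linear in the amount; result rounded half-even at 4 decimals.
    """
    if amount_btc < 0:
        raise DomainError("amount_btc must be nonnegative")
    return round_money(amount_btc * rates.usd_per_btc(date))


def _parse_float(value, *, positive=False, nonnegative=False) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    out = float(value)
    if positive and out <= 0:
        raise ValueError(f"must be positive: {value!r}")
    if nonnegative and out < 0:
        raise ValueError(f"must be nonnegative: {value!r}")
    return out


def _quarter_midpoint(quarter: str) -> dt.date:
    period = pd.Period(str(quarter).strip(), freq="Q")
    mid = period.start_time + (period.end_time - period.start_time) / 2
    return mid.date()


def read_reports(
    path: str | Path,
    dialect: str,
    rates: ExchangeRateTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one source file into (reports, rejects) DataFrames.

    Returns the normalized report frame (columns ``REPORT_COLUMNS``) and a
    rejects frame (row_number, reason, raw). ``rates`` is required for the
    marketplace dialect whenever a row is priced in BTC.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows, rejects = [], []
    for i, rec in enumerate(raw.to_dict(orient="records")):
        try:
            rows.append(_parse_row(rec, dialect, rates))
        except (ValueError, KeyError, ExchangeRateError) as exc:
            rejects.append({"row_number": i, "reason": str(exc), "raw": repr(rec)})
    reports = coerce_frame(pd.DataFrame(rows, columns=list(REPORT_COLUMNS)))
    rejects_frame = pd.DataFrame(rejects, columns=list(REJECT_COLUMNS))
    return reports, rejects_frame


def _parse_row(rec: dict, dialect: str, rates: ExchangeRateTable | None) -> dict:
    get = lambda k: rec.get(k, "").strip() if isinstance(rec.get(k), str) else rec.get(k)

    drug = normalize_drug(get("drug") or "")
    if drug is None:
        raise ValueError(f"unknown drug {rec.get('drug')!r}")

    out: dict = {c: None for c in REPORT_COLUMNS}
    out["drug"] = drug
    out["source"] = dialect
    out["bulk_flag"] = "unanswered"
    out["quantity_units"] = 1
    out["country"] = "US"

    if dialect == "crowdsourced":
        out["report_id"] = get("report_id") or None
        out["formulation"] = get("formulation") or None
        out["strength_mg"] = _parse_float(get("strength_mg"), positive=True)
        qty = _parse_float(get("quantity"), positive=True)
        out["quantity_units"] = int(qty) if qty is not None else 1
        price = _parse_float(get("price_usd"), nonnegative=True)
        if price is None:
            raise ValueError("missing price")
        out["total_price_usd"] = round_money(price)
        rating = get("rating")
        if rating not in (None, ""):
            rating = int(float(rating))
            if rating not in (1, 2, 3, 4, 5):
                raise ValueError(f"rating out of range: {rating}")
            out["rating"] = rating
        attribution = (get("attribution") or "").lower() or None
        if attribution is not None and attribution not in ("personal", "swim", "internet"):
            raise ValueError(f"unknown attribution {attribution!r}")
        out["attribution"] = attribution
        out["ip_token"] = get("ip_hash") or None
        if get("submitted_at"):
            out["submitted_at"] = pd.Timestamp(get("submitted_at"))
        if get("transaction_date"):
            out["transaction_date"] = pd.Timestamp(get("transaction_date")).date()
        elif out["submitted_at"] is not None:
            out["transaction_date"] = out["submitted_at"].date()
        else:
            raise ValueError("missing transaction/submission date")
        out["country"] = (get("country") or "US").upper()
        out["region"] = get("region") or None
        bulk = (get("bulk") or "unanswered").lower()
        if bulk not in ("yes", "no", "unanswered"):
            raise ValueError(f"unknown bulk flag {bulk!r}")
        out["bulk_flag"] = bulk

    elif dialect == "law_enforcement":
        out["report_id"] = get("report_id") or None
        # Officers report the price of the most common dosage strength; one
        # unit is assumed for the per-mg conversion.
        out["strength_mg"] = _parse_float(get("strength_mg"), positive=True)
        price = _parse_float(get("price_usd"), nonnegative=True)
        if price is None:
            raise ValueError("missing price")
        out["total_price_usd"] = round_money(price)
        quarter = get("quarter")
        if not quarter:
            raise ValueError("missing quarter")
        out["transaction_date"] = _quarter_midpoint(quarter)
        out["country"] = (get("country") or "US").upper()

    else:  # marketplace
        out["report_id"] = get("listing_id") or get("report_id") or None
        out["strength_mg"] = _parse_float(get("strength_mg"), positive=True)
        qty = _parse_float(get("quantity"), positive=True)
        out["quantity_units"] = int(qty) if qty is not None else 1
        if not get("posted_date"):
            raise ValueError("missing posted_date")
        posted = pd.Timestamp(get("posted_date")).date()
        out["transaction_date"] = posted
        btc = _parse_float(get("price_btc"), nonnegative=True)
        usd = _parse_float(get("price_usd"), nonnegative=True)
        if btc is not None:
            if rates is None:
                raise ConfigurationError("marketplace dialect with BTC prices requires an exchange-rate table")
            try:
                usd = convert_currency(btc, posted, rates)
            except ExchangeRateError:
                raise ValueError(f"no exchange rate for {posted.isoformat()}") from None
        if usd is None:
            raise ValueError("missing price")
        out["total_price_usd"] = round_money(usd)
        origin = get("ship_origin")
        out["ship_origin"] = origin.upper() if origin else None
        out["country"] = out["ship_origin"] or "US"

    if out["strength_mg"] is not None:
        out["price_per_mg"] = price_per_mg(
            out["total_price_usd"], out["quantity_units"], out["strength_mg"]
        )
    return out


def write_reports(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a normalized report frame to CSV (dates ISO-8601, blanks for null)."""
    out = frame.copy()
    out["transaction_date"] = pd.to_datetime(out["transaction_date"]).dt.strftime("%Y-%m-%d")
    ts = pd.to_datetime(out["submitted_at"])
    out["submitted_at"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S").where(ts.notna(), "")
    out.to_csv(path, index=False)


def read_normalized(path: str | Path) -> pd.DataFrame:
    """Re-read a normalized report CSV written by :func:`write_reports`."""
    return coerce_frame(pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None}))
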