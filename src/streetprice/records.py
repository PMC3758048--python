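"""Normalized price-report records.

One ``PriceReport`` is a single black-market transaction observation,
normalized across the three surveillance streams to US$ per milligram of
active ingredient. The in-memory working container is a pandas DataFrame
with the columns of :data:`REPORT_COLUMNS`; the pydantic model is the
row-level schema used to validate records at the ingestion boundary and in
tests.
"""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DomainError
from .registry import DRUGS

Source = Literal["crowdsourced", "law_enforcement", "marketplace"]
Attribution = Literal["personal", "swim", "internet"]
BulkFlag = Literal["yes", "no", "unanswered"]

#: Column order of the normalized report DataFrame / CSV.
REPORT_COLUMNS: tuple[str, ...] = (
    "report_id",
    "source",
    "drug",
    "formulation",
    "strength_mg",
    "quantity_units",
    "total_price_usd",
    "price_per_mg",
    "transaction_date",
    "country",
    "region",
    "rating",
    "attribution",
    "ip_token",
    "submitted_at",
    "bulk_flag",
    "ship_origin",
)


def round_money(value: float, places: int = 4) -> float:
    """Round a monetary amount half-to-even at `places` decimals.

    Internal monetary arithmetic is carried at 4 decimals, display at 2,
    so cent-level results are reproducible across platforms.
    """
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def price_per_mg(total_price_usd: float, quantity_units: int, strength_mg: float) -> float:
    """US$ per milligram of active ingredient for one transaction.

    total / (units x mg-per-unit), rounded half-even at 4 decimals.
    """
    if strength_mg is None or strength_mg <= 0:
        raise DomainError(f"strength_mg must be positive, got {strength_mg!r}")
    if quantity_units is None or quantity_units < 1:
        raise DomainError(f"quantity_units must be >= 1, got {quantity_units!r}")
    if total_price_usd < 0:
        raise DomainError(f"total_price_usd must be nonnegative, got {total_price_usd!r}")
    return round_money(total_price_usd / (quantity_units * strength_mg))


class PriceReport(BaseModel):
    """One normalized observation of a black-market transaction price."""

    model_config = ConfigDict(frozen=True)

    report_id: str
    source: Source
    drug: str
    formulation: Optional[str] = None
    strength_mg: Optional[float] = None
    quantity_units: int = 1
    total_price_usd: float
    price_per_mg: Optional[float] = None
    transaction_date: dt.date
    country: str = "US"
    region: Optional[str] = None
    rating: Optional[int] = None
    attribution: Optional[Attribution] = None
    ip_token: Optional[str] = None
    submitted_at: Optional[dt.datetime] = None
    bulk_flag: BulkFlag = "unanswered"
    ship_origin: Optional[str] = None

    @field_validator("drug")
    @classmethod
    def _drug_known(cls, v: str) -> str:
        if v not in DRUGS:
            raise ValueError(f"unknown drug {v!r}")
        return v

    @field_validator("strength_mg")
    @classmethod
    def _strength_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("strength_mg must be positive when present")
        return v

    @field_validator("quantity_units")
    @classmethod
    def _quantity_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("quantity_units must be >= 1")
        return v

    @field_validator("total_price_usd")
    @classmethod
    def _price_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("total_price_usd must be nonnegative")
        return v

    @field_validator("rating")
    @classmethod
    def _rating_range(cls, v):
        if v is not None and v not in (1, 2, 3, 4, 5):
            raise ValueError("rating must be in 1..5 when present")
        return v

    @model_validator(mode="after")
    def _derive_price_per_mg(self) -> "PriceReport":
        if self.price_per_mg is None and self.strength_mg is not None:
            object.__setattr__(
                self,
                "price_per_mg",
                price_per_mg(self.total_price_usd, self.quantity_units, self.strength_mg),
            )
        return self


def reports_to_frame(reports: Iterable[PriceReport]) -> pd.DataFrame:
    """Stack PriceReport records into the normalized DataFrame."""
    rows = [r.model_dump() for r in reports]
    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return coerce_frame(frame)


def coerce_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Coerce a report frame to canonical dtypes (nullable where optional)."""
    out = frame.copy()
    for col in REPORT_COLUMNS:
        if col not in out.columns:
            out[col] = None
    out = out[list(REPORT_COLUMNS)]
    out["strength_mg"] = pd.to_numeric(out["strength_mg"], errors="coerce")
    out["quantity_units"] = pd.to_numeric(out["quantity_units"], errors="coerce").fillna(1).astype("int64")
    out["total_price_usd"] = pd.to_numeric(out["total_price_usd"], errors="coerce")
    out["price_per_mg"] = pd.to_numeric(out["price_per_mg"], errors="coerce")
    out["rating"] = pd.to_numeric(out["rating"], errors="coerce").astype("Int64")
    out["transaction_date"] = pd.to_datetime(out["transaction_date"], errors="coerce")
    out["submitted_at"] = pd.to_datetime(out["submitted_at"], errors="coerce")
    for col in ("report_id", "source", "drug", "formulation", "country", "region",
                "attribution", "ip_token", "bulk_flag", "ship_origin"):
        out[col] = out[col].astype("object").where(out[col].notna(), None)
    return out


def frame_to_reports(frame: pd.DataFrame) -> list[PriceReport]:
    """Validate each row of a normalized frame as a PriceReport."""
    reports = []
    for row in frame.to_dict(orient="records"):
        clean = {}
        for key, value in row.items():
            if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NaT:
                continue
            if pd.isna(value):
                continue
            if key == "transaction_date":
                value = pd.Timestamp(value).date()
            elif key == "submitted_at":
                value = pd.Timestamp(value).to_pydatetime()
            elif key == "rating":
                value = int(value)
            clean[key] = value
        reports.append(PriceReport(**clean))
    return reports
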