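"""Credibility and eligibility filters for price-report streams.

Crowdsourced submissions are noisy: the pipeline applies the two
credibility rules used for the 2012 cross-validation study — drop
submissions the submitters themselves rated at the extremes of a 5-point
"cheap"/"overpriced" price scale, and collapse near-simultaneous
same-IP/same-drug duplicate entries — together with eligibility rules
(reporting window, geography, completeness of strength data) and an
optional bulk-purchase exclusion.

Every rule records how many reports it removed; the kept set plus all
per-rule removals always partitions the input exactly.

Rule order is fixed: eligibility (window + geography + ship origin) →
completeness → rating → duplicate → bulk. Because the predicates of the
non-dedup rules are pairwise independent of ordering, permuting them
changes only the audit attribution, never the final kept set, as long as
deduplication runs last.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError

RULE_ORDER = ("eligibility", "completeness", "rating", "duplicate", "bulk")


class FilterConfig(BaseModel):
    """Settings for one filtering pass over a single source stream."""

    model_config = ConfigDict(frozen=True)

    window_start: dt.date
    window_end: dt.date
    country: str = "US"
    exclude_ratings: frozenset[int] = frozenset({1, 5})
    duplicate_window_seconds: float = 10.0
    require_strength: bool = True
    require_formulation: bool = False
    exclude_bulk: bool = False
    marketplace_ship_origin: Optional[str] = "US"
    #: Filter the window on the submission timestamp where available
    #: (falling back to the transaction date), or on the transaction date.
    window_on: str = "submitted"

    @model_validator(mode="after")
    def _check(self) -> "FilterConfig":
        if self.window_start > self.window_end:
            raise ConfigurationError("window_start must be <= window_end")
        if self.duplicate_window_seconds <= 0:
            raise ConfigurationError("duplicate_window_seconds must be positive")
        if self.window_on not in ("submitted", "transaction"):
            raise ConfigurationError("window_on must be 'submitted' or 'transaction'")
        return self


@dataclass
class FilterResult:
    """Kept reports plus a per-rule audit of removals."""

    kept: pd.DataFrame
    removed_by_rule: dict[str, int]
    rule_order: tuple[str, ...] = RULE_ORDER
    removed: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + sum(self.removed_by_rule.values())

    def audit_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": len(self.kept),
                "rule_order": list(self.rule_order),
                "removed_by_rule": self.removed_by_rule,
            },
            indent=2,
        )


def _partition(frame: pd.DataFrame, keep_mask) -> tuple[pd.DataFrame, pd.DataFrame]:
    return frame[keep_mask], frame[~keep_mask]


def filter_eligibility(reports: pd.DataFrame, config: FilterConfig):
    """Keep reports inside the date window, country, and (marketplace) ship origin."""
    if reports.empty:
        return reports, reports
    start, end = pd.Timestamp(config.window_start), pd.Timestamp(config.window_end)
    if config.window_on == "submitted":
        when = pd.to_datetime(reports["submitted_at"]).fillna(
            pd.to_datetime(reports["transaction_date"])
        )
    else:
        when = pd.to_datetime(reports["transaction_date"])
    in_window = (when >= start) & (when < end + pd.Timedelta(days=1))
    in_country = reports["country"].astype(str).str.upper() == config.country.upper()
    keep = in_window & in_country
    if config.marketplace_ship_origin is not None:
        is_market = reports["source"] == "marketplace"
        origin_ok = (
            reports["ship_origin"].astype(str).str.upper()
            == config.marketplace_ship_origin.upper()
        )
        keep &= ~is_market | origin_ok
    return _partition(reports, keep)


def filter_completeness(reports: pd.DataFrame, config: FilterConfig):
    """Keep reports carrying dose-strength (and, where required, formulation) data."""
    if reports.empty:
        return reports, reports
    keep = pd.Series(True, index=reports.index)
    if config.require_strength:
        keep &= reports["strength_mg"].notna()
    if config.require_formulation:
        # Formulation is only collected on the crowdsourced form.
        is_crowd = reports["source"] == "crowdsourced"
        keep &= ~is_crowd | reports["formulation"].notna()
    return _partition(reports, keep)


def filter_outlier_ratings(reports: pd.DataFrame, config: FilterConfig):
    """Drop crowdsourced reports user-rated at the excluded price extremes.

    Only reports *identified* as outliers are removed: unrated reports and
    reports from sources without a rating field pass through.
    """
    if reports.empty:
        return reports, reports
    is_crowd = reports["source"] == "crowdsourced"
    rated_out = reports["rating"].isin(list(config.exclude_ratings)).fillna(False)
    return _partition(reports, ~(is_crowd & rated_out.astype(bool)))


def deduplicate(reports: pd.DataFrame, config: FilterConfig):
    """Collapse same-IP, same-drug submissions arriving within the duplicate window.

    Within each (ip_token, drug) group ordered by submission time, a report
    is removed when it falls strictly less than ``duplicate_window_seconds``
    after the most recently *retained* report of the group (sliding anchor);
    the earliest report of a burst is always retained. Reports without an IP
    token or timestamp pass through.
    """
    if reports.empty:
        return reports, reports
    eligible = reports["ip_token"].notna() & reports["submitted_at"].notna()
    drop_index: list = []
    subset = reports[eligible]
    for _, group in subset.groupby(["ip_token", "drug"], sort=False):
        if len(group) < 2:
            continue
        group = group.sort_values(["submitted_at", "report_id"], kind="mergesort")
        anchor = None
        for idx, ts in zip(group.index, group["submitted_at"]):
            if anchor is not None and (ts - anchor).total_seconds() < config.duplicate_window_seconds:
                drop_index.append(idx)
            else:
                anchor = ts
    keep = ~reports.index.isin(drop_index)
    return _partition(reports, keep)


def filter_bulk(reports: pd.DataFrame, config: FilterConfig):
    """Optionally drop reports flagged as bulk purchases (>10 units)."""
    if reports.empty or not config.exclude_bulk:
        return reports, reports.iloc[0:0]
    return _partition(reports, reports["bulk_flag"] != "yes")


_RULES = {
    "eligibility": filter_eligibility,
    "completeness": filter_completeness,
    "rating": filter_outlier_ratings,
    "duplicate": deduplicate,
    "bulk": filter_bulk,
}


def apply_filters(
    reports: pd.DataFrame,
    config: FilterConfig,
    rule_order: tuple[str, ...] = RULE_ORDER,
) -> FilterResult:
    """Run the full rule chain and return kept reports plus the audit trail."""
    unknown = set(rule_order) - set(_RULES)
    if unknown:
        raise ConfigurationError(f"unknown filter rules: {sorted(unknown)}")
    kept = reports
    removed_by_rule: dict[str, int] = {}
    removed: dict[str, pd.DataFrame] = {}
    for rule in rule_order:
        kept, dropped = _RULES[rule](kept, config)
        removed_by_rule[rule] = len(dropped)
        removed[rule] = dropped
    return FilterResult(
        kept=kept, removed_by_rule=removed_by_rule, rule_order=tuple(rule_order), removed=removed
    )
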