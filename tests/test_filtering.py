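import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from streetprice.filtering import (
    FilterConfig,
    apply_filters,
    deduplicate,
    filter_completeness,
    filter_outlier_ratings,
)

from conftest import frame_of, make_report


@pytest.fixture()
def config():
    return FilterConfig(window_start=dt.date(2012, 1, 1), window_end=dt.date(2012, 6, 30))


def _crowd(i, **kw):
    kw.setdefault("report_id", f"r{i}")
    return make_report(**kw)


class TestCompleteness:
    def test_missing_strength_removed(self, config):
        frame = frame_of(
            [_crowd(0), _crowd(1, strength_mg=None, total_price_usd=10.0), _crowd(2)]
        )
        kept, removed = filter_completeness(frame, config)
        assert len(kept) == 2 and len(removed) == 1
        assert removed.iloc[0]["report_id"] == "r1"

    def test_all_complete_is_identity(self, config):
        frame = frame_of([_crowd(i) for i in range(3)])
        kept, removed = filter_completeness(frame, config)
        assert len(kept) == 3 and removed.empty

    def test_empty_input(self, config):
        frame = frame_of([])
        kept, removed = filter_completeness(frame, config)
        assert kept.empty and removed.empty


class TestOutlierRatings:
    def test_extreme_ratings_removed_nulls_kept(self, config):
        ratings = [1, 2, 3, 4, 5, None]
        frame = frame_of([_crowd(i, rating=r) for i, r in enumerate(ratings)])
        kept, removed = filter_outlier_ratings(frame, config)
        assert sorted(kept["rating"].dropna()) == [2, 3, 4]
        assert kept["rating"].isna().sum() == 1
        assert sorted(removed["rating"]) == [1, 5]

    def test_rule_scope_is_crowdsourced_only(self, config):
        law = make_report(
            report_id="law", source="law_enforcement", rating=None, ip_token=None,
            submitted_at=None, formulation=None,
        )
        crowd = _crowd(0, rating=1)
        kept, removed = filter_outlier_ratings(frame_of([law, crowd]), config)
        assert list(kept["report_id"]) == ["law"]
        assert list(removed["report_id"]) == ["r0"]

    def test_all_midscale_kept(self, config):
        frame = frame_of([_crowd(i, rating=3) for i in range(4)])
        kept, removed = filter_outlier_ratings(frame, config)
        assert len(kept) == 4 and removed.empty


def _timed(i, ip, drug, seconds):
    return _crowd(
        i,
        ip_token=ip,
        drug=drug,
        strength_mg=30.0,
        submitted_at=dt.datetime(2012, 3, 1, 12, 0, 0) + dt.timedelta(seconds=seconds),
    )


class TestDeduplicate:
    def test_dyad_keeps_earliest(self, config):
        frame = frame_of([_timed(0, "a", "oxycodone", 0), _timed(1, "a", "oxycodone", 5)])
        kept, removed = deduplicate(frame, config)
        assert list(kept["report_id"]) == ["r0"]
        assert list(removed["report_id"]) == ["r1"]

    def test_different_drugs_not_duplicates(self, config):
        frame = frame_of([_timed(0, "a", "oxycodone", 0), _timed(1, "a", "morphine", 5)])
        kept, removed = deduplicate(frame, config)
        assert len(kept) == 2 and removed.empty

    def test_sliding_anchor_chain(self, config):
        # 0 s and 12 s survive; 6 s is inside the window of the retained 0 s
        frame = frame_of([_timed(i, "a", "oxycodone", s) for i, s in enumerate([0, 6, 12])])
        kept, _ = deduplicate(frame, config)
        assert sorted(kept["report_id"]) == ["r0", "r2"]

    def test_reports_without_ip_pass_through(self, config):
        frame = frame_of(
            [_crowd(0, ip_token=None), _crowd(1, ip_token=None)]
        )
        kept, removed = deduplicate(frame, config)
        assert len(kept) == 2 and removed.empty


def _oracle_kept(times, window):
    """Independent characterization of the sliding-anchor rule.

    Enumerate all subsets of the (sorted) group; the kept set is the unique
    subset that (a) contains the earliest report, (b) has all consecutive
    kept-to-kept gaps >= window, and (c) every removed report lies strictly
    within the window after the latest kept report preceding it.
    """
    order = sorted(range(len(times)), key=lambda i: times[i])
    ts = [times[i] for i in order]
    for mask in itertools.product([True, False], repeat=len(ts)):
        if not mask[0]:
            continue
        kept = [t for t, m in zip(ts, mask) if m]
        if any(b - a < window for a, b in zip(kept, kept[1:])):
            continue
        ok = True
        for t, m in zip(ts, mask):
            if m:
                continue
            prev = max(k for k in kept if k <= t)
            if t - prev >= window:
                ok = False
                break
        if ok:
            return sorted(kept)
    raise AssertionError("no valid partition found")


@given(
    gaps=st.lists(st.floats(0.0, 25.0), min_size=1, max_size=4),
)
def test_dedup_matches_brute_force_oracle(gaps):
    """Dedup of a single IP/drug group equals subset-enumeration of the rule."""
    config = FilterConfig(window_start=dt.date(2012, 1, 1), window_end=dt.date(2012, 6, 30))
    times = list(np.cumsum([0.0] + [round(g, 3) for g in gaps]))
    frame = frame_of([_timed(i, "a", "oxycodone", s) for i, s in enumerate(times)])
    kept, _ = deduplicate(frame, config)
    got = sorted(
        (pd.to_datetime(kept["submitted_at"]) - pd.Timestamp(2012, 3, 1, 12)).dt.total_seconds()
    )
    assert got == pytest.approx(_oracle_kept(times, 10.0))


class TestApplyFilters:
    def test_each_rule_removes_exactly_one(self, config):
        reports = [
            _crowd(0),  # kept
            _crowd(1, transaction_date=dt.date(2011, 7, 1),
                   submitted_at=dt.datetime(2011, 7, 1, 9, 0, 0)),  # window
            _crowd(2, strength_mg=None, total_price_usd=5.0),  # completeness
            _crowd(3, rating=1),  # rating (cheap extreme)
            _timed(4, "dup", "oxycodone", 0),  # kept (anchor)
            _timed(5, "dup", "oxycodone", 4),  # duplicate
            _crowd(6, rating=4),
            _crowd(7, rating=None),
            _crowd(8),
            _crowd(9),
        ]
        result = apply_filters(frame_of(reports), config)
        assert result.removed_by_rule == {
            "eligibility": 1, "completeness": 1, "rating": 1, "duplicate": 1, "bulk": 0,
        }
        assert len(result.kept) == 6
        assert result.n_input == 10

    def test_geography_counts_under_eligibility(self, config):
        reports = [_crowd(0), _crowd(1, country="CA")]
        result = apply_filters(frame_of(reports), config)
        assert result.removed_by_rule["eligibility"] == 1

    def test_conservation_and_audit(self, config):
        reports = [_crowd(i, rating=(i % 5) + 1) for i in range(20)]
        result = apply_filters(frame_of(reports), config)
        assert len(result.kept) + sum(result.removed_by_rule.values()) == 20
        assert "removed_by_rule" in result.audit_json()

    def test_idempotence(self, config):
        reports = [_crowd(i, rating=(i % 5) + 1) for i in range(12)] + [
            _timed(20, "a", "oxycodone", 0),
            _timed(21, "a", "oxycodone", 3),
        ]
        first = apply_filters(frame_of(reports), config)
        second = apply_filters(first.kept, config)
        assert sum(second.removed_by_rule.values()) == 0
        assert list(second.kept["report_id"]) == list(first.kept["report_id"])

    def test_disabled_rules_are_inert(self):
        config = FilterConfig(
            window_start=dt.date(2000, 1, 1),
            window_end=dt.date(2030, 1, 1),
            exclude_ratings=frozenset(),
        )
        reports = [_crowd(i, rating=r) for i, r in enumerate([1, 5, 3])]
        result = apply_filters(frame_of(reports), config)
        assert len(result.kept) == 3

    def test_kept_set_invariant_under_rule_permutation_with_dedup_last(self, config):
        reports = [
            _crowd(0), _crowd(1, rating=5), _crowd(2, strength_mg=None, total_price_usd=4.0),
            _crowd(3, country="GB"), _timed(4, "a", "oxycodone", 0),
            _timed(5, "a", "oxycodone", 2), _crowd(6, rating=2),
        ]
        frame = frame_of(reports)
        baseline = apply_filters(frame, config).kept["report_id"].tolist()
        for perm in itertools.permutations(("eligibility", "completeness", "rating", "bulk")):
            kept = apply_filters(frame, config, rule_order=perm + ("duplicate",)).kept
            assert sorted(kept["report_id"]) == sorted(baseline)

    def test_bulk_exclusion_switch(self):
        config = FilterConfig(
            window_start=dt.date(2012, 1, 1), window_end=dt.date(2012, 6, 30), exclude_bulk=True
        )
        reports = [_crowd(0, bulk_flag="yes", quantity_units=20), _crowd(1, bulk_flag="no")]
        result = apply_filters(frame_of(reports), config)
        assert result.removed_by_rule["bulk"] == 1
        assert list(result.kept["report_id"]) == ["r1"]
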