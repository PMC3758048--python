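"""Synthetic price-report streams with the statistical structure the
pipeline assumes.

No raw report database ships with the study this pipeline reproduces, so
every stage is exercised on generated data. Per (drug, source) cell,
per-mg prices are drawn log-normally around a configurable true geometric
mean; the default parameterization takes the published 2012 per-cell
geometric means and report counts as ground truth and back-solves the
log-scale SD of each cell from the printed 95% CI half-width via the
log-t interval.

Crowdsourced cells are contaminated the way the live site's data were:

* a configurable fraction of submissions are price outliers whose prices
  are multiplied or divided by a large factor and whose 5-point price
  rating is set to the matching extreme (1 = "cheap", 5 = "overpriced") —
  by default one quarter of submissions, the rated-outlier share the
  study reported;
* a fraction are near-simultaneous same-IP duplicate clones;
* a fraction lack dose-strength data;
* 10% carry a positive bulk-purchase flag.

Each cell draws from its own pseudo-random stream keyed by (seed, drug,
source), so adding a drug never perturbs another cell's draws and a fixed
seed reproduces output bitwise.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, replace
from importlib import resources
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .estimation import summarize
from .filtering import FilterConfig, apply_filters
from .ingestion import ExchangeRateTable
from .records import REPORT_COLUMNS, coerce_frame, round_money

SOURCES = ("crowdsourced", "law_enforcement", "marketplace")

#: Study reporting windows per source (crowdsourced and officer survey ran
#: over the first half of 2012; the marketplace was scraped in October 2012).
STUDY_WINDOWS: dict[str, tuple[dt.date, dt.date]] = {
    "crowdsourced": (dt.date(2012, 1, 1), dt.date(2012, 6, 30)),
    "law_enforcement": (dt.date(2012, 1, 1), dt.date(2012, 6, 30)),
    "marketplace": (dt.date(2012, 10, 1), dt.date(2012, 10, 31)),
}

#: Marketed unit strengths (mg) sampled for each drug.
STRENGTHS_MG: dict[str, tuple[float, ...]] = {
    "hydromorphone": (2, 4, 8),
    "buprenorphine": (2, 8),
    "oxymorphone": (5, 10, 20, 40),
    "methadone": (5, 10),
    "oxycodone": (5, 10, 15, 20, 30, 80),
    "hydrocodone": (5, 7.5, 10),
    "morphine": (15, 30, 60, 100),
    "tramadol": (50, 100),
}

#: "Most common dosage strength" reported on the officer survey.
COMMON_STRENGTH_MG: dict[str, float] = {
    "hydromorphone": 4,
    "buprenorphine": 8,
    "oxymorphone": 10,
    "methadone": 10,
    "oxycodone": 30,
    "hydrocodone": 10,
    "morphine": 30,
    "tramadol": 50,
}

_REGIONS = ("NY", "CA", "TX", "FL", "OH", "CO", "WA", "KY", "MA", "IL")


@dataclass(frozen=True)
class CellParams:
    """Ground truth for one (drug, source) cell."""

    true_gm: float
    log_sd: float
    n: int


@dataclass(frozen=True)
class GeneratorParams:
    """Full configuration of the synthetic-report generator."""

    cells: dict[tuple[str, str], CellParams]
    outlier_fraction: float = 0.25
    outlier_multiplier_range: tuple[float, float] = (4.0, 10.0)
    duplicate_fraction: float = 0.02
    duplicate_gap_seconds: float = 5.0
    missing_strength_fraction: float = 0.03
    bulk_fraction: float = 0.10
    rating_missing_fraction: float = 0.20
    foreign_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in (
            "outlier_fraction",
            "duplicate_fraction",
            "missing_strength_fraction",
            "bulk_fraction",
            "rating_missing_fraction",
            "foreign_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value < 1:
                raise DomainError(f"{name} must be in [0, 1), got {value}")
        if not 0 < self.duplicate_gap_seconds < 10:
            raise DomainError("duplicate_gap_seconds must be in (0, 10)")
        for key, cell in self.cells.items():
            if cell.true_gm <= 0 or cell.log_sd <= 0 or cell.n < 1:
                raise DomainError(f"invalid cell parameters for {key}: {cell}")

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


def backsolve_log_sd(ci_low: float, ci_high: float, n: int) -> float:
    """Log-scale SD implied by a printed geometric-mean CI.

    Inverts the log-t interval: half-width on the log scale is
    t_{0.975,n-1}·s/√n, so s = ln(hi/lo)/2 · √n / t.
    """
    if not 0 < ci_low < ci_high or n < 2:
        raise DomainError("need 0 < ci_low < ci_high and n >= 2")
    half = float(np.log(ci_high / ci_low)) / 2.0
    return half * np.sqrt(n) / stats.t.ppf(0.975, n - 1)


def benchmark_table() -> pd.DataFrame:
    """The published 2012 per-cell summary table (drug, source, n, gm, CI)."""
    with resources.as_file(
        resources.files("streetprice.data") / "benchmark_prices_2012.csv"
    ) as path:
        return pd.read_csv(path)


def default_params_from_table1(seed: int = 0, **overrides) -> GeneratorParams:
    """Generator parameters matching the published per-cell estimates.

    Every cell's true geometric mean and report count are the printed
    values; the per-cell log SD is back-solved from the printed CI.
    """
    cells = {}
    for row in benchmark_table().to_dict(orient="records"):
        cells[(row["drug"], row["source"])] = CellParams(
            true_gm=float(row["gm_price_per_mg"]),
            log_sd=backsolve_log_sd(float(row["ci_low"]), float(row["ci_high"]), int(row["n"])),
            n=int(row["n"]),
        )
    return GeneratorParams(cells=cells, seed=seed, **overrides)


def _per_mg(total: np.ndarray, mg: np.ndarray) -> np.ndarray:
    # same half-even decimal rounding as the ingestion path, so a CSV round
    # trip reproduces price_per_mg exactly
    return np.array([round_money(t / m) for t, m in zip(total, mg)])


def _cell_rng(seed: int, drug: str, source: str) -> np.random.Generator:
    key = zlib.crc32(f"{drug}|{source}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _window_timestamps(rng, n, window, margin_seconds=3600):
    start = pd.Timestamp(window[0])
    end = pd.Timestamp(window[1]) + pd.Timedelta(days=1) - pd.Timedelta(seconds=margin_seconds)
    span = (end - start).total_seconds()
    secs = np.sort(rng.uniform(0, span, n))
    return start + pd.to_timedelta(np.round(secs), unit="s")


def generate_reports(params: GeneratorParams) -> pd.DataFrame:
    """Draw one synthetic normalized report stream (all sources, all cells)."""
    frames = [
        _generate_cell(drug, source, cell, params)
        for (drug, source), cell in sorted(params.cells.items())
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=REPORT_COLUMNS)
    return coerce_frame(out)


def _generate_cell(drug, source, cell, params: GeneratorParams) -> pd.DataFrame:
    rng = _cell_rng(params.seed, drug, source)
    n = cell.n
    per_mg = cell.true_gm * np.exp(cell.log_sd * rng.standard_normal(n))
    strengths = rng.choice(STRENGTHS_MG[drug], size=n)
    rows = pd.DataFrame({c: [None] * n for c in REPORT_COLUMNS})
    rows["report_id"] = [f"{source[:2]}-{drug[:4]}-{i:05d}" for i in range(n)]
    rows["source"] = source
    rows["drug"] = drug
    rows["quantity_units"] = 1
    rows["country"] = "US"
    rows["bulk_flag"] = "unanswered"

    if source == "crowdsourced":
        rows["formulation"] = rng.choice(["tablet", "capsule", "solution"], size=n, p=[0.8, 0.15, 0.05])
        rows["strength_mg"] = strengths
        bulk = rng.random(n) < params.bulk_fraction
        qty = np.ones(n, dtype=int)
        qty[bulk] = rng.integers(11, 60, size=int(bulk.sum()))
        rows["quantity_units"] = qty
        rows["bulk_flag"] = np.where(bulk, "yes", rng.choice(["no", "unanswered"], size=n, p=[0.7, 0.3]))

        outlier = rng.random(n) < params.outlier_fraction
        lo_m, hi_m = params.outlier_multiplier_range
        mult = rng.uniform(lo_m, hi_m, size=n)
        overpriced = rng.random(n) < 0.5
        factor = np.where(outlier, np.where(overpriced, mult, 1.0 / mult), 1.0)
        observed_per_mg = per_mg * factor

        rating = rng.choice([2, 3, 4], size=n).astype(float)
        rating[rng.random(n) < params.rating_missing_fraction] = np.nan
        rating[outlier & overpriced] = 5
        rating[outlier & ~overpriced] = 1
        rows["rating"] = rating

        rows["attribution"] = rng.choice(["personal", "swim", "internet"], size=n, p=[0.6, 0.3, 0.1])
        rows["ip_token"] = [f"ip{rng.integers(0, 2**48):012x}" for _ in range(n)]
        ts = _window_timestamps(rng, n, STUDY_WINDOWS[source])
        rows["submitted_at"] = ts
        rows["transaction_date"] = (ts - pd.to_timedelta(rng.integers(0, 10, n), unit="D")).normalize()
        rows["region"] = rng.choice(_REGIONS, size=n)
        foreign = rng.random(n) < params.foreign_fraction
        rows.loc[foreign, "country"] = rng.choice(["CA", "GB"], size=int(foreign.sum()))

        # per-mg derived from the rounded total so the ingestion invariant
        # price_per_mg = total/(qty*strength) holds exactly after round trips
        total = np.round(observed_per_mg * strengths * qty, 4)
        missing = rng.random(n) < params.missing_strength_fraction
        rows.loc[missing, "strength_mg"] = np.nan
        rows["total_price_usd"] = total
        rows["price_per_mg"] = np.where(missing, np.nan, _per_mg(total, strengths * qty))

        if params.duplicate_fraction > 0:
            dup = rows[rng.random(n) < params.duplicate_fraction].copy()
            if len(dup):
                dup["report_id"] = dup["report_id"] + "-dup"
                dup["submitted_at"] = pd.to_datetime(dup["submitted_at"]) + pd.Timedelta(
                    seconds=params.duplicate_gap_seconds
                )
                rows = pd.concat([rows, dup], ignore_index=True)

    elif source == "law_enforcement":
        strength = COMMON_STRENGTH_MG[drug]
        rows["strength_mg"] = strength
        total = np.round(per_mg * strength, 4)
        rows["total_price_usd"] = total
        rows["price_per_mg"] = _per_mg(total, np.full(n, strength))
        quarter_mid = {1: dt.date(2012, 2, 14), 2: dt.date(2012, 5, 16)}
        quarters = rng.integers(1, 3, size=n)
        rows["transaction_date"] = [pd.Timestamp(quarter_mid[int(q)]) for q in quarters]

    else:  # marketplace
        rows["strength_mg"] = strengths
        qty = rng.choice([1, 2, 5, 10, 20, 30], size=n, p=[0.35, 0.2, 0.2, 0.15, 0.07, 0.03])
        rows["quantity_units"] = qty
        total = np.round(per_mg * strengths * qty, 4)
        rows["total_price_usd"] = total
        rows["price_per_mg"] = _per_mg(total, strengths * qty)
        ts = _window_timestamps(rng, n, STUDY_WINDOWS[source])
        rows["transaction_date"] = ts.normalize()
        foreign = rng.random(n) < params.foreign_fraction
        rows["ship_origin"] = np.where(foreign, "NL", "US")
        rows["country"] = rows["ship_origin"]

    # drop all-empty optional columns; coerce_frame restores them with the
    # right dtype and avoids all-NA concat dtype ambiguity
    return rows.dropna(axis=1, how="all")


def default_filter_configs(
    exclude_ratings: frozenset[int] = frozenset({1, 5}),
) -> dict[str, FilterConfig]:
    """Per-source filter settings matching the study windows."""
    return {
        source: FilterConfig(
            window_start=STUDY_WINDOWS[source][0],
            window_end=STUDY_WINDOWS[source][1],
            exclude_ratings=exclude_ratings,
        )
        for source in SOURCES
    }


def make_exchange_rates(seed: int, window: tuple[dt.date, dt.date] | None = None) -> ExchangeRateTable:
    """Daily USD-per-BTC rates near the ≈$11/BTC level of October 2012."""
    window = window or STUDY_WINDOWS["marketplace"]
    days = pd.date_range(window[0], window[1], freq="D")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB7C,)))
    rates = np.round(11.0 * np.exp(rng.normal(0, 0.02, len(days))), 4)
    return ExchangeRateTable(pd.Series(rates, index=days))


def emit_csv_bundle(params: GeneratorParams, outdir) -> dict[str, str]:
    """Write the three dialect CSVs plus the exchange-rate table.

    Returns a mapping of dialect/rates -> file path. The marketplace file
    is priced in BTC using the emitted rate table, so a full ingestion
    round trip (including currency conversion) is exercised.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = generate_reports(params)
    rates = make_exchange_rates(params.seed)
    paths = {}

    crowd = frame[frame["source"] == "crowdsourced"]
    crowd_csv = pd.DataFrame(
        {
            "report_id": crowd["report_id"],
            "drug": crowd["drug"],
            "formulation": crowd["formulation"],
            "strength_mg": crowd["strength_mg"],
            "quantity": crowd["quantity_units"],
            "price_usd": crowd["total_price_usd"],
            "rating": crowd["rating"],
            "attribution": crowd["attribution"],
            "ip_hash": crowd["ip_token"],
            "submitted_at": pd.to_datetime(crowd["submitted_at"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "transaction_date": pd.to_datetime(crowd["transaction_date"]).dt.strftime("%Y-%m-%d"),
            "country": crowd["country"],
            "region": crowd["region"],
            "bulk": crowd["bulk_flag"],
        }
    )
    paths["crowdsourced"] = str(outdir / "crowdsourced.csv")
    crowd_csv.to_csv(paths["crowdsourced"], index=False)

    law = frame[frame["source"] == "law_enforcement"]
    law_csv = pd.DataFrame(
        {
            "report_id": law["report_id"],
            "drug": law["drug"],
            "strength_mg": law["strength_mg"],
            "price_usd": law["total_price_usd"],
            "quarter": pd.to_datetime(law["transaction_date"]).dt.to_period("Q").astype(str),
            "country": law["country"],
        }
    )
    paths["law_enforcement"] = str(outdir / "law_enforcement.csv")
    law_csv.to_csv(paths["law_enforcement"], index=False)

    market = frame[frame["source"] == "marketplace"]
    posted = pd.to_datetime(market["transaction_date"])
    btc = [
        round(float(total) / rates.usd_per_btc(date), 8)
        for total, date in zip(market["total_price_usd"], posted)
    ]
    market_csv = pd.DataFrame(
        {
            "listing_id": market["report_id"],
            "drug": market["drug"],
            "strength_mg": market["strength_mg"],
            "quantity": market["quantity_units"],
            "price_btc": btc,
            "posted_date": posted.dt.strftime("%Y-%m-%d"),
            "ship_origin": market["ship_origin"],
        }
    )
    paths["marketplace"] = str(outdir / "marketplace.csv")
    market_csv.to_csv(paths["marketplace"], index=False)

    paths["rates"] = str(outdir / "btc_rates.csv")
    rates.to_csv(paths["rates"])
    return paths


def recovery_study(
    params: GeneratorParams,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Parameter-recovery simulation: generate → filter → summarize.

    For each replicate a fresh stream is generated, the study filters are
    applied, and per-cell geometric means with CIs are estimated. Returns
    per-cell relative bias of the mean recovered geometric mean and the
    empirical CI coverage of the true value (coverage reported only when
    n_replicates is large enough to mean anything, i.e. > 1).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    configs = default_filter_configs()
    acc: dict[tuple[str, str], dict] = {
        key: {"gms": [], "cover": 0, "ci_count": 0} for key in params.cells
    }
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence(entropy=(seed, r)).generate_state(1)[0] % 2**31)
        frame = generate_reports(params.with_seed(rep_seed))
        kept = []
        for source, config in configs.items():
            kept.append(apply_filters(frame[frame["source"] == source], config).kept)
        table = summarize(pd.concat(kept, ignore_index=True), alpha=alpha)
        for row in table.to_dict(orient="records"):
            key = (row["drug"], row["source"])
            if key not in acc:
                continue
            acc[key]["gms"].append(row["gm_price_per_mg"])
            if row["ci_defined"]:
                acc[key]["ci_count"] += 1
                if row["ci_low"] <= params.cells[key].true_gm <= row["ci_high"]:
                    acc[key]["cover"] += 1
    rows = []
    for (drug, source), cell in sorted(params.cells.items()):
        a = acc[(drug, source)]
        mean_gm = float(np.mean(a["gms"])) if a["gms"] else float("nan")
        rows.append(
            {
                "drug": drug,
                "source": source,
                "true_gm": cell.true_gm,
                "n_nominal": cell.n,
                "mean_recovered_gm": mean_gm,
                "rel_bias": mean_gm / cell.true_gm - 1.0 if a["gms"] else float("nan"),
                "coverage": a["cover"] / a["ci_count"] if n_replicates > 1 and a["ci_count"] else float("nan"),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
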