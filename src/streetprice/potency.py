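"""Morphine-equivalent pricing and predicted relative potency.

Clinically, opioid doses are interconverted with equianalgesic factors:
1 mg of hydromorphone ≈ 4 mg of morphine, and so on. If the black market
prices drugs by their pharmacologic effect, the ratio of a drug's mean
street price per mg to morphine's — its *predicted relative potency* —
should track the clinical factor. This module converts per-mg prices to
morphine-milligram-equivalent terms, forms the predicted-potency ratios
with bootstrap CIs, and labels each drug as priced consistently with,
above, or below its clinical potency.

The default conversion table is the US VA/DoD 2012 chronic-pain guideline
(shipped as an editable CSV; other published tables can be swapped in).
Outputs ignore route of administration and time-release mechanisms and
must not be used for clinical dose conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, UnknownDrugError

REFERENCE_DRUG = "morphine"

#: Caveat carried in output metadata.
CLINICAL_CAVEAT = "should not be used for clinical conversion"


class EquianalgesicTable:
    """Map drug -> mg of morphine equianalgesic to 1 mg of the drug."""

    def __init__(self, factors: dict[str, float]):
        if REFERENCE_DRUG not in factors or factors[REFERENCE_DRUG] != 1:
            raise DomainError("table must contain morphine with factor exactly 1")
        if any(f <= 0 for f in factors.values()):
            raise DomainError("all potency factors must be positive")
        self._factors = dict(factors)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EquianalgesicTable":
        frame = pd.read_csv(path)
        return cls(dict(zip(frame["drug"], frame["potency_factor"].astype(float))))

    @classmethod
    def default(cls) -> "EquianalgesicTable":
        """The VA/DoD 2012 oral-equianalgesic conversion factors."""
        with resources.as_file(
            resources.files("streetprice.data") / "equianalgesic_va_dod_2012.csv"
        ) as path:
            return cls.from_csv(path)

    def factor(self, drug: str) -> float:
        try:
            return self._factors[drug]
        except KeyError:
            raise UnknownDrugError(f"no equianalgesic factor for {drug!r}") from None

    def __contains__(self, drug: str) -> bool:
        return drug in self._factors

    def drugs(self) -> tuple[str, ...]:
        return tuple(self._factors)


@dataclass(frozen=True)
class PotencyEstimate:
    drug: str
    predicted_potency: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    clinical_factor: Optional[float]
    comparison: Optional[str]
    n: int


def morphine_equivalent_price(price_per_mg: float, drug: str, table: EquianalgesicTable) -> float:
    """US$ per morphine-milligram-equivalent: price_per_mg / potency factor."""
    return price_per_mg / table.factor(drug)


def compare_potency_to_clinical(
    ci_low: Optional[float], ci_high: Optional[float], clinical_factor: float
) -> str:
    """Label a potency ratio CI against the clinical conversion factor."""
    if ci_low is None or ci_high is None or math.isnan(ci_low) or math.isnan(ci_high):
        raise DomainError("comparison requires a confidence interval")
    if ci_low > clinical_factor:
        return "valued_higher"
    if ci_high < clinical_factor:
        return "valued_lower"
    return "indistinguishable"


def predicted_relative_potency(
    summaries: pd.DataFrame,
    table: Optional[EquianalgesicTable] = None,
    reference: str = REFERENCE_DRUG,
    raw_reports: Optional[pd.DataFrame] = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PotencyEstimate]:
    """Predicted relative potency of each drug versus the reference drug.

    ``summaries`` must be restricted to a single source. The point
    estimate for each drug is gm(drug)/gm(reference). When ``raw_reports``
    (the corresponding filtered report stream) is supplied, a CI is formed
    by a nonparametric bootstrap of the log price-ratio (independent
    resampling of the two report groups, percentile interval, fixed seed);
    otherwise the CI is absent and no comparison label is produced. Drugs
    without a clinical factor (e.g. buprenorphine under the default table)
    get a point estimate but no comparison.
    """
    table = table or EquianalgesicTable.default()
    if summaries["source"].nunique() > 1:
        raise DomainError("summaries must be restricted to a single source")
    by_drug = summaries.set_index("drug")
    if reference not in by_drug.index:
        raise DomainError(f"reference drug {reference!r} absent from summaries")
    gm_ref = float(by_drug.loc[reference, "gm_price_per_mg"])

    boot_samples: dict[str, np.ndarray] = {}
    if raw_reports is not None:
        rng = np.random.default_rng(seed)
        groups = {
            drug: np.log(g.loc[g["price_per_mg"] > 0, "price_per_mg"].to_numpy())
            for drug, g in raw_reports.groupby("drug")
        }
        ref_logs = groups.get(reference)
        if ref_logs is None or ref_logs.size == 0:
            raise DomainError(f"reference drug {reference!r} absent from raw reports")
        for drug in by_drug.index:
            logs = groups.get(drug)
            if logs is None or logs.size == 0:
                continue
            drug_means = logs[rng.integers(0, logs.size, (n_boot, logs.size))].mean(axis=1)
            ref_means = ref_logs[rng.integers(0, ref_logs.size, (n_boot, ref_logs.size))].mean(axis=1)
            boot_samples[drug] = np.exp(drug_means - ref_means)

    estimates = []
    for drug, row in by_drug.iterrows():
        point = float(row["gm_price_per_mg"]) / gm_ref
        if drug == reference:
            point = 1.0  # exact self-ratio by construction
        ci_low = ci_high = None
        if drug in boot_samples:
            ci_low, ci_high = (
                float(q) for q in np.quantile(boot_samples[drug], [alpha / 2, 1 - alpha / 2])
            )
        clinical = table.factor(drug) if drug in table else None
        comparison = None
        if clinical is not None and ci_low is not None and drug != reference:
            comparison = compare_potency_to_clinical(ci_low, ci_high, clinical)
        estimates.append(
            PotencyEstimate(
                drug=drug,
                predicted_potency=point,
                ci_low=ci_low,
                ci_high=ci_high,
                clinical_factor=clinical,
                comparison=comparison,
                n=int(row["n"]),
            )
        )
    return estimates


def format_ratio(value: float, is_ci_bound: bool = False) -> str:
    """Display rounding for potency ratios.

    Point estimates print at 1 decimal; CI bounds below 0.5 keep 2
    decimals so small ratios (e.g. tramadol) stay informative.
    """
    if is_ci_bound and abs(value) < 0.5:
        return f"{_round_half_even(value, 2):.2f}"
    return f"{_round_half_even(value, 1):.1f}"


def _round_half_even(value: float, places: int) -> float:
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))
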