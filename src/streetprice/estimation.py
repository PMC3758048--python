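"""Geometric-mean price estimation with confidence intervals.

Street prices per milligram are strongly right-skewed, so each (drug,
source) cell is summarized by the geometric mean with a 95% CI formed on
the log scale with the Student-t quantile:

    gm = exp(mean(log x)),   CI = exp(mean(log x) ± t_{1-α/2, n-1}·s/√n)

where s is the sample SD of the logs. For log-normal prices this interval
is exact for the distribution median (= geometric mean). A nonparametric
bootstrap percentile CI is available as an alternative. Cells with a
single report carry a point estimate and an undefined CI. Zero-price
reports (free sharing) are excluded with an audit count, since only prices
actually paid are analyzed and log(0) is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

SUMMARY_COLUMNS = ("drug", "source", "n", "gm_price_per_mg", "ci_low", "ci_high", "ci_defined")


@dataclass(frozen=True)
class GeometricMeanCI:
    gm: float
    ci_low: float
    ci_high: float
    n: int
    ci_defined: bool


def geometric_mean_ci(
    values: Iterable[float],
    alpha: float = 0.05,
    method: str = "tdist",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> GeometricMeanCI:
    """Geometric mean of positive values with a (1−alpha) CI.

    method="tdist" uses the log-scale Student-t interval; "bootstrap" a
    percentile bootstrap of the geometric mean. n = 1 yields a point
    estimate with ci_defined=False.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise DomainError("geometric mean of an empty sequence is undefined")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise DomainError("all values must be finite and positive")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    logs = np.log(x)
    if x.size == 1:
        return GeometricMeanCI(float(x[0]), float("nan"), float("nan"), 1, False)
    gm = float(np.exp(logs.mean()))
    if method == "tdist":
        s = logs.std(ddof=1)
        half = stats.t.ppf(1 - alpha / 2, x.size - 1) * s / np.sqrt(x.size)
        lo, hi = float(np.exp(logs.mean() - half)), float(np.exp(logs.mean() + half))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        boots = np.exp(logs[idx].mean(axis=1))
        lo, hi = (float(q) for q in np.quantile(boots, [alpha / 2, 1 - alpha / 2]))
    else:
        raise DomainError(f"unknown CI method {method!r}")
    return GeometricMeanCI(gm, lo, hi, int(x.size), True)


def summarize(
    reports: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "tdist",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-(drug, source) geometric-mean price summaries.

    Expects a normalized report frame with ``price_per_mg`` populated.
    Returns one row per (drug, source) pair present, ordered by source and
    descending geometric mean; the count of zero-price reports excluded
    from each cell is recorded in ``frame.attrs["n_zero_excluded"]``.
    """
    usable = reports[reports["price_per_mg"].notna()]
    zeros = int((usable["price_per_mg"] <= 0).sum())
    usable = usable[usable["price_per_mg"] > 0]
    rows = []
    for (drug, source), group in usable.groupby(["drug", "source"], sort=False):
        res = geometric_mean_ci(group["price_per_mg"].to_numpy(), alpha=alpha, method=method, seed=seed)
        rows.append(
            {
                "drug": drug,
                "source": source,
                "n": res.n,
                "gm_price_per_mg": res.gm,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_defined": res.ci_defined,
            }
        )
    table = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    if not table.empty:
        table = table.sort_values(
            ["source", "gm_price_per_mg"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
    table.attrs["n_zero_excluded"] = zeros
    return table
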