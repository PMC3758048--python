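"""Cross-source agreement: Spearman rank correlation and per-drug tests.

The study design is triangulation: with no gold standard for black-market
prices, three independently collected streams are compared. Agreement on
the *ordering* of per-drug mean prices is measured by Spearman's rho on
the vectors of per-drug geometric means shared by each source pair.

Because only eight drugs enter each comparison, the two-sided p-value is
computed by exact permutation — enumerating all n! rank arrangements —
rather than trusting the large-sample t approximation at n = 8; the
t approximation is used above ``exact_max_n``.

Per-drug price differences across sources (e.g. whether morphine costs
more in the officer survey than on the marketplace) are tested with a
heteroscedastic one-way (Welch) ANOVA on log prices, robust to the very
unequal group sizes and variances of the three streams.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .estimation import geometric_mean_ci


@dataclass(frozen=True)
class CorrelationResult:
    source_pair: tuple[str, str]
    n_drugs: int
    rho: float
    p_value: float
    method: str
    drugs: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupDifferenceResult:
    drug: str
    statistic: float
    p_value: float
    df_between: float
    df_within: float
    summaries: pd.DataFrame


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Reduces to 1 − 6·Σd²/(n(n²−1)) when no ranks are tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise DomainError("need at least 3 pairs")
    rx, ry = _ranks(x), _ranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DomainError("rho undefined for a constant-rank vector")
    return float(np.corrcoef(rx, ry)[0, 1])


def _perm_rho_distribution(rx: np.ndarray, ry: np.ndarray, chunk: int = 200_000):
    """Yield arrays of rho over all permutations of ry against fixed rx."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    buf = []
    for perm in itertools.permutations(range(n)):
        buf.append(perm)
        if len(buf) == chunk:
            yield (ry_c[np.array(buf)] @ rx_c) / denom
            buf = []
    if buf:
        yield (ry_c[np.array(buf)] @ rx_c) / denom


def spearman_pvalue(x, y, two_tailed: bool = True, exact_max_n: int = 10) -> tuple[float, str]:
    """p-value for Spearman's rho under the independence null.

    For n <= exact_max_n, the exact permutation distribution over all n!
    rank arrangements is enumerated and p is the proportion of
    arrangements at least as extreme as the observed rho (the identity
    arrangement guarantees p > 0). Larger n uses the Student-t
    approximation t = rho·sqrt((n−2)/(1−rho²)).
    """
    rho_obs = spearman_rho(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= exact_max_n:
        rx, ry = _ranks(x), _ranks(y)
        tol = 1e-12
        count = total = 0
        for rhos in _perm_rho_distribution(rx, ry):
            total += rhos.size
            if two_tailed:
                count += int((np.abs(rhos) >= abs(rho_obs) - tol).sum())
            else:
                count += int((rhos >= rho_obs - tol).sum())
        assert total == math.factorial(n)
        return count / total, "exact_permutation"
    if abs(rho_obs) >= 1.0:
        return 0.0, "t_approximation"
    t = rho_obs * np.sqrt((n - 2) / (1 - rho_obs**2))
    p = stats.t.sf(abs(t), n - 2)
    return float(2 * p if two_tailed else (p if rho_obs > 0 else 1 - p)), "t_approximation"


def cross_source_matrix(
    summaries: pd.DataFrame,
    min_shared_drugs: int = 3,
    exact_max_n: int = 10,
) -> list[CorrelationResult]:
    """Pairwise Spearman agreement between sources on shared-drug mean prices.

    ``summaries`` is the table produced by :func:`streetprice.estimation.summarize`.
    Each unordered source pair is compared on the intersection of its drugs;
    pairs sharing fewer than ``min_shared_drugs`` drugs are skipped with a
    warning.
    """
    wide = summaries.pivot(index="drug", columns="source", values="gm_price_per_mg")
    results = []
    for a, b in itertools.combinations(sorted(wide.columns), 2):
        both = wide[[a, b]].dropna()
        if len(both) < min_shared_drugs:
            warnings.warn(
                f"sources {a!r} and {b!r} share only {len(both)} drugs; skipping", stacklevel=2
            )
            continue
        rho = spearman_rho(both[a].to_numpy(), both[b].to_numpy())
        p, method = spearman_pvalue(both[a].to_numpy(), both[b].to_numpy(), exact_max_n=exact_max_n)
        results.append(
            CorrelationResult(
                source_pair=(a, b),
                n_drugs=len(both),
                rho=rho,
                p_value=p,
                method=method,
                drugs=tuple(both.index),
            )
        )
    return results


def compare_drug_across_sources(reports: pd.DataFrame, drug: str) -> GroupDifferenceResult:
    """Welch one-way ANOVA on log prices of one drug across sources.

    Requires >= 2 sources each contributing >= 2 positive-price reports
    with nonzero within-group log variance. With exactly 2 sources the F
    statistic equals the squared heteroscedastic (Welch) t statistic.
    """
    sub = reports[(reports["drug"] == drug) & (reports["price_per_mg"] > 0)]
    counts = sub.groupby("source").size()
    small = counts[counts < 2]
    if len(counts) < 2 or not small.empty:
        offenders = ", ".join(small.index) if not small.empty else "fewer than 2 sources"
        raise DomainError(f"insufficient data for {drug}: {offenders}")
    logs = pd.DataFrame(
        {"log_price": np.log(sub["price_per_mg"].to_numpy()), "source": sub["source"].to_numpy()}
    )
    if (logs.groupby("source")["log_price"].std(ddof=1) == 0).any():
        raise DomainError(f"degenerate (zero-variance) price group for {drug}")
    import pingouin as pg  # heavy import deferred

    aov = pg.welch_anova(data=logs, dv="log_price", between="source")
    per_source = []
    for source, group in sub.groupby("source"):
        res = geometric_mean_ci(group["price_per_mg"].to_numpy())
        per_source.append(
            {"source": source, "n": res.n, "gm_price_per_mg": res.gm,
             "ci_low": res.ci_low, "ci_high": res.ci_high}
        )
    return GroupDifferenceResult(
        drug=drug,
        statistic=float(aov["F"].iloc[0]),
        p_value=float(aov["p_unc"].iloc[0] if "p_unc" in aov else aov["p-unc"].iloc[0]),
        df_between=float(aov["ddof1"].iloc[0]),
        df_within=float(aov["ddof2"].iloc[0]),
        summaries=pd.DataFrame(per_source),
    )
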