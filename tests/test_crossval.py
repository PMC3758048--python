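import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from streetprice.crossval import (
    compare_drug_across_sources,
    cross_source_matrix,
    spearman_pvalue,
    spearman_rho,
)
from streetprice.errors import DomainError

from conftest import frame_of, make_report


class TestSpearmanRho:
    def test_published_mean_vectors(self, table1_wide):
        sr = table1_wide["crowdsourced"].to_numpy()
        dd = table1_wide["law_enforcement"].to_numpy()
        silk = table1_wide["marketplace"].to_numpy()
        assert spearman_rho(sr, dd) == pytest.approx(1 - 36 / 504)
        assert spearman_rho(sr, silk) == pytest.approx(1 - 12 / 504)
        assert spearman_rho(dd, silk) == pytest.approx(1 - 48 / 504)

    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    @given(
        x=st.lists(st.integers(-100, 100), min_size=4, max_size=12, unique=True),
    )
    def test_monotone_transform_invariance(self, x):
        x = [float(v) for v in x]
        rng = np.random.default_rng(0)
        y = list(rng.permutation(x))
        rho = spearman_rho(x, y)
        assert spearman_rho([math.exp(v / 50) for v in x], y) == pytest.approx(rho)
        assert spearman_rho(x, [3 * v + 1 for v in y]) == pytest.approx(rho)

    def test_agrees_with_scipy(self, table1_wide):
        for a, b in itertools.combinations(table1_wide.columns, 2):
            ours = spearman_rho(table1_wide[a], table1_wide[b])
            ref = stats.spearmanr(table1_wide[a], table1_wide[b]).statistic
            assert ours == pytest.approx(ref)

    def test_errors(self):
        with pytest.raises(DomainError):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(DomainError):
            spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])


def _naive_exact_p(x, y, two_tailed=True):
    """Independent enumerator: untied closed form 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(x)
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]

    def rho_of(perm):
        d2 = sum((a - b) ** 2 for a, b in zip(rx, perm))
        return 1 - 6 * d2 / (n * (n**2 - 1))

    obs = rho_of(ry)
    count = 0
    for perm in itertools.permutations(ry):
        r = rho_of(perm)
        hit = abs(r) >= abs(obs) - 1e-12 if two_tailed else r >= obs - 1e-12
        count += hit
    return count / math.factorial(n)


class TestSpearmanPValue:
    def test_concordant_n4_exact(self):
        p, method = spearman_pvalue([1, 2, 3, 4], [10, 20, 30, 40])
        assert method == "exact_permutation"
        assert p == pytest.approx(2 / 24)

    @given(st.integers(0, 2**31 - 1))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.permutation(n * 10)[:n].astype(float)
        y = rng.permutation(n * 10)[:n].astype(float)
        p, method = spearman_pvalue(x, y)
        assert method == "exact_permutation"
        assert p == pytest.approx(_naive_exact_p(list(x), list(y)))

    def test_published_crowd_vs_law_pvalues(self, table1_wide):
        """n=8 published means: exact two-tailed p is 90/40320; the
        large-sample t approximation reproduces the reported p < .001."""
        sr = table1_wide["crowdsourced"].to_numpy()
        dd = table1_wide["law_enforcement"].to_numpy()
        p_exact, method = spearman_pvalue(sr, dd)
        assert method == "exact_permutation"
        assert p_exact == pytest.approx(90 / 40320)
        p_t, method_t = spearman_pvalue(sr, dd, exact_max_n=5)
        assert method_t == "t_approximation"
        assert p_t < 0.001

    def test_degenerate_input_rejected(self):
        with pytest.raises(DomainError):
            spearman_pvalue([2, 2, 2, 2], [1, 2, 3, 4])


class TestCrossSourceMatrix:
    def test_published_table_reproduces_reported_rhos(self, table1_summaries):
        results = {r.source_pair: r for r in cross_source_matrix(table1_summaries)}
        rhos = {pair: round(r.rho, 2) for pair, r in results.items()}
        assert rhos == {
            ("crowdsourced", "law_enforcement"): 0.93,
            ("crowdsourced", "marketplace"): 0.98,
            ("law_enforcement", "marketplace"): 0.90,
        }
        assert all(r.n_drugs == 8 for r in results.values())
        assert all(r.p_value < 0.05 for r in results.values())

    def test_identical_columns_give_rho_one(self, table1_summaries):
        dup = table1_summaries[table1_summaries["source"] == "crowdsourced"].copy()
        dup["source"] = "mirror"
        both = pd.concat(
            [table1_summaries[table1_summaries["source"] == "crowdsourced"], dup],
            ignore_index=True,
        )
        (res,) = cross_source_matrix(both)
        assert res.rho == pytest.approx(1.0)

    def test_disjoint_drugs_skipped_with_warning(self, table1_summaries):
        a = table1_summaries[table1_summaries["source"] == "crowdsourced"].iloc[:4]
        b = table1_summaries[table1_summaries["source"] == "marketplace"].iloc[4:]
        with pytest.warns(UserWarning, match="share only"):
            results = cross_source_matrix(pd.concat([a, b], ignore_index=True))
        assert results == []


def _price_reports(drug, source, prices):
    rows = []
    for i, p in enumerate(prices):
        rows.append(
            make_report(
                report_id=f"{source}{i}", source=source, drug=drug, strength_mg=1.0,
                total_price_usd=float(p),
                ip_token=None if source != "crowdsourced" else f"ip{i}",
                submitted_at=None if source != "crowdsourced" else make_report().submitted_at,
                formulation=None if source != "crowdsourced" else "tablet",
            )
        )
    return rows


class TestCompareDrugAcrossSources:
    def test_reduces_to_welch_t_squared_for_two_groups(self):
        rng = np.random.default_rng(7)
        a = np.exp(rng.normal(0.0, 0.5, 40))
        b = np.exp(rng.normal(0.3, 0.8, 25))
        frame = frame_of(
            _price_reports("morphine", "crowdsourced", a)
            + _price_reports("morphine", "marketplace", b)
        )
        res = compare_drug_across_sources(frame, "morphine")
        # oracle computed on the stored (4-dp) per-mg prices
        stored = frame.groupby("source")["price_per_mg"]
        la = np.log(stored.get_group("crowdsourced").to_numpy(dtype=float))
        lb = np.log(stored.get_group("marketplace").to_numpy(dtype=float))
        t = stats.ttest_ind(la, lb, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(11)
        cheap = np.exp(rng.normal(0, 0.5, 50))
        dear = 10 * np.exp(rng.normal(0, 0.5, 50))
        frame = frame_of(
            _price_reports("morphine", "crowdsourced", cheap)
            + _price_reports("morphine", "law_enforcement", dear)
        )
        assert compare_drug_across_sources(frame, "morphine").p_value < 1e-3

    def test_type_i_error_calibrated(self):
        """Under one common log-normal law, rejections at alpha=.05 stay near 5%."""
        rng = np.random.default_rng(2012)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [np.log(np.exp(rng.normal(0, 0.6, n))) for n in (25, 15, 10)]
            stat, p = _welch_anova_arrays(groups)
            rejections += p < 0.05
        # 99.9% binomial band around 0.05 at 400 replicates
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_rep, 0.05) / n_rep
        assert lo <= rejections / n_rep <= hi

    def test_degenerate_and_insufficient_inputs(self):
        const = frame_of(
            _price_reports("morphine", "crowdsourced", [2, 2, 2])
            + _price_reports("morphine", "marketplace", [3, 3, 3])
        )
        with pytest.raises(DomainError, match="degenerate"):
            compare_drug_across_sources(const, "morphine")
        single = frame_of(_price_reports("morphine", "crowdsourced", [2, 3]))
        with pytest.raises(DomainError, match="insufficient"):
            compare_drug_across_sources(single, "morphine")


def _welch_anova_arrays(groups):
    """Route the type-I study through the package on minimal frames."""
    rows = []
    for src, g in zip(("crowdsourced", "law_enforcement", "marketplace"), groups):
        rows += _price_reports("morphine", src, np.exp(g))
    res = compare_drug_across_sources(frame_of(rows), "morphine")
    return res.statistic, res.p_value
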