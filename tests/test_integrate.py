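"""Fisher exact (r x c) vs enumeration, logistic expression-status
calibration, summary t-tests, the integration tiers, and the cohort table."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from areqtl import (ExpressionStatus, build_integration_report, cohort_table,
                    fisher_exact, genotype_status_fisher, summary_ttest,
                    welch_t)
from areqtl.integrate import direction_consistent
from conftest import toy_expression


def fisher_oracle(table):
    """Independent full enumeration over fixed margins with Fractions."""
    t = np.asarray(table, dtype=int)
    rs, cs = t.sum(axis=1), t.sum(axis=0)

    def weight(cells):
        w = Fraction(math.factorial(int(t.sum())))
        for v in cells:
            w /= math.factorial(int(v))
        return w

    tables = []
    ranges = [range(min(rs[0], c) + 1) for c in cs]
    if t.shape[0] == 2:
        for first in itertools.product(*ranges):
            if sum(first) != rs[0]:
                continue
            second = cs - np.array(first)
            if (second >= 0).all():
                tables.append(list(first) + list(second))
    else:
        raise NotImplementedError
    w_obs = weight(t.ravel())
    num = sum(w for cells in tables if (w := weight(cells)) <= w_obs)
    den = sum(weight(cells) for cells in tables)
    return num / den


class TestFisherExact:
    def test_cohort_sex_table(self):
        # 2 vs 22 female:male in SNC against 4 vs 16 in SC
        assert fisher_exact([[2, 22], [4, 16]]) == pytest.approx(0.387, abs=5e-4)

    def test_agrees_with_scipy_on_2x2(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9)

    def test_identical_row_proportions_p1(self):
        assert fisher_exact([[3, 6, 9], [1, 2, 3]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_2x3(self, rng):
        for _ in range(40):
            t = rng.integers(0, 6, size=(2, 3))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(
                float(fisher_oracle(t)), abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(0, 8), min_size=6, max_size=6))
    def test_row_and_column_permutation_invariance(self, cells):
        t = np.array(cells).reshape(2, 3)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        p = fisher_exact(t)
        assert fisher_exact(t[::-1]) == pytest.approx(p, abs=1e-12)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact(t[:, perm]) == pytest.approx(p, abs=1e-12)

    def test_genotype_table_collapses(self, rng):
        g = rng.binomial(2, 0.4, 40).astype(float)
        status = pd.Series(np.where(rng.random(40) < 0.5, "SC", "SNC"))
        tab, p = genotype_status_fisher(g, status)
        assert tab.shape == (2, 3) and 0 <= p <= 1
        tab_d, _ = genotype_status_fisher(g, status, collapse="dominant")
        assert tab_d.shape == (2, 2)
        assert tab_d.to_numpy().sum() == tab.to_numpy().sum()


class TestSummaryTtest:
    def test_cohort_packyears_and_age(self):
        # smoking history 52+/-53 (n=24) vs 58+/-28 (n=20): no difference
        _, _, p_pack = summary_ttest(52, 53, 24, 58, 28, 20)
        assert round(p_pack, 2) == 0.63
        # age 53+/-18 vs 68+/-15: clearly different
        _, _, p_age = summary_ttest(53, 18, 24, 68, 15, 20)
        assert p_age < 0.05

    def test_equal_means_t0_p1(self):
        t, _, p = summary_ttest(5, 1, 10, 5, 2, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_consistent_with_raw_welch(self, rng):
        a = rng.normal(50, 10, 24)
        b = rng.normal(55, 12, 20)
        t_raw, df_raw, p_raw = welch_t(a, b)
        t_sum, df_sum, p_sum = summary_ttest(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        assert (t_sum, df_sum, p_sum) == pytest.approx((t_raw, df_raw, p_raw))


class TestLogisticExpressionStatus:
    def test_null_p_uniform(self, rng):
        n = 200
        y = np.array(["SC"] * 100 + ["SNC"] * 100)
        x = toy_expression(rng.normal(size=(2000, n)),
                           samples=[f"s{j}" for j in range(n)])
        from areqtl.integrate import _logistic_p_matrix

        p, _, _ = _logistic_p_matrix((y == "SC").astype(float),
                                     x.values.to_numpy())
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_separation_flagged(self, rng):
        n = 12
        status = ["SC"] * 6 + ["SNC"] * 6
        vals = np.vstack([
            np.r_[np.ones(6), np.zeros(6)],       # perfectly separating
            rng.normal(size=n),
        ])
        x = toy_expression(vals, samples=[f"s{j}" for j in range(n)])
        res = ExpressionStatus(x, status).fit(nperm=100, seed=2)
        assert bool(res.table.loc["p0", "separation"])
        assert not bool(res.table.loc["p1", "separation"])
        assert res.table["p"].between(0, 1).all()

    def test_deterministic_and_corrected_at_least_nominal(self, rng):
        n = 30
        status = ["SC"] * 15 + ["SNC"] * 15
        x = toy_expression(rng.normal(size=(6, n)),
                           samples=[f"s{j}" for j in range(n)])
        a = ExpressionStatus(x, status).fit(nperm=300, seed=8)
        b = ExpressionStatus(x, status).fit(nperm=300, seed=8)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert (a.table["p_corrected"] >= a.table["p"] - 0.05).all()

    def test_matches_statsmodels_on_clean_fit(self, rng):
        import statsmodels.api as sm

        n = 60
        xv = rng.normal(size=n)
        y01 = (rng.random(n) < 1 / (1 + np.exp(-xv))).astype(float)
        if y01.sum() < 3 or y01.sum() > n - 3:
            y01[:3], y01[-3:] = 1, 0
        from areqtl.integrate import _logistic_p_matrix

        p, beta, sep = _logistic_p_matrix(y01, xv[None, :])
        fit = sm.Logit(y01, sm.add_constant(xv)).fit(disp=0)
        llr_p = fit.llr_pvalue
        assert not sep[0]
        assert beta[0] == pytest.approx(fit.params[1], rel=1e-4)
        assert p[0] == pytest.approx(llr_p, rel=1e-4)


class TestIntegrationReport:
    def _frames(self):
        eqtl = pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3", "rs4"],
            "probe": ["g1", "g2", "g3", "g4"],
            "beta": [0.8, -0.5, 0.6, 0.7],
            "p_corrected": [0.01, 0.02, 0.04, 0.5],
        })
        pheno = pd.DataFrame({
            "probe": ["g1", "g2", "g3", "g4"],
            "beta": [-1.2, 0.9, -1.0, -1.0],
            "p_corrected": [0.01, 0.3, 0.2, 0.01],
        })
        geno = pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3", "rs4"],
            "p": [0.02, 0.04, 0.3, 0.01],
            "maf_case": [0.1, 0.4, 0.2, 0.2],
            "maf_control": [0.3, 0.2, 0.2, 0.2],
        })
        return eqtl, pheno, geno

    def test_tiers_partition_and_sorted(self):
        rep = build_integration_report(*self._frames())
        tiers = dict(zip(rep["snp"], rep["tier"]))
        # rs1: all three significant, minor allele raises expression,
        # higher expression protective, allele rarer in cases -> tier 1
        assert tiers["rs1"] == 1
        # rs2: eqtl + geno-status significant (pheno not) -> tier 2
        assert tiers["rs2"] == 2
        # rs3: eqtl only -> tier 3
        assert tiers["rs3"] == 3
        # rs4: eqtl fails alpha -> unranked
        assert np.isnan(tiers["rs4"])
        ranked = rep.dropna(subset=["tier"])
        assert list(ranked["tier"]) == sorted(ranked["tier"])
        assert len(rep) == 4  # every joined record appears exactly once

    def test_empty_inputs_give_empty_report(self):
        empty = pd.DataFrame(columns=["snp", "probe", "beta", "p_corrected"])
        rep = build_integration_report(
            empty, pd.DataFrame(columns=["probe", "beta", "p_corrected"]),
            pd.DataFrame(columns=["snp", "p", "maf_case", "maf_control"]))
        assert len(rep) == 0

    def test_direction_truth_table(self):
        # expression-raising allele & protective expression -> rarer in cases
        assert direction_consistent(+1, -1, -0.1)
        assert direction_consistent(-1, -1, +0.1)
        assert not direction_consistent(+1, -1, +0.1)
        assert not direction_consistent(+1, +1, 0.0)


class TestCohortTable:
    def test_structure_and_comparisons(self, cohort):
        tab = cohort_table(cohort)
        assert set(tab.columns) == {"NS", "SNC", "SC", "SC_vs_SNC"}
        assert tab.loc["n", "NS"] == 8
        assert "±" in tab.loc["age", "SC"]
        assert tab.loc["age", "SC_vs_SNC"].startswith("p=")

    def test_single_group_no_comparisons(self, cohort):
        sub = cohort[cohort["group"] == "NS"]
        tab = cohort_table(sub)
        assert tab["SC_vs_SNC"].isna().all()

    def test_sex_comparison_routes_through_fisher(self):
        rows = []
        for grp, n, nf in (("SNC", 24, 2), ("SC", 20, 4)):
            for i in range(n):
                rows.append((f"{grp}{i}", grp, "F" if i < nf else "M"))
        s = pd.DataFrame(rows, columns=["sample", "group", "sex"]).set_index("sample")
        tab = cohort_table(s)
        p = float(tab.loc["sex_F:M", "SC_vs_SNC"].split("=")[1].split()[0])
        assert p == pytest.approx(fisher_exact([[2, 22], [4, 16]]), abs=5e-3)
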