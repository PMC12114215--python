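"""CCA against independent references, envfit, and correlation screens."""

import numpy as np
import pandas as pd
import pytest

from bentho import CommunityTable, EnvTable, cca, correlation_screen, envfit, top_taxa
from bentho.envdrivers import total_inertia


def _random_case(seed, n=8, p=12, q=3):
    rng = np.random.default_rng(seed)
    y = rng.integers(1, 50, size=(n, p)).astype(float)
    x = rng.normal(size=(n, q))
    ids = [f"S{i}" for i in range(n)]
    table = CommunityTable(
        counts=pd.DataFrame(y, index=ids, columns=[f"T{j}" for j in range(p)])
    )
    env = EnvTable(values=pd.DataFrame(x, index=ids, columns=[f"V{k}" for k in range(q)]))
    return table, env


class TestCCA:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_reference_implementation(self, seed):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import cca as sk_cca

        table, env = _random_case(seed)
        mine = cca(table, env)
        ref = sk_cca(table.counts, env.values)
        k = len(mine.eigenvalues)
        assert np.allclose(mine.eigenvalues, ref.eigvals.values[:k], atol=1e-6)
        assert np.allclose(
            mine.proportion_total, ref.proportion_explained.values[:k], atol=1e-6
        )

    def test_total_inertia_equals_chi_square(self):
        # direct chi-square summation oracle on random 5x8 tables
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(1, 30, size=(5, 8)).astype(float)
            table = CommunityTable(
                counts=pd.DataFrame(
                    y, index=[f"S{i}" for i in range(5)], columns=[f"T{j}" for j in range(8)]
                )
            )
            total = y.sum()
            exp = np.outer(y.sum(1), y.sum(0)) / total
            chi2 = ((y - exp) ** 2 / exp).sum()
            assert total_inertia(table) == pytest.approx(chi2 / total, rel=1e-10)

    def test_two_block_split_on_axis1(self):
        # binary env splitting two taxon blocks -> axis 1 carries >99%
        n = 10
        y = np.zeros((n, 8))
        y[:5, :4] = 20
        y[5:, 4:] = 20
        y += 0.1  # avoid zero-sum columns
        ids = [f"S{i}" for i in range(n)]
        table = CommunityTable(
            counts=pd.DataFrame(y, index=ids, columns=[f"T{j}" for j in range(8)])
        )
        rng = np.random.default_rng(1)
        env = EnvTable(
            values=pd.DataFrame(
                {"split": [0.0] * 5 + [1.0] * 5, "noise": rng.normal(size=n)}, index=ids
            )
        )
        res = cca(table, env)
        assert res.proportion_constrained[0] > 0.99

    def test_sample_duplication_invariance(self):
        table, env = _random_case(5)
        res1 = cca(table, env)
        dup = CommunityTable(
            counts=pd.DataFrame(
                np.vstack([table.matrix()] * 2),
                index=[f"S{i}" for i in range(16)],
                columns=table.taxon_ids,
            )
        )
        env2 = EnvTable(
            values=pd.DataFrame(
                np.vstack([env.values.to_numpy()] * 2),
                index=dup.sample_ids,
                columns=env.variables,
            )
        )
        res2 = cca(dup, env2)
        assert np.allclose(res1.proportion_total, res2.proportion_total, atol=1e-8)

    def test_collinear_env_errors(self):
        table, env = _random_case(6)
        vals = env.values.copy()
        vals["V3"] = 2 * vals["V0"] + 1
        with pytest.raises(ValueError, match="collinear"):
            cca(table, EnvTable(values=vals))

    def test_eigenvalues_sorted_and_proportions_bounded(self):
        table, env = _random_case(7)
        res = cca(table, env)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)
        assert res.proportion_total.sum() <= 1 + 1e-9


class TestEnvfit:
    def test_axis_variable_r2_one(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(12, 2)), index=[f"S{i}" for i in range(12)], columns=["A1", "A2"]
        )
        env = EnvTable(values=pd.DataFrame({"v": scores["A1"]}, index=scores.index))
        fit = envfit(scores, env, n_perm=199, seed=1)
        assert fit.loc[0, "R2"] == pytest.approx(1.0)
        assert fit.loc[0, "p"] == pytest.approx(1 / 200)

    def test_closed_form_r2(self):
        # toy 6-sample case: R2 equals the multiple-correlation formula
        rng = np.random.default_rng(4)
        s = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        ids = [f"S{i}" for i in range(6)]
        scores = pd.DataFrame(s, index=ids, columns=["A1", "A2"])
        env = EnvTable(values=pd.DataFrame({"y": y}, index=ids))
        fit = envfit(scores, env, n_perm=9, seed=0)
        x = np.column_stack([np.ones(6), s])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        r2_ref = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.loc[0, "R2"] == pytest.approx(r2_ref, rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(
            rng.normal(size=(10, 2)), index=[f"S{i}" for i in range(10)], columns=["A1", "A2"]
        )
        y = rng.normal(size=10)
        e1 = EnvTable(values=pd.DataFrame({"y": y}, index=scores.index))
        e2 = EnvTable(values=pd.DataFrame({"y": 3.5 * y - 7}, index=scores.index))
        f1 = envfit(scores, e1, n_perm=49, seed=2)
        f2 = envfit(scores, e2, n_perm=49, seed=2)
        assert f1.loc[0, "R2"] == pytest.approx(f2.loc[0, "R2"], rel=1e-12)

    def test_constant_variable_flagged(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(
            rng.normal(size=(8, 2)), index=[f"S{i}" for i in range(8)], columns=["A1", "A2"]
        )
        env = EnvTable(values=pd.DataFrame({"const": np.ones(8)}, index=scores.index))
        with pytest.warns(UserWarning, match="constant"):
            fit = envfit(scores, env, n_perm=9, seed=0)
        assert fit.loc[0, "R2"] == 0.0 and fit.loc[0, "p"] == 1.0


class TestCorrelationScreen:
    def test_perfect_linear_relation(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]}, index=[f"S{i}" for i in range(5)])
        env = EnvTable(values=pd.DataFrame({"v": 2 * x["a"] + 1}, index=x.index))
        out = correlation_screen(x, env)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-6

    def test_hand_computed_r(self):
        x = pd.DataFrame({"a": [1.0, 2, 3]}, index=["S0", "S1", "S2"])
        env = EnvTable(values=pd.DataFrame({"v": [1.0, 3, 2]}, index=x.index))
        out = correlation_screen(x, env)
        assert out.loc[0, "r"] == pytest.approx(0.5)

    def test_zero_variance_flagged_missing(self):
        x = pd.DataFrame({"a": [1.0, 1, 1, 1]}, index=[f"S{i}" for i in range(4)])
        env = EnvTable(
            values=pd.DataFrame({"v": [1.0, 2, 3, 4]}, index=x.index)
        )
        out = correlation_screen(x, env)
        assert out.loc[0, "undefined"]
        assert np.isnan(out.loc[0, "r"])

    def test_bh_adjustment_column(self, seasonal_table, random_env):
        block = top_taxa(seasonal_table, 5)
        out = correlation_screen(block, random_env, adjust=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"].dropna() >= out["p"].dropna() - 1e-12).all()


def test_top_taxa_ordering(seasonal_table):
    block = top_taxa(seasonal_table, 5)
    means = block.mean(axis=0)
    assert list(means.sort_values(ascending=False).index) == list(block.columns)
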