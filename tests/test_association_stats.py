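"""BH adjustment, rank tests, fold changes, mixed models and the network."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airway_resistome.association_stats import (
    bh_adjust,
    fit_exposure_trend,
    fit_group_model,
    fold_change,
    natural_cubic_basis,
    pairwise_rank_test,
    spearman_network,
    top_features,
)


def bh_oracle(p):
    """Textbook step-up definition: q_(i) = min_{k >= i} p_(k) * m / k."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[k - 1]] * m / k for k in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.037])[0] == 0.037

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, size=25)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, size=15)
        perm = rng.permutation(15)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def rank_sum_enumeration_oracle(x, y):
    """Exact two-sided p by explicit enumeration, coded independently."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    le = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    ge = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    return min(1.0, 2 * min(le, ge))


class TestRankTest:
    def test_identical_singletons(self):
        assert pairwise_rank_test([3.0], [3.0]) == 1.0

    def test_fully_separated_small_groups(self):
        assert pairwise_rank_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_exact_equals_enumeration(self, rng):
        for _ in range(15):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            x = rng.choice([1.0, 2.0, 3.5, 7.0], size=n1)  # ties likely
            y = rng.choice([1.0, 2.0, 3.5, 7.0], size=n2)
            assert pairwise_rank_test(x, y) == pytest.approx(
                rank_sum_enumeration_oracle(x, y), abs=1e-12
            )

    def test_large_n_matches_scipy_normal_approx(self, rng):
        x = rng.normal(0, 1, size=30)
        y = rng.normal(0.7, 1, size=25)
        ours = pairwise_rank_test(x, y)
        theirs = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_rank_test([], [1.0])


class TestFoldChange:
    def test_equal_means(self):
        assert fold_change([1, 3], [2, 2]) == 1.0

    def test_forced_arithmetic(self):
        assert fold_change([2, 2], [1, 1]) == 2.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_change([1.0], [0.0])

    def test_random_groups(self, rng):
        a, b = rng.uniform(1, 5, 9), rng.uniform(1, 5, 7)
        assert fold_change(a, b) == pytest.approx(a.mean() / b.mean())


class TestGroupModel:
    def test_ols_reduction_equals_mean_difference(self, rng):
        df = pd.DataFrame(
            {
                "metric": rng.normal(0, 1, 40),
                "group": ["No-Abx"] * 20 + ["Azithro"] * 20,
            }
        )
        res = fit_group_model(df, "metric", random_effect=None)
        est = res.table.set_index("term").loc["group[Azithro]", "estimate"]
        expected = df.metric[20:].mean() - df.metric[:20].mean()
        assert est == pytest.approx(expected, abs=1e-10)

    def test_mixed_reduces_to_ols_with_tiny_site_variance(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "metric": rng.normal(0, 1, n),
                "group": np.where(rng.random(n) < 0.5, "Azithro", "No-Abx"),
                "site_id": "only_one_site",
            }
        )
        if df["group"].nunique() < 2:
            df.loc[0, "group"] = "Azithro"
        ols = fit_group_model(df, "metric", random_effect=None)
        mixed = fit_group_model(df, "metric", random_effect="site_id")
        a = ols.table.set_index("term").loc["group[Azithro]", "estimate"]
        b = mixed.table.set_index("term").loc["group[Azithro]", "estimate"]
        assert a == pytest.approx(b, abs=1e-6)

    def test_collinear_design_named(self, rng):
        df = pd.DataFrame(
            {
                "metric": rng.normal(0, 1, 20),
                "group": ["Azithro", "No-Abx"] * 10,
                "dup": ["Azithro", "No-Abx"] * 10,
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_group_model(df, "metric", covariates=["dup"], random_effect=None)

    def test_recovers_known_effect(self, rng):
        ests = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 200
            site = r.integers(0, 10, n)
            group = np.where(r.random(n) < 0.5, "Azithro", "No-Abx")
            site_eff = r.normal(0, 0.5, 10)
            y = (group == "Azithro") * 1.0 + site_eff[site] + r.normal(0, 1, n)
            df = pd.DataFrame({"metric": y, "group": group, "site_id": site.astype(str)})
            res = fit_group_model(df, "metric")
            ests.append(res.table.set_index("term").loc["group[Azithro]", "estimate"])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.15)


class TestSplineBasis:
    def test_linear_function_recovered_exactly(self, rng):
        x = rng.uniform(0, 5, 80)
        basis = natural_cubic_basis(x, k=4)
        design = np.column_stack([np.ones_like(x), basis])
        y = 2.0 + 3.0 * x
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(design @ beta, y, atol=1e-8)

    def test_degenerate_inputs(self):
        with pytest.warns(UserWarning, match="shrunk"):
            b = natural_cubic_basis(np.array([0.0, 1.0, 2.0, 0.0, 1.0]), k=4)
        assert b.shape[1] == 1
        with pytest.warns(UserWarning, match="constant"):
            b = natural_cubic_basis(np.zeros(5), k=4)
        assert b.shape[1] == 0


def _trend_frame(rng, n_patients=60, slope=0.0, noise=1.0):
    rows = []
    for i in range(n_patients):
        pid = f"p{i}"
        intercept = rng.normal(0, 0.5)
        for day in (0, 2, 4, 7):
            expo = min(max(day - 1, 0), 5) if i % 2 == 0 else 0
            rows.append(
                {
                    "patient_id": pid,
                    "day_from_admission": day,
                    "azithro_days": expo,
                    "metric": intercept + slope * expo + rng.normal(0, noise),
                    "trajectory_group": int(rng.integers(1, 6)),
                    "sex": ("F", "M")[int(rng.integers(2))],
                    "age_quintile": int(rng.integers(1, 6)),
                    "steroids_ever": bool(rng.integers(2)),
                }
            )
    return pd.DataFrame(rows)


class TestExposureTrend:
    def test_constant_metric_is_flat_and_nonsignificant(self, rng):
        df = _trend_frame(rng, slope=0.0, noise=0.0)
        df["metric"] = 5.0
        res = fit_exposure_trend(df, "metric", co_abx_cols=())
        assert res.lrt["p"] > 0.5
        assert np.allclose(res.curve["fit"], 5.0, atol=1e-6)

    def test_linear_slope_recovered(self):
        rises = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            df = _trend_frame(r, n_patients=75, slope=0.5, noise=1.0)
            res = fit_exposure_trend(df, "metric", co_abx_cols=())
            curve = res.curve
            rise = curve["fit"].iloc[-1] - curve["fit"].iloc[0]
            rises.append(rise)
        assert np.mean(rises) == pytest.approx(2.5, rel=0.3)

    def test_restriction_precondition(self, rng):
        df = _trend_frame(rng)
        df["day_from_admission"] = 50
        with pytest.raises(ValueError, match="restriction"):
            fit_exposure_trend(df, "metric", co_abx_cols=())


class TestSpearmanNetwork:
    def test_monotone_pairs(self):
        x = np.arange(10, dtype=float)
        taxa = pd.DataFrame({"up": x, "down": -x}, index=[f"s{i}" for i in range(10)])
        args = pd.DataFrame({"gene": x**3}, index=taxa.index)
        out = spearman_network(taxa, args, top_n=None).set_index(["taxon", "gene"])
        assert out.loc[("up", "gene"), "rho"] == pytest.approx(1.0)
        assert out.loc[("down", "gene"), "rho"] == pytest.approx(-1.0)
        # the edge rule is one-sided positive: a perfect negative is never an edge
        assert not out.loc[("down", "gene"), "edge"]

    def test_matches_rank_then_pearson_oracle(self, rng):
        taxa = pd.DataFrame(
            rng.uniform(0, 5, size=(20, 6)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"t{j}" for j in range(6)],
        )
        args = pd.DataFrame(
            rng.uniform(0, 5, size=(20, 4)),
            index=taxa.index,
            columns=[f"g{j}" for j in range(4)],
        )
        out = spearman_network(taxa, args, top_n=None)
        for row in out.itertuples(index=False):
            u = stats.rankdata(taxa[row.taxon])
            v = stats.rankdata(args[row.gene])
            oracle = np.corrcoef(u, v)[0, 1]
            assert row.rho == pytest.approx(oracle, abs=1e-10)
        # edge rule, re-applied independently
        for row in out.itertuples(index=False):
            assert row.edge == (row.rho > 0.2 and row.q < 0.05)

    def test_constant_vector_flagged_not_in_family(self, rng):
        taxa = pd.DataFrame(
            {"const": np.ones(10), "var": rng.uniform(0, 1, 10)},
            index=[f"s{i}" for i in range(10)],
        )
        args = pd.DataFrame({"gene": rng.uniform(0, 1, 10)}, index=taxa.index)
        out = spearman_network(taxa, args, top_n=None).set_index("taxon")
        assert out.loc["const", "undefined"] and np.isnan(out.loc["const", "q"])
        assert not out.loc["var", "undefined"]

    def test_monotone_transform_invariance(self, rng):
        u = rng.uniform(0, 5, 15)
        v = rng.uniform(0, 5, 15)
        idx = [f"s{i}" for i in range(15)]
        base = spearman_network(
            pd.DataFrame({"t": u}, index=idx), pd.DataFrame({"g": v}, index=idx), top_n=None
        )
        trans = spearman_network(
            pd.DataFrame({"t": np.exp(u)}, index=idx),
            pd.DataFrame({"g": v**3 + 1}, index=idx),
            top_n=None,
        )
        assert base["rho"][0] == pytest.approx(trans["rho"][0], abs=1e-12)

    def test_top_features_selection(self, rng):
        table = pd.DataFrame(
            {"big": [10, 10], "mid": [3, 3], "small": [1, 1]}, index=["s1", "s2"]
        )
        assert top_features(table, 2) == ["big", "mid"]
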