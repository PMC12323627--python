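"""Distances, dbRDA, forward selection, ANOSIM and Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from symbionet import (
    ExpressionMatrix,
    anosim,
    bray_curtis,
    dbrda,
    forward_select,
    gower_center,
    mann_whitney_z,
    pathway_ledger,
    rclr,
    robust_aitchison,
)
from symbionet.io import DistanceMatrix


def _em(columns, compartment="SOL"):
    arr = np.asarray(columns, dtype=float).T  # rows of samples -> genes x samples
    return ExpressionMatrix(
        compartment,
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
    )


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(_em([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(_em([[1, 2, 0, 0], [0, 0, 3, 4]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_closed_form(self):
        d = bray_curtis(_em([[2, 1, 0], [1, 1, 2]]))
        assert d.values[0, 1] == pytest.approx(3 / 7)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(_em([[1, 2], [0, 0]]))

    def test_range_zero_one(self):
        rng = np.random.default_rng(0)
        d = bray_curtis(_em(rng.random((6, 9)) * 100))
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()


class TestRobustAitchison:
    def test_constant_sample_all_zero(self):
        t = rclr(_em([[1, 1, 1, 1]]))
        np.testing.assert_allclose(t.to_numpy(), 0.0, atol=1e-12)

    def test_geometric_mean_centering(self):
        t = rclr(_em([[1, 10, 100]]))
        np.testing.assert_allclose(
            t.to_numpy()[0], [-math.log(10), 0.0, math.log(10)], atol=1e-12
        )

    def test_zero_handling_convention(self):
        # zeros excluded from the geometric mean and left at 0 after centering
        t = rclr(_em([[0, 10, 1000]]))
        np.testing.assert_allclose(
            t.to_numpy()[0], [0.0, math.log(0.1), math.log(10)], atol=1e-12
        )

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        d = robust_aitchison(_em(rng.integers(0, 50, (5, 12)))).values
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestGowerCenter:
    def test_two_point_eigenvalue(self):
        delta = 3.7
        d = DistanceMatrix(["a", "b"], np.array([[0.0, delta], [delta, 0.0]]))
        evals = np.linalg.eigvalsh(gower_center(d))
        assert max(evals) == pytest.approx(delta**2 / 2)

    def test_row_sums_zero(self):
        rng = np.random.default_rng(2)
        G = gower_center(_dm(rng.random((7, 3))))
        np.testing.assert_allclose(G.sum(axis=1), 0.0, atol=1e-10)

    def test_pcoa_matches_pca_on_euclidean_input(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 4))
        G = gower_center(_dm(X))
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = evals > 1e-10
        Y = evecs[:, pos] * np.sqrt(evals[pos])
        # PCoA eigenvalues equal squared singular values of the centered data
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        np.testing.assert_allclose(np.sort(evals[pos])[::-1], np.sort(s**2)[::-1],
                                   atol=1e-10)
        # and the coordinates reproduce the pairwise distances
        np.testing.assert_allclose(squareform(pdist(Y)), squareform(pdist(Xc)),
                                   atol=1e-10)


class TestDbrda:
    def test_saturated_dummies_full_variance(self):
        rng = np.random.default_rng(4)
        d = _dm(rng.random((6, 3)))
        dummies = pd.DataFrame(np.eye(6)[:, :5], index=d.sample_ids)
        res = dbrda(d, dummies, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.df_model + res.df_residual == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_limit_equals_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((8, 3))
        X = rng.standard_normal((8, 2))
        res = dbrda(_dm(Y), pd.DataFrame(X, index=[f"s{i}" for i in range(8)]),
                    n_perm=99, seed=0)
        Yc, Xc = Y - Y.mean(0), X - X.mean(0)
        B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        r2 = np.sum((Xc @ B) ** 2) / np.sum(Yc**2)
        assert res.R == pytest.approx(r2, abs=1e-8)

    def test_pseudo_f_equals_direct_permanova(self):
        # one binary factor, Bray-Curtis, 6 samples: within/between SS formula
        rng = np.random.default_rng(5)
        m = _em(rng.random((6, 5)) * 10)
        dm = bray_curtis(m)
        groups = np.array([0, 0, 0, 1, 1, 1])
        res = dbrda(dm, pd.DataFrame({"g": groups}, index=dm.sample_ids),
                    n_perm=999, seed=0)
        D2 = dm.values**2
        n = 6
        sst = D2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in (0, 1):
            idx = np.where(groups == g)[0]
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        f_direct = ((sst - ssw) / 1) / (ssw / (n - 2))
        assert res.F == pytest.approx(f_direct, abs=1e-10)

    def test_f_matches_skbio_permanova(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM, permanova

        rng = np.random.default_rng(6)
        m = _em(rng.random((8, 6)) * 10)
        dm = bray_curtis(m)
        groups = ["a"] * 4 + ["b"] * 4
        res = dbrda(dm, pd.DataFrame({"g": [0] * 4 + [1] * 4}, index=dm.sample_ids),
                    n_perm=99, seed=0)
        sk = permanova(SkDM(dm.values, dm.sample_ids), grouping=groups, permutations=99)
        assert res.F == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_r_invariant_to_rescaling_and_aliasing(self):
        rng = np.random.default_rng(7)
        d = _dm(rng.random((9, 4)))
        X = pd.DataFrame(rng.standard_normal((9, 2)), index=d.sample_ids,
                         columns=["u", "v"])
        base = dbrda(d, X, n_perm=99, seed=0)
        scaled = X * [100.0, 0.01]
        assert dbrda(d, scaled, n_perm=99, seed=0).R == pytest.approx(base.R)
        aliased = X.assign(w=X["u"] * 2)
        res = dbrda(d, aliased, n_perm=99, seed=0)
        assert res.R == pytest.approx(base.R)
        assert res.df_model == 2

    def test_permutation_p_valid_under_null(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_trials = 200
        for t in range(n_trials):
            d = _dm(rng.random((10, 3)))
            x = pd.DataFrame({"x": rng.standard_normal(10)}, index=d.sample_ids)
            res = dbrda(d, x, n_perm=99, seed=t)
            rejections += res.p_perm < 0.05
        se = math.sqrt(0.05 * 0.95 / n_trials)
        assert abs(rejections / n_trials - 0.05) < 3 * se

    def test_df_accounting(self):
        rng = np.random.default_rng(9)
        for k in (1, 2, 3):
            d = _dm(rng.random((14, 5)))
            X = pd.DataFrame(rng.standard_normal((14, k)), index=d.sample_ids)
            res = dbrda(d, X, n_perm=99, seed=0)
            assert res.df_model + res.df_residual == 13


class TestForwardSelect:
    def test_pure_noise_rarely_selects(self):
        rng = np.random.default_rng(10)
        empty = 0
        runs = 100
        for t in range(runs):
            d = _dm(rng.random((10, 3)))
            cands = pd.DataFrame(rng.standard_normal((10, 3)), index=d.sample_ids,
                                 columns=["a", "b", "c"])
            chosen, _ = forward_select(d, cands, n_perm=199, seed=t)
            empty += not chosen
        assert empty >= 80  # per-step familywise alpha ~ 1-(1-.05)^3

    def test_planted_predictor_selected_first(self):
        rng = np.random.default_rng(11)
        first = 0
        for t in range(20):
            x = rng.standard_normal(12)
            Y = np.outer(x, rng.standard_normal(4)) + 0.3 * rng.standard_normal((12, 4))
            d = _dm(Y)
            cands = pd.DataFrame(
                {"signal": x, "noise1": rng.standard_normal(12),
                 "noise2": rng.standard_normal(12)},
                index=d.sample_ids,
            )
            chosen, _ = forward_select(d, cands, n_perm=199, seed=t)
            first += bool(chosen) and chosen[0] == "signal"
        assert first >= 18

    def test_duplicate_candidate_enters_once(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(12)
        d = _dm(np.outer(x, [1, 2, 1]) + 0.1 * rng.standard_normal((12, 3)))
        cands = pd.DataFrame({"a": x, "b": x}, index=d.sample_ids)
        chosen, _ = forward_select(d, cands, n_perm=199, seed=0)
        assert len(chosen) == 1


class TestAnosim:
    def test_complete_separation(self):
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        r, _ = anosim(_dm(pts), ["a", "a", "a", "b", "b", "b"], seed=0)
        assert r == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(13)
        d = _dm(rng.random((6, 3)))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        r_obs, p = anosim(d, labels, seed=0)

        # independent brute force over the 20 distinct labelings
        condensed = squareform(d.values, checks=False)
        ranks = stats.rankdata(condensed)
        pairs = list(itertools.combinations(range(6), 2))
        M = len(pairs)

        def r_of(lab):
            within = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] == lab[j]]
            between = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] != lab[j]]
            return (np.mean(between) - np.mean(within)) / (M / 2)

        labelings = {tuple(lab) for lab in itertools.permutations(labels)}
        assert len(labelings) == 20
        r_stars = [r_of(lab) for lab in labelings]
        assert p == pytest.approx(
            sum(r >= r_obs - 1e-12 for r in r_stars) / len(r_stars)
        )

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM, anosim as sk_anosim

        rng = np.random.default_rng(14)
        d = _dm(rng.random((12, 4)))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        r, _ = anosim(d, labels, n_perm=99, seed=0)
        sk = sk_anosim(SkDM(d.values, d.sample_ids), grouping=labels, permutations=99)
        assert r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(15)
        d = _dm(rng.random((12, 3)))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        rs = []
        condensed = squareform(d.values, checks=False)
        for _ in range(2000):
            r, _ = anosim(d, labels[rng.permutation(12)], n_perm=99, seed=1)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.02

    def test_singleton_group_rejected(self):
        d = _dm(np.random.default_rng(0).random((4, 2)))
        with pytest.raises(ValueError, match="size 1"):
            anosim(d, ["a", "a", "a", "b"], seed=0)


class TestMannWhitney:
    def test_all_ties(self):
        u, z, _ = mann_whitney_z([5, 5, 5, 5], [5, 5, 5])
        assert u == pytest.approx(4 * 3 / 2)
        assert z == 0.0

    def test_complete_separation_exact(self):
        u, _, p = mann_whitney_z([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_z_matches_direct_formula(self):
        x = [12.0, 15.0, 11.0, 19.0, 14.0]
        y = [18.0, 21.0, 20.0, 13.0, 22.0]
        u, z, _ = mann_whitney_z(x, y)
        pooled = np.asarray(x + y)
        ranks = stats.rankdata(pooled)
        u1 = ranks[:5].sum() - 5 * 6 / 2
        mu = 25 / 2
        var = 5 * 5 / 12 * 11  # no ties
        z_ref = (abs(u1 - mu) - 0.5) / math.sqrt(var)
        assert z == pytest.approx(z_ref)
        assert u == pytest.approx(min(u1, 25 - u1))

    def test_u_matches_scipy(self):
        rng = np.random.default_rng(16)
        x, y = rng.random(15), rng.random(12)
        u, _, _ = mann_whitney_z(x, y)
        u_ref = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert u == pytest.approx(min(u_ref, 15 * 12 - u_ref))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1.0])


class TestPathwayLedger:
    def test_identical_subsets_give_zero_dr(self, four_culture_sheet, tiny_sim):
        matrices, _, catalog, _ = tiny_sim
        host = matrices["host"]
        sol = matrices["SOL"]
        # overwrite: make every negative sample a copy of a positive sample
        pos = four_culture_sheet.ids_by_status(True)
        neg = four_culture_sheet.ids_by_status(False)
        host_df = host.data.loc[:, pos[: len(neg)]].copy()
        host_df.columns = neg
        host2 = ExpressionMatrix("host", pd.concat([host.data[pos], host_df], axis=1))
        sol_df = sol.data.loc[:, pos[: len(neg)]].copy()
        sol_df.columns = neg
        sol2 = ExpressionMatrix("SOL", pd.concat([sol.data[pos], sol_df], axis=1))
        small_catalog = type(catalog)(
            sets={pid: catalog.members(pid) for pid in catalog.pathway_ids[:3]}
        )
        led = pathway_ledger(host2, sol2, small_catalog, four_culture_sheet,
                             n_perm=99, seed=5)
        np.testing.assert_allclose(led["dR"], 0.0, atol=1e-12)
        # dR recomputable from stored R columns
        np.testing.assert_allclose(led["dR"], led["R_with"] - led["R_without"],
                                   atol=1e-12)
        # df accounting: model + residual = n - 1
        n_pos = len(pos)
        assert (led["df_model_with"] + led["df_residual_with"] == n_pos - 1).all()
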