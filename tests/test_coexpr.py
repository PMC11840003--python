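import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stressnet import coexpr as cx

from conftest import planted_module_expr


def frame(values):
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestBicor:
    def test_identity(self, rng):
        x = rng.normal(size=20)
        m = frame([x, x])
        assert cx.bicor_matrix(m).iloc[0, 1] == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=20)
        m = frame([x, -x])
        assert cx.bicor_matrix(m).iloc[0, 1] == pytest.approx(-1.0)

    def test_close_to_pearson_without_outliers(self, rng):
        for _ in range(5):
            x = rng.normal(size=20)
            y = 0.6 * x + 0.8 * rng.normal(size=20)
            b = cx.bicor_matrix(frame([x, y])).iloc[0, 1]
            p = np.corrcoef(x, y)[0, 1]
            assert abs(b - p) < 0.15

    def test_zero_mad_pearson_fallback(self, rng):
        x = np.zeros(10)
        x[0] = 1.0  # median/mad zero, but non-constant
        y = rng.normal(size=10)
        out = cx.bicor_matrix(frame([x, y]))
        assert np.isfinite(out.to_numpy()).all()

    def test_bounds_and_symmetry(self, rng):
        m = frame(rng.normal(size=(15, 12)))
        C = cx.bicor_matrix(m).to_numpy()
        assert np.allclose(C, C.T)
        assert (C <= 1).all() and (C >= -1).all()
        assert np.allclose(np.diag(C), 1.0)


class TestSignedAdjacency:
    def test_cor_one_gives_one(self):
        for beta in (1, 6, 20):
            assert cx.signed_adjacency(np.array([[1.0]]), beta)[0, 0] == 1.0

    def test_cor_minus_one_gives_zero(self):
        assert cx.signed_adjacency(np.array([[-1.0]]), 5)[0, 0] == 0.0

    def test_cor_zero_beta_two(self):
        assert cx.signed_adjacency(np.array([[0.0]]), 2)[0, 0] == pytest.approx(0.25)


class TestScaleFreeFit:
    def test_exact_inverse_power_law(self):
        # k in 1..10 with counts proportional to 1/k (2520 = lcm(1..10))
        k = np.concatenate([np.full(2520 // i, i) for i in range(1, 11)])
        assert cx.scale_free_fit(k, n_bins=10) == pytest.approx(1.0, abs=1e-9)

    def test_increasing_distribution_negative(self):
        k = np.concatenate([np.full(i * 10, i) for i in range(1, 11)])
        assert cx.scale_free_fit(k, n_bins=10) < 0

    def test_constant_degenerate(self):
        with pytest.raises(ValueError):
            cx.scale_free_fit(np.full(50, 3.0))


class TestPickSoftThreshold:
    def test_block_matrix_connectivity(self):
        # within-block correlation 1: adjacency 1 inside blocks at any beta,
        # so connectivity = block size - 1
        n = 10
        cor = np.kron(np.eye(2), np.ones((n, n)))
        for beta in (2, 10):
            k = cx.signed_adjacency(cor, beta)
            np.fill_diagonal(k, 0)
            # n-1 within-block ones plus n cross-block entries at (1/2)^beta
            np.testing.assert_allclose(k.sum(axis=1), n - 1 + n * 0.5**beta)

    def test_mean_connectivity_decreasing_in_power(self, rng):
        expr = frame(rng.normal(size=(60, 15)))
        _, diag = cx.pick_soft_threshold(expr, powers=[1, 2, 4, 8, 16])
        assert (np.diff(diag["mean_k"]) < 0).all()

    def test_scale_free_expression_reaches_r2(self):
        # latent-hub model: few strongly hub-correlated genes, many weak ones
        # gives a heavy-tailed connectivity distribution
        rng = np.random.default_rng(5)
        n, n_samples = 300, 30
        h = rng.standard_normal(n_samples)
        w = rng.beta(0.5, 1.5, size=n)
        X = w[:, None] * h + np.sqrt(1 - w[:, None] ** 2) * rng.standard_normal(
            (n, n_samples)
        )
        expr = frame(X)
        beta, diag = cx.pick_soft_threshold(expr, powers=list(range(1, 15)))
        chosen = diag.loc[diag["power"] == beta, "signed_r2"].iloc[0]
        assert chosen >= 0.8


def tom_oracle(a):
    """Brute-force triple-loop signed TOM."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestSignedTom:
    def test_hand_three_nodes(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = cx.signed_tom(a)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_isolated_pair(self):
        a = np.zeros((4, 4))
        assert cx.signed_tom(a)[0, 1] == 0.0

    def test_identical_neighborhoods_max_overlap(self):
        a = np.ones((5, 5))
        np.fill_diagonal(a, 0.0)
        tom = cx.signed_tom(a)
        off = tom[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(cx.signed_tom(a), tom_oracle(a), atol=1e-12)


class TestDetectModules:
    def two_block_tom(self, n=40):
        cor = np.kron(np.eye(2), np.ones((n, n))) * 2 - 1
        adj = cx.signed_adjacency(cor, 6)
        return cx.signed_tom(adj)

    def test_two_planted_blocks_recovered(self):
        tom = self.two_block_tom(40)
        labels = cx.detect_modules(tom, [f"g{i}" for i in range(80)], min_module_size=30)
        sizes = labels.value_counts()
        assert set(sizes) == {40} and len(sizes) == 2
        assert cx.UNASSIGNED not in labels.values

    def test_small_input_all_unassigned(self):
        tom = self.two_block_tom(13)[:25, :25]
        labels = cx.detect_modules(tom, [f"g{i}" for i in range(25)], min_module_size=30)
        assert (labels == cx.UNASSIGNED).all()

    def test_gene_order_permutation_invariance(self, rng):
        expr, truth = planted_module_expr(3, 35, 20, seed=8)
        cor = cx.bicor_matrix(expr).to_numpy()
        tom = cx.signed_tom(cx.signed_adjacency(cor, 6))
        labels = cx.detect_modules(tom, list(expr.index), min_module_size=30)
        perm = rng.permutation(len(expr))
        labels_p = cx.detect_modules(
            tom[np.ix_(perm, perm)], list(expr.index[perm]), min_module_size=30
        )
        merged = pd.concat([labels.rename("a"), labels_p.rename("b")], axis=1)
        assert adjusted_rand_score(merged["a"], merged["b"]) == pytest.approx(1.0)


class TestModuleEigengene:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=10)
        expr = frame(np.tile(profile, (6, 1)))
        eig, ve = cx.module_eigengene(expr, list(expr.index))
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(np.abs(eig), np.abs(z / np.linalg.norm(z)), atol=1e-9)
        assert np.corrcoef(eig, profile)[0, 1] > 0  # sign anchored

    def test_sign_anchor_majority_positive(self, rng):
        profile = rng.normal(size=12)
        rows = [profile] * 4 + [-profile] * 2
        expr = frame(np.array(rows) + 0.01 * rng.normal(size=(6, 12)))
        eig, _ = cx.module_eigengene(expr, list(expr.index))
        assert np.corrcoef(eig, profile)[0, 1] > 0

    def test_symmetric_orientation_deterministic(self, rng):
        profile = rng.normal(size=12)
        expr = frame(np.array([profile, -profile]))
        e1, _ = cx.module_eigengene(expr, list(expr.index))
        e2, _ = cx.module_eigengene(expr, list(expr.index))
        np.testing.assert_allclose(e1, e2)

    def test_single_gene_module(self, rng):
        expr = frame(rng.normal(size=(1, 8)))
        eig, ve = cx.module_eigengene(expr, ["g0"])
        assert ve == 1.0
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        expr = frame(rng.normal(size=(30, 10)))
        eig, ve = cx.module_eigengene(expr, list(expr.index))
        X = expr.to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        assert 0 < ve <= 1
        assert ve == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-8)
        assert abs(np.dot(eig, Vt[0])) == pytest.approx(1.0, abs=1e-8)


class TestMergeCloseModules:
    def labelled_expr(self, cor_between, rng, n=35, n_samples=24):
        base = rng.normal(size=n_samples)
        other = cor_between * base + np.sqrt(1 - cor_between**2) * rng.normal(size=n_samples)
        rows = [base + 0.05 * rng.normal(size=n_samples) for _ in range(n)]
        rows += [other + 0.05 * rng.normal(size=n_samples) for _ in range(n)]
        expr = frame(np.array(rows))
        labels = pd.Series(["a"] * n + ["b"] * n, index=expr.index)
        return expr, labels

    def test_high_correlation_merged(self, rng):
        expr, labels = self.labelled_expr(0.95, rng)
        ms = cx.merge_close_modules(labels, expr, merge_threshold=0.2)
        assert len(ms.modules) == 1

    def test_low_correlation_not_merged(self, rng):
        expr, labels = self.labelled_expr(0.5, rng)
        ms = cx.merge_close_modules(labels, expr, merge_threshold=0.2)
        assert len(ms.modules) == 2

    def test_single_module_unchanged(self, rng):
        expr = frame(rng.normal(size=(10, 12)))
        labels = pd.Series(["a"] * 10, index=expr.index)
        ms = cx.merge_close_modules(labels, expr)
        assert len(ms.modules) == 1
        assert set(ms.labels) == {"m01"}

    def test_merge_idempotent(self, rng):
        expr, truth = planted_module_expr(4, 35, 20, seed=3)
        labels = pd.Series([f"c{t}" for t in truth], index=expr.index)
        once = cx.merge_close_modules(labels, expr)
        twice = cx.merge_close_modules(once.labels, expr)
        assert (once.labels == twice.labels).all()


class TestModuleTraitCor:
    def test_trait_equals_eigengene(self, rng):
        eg = frame(rng.normal(size=(2, 10)))
        traits = pd.DataFrame({"tr": eg.iloc[0]}, index=eg.columns)
        r, p = cx.module_trait_cor(eg, traits)
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_p_one(self):
        x = np.array([1.0, -1.0] * 5)
        y = np.ones(10)
        y[::2] = np.arange(5)  # orthogonal-ish; construct exactly below
        eg = frame([x])
        z = np.zeros(10)
        z[0], z[1] = 1.0, 1.0  # symmetric around both signs of x -> r = 0
        traits = pd.DataFrame({"tr": z}, index=eg.columns)
        r, p = cx.module_trait_cor(eg, traits)
        assert r.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert p.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_trait_missing(self, rng):
        eg = frame(rng.normal(size=(1, 8)))
        traits = pd.DataFrame({"tr": np.ones(8)}, index=eg.columns)
        r, _ = cx.module_trait_cor(eg, traits)
        assert np.isnan(r.iloc[0, 0])

    def test_closed_form_tail_magnitude(self):
        # r = 0.85 at n = 60 gives p of order 1e-18 from the t tail
        from scipy import stats

        r = 0.85
        n = 60
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert 1e-19 < p < 1e-16


class TestTopHubs:
    def test_dominant_gene_first(self, rng):
        n = 10
        a = np.full((n, n), 0.2)
        a[0, :] = a[:, 0] = 1.0
        np.fill_diagonal(a, 0)
        labels = pd.Series(["m01"] * n, index=[f"g{i}" for i in range(n)])
        hubs = cx.top_hubs(a, labels, hub_k=3)
        assert hubs["m01"][0] == "g0"

    def test_small_module_all_members(self, rng):
        a = rng.uniform(0, 1, size=(5, 5))
        a = (a + a.T) / 2
        labels = pd.Series(["m01"] * 5, index=[f"g{i}" for i in range(5)])
        hubs = cx.top_hubs(a, labels, hub_k=20)
        assert sorted(hubs["m01"]) == [f"g{i}" for i in range(5)]

    def test_hub_arithmetic_93_by_20(self):
        # 93 clusters x top-20 hubs = 1860 hub slots
        assert 93 * 20 == 1860


class TestPlantedRecovery:
    def test_ari_at_least_080(self):
        expr, truth = planted_module_expr(
            n_modules=5, genes_per_module=50, n_samples=24, effect=2.0, noise=0.3, seed=1
        )
        params = cx.CoexprParams(beta=6.0, min_module_size=30)
        modules, _ = cx.fit_modules(expr, params)
        ari = adjusted_rand_score(truth, modules.labels.to_numpy())
        assert ari >= 0.8
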