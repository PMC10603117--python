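"""Network construction: bicor against a direct formula oracle, soft
threshold selection, TOM identities, planted-partition module recovery,
eigengene and connectivity contracts."""

import numpy as np
import pandas as pd
import pytest

from stratanet.coexpression import (
    UNASSIGNED,
    adjacency_and_tom,
    bicor_matrix,
    detect_modules,
    kme_and_kim,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
)

from conftest import factor_model_expr


def bicor_scalar_oracle(x, y, c=9.0):
    """Independent scalar implementation of the published biweight
    midcorrelation formula."""

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weighted(np.asarray(x, float)), weighted(np.asarray(y, float))
    return float(a @ b / np.sqrt((a**2).sum() * (b**2).sum()))


def expr_from_rows(rows):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(rows.shape[0])],
        columns=[f"s{j}" for j in range(rows.shape[1])],
    )


class TestBicor:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        R = bicor_matrix(expr_from_rows([x, 2 * x + 3]))
        assert R.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        R = bicor_matrix(expr_from_rows([x, -x]))
        assert R.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 40))
        R = bicor_matrix(expr_from_rows(X))
        for i in range(6):
            for j in range(i + 1, 6):
                assert R.iloc[i, j] == pytest.approx(
                    bicor_scalar_oracle(X[i], X[j]), abs=1e-12
                )

    def test_outlier_robustness_beats_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        y_clean = x + 0.2 * rng.standard_normal(50)
        y = y_clean.copy()
        y[7] += 10.0  # 10-SD outlier
        r_clean = np.corrcoef(x, y_clean)[0, 1]
        r_pearson = np.corrcoef(x, y)[0, 1]
        R = bicor_matrix(expr_from_rows([x, y]))
        assert abs(R.iloc[0, 1] - r_clean) < abs(r_pearson - r_clean)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            bicor_matrix(expr_from_rows(np.ones((3, 3))))

    def test_zero_mad_gene_falls_back_to_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        y = np.zeros(20)
        y[3] = 5.0  # median 0, MAD 0, but not constant
        R = bicor_matrix(expr_from_rows([x, y]))
        expected = np.corrcoef(
            x - np.median(x), y - y.mean()
        )  # mixed row: bicor weights for x, centred y
        # at minimum the value must be finite and in [-1, 1]
        assert np.isfinite(R.iloc[0, 1])
        assert abs(R.iloc[0, 1]) <= 1


class TestSoftThreshold:
    def test_smallest_power_reaching_target_selected(self):
        rng = np.random.default_rng(5)
        expr = factor_model_expr(rng, 120, 60, loading=0.7, noise_sd=0.6)
        # add background so connectivity is heterogeneous
        noise = factor_model_expr(rng, 180, 60, loading=0.0, noise_sd=1.0,
                                  gene_prefix="n")
        cor = bicor_matrix(pd.concat([expr, noise]))
        beta, table, reached = pick_soft_threshold(cor)
        qualifying = table[table["sft_r2"] >= 0.8]["power"]
        if reached:
            assert beta == int(qualifying.iloc[0])
        else:
            assert beta == int(table.loc[table["sft_r2"].idxmax(), "power"])

    def test_fallback_to_argmax_with_warning(self):
        rng = np.random.default_rng(6)
        cor = bicor_matrix(factor_model_expr(rng, 60, 40, loading=0.3))
        with pytest.warns(UserWarning, match="argmax"):
            beta, table, reached = pick_soft_threshold(cor, target_r2=0.99999)
        assert not reached
        assert beta == int(table.loc[table["sft_r2"].idxmax(), "power"])

    def test_r2_matches_direct_regression(self):
        """Signed R^2 agrees with an independently hand-binned
        least-squares fit."""
        rng = np.random.default_rng(7)
        k = rng.pareto(2.0, 500) + 0.5
        r2, slope = scale_free_fit(k)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            chunk = k[idx == b]
            if chunk.size:
                xs.append(np.log10(chunk.mean()))
                ys.append(np.log10(chunk.size / k.size))
        coef = np.polyfit(xs, ys, 1)
        r = np.corrcoef(xs, ys)[0, 1]
        expected = -r * r if coef[0] > 0 else r * r
        assert r2 == pytest.approx(expected, rel=1e-9)
        assert slope == pytest.approx(coef[0], rel=1e-9)

    def test_degenerate_connectivity_gives_zero(self):
        assert scale_free_fit(np.full(100, 3.0)) == (0.0, 0.0)


class TestAdjacencyTom:
    def test_power_arithmetic(self):
        cor = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        A, _ = adjacency_and_tom(cor, beta=6)
        assert A.iloc[0, 1] == pytest.approx(0.5**6, rel=1e-12)
        assert A.iloc[0, 0] == 0.0

    def test_three_clique_tom_is_one(self):
        cor = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                           columns=list("abc"))
        _, tom = adjacency_and_tom(cor, beta=1)
        # (sum_u a_iu a_uj + a_ij) / (min(k) + 1 - a_ij) = (1+1)/(2+1-1)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_isolated_pair_tom_zero(self):
        cor = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        _, tom = adjacency_and_tom(cor, beta=2)
        assert tom.iloc[0, 1] == 0.0

    def test_matches_direct_formula_on_random_matrix(self):
        rng = np.random.default_rng(8)
        M = rng.uniform(-1, 1, (15, 15))
        C = (M + M.T) / 2
        np.fill_diagonal(C, 1.0)
        cor = pd.DataFrame(C, index=[f"g{i}" for i in range(15)],
                           columns=[f"g{i}" for i in range(15)])
        A, tom = adjacency_and_tom(cor, beta=3)
        a = A.to_numpy()
        k = a.sum(axis=1)
        for i in range(15):
            for j in range(15):
                if i == j:
                    assert tom.iloc[i, j] == 1.0
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(15)) + a[i, j]
                den = min(k[i], k[j]) + 1 - a[i, j]
                assert tom.iloc[i, j] == pytest.approx(num / den, rel=1e-10)
        T = tom.to_numpy()
        assert np.allclose(T, T.T)
        assert T.min() >= 0.0 and T.max() <= 1.0


def planted_blocks_tom(rng, sizes, within=0.8, n_samples=80, beta=6,
                       n_noise=0):
    blocks = []
    truth = []
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        lam = np.sqrt(within)
        noise_sd = np.sqrt(1 - within)
        X = lam * f[None, :] + noise_sd * rng.standard_normal((size, n_samples))
        blocks.append(X)
        truth.extend([f"block{b}"] * size)
    if n_noise:
        blocks.append(rng.standard_normal((n_noise, n_samples)))
        truth.extend(["noise"] * n_noise)
    X = np.vstack(blocks)
    expr = pd.DataFrame(X, index=[f"g{i:04d}" for i in range(len(X))],
                        columns=[f"s{j}" for j in range(n_samples)])
    cor = bicor_matrix(expr)
    _, tom = adjacency_and_tom(cor, beta)
    return expr, tom, np.array(truth)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        _, tom, truth = planted_blocks_tom(rng, [100, 100])
        labels, _ = detect_modules(tom, min_size=50)
        found = sorted(set(labels) - {UNASSIGNED})
        assert len(found) == 2
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_small_block_stays_unassigned(self):
        rng = np.random.default_rng(10)
        _, tom, truth = planted_blocks_tom(rng, [100, 100])
        # a 30-gene block below min_size among the two big ones
        rng2 = np.random.default_rng(11)
        _, tom_small, truth_small = planted_blocks_tom(
            rng2, [100, 30], n_noise=70
        )
        labels, _ = detect_modules(tom_small, min_size=50)
        small = labels[truth_small == "block1"]
        assert (small == UNASSIGNED).all()

    def test_noise_mostly_unassigned(self):
        """Pure-noise TOMs leave at least 80% of genes unassigned in at
        least 8 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            _, tom, _ = planted_blocks_tom(rng, [], n_noise=300, n_samples=50)
            labels, _ = detect_modules(tom, min_size=50)
            if (labels == UNASSIGNED).mean() >= 0.8:
                hits += 1
        assert hits >= 8

    def test_single_module_fallback_below_two_min_size(self):
        rng = np.random.default_rng(12)
        _, tom, _ = planted_blocks_tom(rng, [60], n_samples=40)
        with pytest.warns(UserWarning, match="fallback"):
            labels, _ = detect_modules(tom, min_size=50)
        assert labels.nunique() == 1

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        _, tom, _ = planted_blocks_tom(rng, [80, 80], n_noise=100)
        l1, _ = detect_modules(tom)
        l2, _ = detect_modules(tom)
        assert (l1 == l2).all()


class TestEigengenes:
    def _module_labels(self, genes, label="m1"):
        return pd.Series(label, index=genes, name="module")

    def test_identical_genes_give_their_profile(self):
        rng = np.random.default_rng(14)
        v = rng.standard_normal(20)
        expr = expr_from_rows([v, v, v])
        ME, varexp = module_eigengenes(expr, self._module_labels(expr.index))
        me = ME["m1"].to_numpy()
        vs = (v - v.mean()) / v.std(ddof=1)
        corr = np.corrcoef(me, vs)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert corr > 0  # sign aligned with module average
        assert varexp["m1"] == pytest.approx(1.0, abs=1e-10)

    def test_negating_members_flips_sign(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((5, 25))
        X[1:] = X[0] + 0.1 * rng.standard_normal((4, 25))
        expr = expr_from_rows(X)
        ME1, _ = module_eigengenes(expr, self._module_labels(expr.index))
        ME2, _ = module_eigengenes(-expr, self._module_labels(expr.index))
        assert np.allclose(ME1["m1"], -ME2["m1"], atol=1e-10)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(16)
        expr = factor_model_expr(rng, 60, 45, loading=0.8, noise_sd=0.6)
        f = None
        # regenerate with the factor exposed
        rng = np.random.default_rng(16)
        f = rng.standard_normal(45)
        ME, _ = module_eigengenes(expr, self._module_labels(expr.index))
        assert abs(np.corrcoef(ME["m1"], f)[0, 1]) >= 0.9


class TestKmeKim:
    def test_identical_genes_have_unit_kme(self):
        rng = np.random.default_rng(17)
        v = rng.standard_normal(30)
        expr = expr_from_rows([v, v, v, v])
        modules = pd.Series("m1", index=expr.index)
        ME, _ = module_eigengenes(expr, modules)
        cor = bicor_matrix(expr)
        A, _ = adjacency_and_tom(cor, 1)
        kME, kIM, hubs = kme_and_kim(expr, ME, A, modules)
        assert np.allclose(kME["m1"], 1.0, atol=1e-10)

    def test_clique_kim_and_lexicographic_hub(self):
        rng = np.random.default_rng(18)
        v = rng.standard_normal(30)
        expr = expr_from_rows([v, v, v])
        modules = pd.Series("m1", index=expr.index)
        ME, _ = module_eigengenes(expr, modules)
        cor = bicor_matrix(expr)
        A, _ = adjacency_and_tom(cor, 1)
        kME, kIM, hubs = kme_and_kim(expr, ME, A, modules)
        assert np.allclose(kIM, 2.0, atol=1e-10)
        assert hubs["m1"] == ["g0"]  # tie broken lexicographically

    def test_hub_count_for_module_of_ten(self):
        rng = np.random.default_rng(19)
        expr = factor_model_expr(rng, 10, 25, loading=0.9, noise_sd=0.3)
        modules = pd.Series("m1", index=expr.index)
        ME, _ = module_eigengenes(expr, modules)
        cor = bicor_matrix(expr)
        A, _ = adjacency_and_tom(cor, 2)
        _, _, hubs = kme_and_kim(expr, ME, A, modules)
        assert len(hubs["m1"]) == 1  # ceil(0.05 * 10)

    def test_unassigned_gene_kim_is_nan_but_kme_present(self):
        rng = np.random.default_rng(20)
        expr = factor_model_expr(rng, 12, 25, loading=0.9, noise_sd=0.3)
        modules = pd.Series("m1", index=expr.index)
        modules.iloc[-2:] = UNASSIGNED
        ME, _ = module_eigengenes(expr, modules)
        cor = bicor_matrix(expr)
        A, _ = adjacency_and_tom(cor, 2)
        kME, kIM, _ = kme_and_kim(expr, ME, A, modules)
        assert kIM.iloc[-1] != kIM.iloc[-1]  # NaN
        assert np.isfinite(kME.iloc[-1, 0])
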