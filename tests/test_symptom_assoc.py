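"""Symptom association: point-biserial identities and calibration,
max-T permutation behaviour, GS/kME relations, Fisher enrichment with
enumeration oracle, GMT handling."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from stratanet.symptom_assoc import (
    gene_significance,
    gmt_enrichment,
    gs_kme_correlation,
    module_enrichment_fet,
    module_symptom_association,
    point_biserial,
)


class TestPointBiserial:
    def test_equals_pearson_on_01_coding(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 0, 1  # both classes present
        x = rng.standard_normal(30)
        r, _ = point_biserial(y, x)
        assert r == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-12)

    def test_hand_formula_example(self):
        y = [0, 0, 1, 1]
        x = [-1.0, -0.5, 0.5, 1.0]
        # oracle: direct point-biserial formula
        x = np.asarray(x)
        m1, m0 = x[2:].mean(), x[:2].mean()
        s = x.std(ddof=0)
        expected = (m1 - m0) / s * np.sqrt(0.5 * 0.5)
        r, _ = point_biserial(y, list(x))
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(0.9486832980505138, abs=1e-9)

    def test_parametric_p_calibrated_under_null(self):
        rng = np.random.default_rng(1)
        n, reps = 40, 1000
        y = np.r_[np.zeros(20), np.ones(20)]
        hits = 0
        for _ in range(reps):
            _, p = point_biserial(y, rng.standard_normal(n))
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(10), np.ones(10)]
        x = rng.standard_normal(20)
        r1, _ = point_biserial(y, x)
        r2, _ = point_biserial(y, 5.0 * x - 3.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="symptom"):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="values"):
            point_biserial([0, 1, 0], [2.0, 2.0, 2.0])


def _me_table(rng, n_samples, n_modules):
    return pd.DataFrame(
        rng.standard_normal((n_samples, n_modules)),
        index=[f"s{j}" for j in range(n_samples)],
        columns=[f"mod{m}" for m in range(n_modules)],
    )


class TestModuleSymptomAssociation:
    def test_perfect_separation_reaches_extreme_rank_bound(self):
        rng = np.random.default_rng(3)
        ME = _me_table(rng, 24, 3)
        y = (ME["mod0"] > ME["mod0"].median()).astype("int64")
        symptoms = pd.DataFrame({"sym": pd.array(y, dtype="Int64")},
                                index=ME.index)
        n_perm = 500
        table, _ = module_symptom_association(
            ME, symptoms, n_perm=n_perm, seed=4
        )
        top = table.set_index("module").loc["mod0"]
        assert top["p_perm"] == pytest.approx(1 / (n_perm + 1), rel=1e-12)

    def test_small_class_skipped_with_reason(self):
        rng = np.random.default_rng(5)
        ME = _me_table(rng, 20, 2)
        y = pd.array([1] * 18 + [0] * 2, dtype="Int64")
        symptoms = pd.DataFrame({"sym": y}, index=ME.index)
        table, skipped = module_symptom_association(ME, symptoms, seed=0,
                                                    n_perm=100)
        assert len(table) == 0
        assert "sym" in skipped and "class sizes" in skipped["sym"]

    def test_p_monotone_in_observed_effect(self):
        """max-T adjusted p never increases with |r|."""
        rng = np.random.default_rng(6)
        ME = _me_table(rng, 30, 5)
        y = pd.array(rng.integers(0, 2, 30), dtype="Int64")
        y[:5], y[-5:] = 0, 1
        symptoms = pd.DataFrame({"sym": y}, index=ME.index)
        table, _ = module_symptom_association(ME, symptoms, n_perm=300, seed=7)
        t = table.sort_values("r_pb", key=lambda s: s.abs())
        assert (t["p_perm"].diff().dropna() <= 1e-12).all()

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(8)
        ME = _me_table(rng, 20, 2)
        y = pd.array([0] * 8 + [1] * 8 + [pd.NA] * 4, dtype="Int64")
        symptoms = pd.DataFrame({"sym": y}, index=ME.index)
        table, _ = module_symptom_association(ME, symptoms, n_perm=100, seed=9)
        assert (table["n_used"] == 16).all()


class TestGeneSignificance:
    def test_gene_equal_to_symptom_has_unit_gs(self):
        rng = np.random.default_rng(10)
        y = pd.Series(
            pd.array([0, 1] * 10, dtype="Int64"),
            index=[f"s{j}" for j in range(20)],
        )
        X = rng.standard_normal((5, 20))
        X[0] = y.astype(float).to_numpy()
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(5)],
                            columns=y.index)
        GS, assoc, flags = gene_significance(expr, y)
        assert GS["g0"] == pytest.approx(1.0, abs=1e-12)
        assert "g0" in assoc

    def test_antisymmetric_under_relabel(self):
        rng = np.random.default_rng(11)
        y = pd.Series(pd.array([0] * 10 + [1] * 10, dtype="Int64"),
                      index=[f"s{j}" for j in range(20)])
        expr = pd.DataFrame(rng.standard_normal((6, 20)),
                            index=[f"g{i}" for i in range(6)], columns=y.index)
        GS1, _, _ = gene_significance(expr, y)
        GS2, _, _ = gene_significance(expr, 1 - y)
        assert np.allclose(GS1, -GS2, atol=1e-12)

    def test_null_associated_fraction_near_alpha(self):
        rng = np.random.default_rng(12)
        y = pd.Series(pd.array([0] * 20 + [1] * 20, dtype="Int64"),
                      index=[f"s{j}" for j in range(40)])
        expr = pd.DataFrame(rng.standard_normal((2000, 40)),
                            index=[f"g{i}" for i in range(2000)],
                            columns=y.index)
        _, assoc, _ = gene_significance(expr, y)
        assert len(assoc) / 2000 == pytest.approx(0.05, abs=0.02)

    def test_constant_gene_flagged_zero(self):
        y = pd.Series(pd.array([0, 0, 1, 1], dtype="Int64"),
                      index=list("abcd"))
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]],
            index=["g0", "g1"], columns=y.index,
        )
        with pytest.warns(UserWarning):
            GS, assoc, flags = gene_significance(expr, y)
        assert GS["g0"] == 0.0 and bool(flags["g0"])


class TestGsKmeCorrelation:
    def test_identity_line(self):
        rng = np.random.default_rng(13)
        kme = pd.Series(rng.uniform(0.2, 0.9, 40),
                        index=[f"g{i}" for i in range(40)])
        out = gs_kme_correlation(kme.copy(), kme, list(kme.index))
        assert out["r"] == pytest.approx(1.0, abs=1e-12)
        assert out["slope"] == pytest.approx(1.0, abs=1e-10)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_negated_line(self):
        rng = np.random.default_rng(14)
        kme = pd.Series(rng.uniform(0.2, 0.9, 30),
                        index=[f"g{i}" for i in range(30)])
        out = gs_kme_correlation(-kme, kme, list(kme.index))
        assert out["r"] == pytest.approx(-1.0, abs=1e-12)

    def test_null_correlation_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            genes = [f"g{i}" for i in range(100)]
            kme = pd.Series(rng.uniform(-1, 1, 100), index=genes)
            gs = pd.Series(rng.uniform(-0.5, 0.5, 100), index=genes)
            out = gs_kme_correlation(gs, kme, genes)
            if abs(out["r"]) < 0.3:
                hits += 1
        assert hits >= 18

    def test_band_covers_fit(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(50)]
        kme = pd.Series(rng.uniform(0, 1, 50), index=genes)
        gs = pd.Series(0.5 * kme + 0.1 * rng.standard_normal(50), index=genes)
        out = gs_kme_correlation(gs, kme, genes)
        band = out["band"]
        assert (band["lo"] <= band["fit"]).all()
        assert (band["fit"] <= band["hi"]).all()

    def test_degenerate_variance_errors(self):
        genes = ["a", "b", "c"]
        kme = pd.Series([0.5, 0.5, 0.5], index=genes)
        gs = pd.Series([0.1, 0.2, 0.3], index=genes)
        with pytest.raises(ValueError):
            gs_kme_correlation(gs, kme, genes)


class TestEnrichment:
    def test_fisher_matches_enumeration(self):
        """Module 50, target 100, overlap 25, background 1000."""
        background = [f"g{i}" for i in range(1000)]
        module = background[:25] + background[100:125]  # 50 genes
        target = background[:25] + background[200:275]  # 100, overlap 25
        _, p, _ = module_enrichment_fet(module, target, background)
        p_oracle = sum(
            comb(100, x) * comb(900, 50 - x) for x in range(25, 51)
        ) / comb(1000, 50)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_zero_overlap(self):
        background = [f"g{i}" for i in range(100)]
        odds, p, _ = module_enrichment_fet(background[:10], background[50:60],
                                           background)
        assert odds == 0.0 and p == 1.0

    def test_module_equals_target_minimal_p(self):
        background = [f"g{i}" for i in range(60)]
        module = background[:12]
        _, p, _ = module_enrichment_fet(module, module, background)
        assert p == pytest.approx(1 / comb(60, 12), rel=1e-9)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            module_enrichment_fet(["a"], ["a"], [])


class TestGmt:
    def _write_gmt(self, path, lines):
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_composition_with_direct_fet(self, tmp_path):
        background = [f"g{i}" for i in range(200)]
        module = background[:30]
        term_genes = background[10:60]
        gmt = self._write_gmt(
            tmp_path / "sets.gmt",
            ["term1\tdesc\t" + "\t".join(term_genes),
             "term2\tdesc\t" + "\t".join(background[100:150])],
        )
        table = gmt_enrichment(module, gmt, background)
        _, p_direct, _ = module_enrichment_fet(module, term_genes, background)
        got = table.set_index("term").loc["term1", "p"]
        assert got == pytest.approx(p_direct, rel=1e-12)

    def test_term_equal_to_module_ranks_first(self, tmp_path):
        background = [f"g{i}" for i in range(100)]
        module = background[:20]
        gmt = self._write_gmt(
            tmp_path / "sets.gmt",
            ["exact\td\t" + "\t".join(module),
             "other\td\t" + "\t".join(background[40:80])],
        )
        table = gmt_enrichment(module, gmt, background)
        assert table.iloc[0]["term"] == "exact"

    def test_disjoint_term_skipped(self, tmp_path):
        background = [f"g{i}" for i in range(50)]
        gmt = self._write_gmt(
            tmp_path / "sets.gmt",
            ["inside\td\t" + "\t".join(background[:10]),
             "outside\td\tx1\tx2\tx3"],
        )
        table = gmt_enrichment(background[:5], gmt, background)
        assert "outside" not in set(table["term"])
        assert table.attrs["skipped_terms"] == ["outside"]

    def test_malformed_line_reports_number(self, tmp_path):
        gmt = self._write_gmt(
            tmp_path / "bad.gmt",
            ["ok\td\tg1\tg2", "broken_line_without_genes"],
        )
        with pytest.raises(ValueError, match="line 2"):
            gmt_enrichment(["g1"], gmt, ["g1", "g2"])
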