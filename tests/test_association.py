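import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import panelgwas as pg
from panelgwas.association import _DELTA_GRID
from panelgwas.errors import EstimationError, ValidationError


def make_geno(calls, chrom="2L", variant_class="SNP", alt=None):
    """Build a GenotypeMatrix directly from a calls array (rows=variants)."""
    calls = np.asarray(calls, dtype=float)
    m, n = calls.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 10 * (np.arange(m) + 1),
            "variant_id": [f"{chrom}_{10 * (i + 1)}_{variant_class}" for i in range(m)],
            "ref": "A",
            "alt": alt if alt is not None else "G",
            "variant_class": variant_class,
        }
    )
    return pg.GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(n)], variants=variants, calls=calls
    )


def dense_reml_loglik(delta, y, X, A):
    """Independent dense-matrix restricted likelihood (no eigendecomposition)."""
    n, p = X.shape
    H = A + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    XtHiX = X.T @ Hi @ X
    b = np.linalg.solve(XtHiX, X.T @ Hi @ y)
    r = y - X @ b
    sig = (r @ Hi @ r) / (n - p)
    _, ld_h = np.linalg.slogdet(H)
    _, ld_x = np.linalg.slogdet(XtHiX)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi * sig) + (n - p) + ld_h + ld_x - ld_xx)


class TestFilter:
    def test_maf_boundary_inclusive(self):
        # 20 lines: 1 alt call -> maf exactly 0.05 (kept);
        # 1000 lines: 49 alt calls -> maf 0.049 (dropped)
        row_keep = np.zeros((1, 20))
        row_keep[0, 0] = 2.0
        g = make_geno(row_keep)
        assert pg.filter_variants(g, pg.FilterSpec()).n_variants == 1
        row_drop = np.zeros((1, 1000))
        row_drop[0, :49] = 2.0
        g2 = make_geno(row_drop)
        assert g2.maf()[0] == pytest.approx(0.049)
        assert pg.filter_variants(g2, pg.FilterSpec()).n_variants == 0

    def test_missingness_boundary_strict(self):
        row = np.zeros((1, 10))
        row[0, :3] = np.nan
        row[0, 3:7] = 2.0
        g = make_geno(row)
        assert g.missingness()[0] == pytest.approx(0.30)
        assert pg.filter_variants(g, pg.FilterSpec()).n_variants == 0
        row2 = row.copy()
        row2[0, 2] = 2.0  # missingness 0.2 now
        assert pg.filter_variants(make_geno(row2), pg.FilterSpec()).n_variants == 1

    def test_non_biallelic_removed(self):
        calls = np.array([[0.0, 2.0, 0.0, 2.0]])
        g = make_geno(calls, alt="G,T")
        assert pg.filter_variants(g, pg.FilterSpec()).n_variants == 0

    def test_class_restriction(self):
        calls = np.tile([0.0, 2.0, 0.0, 2.0], (2, 1))
        g = make_geno(calls, variant_class="DEL")
        spec = pg.FilterSpec(include_classes=("SNP",))
        assert pg.filter_variants(g, spec).n_variants == 0
        spec2 = pg.FilterSpec(include_classes=("SNP", "DEL"))
        assert pg.filter_variants(g, spec2).n_variants == 2


class TestGrm:
    def test_identical_lines_maximally_related(self):
        rng = np.random.default_rng(0)
        base = rng.choice([0.0, 2.0], size=(30, 1))
        calls = np.hstack([base, base, rng.choice([0.0, 2.0], size=(30, 2))])
        a = pg.compute_grm(make_geno(calls))
        assert a.iloc[0, 1] == pytest.approx(a.iloc[0, 0])
        assert a.iloc[0, 1] == pytest.approx(a.iloc[1, 1])

    def test_matches_double_loop_on_fixture(self):
        calls = np.array(
            [
                [0, 2, 2, 0],
                [2, 2, 0, 0],
                [0, 0, 2, 2],
                [2, 0, 2, 0],
                [0, 2, 0, 0],
                [2, 2, 2, 0],
            ],
            dtype=float,
        )
        a = pg.compute_grm(make_geno(calls)).to_numpy()
        x = calls / 2
        p = x.mean(axis=1)
        expected = np.zeros((4, 4))
        m = len(p)
        for j in range(4):
            for k in range(4):
                expected[j, k] = np.mean(
                    [(x[v, j] - p[v]) * (x[v, k] - p[v]) / (p[v] * (1 - p[v]))
                     for v in range(m)]
                )
        np.testing.assert_allclose(a, expected, atol=1e-12)

    def test_diagonal_mean_near_one_and_offdiag_near_zero(self):
        cfg = pg.SimConfig(
            n_lines=40, n_variants=1000, ld_copy_prob=0.0, ld_block_len=1,
            missing_prob=0.0, maf_law=("uniform", 0.2, 0.5), seed=8,
        )
        a = pg.compute_grm(pg.simulate_genotypes(cfg)).to_numpy()
        assert abs(np.mean(np.diag(a)) - 1.0) < 0.05
        off = a[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 3.0 / np.sqrt(1000)

    def test_duplicate_variant_equals_double_weight(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0.0, 2.0], size=(12, 8))
        dup = np.vstack([calls, calls[:1]])
        a_dup = pg.compute_grm(make_geno(dup)).to_numpy()
        w = np.ones(12)
        w[0] = 2.0
        a_w = pg.compute_grm(make_geno(calls), weights=w).to_numpy()
        np.testing.assert_allclose(a_dup, a_w, atol=1e-12)

    def test_monomorphic_only_is_error(self):
        with pytest.raises(EstimationError):
            pg.compute_grm(make_geno(np.zeros((3, 5))))


def random_instance(rng, n, n_cov=0):
    z = rng.normal(size=(n, 3 * n))
    a = z @ z.T / (3 * n)
    a /= np.mean(np.diag(a))
    ids = [f"L{i}" for i in range(n)]
    adf = pd.DataFrame(a, index=ids, columns=ids)
    u = np.linalg.cholesky(a + 1e-10 * np.eye(n)) @ rng.normal(size=n)
    y = pd.Series(5 + u + rng.normal(size=n), index=ids)
    x0 = None
    if n_cov:
        x0 = pd.DataFrame(
            rng.normal(size=(n, n_cov)), index=ids,
            columns=[f"c{j}" for j in range(n_cov)],
        )
    return y, x0, adf


class TestNullModel:
    def test_reml_optimum_beats_dense_grid(self):
        rng = np.random.default_rng(5)
        y, x0, a = random_instance(rng, 12)
        fit = pg.fit_null_mixed_model(y, x0, a)
        x_mat = np.ones((12, 1))
        grid = np.logspace(-5, 5, 1000)
        best = max(
            dense_reml_loglik(d, y.to_numpy(), x_mat, a.to_numpy()) for d in grid
        )
        assert fit.loglik >= best - 1e-6

    def test_flat_profile_resolves_to_zero_genetic_variance(self, caplog):
        n = 15
        ids = [f"L{i}" for i in range(n)]
        a = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        y = pd.Series(np.random.default_rng(1).normal(size=n), index=ids)
        with caplog.at_level(logging.WARNING, logger="panelgwas"):
            fit = pg.fit_null_mixed_model(y, None, a)
        assert fit.sigma_g2 == 0.0
        assert "flat" in caplog.text

    def test_misaligned_ids_rejected(self):
        rng = np.random.default_rng(2)
        y, _, a = random_instance(rng, 8)
        y.index = [f"OTHER{i}" for i in range(8)]
        with pytest.raises(ValidationError):
            pg.fit_null_mixed_model(y, None, a)

    def test_variance_ratio_recovery(self):
        """Mean fitted sigma_g2/(sigma_g2+sigma_e2) near truth 0.5 over
        200 simulated line-mean phenotypes on 100 lines."""
        cfg = pg.SimConfig(n_lines=100, n_variants=800, missing_prob=0.0, seed=77)
        a = pg.compute_grm(pg.filter_variants(pg.simulate_genotypes(cfg)))
        av = a.to_numpy()
        chol = np.linalg.cholesky(av + 1e-9 * np.eye(100))
        rng = np.random.default_rng(202)
        ratios = []
        for _ in range(200):
            u = chol @ rng.normal(size=100)
            y = pd.Series(10 + u + rng.normal(size=100), index=a.index)
            f = pg.fit_null_mixed_model(y, None, a)
            ratios.append(f.sigma_g2 / (f.sigma_g2 + f.sigma_e2))
        assert abs(np.mean(ratios) - 0.5) < 0.05


class TestScan:
    def test_reduces_to_ols_when_no_genetic_variance(self):
        rng = np.random.default_rng(6)
        n, m = 25, 30
        calls = rng.choice([0.0, 2.0], size=(m, n), p=[0.6, 0.4])
        geno = make_geno(calls)
        ids = geno.line_ids
        a = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        y = pd.Series(rng.normal(size=n), index=ids)
        fit = pg.fit_null_mixed_model(y, None, a)
        assert fit.sigma_g2 == 0.0
        scan = pg.scan_snps(fit, geno)
        x = calls / 2
        vids = list(geno.variants["variant_id"])
        for row in scan.itertuples(index=False):
            g = x[vids.index(row.variant_id)]
            xf = np.column_stack([np.ones(n), g])
            b = np.linalg.lstsq(xf, y.to_numpy(), rcond=None)[0]
            r = y.to_numpy() - xf @ b
            s2 = (r @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(xf.T @ xf)[1, 1])
            t = b[1] / se
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert row.p_value == pytest.approx(p, abs=1e-9)
            assert row.beta == pytest.approx(b[1], abs=1e-9)

    def test_p_monotone_in_statistic(self, small_geno, small_panel):
        panel, _ = small_panel
        kept = pg.filter_variants(small_geno)
        fit = pg.fit_null_mixed_model(
            panel.line_means(), None, pg.compute_grm(kept)
        )
        scan = pg.scan_snps(fit, kept)
        full = scan[scan["n_used"] == scan["n_used"].max()]
        s = full.sort_values("p_value")
        stats_abs = s["statistic"].abs().to_numpy()
        assert (np.diff(stats_abs) <= 1e-12).all()

    def test_perfect_fit_reports_floor_not_zero(self):
        calls = np.array([[0.0, 0.0, 2.0, 2.0, 0.0, 2.0]] * 2)
        geno = make_geno(calls)
        ids = geno.line_ids
        a = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        y = pd.Series(calls[0] * 3.5 + 1, index=ids)  # exact function of SNP
        fit = pg.fit_null_mixed_model(y, None, a)
        scan = pg.scan_snps(fit, geno)
        assert (scan["p_value"] > 0).all()

    def test_monomorphic_after_missing_dropped(self, caplog):
        calls = np.array(
            [[0.0, np.nan, np.nan, 0.0, 0.0, 2.0],  # alt only on missing lines
             [0.0, 2.0, 0.0, 2.0, 0.0, 2.0]]
        )
        calls[0, 5] = np.nan  # now monomorphic among non-missing
        geno = make_geno(calls)
        ids = geno.line_ids
        a = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        y = pd.Series([1.0, 2, 3, 4, 5, 6.0], index=ids)
        fit = pg.fit_null_mixed_model(y, None, a)
        with caplog.at_level(logging.INFO, logger="panelgwas"):
            scan = pg.scan_snps(fit, geno)
        assert len(scan) == 1
        assert scan.iloc[0].n_used == 6

    def test_lrt_and_wald_agree_on_ranking(self, small_geno, small_panel):
        panel, _ = small_panel
        kept = pg.filter_variants(small_geno)
        fit = pg.fit_null_mixed_model(panel.line_means(), None, pg.compute_grm(kept))
        wald = pg.scan_snps(fit, kept).set_index("variant_id")
        lrt = pg.scan_snps(fit, kept, test="lrt").set_index("variant_id")
        top_w = wald["p_value"].nsmallest(5).index
        top_l = lrt["p_value"].nsmallest(5).index
        assert set(top_w) == set(top_l)


class TestInflation:
    def test_lambda_one_at_null_median(self):
        lam, _ = pg.genomic_inflation(np.full(500, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_qq_expected_quantiles_for_n4(self):
        _, qq = pg.genomic_inflation(np.array([0.2, 0.4, 0.6, 0.8]))
        np.testing.assert_allclose(
            qq["expected"], -np.log10([0.125, 0.375, 0.625, 0.875])
        )
        np.testing.assert_allclose(
            qq["observed"], -np.log10([0.2, 0.4, 0.6, 0.8])
        )

    def test_few_pvalues_warn_but_compute(self, caplog):
        with caplog.at_level(logging.WARNING, logger="panelgwas"):
            lam, _ = pg.genomic_inflation(np.linspace(0.01, 0.99, 50))
        assert np.isfinite(lam)
        assert "unstable" in caplog.text
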