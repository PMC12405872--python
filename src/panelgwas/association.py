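"""Linear mixed-model association scan for inbred-line panels.

The model on line means is ``y = X b + u + e`` with ``u ~ N(0, sigma_g2 A)``
and ``e ~ N(0, sigma_e2 I)``, where ``A`` is a genomic relationship matrix
computed from standardized homozygous genotypes. Variance components are
estimated once under the null by restricted maximum likelihood, profiled
over the ratio ``delta = sigma_e2 / sigma_g2`` on the eigenbasis of ``A``
(a single eigendecomposition serves every likelihood evaluation, as in the
EMMA family of solvers). Each variant is then tested as a fixed effect by a
Wald t-test with the variance-component ratio held at the null fit and the
overall scale re-estimated per variant — which reduces exactly to the
ordinary-least-squares t-test when ``sigma_g2 = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .containers import GenotypeMatrix
from .errors import EstimationError, ValidationError

logger = logging.getLogger("panelgwas")

_P_FLOOR = np.nextafter(0.0, 1.0)  # degenerate (perfect-fit) variants
_DELTA_GRID = np.logspace(-5.0, 5.0, 61)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """MAF >= maf_min (inclusive), missingness < miss_max (strict),
    biallelic only, optionally restricted to specific variant classes."""

    maf_min: float = 0.05
    miss_max: float = 0.30
    include_classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValidationError(f"maf_min={self.maf_min} outside [0, 0.5]")
        if not 0.0 < self.miss_max <= 1.0:
            raise ValidationError(f"miss_max={self.miss_max} outside (0, 1]")


def filter_variants(geno: GenotypeMatrix, spec: FilterSpec | None = None) -> GenotypeMatrix:
    """Apply the standard panel-GWAS variant filter; logs drop counts."""
    spec = spec or FilterSpec()
    maf = geno.maf()
    miss = geno.missingness()
    bial = geno.is_biallelic()
    keep = (maf >= spec.maf_min) & (miss < spec.miss_max) & bial
    if spec.include_classes is not None:
        keep &= geno.variants["variant_class"].isin(spec.include_classes).to_numpy()
    n_maf = int(((maf < spec.maf_min)).sum())
    n_miss = int((miss >= spec.miss_max).sum())
    n_bial = int((~bial).sum())
    logger.info(
        "filter: %d/%d retained (dropped: %d maf, %d missingness, %d non-biallelic)",
        int(keep.sum()), geno.n_variants, n_maf, n_miss, n_bial,
    )
    if not keep.any():
        logger.warning("variant filter removed every variant")
    return geno.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

def compute_grm(
    geno: GenotypeMatrix, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Standardized cross-product kinship over lines.

    With calls coded 0/1 (ref/alt homozygote) and per-variant alternate
    frequency p, ``A[j,k] = (1/M) sum_m (x_jm - p_m)(x_km - p_m) /
    (p_m (1 - p_m))``. Missing calls are mean-imputed (for the GRM only).
    Monomorphic variants carry no information and are excluded.
    """
    x = geno.dosage()
    p = geno.alt_freq()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if weights is None:
        weights = np.ones(geno.n_variants)
    weights = np.asarray(weights, dtype=float)
    if not poly.any():
        raise EstimationError("all variants monomorphic; GRM undefined")
    x, p, w = x[poly], p[poly], weights[poly]
    x = np.where(np.isnan(x), p[:, None], x)
    z = (x - p[:, None]) / np.sqrt(p * (1.0 - p))[:, None]
    a = (z * w[:, None]).T @ z / w.sum()
    return pd.DataFrame(a, index=geno.line_ids, columns=geno.line_ids)


# ---------------------------------------------------------------------------
# null-model REML fit
# ---------------------------------------------------------------------------

@dataclass
class NullModelFit:
    """REML variance components with the eigen-rotation state for the scan."""

    line_ids: list[str]
    y: np.ndarray
    X0: np.ndarray
    A: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float
    eigenvalues: np.ndarray
    U: np.ndarray
    loglik: float
    covariate_names: list[str] = field(default_factory=list)

    @property
    def heritability_on_means(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_loglik_rotated(
    delta: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray, logdet_xtx: float
) -> tuple[float, float]:
    """Restricted log-likelihood at ``delta`` (profiled scale), plus the
    profiled sigma_g2, using pre-rotated data."""
    n, p = Xt.shape
    w = 1.0 / (s + delta)
    xtwx = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(xtwx, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    df = n - p
    sigma = rss / df
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * sigma)
        + df
        + float(np.sum(np.log(s + delta)))
        + logdet_xtwx
        - logdet_xtx
    )
    return ll, sigma


def fit_null_mixed_model(
    y: pd.Series,
    X0: pd.DataFrame | None,
    A: pd.DataFrame,
) -> NullModelFit:
    """REML fit of the single-variance-component null model.

    ``y`` is the (corrected) line-mean phenotype indexed by line id; ``X0``
    optional covariates on the same index (an intercept is always added);
    ``A`` the relationship matrix over at least those lines. The ratio
    delta is profiled on a 61-point log grid spanning 1e-5..1e5 and refined
    by bounded scalar minimization (tolerance < 1e-8 in delta).
    """
    y = y.dropna()
    ids = list(y.index)
    if not set(ids) <= set(A.index):
        missing = sorted(set(ids) - set(A.index))
        raise ValidationError(f"lines absent from relationship matrix: {missing[:5]}")
    a = A.loc[ids, ids].to_numpy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("relationship matrix is not symmetric")
    cols = ["intercept"]
    design = [np.ones(len(ids))]
    if X0 is not None:
        if not set(ids) <= set(X0.index):
            missing = sorted(set(ids) - set(X0.index))
            raise ValidationError(f"lines absent from covariates: {missing[:5]}")
        xc = X0.loc[ids]
        for c in xc.columns:
            v = xc[c].to_numpy(dtype=float)
            if np.std(v) > 0:  # drop constant covariates
                design.append(v)
                cols.append(str(c))
    X = np.column_stack(design)
    n, p = X.shape
    if n <= p:
        raise EstimationError("more fixed effects than lines")

    s, U = linalg.eigh(a)
    if s[0] < -1e-6 * max(1.0, s[-1]):
        raise EstimationError(
            f"relationship matrix not PSD (min eigenvalue {s[0]:.3g})"
        )
    s = np.clip(s, 0.0, None)
    yv = y.to_numpy(dtype=float)
    yt, Xt = U.T @ yv, U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    grid_ll = np.array(
        [_reml_loglik_rotated(d, s, yt, Xt, logdet_xtx)[0] for d in _DELTA_GRID]
    )
    flat = grid_ll.max() - grid_ll.min() < 1e-9
    if flat or np.ptp(s) < 1e-9:
        # A indistinguishable from a multiple of I: delta unidentifiable
        logger.warning(
            "flat REML profile (relationship matrix ~ identity); "
            "resolving to sigma_g2 = 0"
        )
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        rss = float(np.sum((yv - X @ beta) ** 2))
        sigma_e2 = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma_e2) + (n - p))
        return NullModelFit(
            line_ids=ids, y=yv, X0=X, A=a, sigma_g2=0.0, sigma_e2=sigma_e2,
            delta=np.inf, eigenvalues=s, U=U, loglik=ll, covariate_names=cols,
        )

    i = int(np.argmax(grid_ll))
    lo = _DELTA_GRID[max(i - 1, 0)]
    hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik_rotated(10.0**ld, s, yt, Xt, logdet_xtx)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(10.0 ** res.x)
    ll, sigma_g2 = _reml_loglik_rotated(delta, s, yt, Xt, logdet_xtx)
    sigma_e2 = delta * sigma_g2
    if delta >= 0.99 * _DELTA_GRID[-1]:
        # optimum on the upper boundary: genetic variance indistinguishable
        # from zero at this sample size
        logger.warning("delta at grid boundary; sigma_g2 effectively 0")
    return NullModelFit(
        line_ids=ids, y=yv, X0=X, A=a, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
        delta=delta, eigenvalues=s, U=U, loglik=ll, covariate_names=cols,
    )


# ---------------------------------------------------------------------------
# per-variant scan
# ---------------------------------------------------------------------------

def _wald_from_gls(
    V: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float] | None:
    """Dense GLS Wald test of the last column of X.

    Whitens by the Cholesky factor of V and residualizes the tested column
    on the remaining (possibly rank-deficient after pairwise deletion)
    covariates via SVD least squares. Returns ``None`` when the tested
    column is collinear with the covariates or no residual df remain.
    """
    n = X.shape[0]
    L = linalg.cholesky(V, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    X0w, h = Xw[:, :-1], Xw[:, -1]
    coef_h, _, rank0, _ = linalg.lstsq(X0w, h)
    h_perp = h - X0w @ coef_h
    hh = float(h_perp @ h_perp)
    if hh <= 1e-10 * max(float(h @ h), 1e-300):
        return None
    coef_y, _, _, _ = linalg.lstsq(X0w, yw)
    z_perp = yw - X0w @ coef_y
    beta = float(h_perp @ yw) / hh
    rss = max(float(z_perp @ z_perp) - beta * beta * hh, 0.0)
    df = n - (rank0 + 1)
    if df < 1:
        return None
    scale = rss / df
    se = float(np.sqrt(scale / hh))
    if se <= 0.0 or not np.isfinite(se):
        return beta, np.finfo(float).tiny, np.inf, _P_FLOOR
    t = beta / se
    pval = max(2.0 * stats.t.sf(abs(t), df), _P_FLOOR)
    return beta, se, t, pval


def scan_snps(
    fit: NullModelFit,
    geno: GenotypeMatrix,
    test: str = "wald",
    refit: bool = False,
) -> pd.DataFrame:
    """Per-variant fixed-effect tests at the null variance components.

    Lines with a missing call are dropped pairwise per variant (variants
    with complete calls go through the fast eigen-rotation path; the result
    is identical to a dense GLS solve). Variants monomorphic among the
    retained lines are skipped with a log entry. Output is sorted by genome
    position.
    """
    if test not in ("wald", "lrt"):
        raise ValidationError(f"unknown test {test!r}")
    sub = geno.select_lines(fit.line_ids)
    x_all = sub.dosage()
    n = len(fit.line_ids)
    yv, X0 = fit.y, fit.X0
    p0 = X0.shape[1]
    V = fit.sigma_g2 * fit.A + fit.sigma_e2 * np.eye(n)

    # fast path precomputation on the rotated, whitened design
    if np.isfinite(fit.delta) and fit.sigma_g2 > 0:
        w = 1.0 / (fit.sigma_g2 * fit.eigenvalues + fit.sigma_e2)
        rot = fit.U.T
    else:
        w = np.full(n, 1.0 / fit.sigma_e2)
        rot = np.eye(n)
    sw = np.sqrt(w)
    C = sw[:, None] * (rot @ X0)
    z = sw * (rot @ yv)
    Q, _ = np.linalg.qr(C)
    z_perp = z - Q @ (Q.T @ z)
    rss0 = float(z_perp @ z_perp)

    records = []
    n_skipped = 0
    complete = ~np.isnan(x_all).any(axis=1)
    meta = sub.variants

    def emit(i, beta, se, stat, pval, used):
        v = meta.iloc[i]
        records.append(
            (v.variant_id, v.chrom, v.pos, beta, se, stat, pval, used)
        )

    # ---- complete-call variants: vectorized Frisch-Waugh on whitened data
    idx_c = np.flatnonzero(complete)
    if len(idx_c) and not refit:
        G = x_all[idx_c].T  # n x m
        H = sw[:, None] * (rot @ G)
        Hp = H - Q @ (Q.T @ H)
        hh = np.einsum("ij,ij->j", Hp, Hp)
        ok = hh > 1e-12
        bz = Hp.T @ z
        df = n - p0 - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, bz / hh, np.nan)
            rss = rss0 - np.where(ok, bz * bz / hh, 0.0)
            rss = np.maximum(rss, 0.0)
            scale = rss / df
            se = np.sqrt(scale / hh)
        for k, i in enumerate(idx_c):
            if not ok[k]:
                n_skipped += 1
                continue
            if test == "lrt":
                stat = n * np.log(rss0 / rss[k]) if rss[k] > 0 else np.inf
                pval = max(float(stats.chi2.sf(stat, 1)), _P_FLOOR)
                emit(i, float(beta[k]), float(se[k]), float(stat), pval, n)
                continue
            if se[k] <= 0 or not np.isfinite(se[k]):
                emit(i, float(beta[k]), float(np.finfo(float).tiny), np.inf,
                     _P_FLOOR, n)
                continue
            t = float(beta[k] / se[k])
            pval = max(2.0 * stats.t.sf(abs(t), df), _P_FLOOR)
            emit(i, float(beta[k]), float(se[k]), t, pval, n)

    # ---- variants with missing calls (or exact per-variant refit): dense GLS
    idx_d = np.flatnonzero(~complete) if not refit else np.arange(len(meta))
    for i in idx_d:
        x = x_all[i]
        mask = ~np.isnan(x)
        used = int(mask.sum())
        xs = x[mask]
        if used < p0 + 2 or np.ptp(xs) == 0.0:
            n_skipped += 1
            continue
        Xi = np.column_stack([X0[mask], xs])
        if refit:
            a_sub = pd.DataFrame(
                fit.A[np.ix_(mask, mask)],
                index=np.array(fit.line_ids)[mask],
                columns=np.array(fit.line_ids)[mask],
            )
            yi = pd.Series(yv[mask], index=a_sub.index)
            covs = pd.DataFrame(Xi[:, 1:], index=a_sub.index)
            f = fit_null_mixed_model(yi, covs, a_sub)
            Vi = f.sigma_g2 * a_sub.to_numpy() + f.sigma_e2 * np.eye(used)
            wald = _wald_from_gls(Vi, f.X0, f.y)
        else:
            Vi = V[np.ix_(mask, mask)]
            wald = _wald_from_gls(Vi, Xi, yv[mask])
        if wald is None:
            n_skipped += 1
            continue
        beta, se, tstat, pval = wald
        emit(i, beta, se, tstat, pval, used)

    if n_skipped:
        logger.info("scan: %d variants skipped (monomorphic after dropping "
                    "missing calls)", n_skipped)
    out = pd.DataFrame(
        records,
        columns=["variant_id", "chrom", "pos", "beta", "se", "statistic",
                 "p_value", "n_used"],
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def genomic_inflation(results: pd.DataFrame | np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and Q-Q coordinates.

    lambda_gc is the median association chi-square (1 df, from the two-sided
    p-values) over its null expectation ``qchisq(0.5, 1) = 0.4549...``.
    Q-Q points pair the rank-i expected quantile ``-log10((i - 0.5) / n)``
    with the observed p-values sorted ascending.
    """
    p = results["p_value"].to_numpy() if isinstance(results, pd.DataFrame) else np.asarray(results, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise EstimationError("no p-values")
    if p.size < 100:
        logger.warning("fewer than 100 p-values; lambda estimate is unstable")
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, 1))
    n = p.size
    obs = np.sort(p)
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed": -np.log10(obs),
        }
    )
    return lam, qq
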