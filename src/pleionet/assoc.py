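"""Genotype QC, mixed-model association and the multi-trait pleiotropy test.

The single-trait scan follows the leave-one-chromosome-out (LOCO) mixed
linear model y = a + b x + g + e, where g is a polygenic effect with
covariance proportional to a genomic relationship matrix (GRM) built from
every chromosome except the one carrying the tested marker.  Variance
components are estimated once per (trait, left-out chromosome) by REML on
the null model and then held fixed for the per-marker generalized
least-squares Wald tests (the EMMAX-style approximation).

The pleiotropy statistic combines the per-trait signed Wald t-values of a
marker: chi2_i = t_i' V^-1 t_i with V the traits x traits correlation matrix
of signed t-values over all markers, referred to a chi-square with one
degree of freedom per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    ConfigurationError,
    EmptyResultError,
    GenotypeMatrix,
    MarkerStats,
    PleioTable,
    TraitPanel,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- QC


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_retained: int


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per marker, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(G.dosages, axis=0) / 2.0


def qc_genotypes(
    G: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers with MAF < ``maf_min`` or call rate < ``call_rate_min``.

    Both boundaries are strict: a marker at exactly the threshold is kept.
    """
    if G.n_markers == 0:
        raise ConfigurationError("empty genotype matrix")
    p = allele_frequencies(G)
    maf = np.minimum(p, 1 - p)
    call_rate = 1.0 - np.isnan(G.dosages).mean(axis=0)
    fail_maf = maf < maf_min
    fail_cr = call_rate < call_rate_min
    keep = ~(fail_maf | fail_cr)
    report = QCReport(
        n_input=G.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int((fail_cr & ~fail_maf).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise EmptyResultError("QC removed every marker")
    out = GenotypeMatrix(
        dosages=G.dosages[:, keep],
        markers=G.markers.loc[keep].copy(),
        samples=list(G.samples),
    )
    return out, report


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-marker mean (post-QC convention)."""
    if not np.isnan(dosages).any():
        return dosages
    X = dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X


# ---------------------------------------------------------------- GRM


def compute_grm(
    G: GenotypeMatrix, exclude_chrom: str | None = None
) -> np.ndarray:
    """Allele-frequency-standardized genomic relationship matrix.

    A = (1/m) sum_i (x_i - 2 p_i)(x_i - 2 p_i)' / (2 p_i (1 - p_i)), summed
    over included markers; monomorphic markers are skipped with a warning.
    """
    keep = np.ones(G.n_markers, dtype=bool)
    if exclude_chrom is not None:
        keep &= (G.markers["chrom"] != exclude_chrom).to_numpy()
    X = mean_impute(G.dosages[:, keep])
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < keep.sum():
        log.warning("GRM: skipping %d monomorphic markers", int((~poly).sum()))
    X = X[:, poly]
    p = p[poly]
    m = X.shape[1]
    if m < 1 or (exclude_chrom is not None and m < 2):
        raise ConfigurationError(
            "fewer than 2 markers available for the GRM after exclusion"
        )
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (Z @ Z.T) / m


# ---------------------------------------------------------------- REML


@dataclass
class VarianceFit:
    """REML variance components of the null mixed model.

    ``h2`` is the ratio sigma_g^2 / (sigma_g^2 + sigma_e^2) on the GRM scale;
    ``sigma2`` the total variance; ``beta`` the GLS fixed-effect estimates.
    """

    h2: float
    sigma2: float
    beta: np.ndarray
    loglik: float


def _reml_eig(
    y: np.ndarray, X: np.ndarray, eigvals: np.ndarray, U: np.ndarray
) -> VarianceFit:
    """Profile REML over h2 using the eigendecomposition of the GRM."""
    n, p = X.shape
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(h2: float) -> float:
        v = h2 * eigvals + (1 - h2)
        w = 1.0 / v
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(sigma2)
            + np.sum(np.log(v))
            + logdet_xwx
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(1e-6, 1 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("REML did not converge (degenerate likelihood)")
    h2 = float(res.x)
    v = h2 * eigvals + (1 - h2)
    w = 1.0 / v
    XtWX = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sigma2 = float(r @ (w * r)) / (n - p)
    return VarianceFit(h2=h2, sigma2=sigma2, beta=beta, loglik=-float(res.fun))


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError("covariate design is rank-deficient")
    return X


def adjust_phenotype(
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    grm: np.ndarray,
) -> tuple[np.ndarray, VarianceFit]:
    """Pre-adjust a phenotype with the null mixed model.

    Fits y = X beta + g + e by REML (X = intercept plus covariates, g a
    polygenic effect with covariance proportional to the GRM) and returns the
    fixed-effect residuals y - X beta_hat, which downstream association then
    tests against each marker.
    """
    y = np.asarray(trait, dtype=float)
    name = trait.name if isinstance(trait, pd.Series) else "trait"
    X = _design(len(y), None if covariates is None else np.asarray(covariates))
    eigvals, U = np.linalg.eigh(grm)
    eigvals = np.clip(eigvals, 0, None)
    try:
        fit = _reml_eig(y, X, eigvals, U)
    except RuntimeError as exc:
        raise RuntimeError(f"REML failed for trait {name!r}: {exc}") from exc
    adjusted = y - X @ fit.beta
    return adjusted, fit


# ---------------------------------------------------------------- LOCO scan


def mlma_loco(
    G: GenotypeMatrix, panel: TraitPanel, covariates_in_test: bool = False
) -> MarkerStats:
    """LOCO mixed-model association scan for every trait and marker.

    For each (trait, chromosome) the null-model variance components are
    fitted once on the GRM that excludes the chromosome; every marker on it
    is then tested by generalized least squares with those components fixed,
    yielding effect, standard error, signed t and a Wald p-value.
    """
    if list(panel.traits.index) != list(G.samples):
        raise ConfigurationError("trait panel rows must match genotype samples")
    chroms = list(dict.fromkeys(G.markers["chrom"]))
    single_chrom = len(chroms) < 2
    if single_chrom:
        log.warning(
            "only one chromosome present: falling back to a plain mixed model "
            "with the full-genome GRM"
        )

    X0 = _design(
        G.n_samples,
        None
        if (panel.covariates is None or not covariates_in_test)
        else panel.covariates.to_numpy(),
    )
    dos = mean_impute(G.dosages)

    marker_index = G.markers.index
    out = {
        k: pd.DataFrame(
            np.nan, index=marker_index, columns=panel.trait_names
        )
        for k in ("beta", "se", "t", "p")
    }

    for chrom in chroms:
        on_chrom = (G.markers["chrom"] == chrom).to_numpy()
        A = compute_grm(G, exclude_chrom=None if single_chrom else chrom)
        eigvals, U = np.linalg.eigh(A)
        eigvals = np.clip(eigvals, 0, None)
        M = U.T @ dos[:, on_chrom]
        X0t = U.T @ X0
        for trait in panel.trait_names:
            y = panel.traits[trait].to_numpy(dtype=float)
            fit = _reml_eig(y, X0, eigvals, U)
            w = 1.0 / (fit.h2 * eigvals + (1 - fit.h2))
            yt = U.T @ y
            beta, se = _gls_scan(yt, X0t, M, w, fit.sigma2)
            tvals = np.divide(
                beta, se, out=np.zeros_like(beta), where=se > 0
            )
            pvals = stats.chi2.sf(tvals**2, df=1)
            out["beta"].loc[on_chrom, trait] = beta
            out["se"].loc[on_chrom, trait] = se
            out["t"].loc[on_chrom, trait] = tvals
            out["p"].loc[on_chrom, trait] = pvals
    return MarkerStats(**out)


def _gls_scan(
    yt: np.ndarray, X0t: np.ndarray, M: np.ndarray, w: np.ndarray, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS Wald test with fixed weights.

    Solves, for each marker column x of M, the weighted regression of yt on
    [X0t, x] and returns the marker coefficient and its standard error.
    Uses the partitioned-regression identity: project x and y off the null
    design under the GLS inner product, then do a 1-D weighted fit.
    """
    WX0 = w[:, None] * X0t
    G0 = X0t.T @ WX0  # p x p
    G0_inv = np.linalg.inv(G0)
    # residualize y and every marker against X0 in the W metric
    coef_y = G0_inv @ (WX0.T @ yt)
    ry = yt - X0t @ coef_y
    coef_M = G0_inv @ (WX0.T @ M)
    RM = M - X0t @ coef_M
    xx = np.einsum("ij,i,ij->j", RM, w, RM)
    xy = np.einsum("ij,i,i->j", RM, w, ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(xx > 0, xy / np.maximum(xx, 1e-300), 0.0)
        se = np.where(xx > 0, np.sqrt(sigma2 / np.maximum(xx, 1e-300)), np.inf)
    return beta, se


# ---------------------------------------------------------------- pleiotropy


def trait_correlation_matrix(
    stats_: MarkerStats, ridge: float | None = None, cond_max: float = 1e8
) -> pd.DataFrame:
    """Correlation matrix V of the traits' signed t-values across markers."""
    T = stats_.t.dropna(axis=0, how="any")
    if T.shape[1] < 2:
        raise ConfigurationError("need at least 2 traits")
    if T.shape[0] < 3:
        raise ConfigurationError("need at least 3 markers to estimate V")
    V = T.corr().to_numpy()
    if ridge:
        V = V + ridge * np.eye(V.shape[0])
        V = V / np.sqrt(np.outer(np.diag(V), np.diag(V)))
    if not np.all(np.isfinite(V)):
        raise ConfigurationError("V contains non-finite entries (constant t column?)")
    if np.linalg.cond(V) > cond_max:
        raise ConfigurationError(
            "trait t-value correlation matrix is near-singular "
            f"(condition number > {cond_max:g}); duplicated traits? "
            "Consider the ridge option (e.g. ridge=1e-6)."
        )
    return pd.DataFrame(V, index=stats_.t.columns, columns=stats_.t.columns)


def pleiotropy_statistic(stats_: MarkerStats, V: pd.DataFrame) -> PleioTable:
    """Per-marker multi-trait chi-square: chi2 = t' V^-1 t, df = #traits."""
    T = stats_.t
    df = T.shape[1]
    finite = np.isfinite(T.to_numpy()).all(axis=1)
    if not finite.all():
        log.warning(
            "pleiotropy: excluding %d markers with non-finite t-values",
            int((~finite).sum()),
        )
    Tf = T.loc[finite]
    Vinv = np.linalg.inv(V.to_numpy())
    tv = Tf.to_numpy()
    chi2 = np.einsum("ij,jk,ik->i", tv, Vinv, tv)
    chi2 = np.clip(chi2, 0, None)
    pvals = stats.chi2.sf(chi2, df=df)
    table = pd.DataFrame(
        {"chi2": chi2, "df": df, "p": pvals}, index=Tf.index
    )
    return PleioTable(table=table, V=V)
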