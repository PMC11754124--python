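"""Hypothesis tests for NB and quasi-NB GLM fits.

Likelihood-ratio tests (fixed NB-dispersion), quasi-F tests (likelihood
ratio numerator, EB-squeezed quasi-dispersion denominator on posterior df),
threshold (TREAT-style) tests against a fold-change cutoff, BH adjustment
and result ranking.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DesignMatrix
from .glm import GLMFit, fit_levenberg
from .io import ResultTable
from .quasi import QLFit

__all__ = [
    "glm_lrt",
    "ql_ftest",
    "glm_treat",
    "bh_adjust",
    "top_tags",
    "decide_tests",
]

_LOG2 = np.log(2.0)


def _contrast_matrix(p: int, contrast=None, coef=None) -> np.ndarray:
    """Resolve a coefficient index set or contrast spec to a p x r matrix."""
    if (contrast is None) == (coef is None):
        raise ValueError("specify exactly one of contrast or coef")
    if coef is not None:
        idx = np.atleast_1d(np.asarray(coef, dtype=int))
        C = np.zeros((p, idx.size))
        for j, k in enumerate(idx):
            if not 0 <= k < p:
                raise ValueError(f"coefficient index {k} out of range")
            C[k, j] = 1.0
        return C
    C = np.asarray(contrast, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != p:
        raise ValueError(f"contrast has {C.shape[0]} rows, design has {p} coefficients")
    r = C.shape[1]
    if r < 1 or np.linalg.matrix_rank(C) < r:
        raise ValueError("contrast matrix must have full column rank >= 1")
    return C


def _null_space_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the coefficient directions orthogonal to C."""
    p, r = C.shape
    q, _ = np.linalg.qr(np.hstack([C, np.eye(p)]))
    return q[:, r:p]


def _refit_null(fit: GLMFit, C: np.ndarray) -> np.ndarray:
    """Deviance of the null model whose column space is orthogonal to C."""
    B = _null_space_basis(C)
    offsets = fit.offset.expand()
    if B.shape[1] == 0:
        from .glm import _weighted_deviance

        mu0 = np.exp(offsets)
        return _weighted_deviance(fit.counts, mu0, fit.phi, fit.weight_matrix())
    X0 = fit.design.values @ B
    null_dm = DesignMatrix(X0, [f"null{j + 1}" for j in range(X0.shape[1])])
    nfit = fit_levenberg(
        fit.counts, null_dm, offsets, fit.phi, weights=fit.weights
    )
    return nfit.deviance


def _lr_statistic(fit: GLMFit, C: np.ndarray) -> np.ndarray:
    dev0 = _refit_null(fit, C)
    return np.maximum(dev0 - fit.deviance, 0.0)


def _logfc_columns(fit: GLMFit, C: np.ndarray) -> dict:
    """Reported log2 fold changes from prior-count-shrunk coefficients."""
    beta = fit.coefficients_shrunk if fit.coefficients_shrunk is not None else fit.coefficients
    beta = np.where(np.isfinite(beta), beta, 0.0)
    vals = beta @ C / _LOG2
    if C.shape[1] == 1:
        return {"logFC": vals[:, 0]}
    return {f"logFC.{j + 1}": vals[:, j] for j in range(C.shape[1])}


def _assemble(fit, cols, stat_name, p, sort=False) -> ResultTable:
    cols["PValue"] = p
    cols["FDR"] = bh_adjust(p)
    tbl = ResultTable(
        table=pd.DataFrame(cols),
        genes=getattr(fit, "genes", None),
        statistic=stat_name,
    )
    return tbl


def glm_lrt(fit: GLMFit, contrast=None, coef=None) -> ResultTable:
    """Likelihood-ratio test of a contrast at fixed NB-dispersion.

    The null fit spans the coefficient directions orthogonal to the
    contrast; ``LR = deviance_null - deviance_full >= 0`` is referred to a
    chi-square on r df.
    """
    C = _contrast_matrix(fit.design.n_coef, contrast, coef)
    r = C.shape[1]
    LR = _lr_statistic(fit, C)
    p = stats.chi2.sf(LR, r)
    cols = _logfc_columns(fit, C)
    cols["logCPM"] = fit.abundance
    cols["LR"] = LR
    return _assemble(fit, cols, "LR", p)


def ql_ftest(qlfit: QLFit, contrast=None, coef=None) -> ResultTable:
    """Quasi-F test: LR statistic numerator, squeezed quasi-dispersion
    denominator, on (r, posterior df).

    With infinite prior df the posterior df is infinite and the reference
    distribution is chi-square on r df of ``LR/s2``.  Genes with zero
    adjusted residual df get an NA p-value.
    """
    fit = qlfit.glm
    C = _contrast_matrix(fit.design.n_coef, contrast, coef)
    r = C.shape[1]
    LR = _lr_statistic(fit, C)
    s2 = np.clip(qlfit.s2_post, 1e-300, None)
    F = (LR / r) / s2
    df2 = qlfit.df_post
    p = np.empty(fit.n_genes)
    inf = np.isinf(df2)
    fin = ~inf
    if r == 1:
        # equivalent single-df tail form shared with the threshold test
        z = np.sqrt(np.maximum(F, 0.0))
        if inf.any():
            p[inf] = 2.0 * stats.norm.sf(z[inf])
        if fin.any():
            p[fin] = 2.0 * stats.t.sf(z[fin], df2[fin])
    else:
        if inf.any():
            p[inf] = stats.chi2.sf(LR[inf] / s2[inf], r)
        if fin.any():
            p[fin] = stats.f.sf(F[fin], r, df2[fin])
    p[qlfit.df_adj == 0] = np.nan
    cols = _logfc_columns(fit, C)
    cols["logCPM"] = qlfit.abundance
    cols["F"] = F
    return _assemble(qlfit, cols, "F", p)


def glm_treat(fit_or_qlfit, contrast=None, coef=None, lfc_threshold: float = 0.0) -> ResultTable:
    """Test differential abundance relative to a log2-fold-change threshold.

    For a single contrast with estimate ``bhat``, two boundary nulls at
    ``+tau`` and ``-tau`` (natural-log ``tau = lfc_threshold * log 2``) are
    fitted by constraining the contrast via an offset shift; the signed
    square roots of the resulting deviance differences (scaled by the
    posterior quasi-dispersion) are referred to the posterior-df t
    distribution and their upper tails summed.  With ``tau = 0`` this
    reproduces the ordinary two-sided test exactly, and at
    ``|logFC| = tau`` the p-value is at least 0.5.
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be non-negative")
    if isinstance(fit_or_qlfit, QLFit):
        qfit = fit_or_qlfit
        fit = qfit.glm
        s2 = np.clip(qfit.s2_post, 1e-300, None)
        df2 = qfit.df_post
        abundance = qfit.abundance
    else:
        fit = fit_or_qlfit
        s2 = np.ones(fit.n_genes)
        df2 = np.full(fit.n_genes, np.inf)
        abundance = fit.abundance
    C = _contrast_matrix(fit.design.n_coef, contrast, coef)
    if C.shape[1] != 1:
        raise ValueError("threshold tests require a single-column contrast")
    c = C[:, 0]
    tau = lfc_threshold * _LOG2

    beta = np.where(np.isfinite(fit.coefficients), fit.coefficients, 0.0)
    bhat = beta @ c  # unshrunk contrast estimate, natural log
    sign = np.where(bhat >= 0, 1.0, -1.0)

    # reparameterize so the contrast is the first coefficient:
    # eta = X M gamma with M^{-1} = [c'; B'] -> gamma_1 = c' beta
    B = _null_space_basis(C)
    Minv = np.vstack([c[None, :], B.T])
    M = np.linalg.inv(Minv)
    X = fit.design.values
    x_contrast = X @ M[:, 0]
    X_null = X @ M[:, 1:]
    offsets = fit.offset.expand()

    def _null_dev(gamma0_per_gene):
        shift = gamma0_per_gene[:, None] * x_contrast[None, :]
        if X_null.shape[1] == 0:
            from .glm import _weighted_deviance

            mu0 = np.exp(offsets + shift)
            return _weighted_deviance(fit.counts, mu0, fit.phi, fit.weight_matrix())
        nfit = fit_levenberg(
            fit.counts,
            DesignMatrix(X_null, [f"n{j}" for j in range(X_null.shape[1])]),
            offsets + shift,
            fit.phi,
            weights=fit.weights,
        )
        return nfit.deviance

    if tau == 0:
        dev_near = _refit_null(fit, C)
        dev_far = dev_near
    else:
        dev_near = _null_dev(sign * tau)
        dev_far = _null_dev(-sign * tau)
    LR_near = np.maximum(dev_near - fit.deviance, 0.0)
    LR_far = np.maximum(dev_far - fit.deviance, 0.0)

    z_near = np.where(np.abs(bhat) >= tau, 1.0, -1.0) * np.sqrt(LR_near / s2)
    z_far = np.sqrt(LR_far / s2)

    p = np.empty(fit.n_genes)
    inf = np.isinf(df2)
    if inf.any():
        p[inf] = stats.norm.sf(z_near[inf]) + stats.norm.sf(z_far[inf])
    fin = ~inf
    if fin.any():
        p[fin] = stats.t.sf(z_near[fin], df2[fin]) + stats.t.sf(z_far[fin], df2[fin])
    p = np.minimum(p, 1.0)

    cols = _logfc_columns(fit, C)
    cols["logCPM"] = abundance
    cols["unshrunk.logFC"] = bhat / _LOG2
    return _assemble(fit_or_qlfit, cols, "z", p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA values propagate without affecting the ranks (or the denominator m)
    of the others.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        from statsmodels.stats.multitest import multipletests

        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def top_tags(tbl: ResultTable, n: Optional[int] = None, sort_by: str = "pvalue") -> ResultTable:
    """Stable ranking of a result table; ties keep gene order."""
    df = tbl.table
    if sort_by == "pvalue":
        order = np.argsort(df["PValue"].to_numpy(), kind="stable")
    elif sort_by == "logfc":
        order = np.argsort(-np.abs(df["logFC"].to_numpy()), kind="stable")
    else:
        raise ValueError("sort_by must be 'pvalue' or 'logfc'")
    if n is not None:
        order = order[:n]
    genes = None
    if tbl.genes is not None:
        genes = tbl.genes.iloc[order].reset_index(drop=True)
    return ResultTable(
        table=df.iloc[order].reset_index(drop=True),
        genes=genes,
        statistic=tbl.statistic,
        sorted=True,
    )


def decide_tests(tbl: ResultTable, fdr: float = 0.05, lfc: float = 0.0) -> np.ndarray:
    """Per-gene calls in {-1, 0, +1} at an FDR threshold and optional
    minimum absolute log2 fold change."""
    f = tbl.table["FDR"].to_numpy()
    logfc = tbl.table["logFC"].to_numpy()
    sig = np.nan_to_num(f, nan=1.0) <= fdr
    up = sig & (logfc > lfc)
    down = sig & (logfc < -lfc)
    return up.astype(int) - down.astype(int)
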