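"""Cox-Reid adjusted profile likelihood and weighted-likelihood EB
estimation of common, trended and tagwise NB-dispersions.

Genewise maximum likelihood underestimates the NB-dispersion because the
same data estimate the mean model; the Cox-Reid adjustment subtracts half
the log-determinant of the Fisher information at the fit, the GLM analogue
of REML.  Dispersions are then shared across genes by weighted-likelihood
empirical Bayes: a common value maximizes the equally weighted sum of
genewise APLs; a trend maximizes an abundance-local moving average of the
APLs; and the tagwise (gene-specific) value maximizes the gene's own APL
plus a prior-weighted copy of its locally shared APL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .datamodel import CountDataset, _as_design, resolve_offsets
from .glm import fit_levenberg, nb_log_density_continuous

__all__ = [
    "DispersionSet",
    "adjusted_profile_lik",
    "maximize_interpolant",
    "estimate_disp",
    "default_grid",
    "common_dispersion_top",
]

# 21 points, equal log2 spacing, spanning BCV 0.005..2 (phi 2.5e-5..4)
_GRID_LEN = 21
_BCV_LO, _BCV_HI = 0.005, 2.0


def default_grid(center: Optional[float] = None, length: int = _GRID_LEN):
    """Dispersion grid on a log2 scale.

    Without a center, spans BCV 0.005 to 2; with one, a refinement grid of
    the same length spanning a factor of 2**6 either side of the center.
    """
    if center is None:
        return 2.0 ** np.linspace(np.log2(_BCV_LO**2), np.log2(_BCV_HI**2), length)
    center = float(np.clip(center, 1e-10, 1e4))
    return center * 2.0 ** np.linspace(-6, 6, length)


def adjusted_profile_lik(phi, y, design, offsets, weights=None):
    """Per-gene Cox-Reid adjusted profile log-likelihood at fixed ``phi``.

    Fits the genewise GLM at ``phi``, evaluates the continuous-NB
    log-likelihood at the fit, and subtracts half the log-determinant of the
    Fisher information ``X' W X`` (working weights ``w mu/(1 + phi mu)``).
    The determinant is computed from an eigendecomposition with eigenvalues
    floored at 1e-300 before the log, so genes with degenerate information
    (e.g. all-zero rows) still contribute the non-degenerate part.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    G, n = y.shape
    dm = _as_design(design, n)
    X = dm.values
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    w = np.ones_like(y) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), y.shape
    )
    phi_g = np.full(G, float(phi)) if np.ndim(phi) == 0 else np.asarray(phi, float)

    fit = fit_levenberg(y, dm, offsets, phi_g, weights=None if weights is None else w)
    mu = fit.fitted
    phim = np.broadcast_to(phi_g[:, None], y.shape)
    ll = (w * nb_log_density_continuous(y, np.maximum(mu, 1e-300), phim)).sum(axis=1)

    wwork = w * mu / (1.0 + phim * mu)
    info = np.einsum("gn,ni,nj->gij", wwork, X, X, optimize=True)
    eigs = np.linalg.eigvalsh(info)
    logdet = np.log(np.clip(eigs, 1e-300, None)).sum(axis=1)
    return ll - 0.5 * logdet


def maximize_interpolant(grid, values):
    """Maximize a cubic spline through per-gene values over log(phi).

    ``grid`` holds strictly increasing dispersion values (>= 4 points);
    a not-a-knot cubic spline (which reproduces cubic polynomials, hence
    quadratic likelihood approximations, exactly) is fitted on the
    log-dispersion scale and the maximizer is found among interior
    stationary points and the grid endpoints.  Genes
    with non-finite values use their finite subset.  Returns the argmax on
    the original dispersion scale.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 4 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 4 points")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    G, K = values.shape
    if K != grid.size:
        raise ValueError("values must have one column per grid point")
    x = np.log(grid)

    finite = np.isfinite(values).all(axis=1)
    out = np.empty(G)
    if finite.any():
        out[finite] = _maximize_block(x, values[finite])
    for g in np.flatnonzero(~finite):
        mask = np.isfinite(values[g])
        if mask.sum() >= 4:
            out[g] = _maximize_block(x[mask], values[g][mask][None, :])[0]
        elif mask.any():
            out[g] = np.exp(x[mask][np.argmax(values[g][mask])])
        else:
            out[g] = grid[0]
    return out


def _maximize_block(x, vals):
    """Vectorized spline maximization for an all-finite block."""
    G, K = vals.shape
    cs = CubicSpline(x, vals.T, bc_type="not-a-knot")
    c = cs.c  # (4, K-1, G)
    best_val = vals.max(axis=1)
    best_x = x[np.argmax(vals, axis=1)]
    h = np.diff(x)
    for i in range(K - 1):
        c3, c2, c1, _c0 = c[0, i], c[1, i], c[2, i], c[3, i]
        # derivative roots of c3 t^3 + c2 t^2 + c1 t + c0 on [0, h_i]
        A, B, C = 3.0 * c3, 2.0 * c2, c1
        disc = B * B - 4.0 * A * C
        with np.errstate(invalid="ignore", divide="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            # numerically stable roots: q/A and C/q with q = -(B + sign(B) sq)/2,
            # valid also when the cubic coefficient nearly vanishes
            q = -0.5 * (B + np.where(B >= 0, 1.0, -1.0) * sq)
            for t in (q / A, C / q):
                ok = (disc >= 0) & np.isfinite(t) & (t > 0) & (t < h[i])
                if ok.any():
                    tv = t[ok]
                    val = ((c3[ok] * tv + c2[ok]) * tv + c1[ok]) * tv + c[3, i][ok]
                    better = val > best_val[ok]
                    idx = np.flatnonzero(ok)[better]
                    best_val[idx] = val[better]
                    best_x[idx] = x[i] + tv[better]
    return np.exp(best_x)


def _moving_average(mat, span_genes):
    """Symmetric moving average down the gene axis with edge shrinkage."""
    G = mat.shape[0]
    h = max(int(span_genes // 2), 1)
    cs = np.cumsum(np.vstack([np.zeros((1, mat.shape[1])), mat]), axis=0)
    lo = np.maximum(np.arange(G) - h, 0)
    hi = np.minimum(np.arange(G) + h + 1, G)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def common_dispersion_top(ds: CountDataset, design, gene_index=None) -> float:
    """Common NB-dispersion maximizing the summed APL over a gene subset."""
    idx = np.arange(ds.n_genes) if gene_index is None else np.asarray(gene_index)
    sub = ds[idx, :] if len(idx) != ds.n_genes else ds
    dm = _as_design(design, ds.n_samples)
    offs = resolve_offsets(sub).expand()
    w = None if sub.weights is None else sub.weights.expand()
    grid = default_grid()
    apl = np.column_stack(
        [adjusted_profile_lik(g, sub.counts, dm, offs, w) for g in grid]
    )
    common = maximize_interpolant(grid, apl.mean(axis=0, keepdims=True))[0]
    grid2 = default_grid(center=common)
    apl2 = np.column_stack(
        [adjusted_profile_lik(g, sub.counts, dm, offs, w) for g in grid2]
    )
    return float(maximize_interpolant(grid2, apl2.mean(axis=0, keepdims=True))[0])


@dataclass
class DispersionSet:
    """Common, trended and tagwise NB-dispersion estimates."""

    common: float
    trended: np.ndarray
    tagwise: np.ndarray
    genewise: np.ndarray
    abundance: np.ndarray
    prior_df: float
    grid: np.ndarray
    span: float

    def bcv_table(self) -> pd.DataFrame:
        """Square-root dispersions (BCV scale) for plotting vs abundance."""
        return pd.DataFrame(
            {
                "abundance": self.abundance,
                "common": np.sqrt(self.common) * np.ones_like(self.abundance),
                "trended": np.sqrt(self.trended),
                "tagwise": np.sqrt(self.tagwise),
            }
        )


def estimate_disp(
    ds: CountDataset,
    design,
    prior_df: Optional[float] = None,
    span: Optional[float] = None,
) -> DispersionSet:
    """Weighted-likelihood EB estimation of NB-dispersions.

    The common dispersion maximizes the equally weighted APL sum; the trend
    maximizes abundance-local moving averages of the genewise APLs; the
    tagwise estimates maximize ``APL_g + G0 * APL_local`` with
    ``G0 = prior_df / residual_df``.  When not supplied, the prior df is
    estimated from the spread of genewise deviance dispersions about the
    trend by the same moment fit used for quasi-dispersion moderation.
    """
    from .norm import ave_log_cpm
    from .quasi import fit_f_dist

    dm = _as_design(design, ds.n_samples)
    G, n = ds.n_genes, ds.n_samples
    p = dm.n_coef
    df_resid = n - p
    if df_resid < 1:
        raise ValueError(
            "no residual df: supply an external dispersion and use the QL "
            "pipeline instead"
        )
    offs = resolve_offsets(ds).expand()
    w = None if ds.weights is None else ds.weights.expand()
    abundance = ave_log_cpm(ds)

    grid1 = default_grid()
    apl1 = np.column_stack(
        [adjusted_profile_lik(g, ds.counts, dm, offs, w) for g in grid1]
    )
    common1 = maximize_interpolant(grid1, apl1.mean(axis=0, keepdims=True))[0]
    grid = default_grid(center=common1)
    apl = np.column_stack(
        [adjusted_profile_lik(g, ds.counts, dm, offs, w) for g in grid]
    )
    common = float(maximize_interpolant(grid, apl.mean(axis=0, keepdims=True))[0])

    if span is None:
        span = min(max(0.25, 10.0 / G), 1.0)
    order = np.argsort(abundance, kind="stable")
    span_genes = max(int(np.ceil(span * G)), 2)
    apl_smooth_sorted = _moving_average(apl[order], span_genes)
    apl_smooth = np.empty_like(apl)
    apl_smooth[order] = apl_smooth_sorted

    trended = maximize_interpolant(grid, apl_smooth)
    genewise = maximize_interpolant(grid, apl)

    if prior_df is None:
        fit = fit_levenberg(
            ds.counts, dm, offs, np.maximum(trended, 1e-10), weights=w
        )
        with np.errstate(invalid="ignore"):
            s2 = fit.deviance / df_resid
        try:
            _, d0 = fit_f_dist(s2, np.full(G, float(df_resid)), abundance)
        except ValueError:
            d0 = np.inf
        prior_df = d0
    prior_df = float(prior_df)

    if np.isinf(prior_df):
        tagwise = trended.copy()
    elif prior_df == 0:
        tagwise = genewise.copy()
    else:
        G0 = prior_df / df_resid
        tagwise = maximize_interpolant(grid, apl + G0 * apl_smooth)

    return DispersionSet(
        common=common,
        trended=trended,
        tagwise=tagwise,
        genewise=genewise,
        abundance=abundance,
        prior_df=prior_df,
        grid=grid,
        span=span,
    )
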