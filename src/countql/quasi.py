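"""Bias-adjusted quasi-likelihood engine.

Classical quasi-likelihood treats the GLM residual deviance as a scaled
chi-square on ``n - p`` df, which is badly biased when fitted means are
small.  Here each unit deviance is instead moment-matched to a scaled
chi-square on *fractional* df: given the fitted mean and NB-dispersion of
each observation, the exact mean ``e`` and variance ``v`` of the unit
deviance are computed and matched by a scale ``s = v/(2e)`` and df
``k = 2 e^2 / v``.  Summed over the observations of a gene, these give a
bias-adjusted residual deviance and fractional residual df from which a
nearly unbiased quasi-dispersion estimate follows, even for fitted values
close to zero.

The genewise quasi-dispersions are then moderated towards an
abundance-dependent trend by an empirical-Bayes F-distribution fit that
supports unequal, fractional residual df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .datamodel import CountDataset
from .glm import GLMFit, glm_fit, nb_unit_deviance

__all__ = [
    "DevianceMoments",
    "QLFit",
    "unit_deviance_moments",
    "adjusted_deviance_df",
    "fit_f_dist",
    "squeeze_quasi_dispersions",
    "ql_fit",
]

# beyond this mean-variance size the gamma-limit moments are used
_MOMENT_CROSSOVER = 1e4
_MAX_TERMS = 1_000_000


@dataclass
class DevianceMoments:
    """First two moments of the NB unit deviance, and the matched scaled
    chi-square parameters (df ``k = 2e^2/v``, scale ``s = v/(2e)``)."""

    e: np.ndarray
    v: np.ndarray

    @property
    def df(self) -> np.ndarray:
        return 2.0 * self.e**2 / self.v

    @property
    def scale(self) -> np.ndarray:
        return self.v / (2.0 * self.e)


def _moments_gamma_limit(phi):
    """mu -> infinity limit: deviance of the gamma mixing distribution.

    For ``phi = 0`` this is the chi-square(1) limit ``(e, v) = (1, 2)``;
    for ``phi > 0`` with ``a = 1/phi``, ``e = 2a(log a - psi(a))`` and
    ``v = 4a^2(psi'(a) - 1/a)``.
    """
    phi = np.asarray(phi, dtype=float)
    e = np.ones_like(phi)
    v = np.full_like(phi, 2.0)
    pos = phi > 1e-12
    if pos.any():
        a = 1.0 / phi[pos]
        e[pos] = 2.0 * a * (np.log(a) - special.digamma(a))
        v[pos] = 4.0 * a * a * (special.polygamma(1, a) - 1.0 / a)
    return e, v


def _moments_exact_block(mu, phi, ymax_cap):
    """Probability-weighted summation of d and d^2 over y = 0..ymax."""
    P = mu.size
    e = np.empty(P)
    v = np.empty(P)
    a = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
    y = np.arange(ymax_cap + 1, dtype=float)
    # chunk pairs so the (pairs x ymax) workspace stays modest
    step = max(1, int(5_000_000 // (ymax_cap + 1)))
    for lo in range(0, P, step):
        sl = slice(lo, min(lo + step, P))
        mm = mu[sl][:, None]
        ph = phi[sl][:, None]
        pois = phi[sl] == 0
        pmf = np.empty((mm.shape[0], y.size))
        if pois.any():
            pmf[pois] = stats.poisson.pmf(y[None, :], mm[pois])
        nb = ~pois
        if nb.any():
            aa = a[sl][nb][:, None]
            pmf[nb] = stats.nbinom.pmf(y[None, :], aa, aa / (aa + mm[nb]))
        d = nb_unit_deviance(y[None, :], mm, ph)
        e[sl] = (pmf * d).sum(axis=1)
        v[sl] = (pmf * d * d).sum(axis=1) - e[sl] ** 2
    return e, v


def unit_deviance_moments(mu, phi) -> DevianceMoments:
    """Exact mean and variance of the NB unit deviance at ``(mu, phi)``.

    For ``mu (1 + phi mu)`` below a crossover the moments are computed by
    explicit probability-weighted summation over the integers (to cumulative
    probability ``1 - 1e-12``, capped at 1e6 terms); above it, the gamma
    mixing-distribution limit is used, with continuity at the crossover
    better than 1e-3 relative.  Repeated ``(mu, phi)`` pairs are de-duplicated
    internally, so matrix inputs with repeat structure are cheap.
    """
    mu_in = np.asarray(mu, dtype=float)
    phi_in = np.asarray(phi, dtype=float)
    mu_b, phi_b = np.broadcast_arrays(mu_in, phi_in)
    shape = mu_b.shape
    mu_f = mu_b.ravel()
    phi_f = phi_b.ravel()
    if np.any(mu_f <= 0):
        raise ValueError("mu must be positive")
    if np.any(phi_f < 0):
        raise ValueError("phi must be non-negative")

    key = mu_f + 1j * phi_f
    uniq, inv = np.unique(key, return_inverse=True)
    umu = uniq.real
    uphi = uniq.imag

    e = np.empty(uniq.size)
    v = np.empty(uniq.size)
    asym = umu * (1.0 + uphi * umu) > _MOMENT_CROSSOVER
    if asym.any():
        e[asym], v[asym] = _moments_gamma_limit(uphi[asym])
    ex = ~asym
    if ex.any():
        mu_e, phi_e = umu[ex], uphi[ex]
        a_e = np.where(phi_e > 0, 1.0 / np.where(phi_e > 0, phi_e, 1.0), np.inf)
        # smallest y with cumulative probability >= 1 - 1e-12
        with np.errstate(all="ignore"):
            ymax = np.where(
                phi_e == 0,
                stats.poisson.ppf(1.0 - 1e-12, mu_e),
                stats.nbinom.ppf(1.0 - 1e-12, a_e, a_e / (a_e + mu_e)),
            )
        ymax = np.minimum(np.nan_to_num(ymax, nan=_MAX_TERMS) + 1, _MAX_TERMS).astype(
            np.int64
        )
        ee = np.empty(mu_e.size)
        vv = np.empty(mu_e.size)
        order = np.argsort(ymax)
        bounds = [64, 256, 1024, 4096, 16384, 65536, _MAX_TERMS]
        start = 0
        for cap in bounds:
            end = np.searchsorted(ymax[order], cap, side="right")
            if end > start:
                idx = order[start:end]
                ee[idx], vv[idx] = _moments_exact_block(mu_e[idx], phi_e[idx], cap)
                start = end
            if start == mu_e.size:
                break
        e[ex] = ee
        v[ex] = vv

    e = np.maximum(e, 1e-300)
    v = np.maximum(v, 1e-300)
    return DevianceMoments(e[inv].reshape(shape), v[inv].reshape(shape))


def adjusted_deviance_df(fit: GLMFit):
    """Per-gene bias-adjusted residual deviance and fractional residual df.

    Each observation with positive fitted mean contributes an adjusted
    deviance ``w d / s`` and df ``w k``, with ``(s, k)`` the moment-matched
    scale and df at ``(mu_hat, phi)``; observations with fitted mean exactly
    zero contribute nothing.  The gene's residual df is the total df scaled
    by ``(n_g - p)/n_g`` (``n_g`` = nonzero-fitted observation count), which
    reduces to the classical ``n - p`` in the large-count Poisson limit.
    Genes with ``n_g <= p`` get ``(0, 0)`` and are excluded from the EB fit.

    Returns ``(D_adj, df_adj)``; the raw quasi-dispersion estimate is their
    ratio.
    """
    y = fit.counts
    mu = fit.fitted
    G, n = mu.shape
    p = fit.design.n_coef
    w = fit.weight_matrix()
    phi_mat = np.broadcast_to(fit.phi[:, None], mu.shape)

    pos = mu > 0
    d_adj = np.zeros_like(mu)
    k = np.zeros_like(mu)
    if pos.any():
        mom = unit_deviance_moments(mu[pos], phi_mat[pos])
        d = nb_unit_deviance(y[pos], mu[pos], phi_mat[pos])
        d_adj[pos] = w[pos] * d / mom.scale
        k[pos] = w[pos] * mom.df

    n_g = pos.sum(axis=1).astype(float)
    K = k.sum(axis=1)
    usable = n_g > p
    df_adj = np.zeros(G)
    df_adj[usable] = K[usable] * (n_g[usable] - p) / n_g[usable]
    D_adj = np.where(usable, d_adj.sum(axis=1), 0.0)
    return D_adj, df_adj


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _weighted_local_regression(x, z, w, frac=0.3):
    """df-weighted local linear regression of z on x (tricube kernel).

    Returns fitted values at every x.  The window is the ``frac`` fraction
    of points nearest in rank, shrunk symmetrically at the edges.
    """
    n = x.size
    if n == 1:
        return z.copy()
    order = np.argsort(x, kind="stable")
    xs, zs, ws = x[order], z[order], w[order]
    h = max(int(np.ceil(frac * n / 2)), 2)
    fitted = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        xi = xs[lo:hi]
        zi = zs[lo:hi]
        dist = np.abs(xi - xs[i])
        dmax = dist.max()
        if dmax <= 0:
            kern = np.ones_like(dist)
        else:
            kern = (1.0 - (dist / dmax) ** 3) ** 3
            kern = np.maximum(kern, 1e-4)
        wi = kern * ws[lo:hi]
        sw = wi.sum()
        xm = (wi * xi).sum() / sw
        zm = (wi * zi).sum() / sw
        sxx = (wi * (xi - xm) ** 2).sum()
        slope = (wi * (xi - xm) * (zi - zm)).sum() / sxx if sxx > 1e-12 else 0.0
        fitted[i] = zm + slope * (xs[i] - xm)
    out = np.empty(n)
    out[order] = fitted
    return out


def fit_f_dist(s2, df, covariate, window: float = 0.3, min_df: float = 0.05):
    """Empirical-Bayes F-distribution fit with unequal fractional df.

    Models ``s2_g ~ s0^2(x_g) F(df_g, d0)``.  On ``z = log s2`` the
    df-dependent mean offset of a log chi-square
    (``digamma(df/2) - log(df/2)``) is removed, the remainder is smoothed on
    the abundance covariate by a df-weighted local regression, and the prior
    df ``d0`` solves the moment equation
    ``var(detrended z) - mean trigamma(df/2) = trigamma(d0/2)``.
    No excess spread gives ``d0 = inf``.

    Returns ``(s0^2 per gene on the dispersion scale, d0)``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > min_df)
    if df[np.isfinite(df)].max(initial=0.0) <= 0:
        raise ValueError("all residual df are zero; cannot fit an F-distribution")
    if ok.sum() < 10:
        raise ValueError("need at least 10 genes with positive df and s2 > 0")

    z = np.log(s2[ok])
    half = df[ok] / 2.0
    offset = special.digamma(half) - np.log(half)
    e = z - offset
    trend_ok = _weighted_local_regression(covariate[ok], e, df[ok], frac=window)

    resid = e - trend_ok
    mean_tri = np.mean(special.polygamma(1, half))
    excess = float(np.mean(resid**2) * ok.sum() / max(ok.sum() - 1, 1) - mean_tri)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
    else:
        d0 = np.inf

    # extend the trend to all genes (flat beyond the fitted range)
    xs = covariate[ok]
    order = np.argsort(xs, kind="stable")
    trend_all = np.interp(covariate, xs[order], trend_ok[order])
    if np.isfinite(d0):
        correction = np.log(d0 / 2.0) - special.digamma(d0 / 2.0)
    else:
        correction = 0.0
    s20 = np.exp(trend_all - correction)
    return s20, d0


def squeeze_quasi_dispersions(s2, df, trend, d0):
    """EB posterior quasi-dispersions and posterior df.

    ``s2_post = (d0 trend + df s2)/(d0 + df)``; the ``d0 = inf`` limit is
    the trend itself.  Posterior df = ``d0 + df``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    trend = np.broadcast_to(np.asarray(trend, dtype=float), s2.shape)
    if np.isinf(d0):
        return trend.copy(), np.full_like(s2, np.inf)
    contrib = np.where(df > 0, df * np.nan_to_num(s2), 0.0)
    post = (d0 * trend + contrib) / (d0 + df)
    if d0 == 0:
        post = np.where(df > 0, s2, trend)
    return post, d0 + df


@dataclass
class QLFit:
    """A quasi-likelihood fit: genewise GLMs plus quasi-dispersion EB."""

    glm: GLMFit
    deviance_adj: np.ndarray
    df_adj: np.ndarray
    s2_raw: np.ndarray
    s2_trend: np.ndarray
    prior_df: float
    s2_post: np.ndarray
    df_post: np.ndarray
    abundance: np.ndarray
    dispersion: float

    @property
    def n_genes(self) -> int:
        return self.glm.n_genes

    @property
    def genes(self):
        return self.glm.genes

    def ql_plot_data(self):
        """Quarter-root raw and squeezed quasi-dispersions vs abundance."""
        import pandas as pd

        return pd.DataFrame(
            {
                "abundance": self.abundance,
                "raw": np.power(np.clip(self.s2_raw, 0, None), 0.25),
                "squeezed": np.power(np.clip(self.s2_post, 0, None), 0.25),
                "trend": np.power(np.clip(self.s2_trend, 0, None), 0.25),
            }
        )


def ql_fit(
    ds: CountDataset,
    design,
    dispersion: Optional[float] = None,
    top_proportion: float = 0.05,
    prior_count: float = 0.125,
) -> QLFit:
    """Fit the quasi-NB pipeline to a dataset.

    Unless supplied, the NB-dispersion is a single constant estimated by
    maximizing the summed adjusted profile likelihood over the
    ``top_proportion`` most abundant genes.  Genewise GLMs are then fitted,
    bias-adjusted deviances and fractional df computed, and the raw
    quasi-dispersions squeezed towards an abundance trend.
    """
    from .dispersion import common_dispersion_top  # local import, avoids cycle
    from .norm import ave_log_cpm

    abundance = ave_log_cpm(ds)
    if dispersion is None:
        n_top = int(np.ceil(top_proportion * ds.n_genes))
        if n_top < 10:
            warnings.warn(
                "fewer than 10 genes in the top-abundance set; using all genes"
            )
            top_idx = np.arange(ds.n_genes)
        else:
            top_idx = np.argsort(abundance, kind="stable")[::-1][:n_top]
        dispersion = common_dispersion_top(ds, design, top_idx)
    dispersion = float(dispersion)

    fit = glm_fit(ds, design, dispersion, prior_count=prior_count)
    fit.abundance = abundance
    D_adj, df_adj = adjusted_deviance_df(fit)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_raw = np.where(df_adj > 0, D_adj / np.where(df_adj > 0, df_adj, 1.0), np.nan)

    s2_trend, d0 = fit_f_dist(s2_raw, df_adj, abundance)
    s2_post, df_post = squeeze_quasi_dispersions(s2_raw, df_adj, s2_trend, d0)
    if np.isscalar(df_post) or np.ndim(df_post) == 0:
        df_post = np.full(ds.n_genes, float(df_post))
    else:
        df_post = np.asarray(df_post, dtype=float)
    if not np.isinf(d0):
        df_post = d0 + df_adj
    return QLFit(
        glm=fit,
        deviance_adj=D_adj,
        df_adj=df_adj,
        s2_raw=s2_raw,
        s2_trend=s2_trend,
        prior_df=d0,
        s2_post=s2_post,
        df_post=df_post,
        abundance=abundance,
        dispersion=dispersion,
    )
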