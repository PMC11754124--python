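"""Negative-binomial GLM core.

Implements the continuous generalization of the NB log-density (binomial
coefficients replaced by gamma functions, so fractional counts are handled
without rounding), the corresponding unit deviance with numerically stable
evaluation near ``y = mu`` and for small dispersions, one-group Fisher
scoring, and general-design fitting by Levenberg-damped Fisher scoring with
a one-way fast path.

Model: ``log mu_gi = x_i' beta_g + o_gi`` with offsets ``o_gi`` the natural
log effective library sizes, and quasi-NB variance
``sigma2_g / w_gi * (mu + phi_g mu^2)``.  The NB-dispersion ``phi`` enters
the fitting; the quasi-dispersion ``sigma2`` only rescales test statistics
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special

from .datamodel import (
    CompressedTable,
    CountDataset,
    DesignMatrix,
    _as_design,
    resolve_offsets,
)

__all__ = [
    "GLMFit",
    "nb_unit_deviance",
    "nb_log_density_continuous",
    "fit_one_group",
    "fit_levenberg",
    "add_prior_counts",
    "glm_fit",
]

# Linear predictor bound: fitted means confined to [1e-10, 1e10] x ELS.
_ETA_BOUND = 23.02585092994046


def _gfun(x, x0):
    """x*log(x/x0) - (x - x0), elementwise, stable for x near x0; x=0 -> x0."""
    x = np.asarray(x, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    x, x0 = np.broadcast_arrays(x, x0)
    eps = (x - x0) / x0
    out = np.empty_like(eps)
    near = np.abs(eps) < 0.05
    # series: x0 * sum_{k>=2} (-1)^k eps^k / (k (k-1))
    e = eps[near]
    acc = np.zeros_like(e)
    term = e * e
    for k in range(2, 15):
        acc += term / (k * (k - 1)) * (1.0 if k % 2 == 0 else -1.0)
        term = term * e
    out[near] = x0[near] * acc
    far = ~near
    xf, x0f = x[far], x0[far]
    with np.errstate(divide="ignore", invalid="ignore"):
        val = special.xlogy(xf, xf / x0f) - (xf - x0f)
    out[far] = val
    return out


def nb_unit_deviance(y, mu, phi):
    """Unit deviance of the (continuous) NB distribution.

    ``d = 2 [ y log(y/mu) - (y + 1/phi) log((1 + phi y)/(1 + phi mu)) ]``
    with the ``y = 0`` limit ``(2/phi) log(1 + phi mu)``; ``phi = 0`` gives
    the Poisson unit deviance ``2 [ y log(y/mu) - (y - mu) ]``.  Fractional
    ``y`` is allowed; evaluation is continuous in ``y`` and accurate
    (>= 10 significant digits) near ``y = mu`` and for ``phi -> 0``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative")
    y, mu, phi = np.broadcast_arrays(y, mu, phi)
    out = np.empty_like(np.asarray(y, dtype=float))

    delta = y - mu
    small = np.abs(delta) < 0.05 * mu  # both relative deviations < 5%

    pois = phi == 0.0
    # --- Poisson branch ---
    m = pois
    if m.any():
        out[m] = 2.0 * _gfun(y[m], mu[m])

    # --- NB, y near mu: direct series in delta, no cancellation ---
    m = (~pois) & small
    if m.any():
        d, mm, ph = delta[m], mu[m], phi[m]
        a = 1.0 / ph
        # bracket_k = mu^(1-k) - (mu+a)^(1-k), computed via expm1 for stability
        lr = np.log1p(a / mm)
        acc = np.zeros_like(d)
        dk = d * d  # delta^k
        for k in range(2, 15):
            bracket = mm ** (1.0 - k) * (-np.expm1((1.0 - k) * lr))
            acc += (1.0 if k % 2 == 0 else -1.0) * dk * bracket / (k * (k - 1))
            dk = dk * d
        out[m] = 2.0 * acc

    # --- NB, general: d = 2 [ g(y, mu) - g(y + a, mu + a) ] ---
    m = (~pois) & ~small
    if m.any():
        a = 1.0 / phi[m]
        out[m] = 2.0 * (_gfun(y[m], mu[m]) - _gfun(y[m] + a, mu[m] + a))
    return np.maximum(out, 0.0)


def nb_log_density_continuous(y, mu, phi):
    """Log-density of the continuous NB generalization.

    The binomial coefficient of the NB probability mass function is replaced
    by ``Gamma(y + 1/phi) / (Gamma(1/phi) Gamma(y + 1))``, giving a smooth
    function of ``y`` that coincides with the NB log-pmf at integers.
    ``phi = 0`` gives the Poisson form with the factorial generalized by the
    gamma function.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    y, mu, phi = np.broadcast_arrays(y, mu, phi)
    out = np.empty_like(np.asarray(y, dtype=float))
    pois = phi == 0.0
    if pois.any():
        out[pois] = (
            special.xlogy(y[pois], mu[pois]) - mu[pois] - special.gammaln(y[pois] + 1.0)
        )
    m = ~pois
    if m.any():
        a = 1.0 / phi[m]
        mm = mu[m]
        yy = y[m]
        out[m] = (
            special.gammaln(yy + a)
            - special.gammaln(a)
            - special.gammaln(yy + 1.0)
            - a * np.log1p(mm / a)
            + special.xlogy(yy, mm / (a + mm))
        )
    return out


@dataclass
class GLMFit:
    """A batch of genewise NB GLM fits."""

    coefficients: np.ndarray  # genes x p, natural log scale
    fitted: np.ndarray  # genes x samples
    deviance: np.ndarray  # per gene, weighted residual deviance
    phi: np.ndarray  # NB-dispersion used, per gene
    design: DesignMatrix
    offset: CompressedTable
    weights: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None
    iterations: Optional[np.ndarray] = None
    all_zero: Optional[np.ndarray] = None
    coefficients_shrunk: Optional[np.ndarray] = None  # prior-count shrunk
    abundance: Optional[np.ndarray] = None  # average log2-CPM
    counts: Optional[np.ndarray] = None
    genes: Optional[object] = None  # gene annotation DataFrame

    @property
    def n_genes(self) -> int:
        return self.fitted.shape[0]

    @property
    def n_samples(self) -> int:
        return self.fitted.shape[1]

    def weight_matrix(self) -> np.ndarray:
        if self.weights is None:
            return np.ones_like(self.fitted)
        return np.broadcast_to(self.weights, self.fitted.shape)

    def residual_deviances(self) -> np.ndarray:
        """Weighted per-observation unit deviances at the fit."""
        w = self.weight_matrix()
        d = np.zeros_like(self.fitted)
        pos = self.fitted > 0
        if pos.any():
            phi = np.broadcast_to(self.phi[:, None], self.fitted.shape)
            d[pos] = nb_unit_deviance(
                np.broadcast_to(self.counts, self.fitted.shape)[pos]
                if self.counts is not None
                else 0.0,
                self.fitted[pos],
                phi[pos],
            )
        return w * d


def _weighted_deviance(y, mu, phi, w):
    """Row sums of weighted unit deviances; observations with mu=0 need y=0."""
    d = np.zeros_like(y)
    pos = mu > 0
    if pos.any():
        phim = np.broadcast_to(phi[:, None], y.shape)
        d[pos] = nb_unit_deviance(y[pos], mu[pos], phim[pos])
    return (w * d).sum(axis=1)


def _expand_phi(phi, n_genes):
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        return np.full(n_genes, float(phi))
    if phi.shape != (n_genes,):
        raise ValueError("phi must be a scalar or one value per gene")
    return phi


def fit_one_group(y, offsets, phi, weights=None, tol=1e-10, maxit=50):
    """Fit intercept-only NB GLMs, one per gene, by Fisher scoring.

    Solves the score equation ``sum_i w_i (y_i - mu_i)/(1 + phi mu_i) = 0``
    with ``mu_i = exp(beta + o_i)``.  With equal offsets and unit weights the
    fitted mean equals the (weighted) arithmetic mean of ``y`` exactly.
    All-zero genes get ``beta = -inf`` with zero fitted values.

    Returns ``(beta, mu, converged, iterations)``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    G, n = y.shape
    phi = _expand_phi(phi, G)
    w = np.ones_like(y) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), y.shape
    )

    beta = np.full(G, -np.inf)
    mu = np.zeros_like(y)
    converged = np.ones(G, dtype=bool)
    iters = np.zeros(G, dtype=int)

    sw_y = (w * y).sum(axis=1)
    active = sw_y > 0
    if not active.any():
        return beta, mu, converged, iters

    b = np.log(sw_y[active]) - np.log((w[active] * np.exp(offsets[active])).sum(axis=1))
    ya, oa, wa, pa = y[active], offsets[active], w[active], phi[active]
    conv_a = np.zeros(b.shape, dtype=bool)
    it_a = np.zeros(b.shape, dtype=int)
    for _ in range(maxit):
        m = np.exp(np.clip(b[:, None], -_ETA_BOUND, _ETA_BOUND) + oa)
        denom = 1.0 + pa[:, None] * m
        score = (wa * (ya - m) / denom).sum(axis=1)
        info = (wa * m / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
        upd = ~conv_a
        b[upd] += step[upd]
        it_a[upd] += 1
        conv_a |= np.abs(step) < tol * (np.abs(b) + 1.0)
        if conv_a.all():
            break
    mu_a = np.exp(np.clip(b[:, None], -_ETA_BOUND, _ETA_BOUND) + oa)
    beta[active] = b
    mu[active] = mu_a
    converged[active] = conv_a
    iters[active] = it_a
    return beta, mu, converged, iters


def _oneway_structure(design: np.ndarray):
    """Detect a one-way layout: #distinct design rows equals #coefficients.

    Returns ``(group_codes, unique_rows)`` or None.
    """
    n, p = design.shape
    uniq, codes = np.unique(design, axis=0, return_inverse=True)
    if uniq.shape[0] != p:
        return None
    if np.linalg.matrix_rank(uniq) < p:
        return None
    return codes, uniq


def fit_levenberg(
    y,
    design,
    offsets,
    phi,
    weights=None,
    start=None,
    tol=1e-10,
    maxit=50,
):
    """Fit genewise NB GLMs for a general full-rank design.

    Damped Fisher scoring: the expected information ``X' W X`` (working
    weights ``w mu/(1 + phi mu)``) has a Levenberg term added to its
    diagonal; a step is accepted only if the deviance does not increase,
    otherwise the damping is multiplied by 10 and the step retried.  The
    deviance sequence is therefore non-increasing by construction.
    One-way layouts bypass the damped iteration entirely via groupwise
    Fisher scoring.

    Returns a :class:`GLMFit` (design/offset attached by the caller;
    here they are stored from the raw arrays).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    G, n = y.shape
    if isinstance(design, DesignMatrix):
        X = design.values
        dm = design
    else:
        dm = _as_design(design, n)
        X = dm.values
    p = X.shape[1]
    offsets_arr = np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    if not np.all(np.isfinite(offsets_arr)):
        raise ValueError("offsets must be finite")
    phi = _expand_phi(phi, G)
    w = np.ones_like(y) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), y.shape
    ).astype(float)

    all_zero = y.sum(axis=1) == 0

    oneway = _oneway_structure(X) if start is None else None
    if oneway is not None:
        codes, uniq = oneway
        eta_groups = np.empty((G, p))
        mu = np.zeros_like(y)
        converged = np.ones(G, dtype=bool)
        iters = np.zeros(G, dtype=int)
        for j in range(p):
            cols = codes == j
            bj, mj, cj, ij = fit_one_group(
                y[:, cols], offsets_arr[:, cols], phi, w[:, cols], tol=tol, maxit=maxit
            )
            eta_groups[:, j] = bj
            mu[:, cols] = mj
            converged &= cj
            iters = np.maximum(iters, ij)
        # map group log-means back to coefficients: uniq @ beta = eta_groups
        finite = np.isfinite(eta_groups).all(axis=1)
        beta = np.full((G, p), -np.inf)
        if finite.any():
            beta[finite] = np.linalg.solve(
                uniq[None, :, :].repeat(int(finite.sum()), axis=0),
                eta_groups[finite][:, :, None],
            )[:, :, 0]
        dev = _weighted_deviance(y, mu, phi, w)
        beta[all_zero] = -np.inf
        mu[all_zero] = 0.0
        fit = GLMFit(
            coefficients=beta,
            fitted=mu,
            deviance=dev,
            phi=phi,
            design=dm,
            offset=CompressedTable(offsets_arr, y.shape, "full"),
            weights=None if weights is None else w,
            converged=converged,
            iterations=iters,
            all_zero=all_zero,
            counts=y,
        )
        return fit

    # --- general design: batched Levenberg-damped Fisher scoring ---
    if start is None:
        # linear regression of log((y + 1/8)/ELS) on the design
        z = np.log((y + 0.125) / np.exp(offsets_arr))
        pinv = np.linalg.pinv(X)
        beta = z @ pinv.T
    else:
        beta = np.array(start, dtype=float).reshape(G, p).copy()

    def mu_of(b):
        eta = np.clip(b @ X.T, -_ETA_BOUND, _ETA_BOUND) + offsets_arr
        return np.exp(eta)

    mu = mu_of(beta)
    dev = _weighted_deviance(y, mu, phi, w)
    lam = np.full(G, 1e-6)
    converged = np.zeros(G, dtype=bool)
    converged[all_zero] = True
    iters = np.zeros(G, dtype=int)

    eye = np.eye(p)
    for _ in range(maxit):
        act = ~converged
        if not act.any():
            break
        ya, mua, wa = y[act], mu[act], w[act]
        pa = phi[act][:, None]
        denom = 1.0 + pa * mua
        score = ((wa * (ya - mua) / denom)) @ X  # (g, p)
        wwork = wa * mua / denom
        info = np.einsum("gn,ni,nj->gij", wwork, X, X, optimize=True)
        diag = np.einsum("gii->gi", info).copy()
        diag[diag < 1e-300] = 1e-300

        idx = np.flatnonzero(act)
        pending = np.ones(idx.size, dtype=bool)
        new_beta = beta[act].copy()
        new_mu = mua.copy()
        new_dev = dev[act].copy()
        lam_a = lam[act].copy()
        for _retry in range(40):
            if not pending.any():
                break
            A = info[pending] + (lam_a[pending, None] * diag[pending])[:, :, None] * eye
            try:
                delta = np.linalg.solve(A, score[pending][:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                A = A + 1e-8 * eye
                delta = np.linalg.solve(A, score[pending][:, :, None])[:, :, 0]
            b_try = beta[act][pending] + delta
            mu_try = np.exp(
                np.clip(b_try @ X.T, -_ETA_BOUND, _ETA_BOUND)
                + offsets_arr[act][pending]
            )
            d_try = _weighted_deviance(
                y[act][pending], mu_try, phi[act][pending], w[act][pending]
            )
            ok = d_try <= dev[act][pending] * (1 + 1e-12) + 1e-12
            sub = np.flatnonzero(pending)
            acc = sub[ok]
            new_beta[acc] = b_try[ok]
            new_mu[acc] = mu_try[ok]
            new_dev[acc] = d_try[ok]
            lam_a[acc] = np.maximum(lam_a[acc] / 10.0, 1e-10)
            rej = sub[~ok]
            lam_a[rej] *= 10.0
            pending[acc] = False
            pending[lam_a > 1e12] = False  # step failed; keep current iterate
        changed = np.abs(dev[act] - new_dev) <= tol * (new_dev + 1.0)
        beta[idx] = new_beta
        mu[idx] = new_mu
        conv_now = changed
        converged[idx] = conv_now
        dev[idx] = new_dev
        lam[idx] = lam_a
        iters[idx] += 1

    beta[all_zero] = -np.inf
    mu[all_zero] = 0.0
    dev[all_zero] = 0.0
    return GLMFit(
        coefficients=beta,
        fitted=mu,
        deviance=dev,
        phi=phi,
        design=dm,
        offset=CompressedTable(offsets_arr, y.shape, "full"),
        weights=None if weights is None else w,
        converged=converged,
        iterations=iters,
        all_zero=all_zero,
        counts=y,
    )


def add_prior_counts(ds: CountDataset, prior_count: float = 0.125):
    """Augment counts by library-size-proportional prior counts.

    Sample ``i`` receives ``prior_i = prior_count * ELS_i / mean(ELS)``;
    the offsets become ``log(ELS_i + 2 prior_i)``.  The augmented data are
    used only for re-fitting reported log-fold-changes (shrinking them
    towards zero); fitted values and tests use the unaugmented fit.

    Returns ``(augmented counts, adjusted offsets CompressedTable)``.
    """
    off = resolve_offsets(ds)
    if prior_count == 0:
        return ds.counts.copy(), off
    if off.kind in ("scalar", "per_sample"):
        els = np.exp(np.broadcast_to(off.payload, (ds.n_samples,)).astype(float))
        prior = prior_count * els / els.mean()
        aug = ds.counts + prior[None, :]
        new_off = CompressedTable(
            np.log(els + 2.0 * prior), (ds.n_genes, ds.n_samples), "per_sample"
        )
        return aug, new_off
    els = np.exp(off.expand())
    prior = prior_count * els / els.mean(axis=1, keepdims=True)
    aug = ds.counts + prior
    new_off = CompressedTable(np.log(els + 2.0 * prior), els.shape, "full")
    return aug, new_off


def glm_fit(
    ds: CountDataset,
    design,
    dispersion,
    prior_count: float = 0.125,
    tol: float = 1e-10,
    maxit: int = 50,
) -> GLMFit:
    """Fit genewise NB GLMs to a dataset at fixed NB-dispersion.

    Also re-fits the coefficients on prior-count-augmented data to obtain
    shrunk coefficients used for reported log-fold-changes.
    """
    from .norm import ave_log_cpm  # local import to avoid cycle

    dm = _as_design(design, ds.n_samples)
    off = resolve_offsets(ds)
    offsets = off.expand()
    w = None if ds.weights is None else ds.weights.expand()
    phi = _expand_phi(dispersion, ds.n_genes)
    fit = fit_levenberg(ds.counts, dm, offsets, phi, weights=w, tol=tol, maxit=maxit)
    fit.offset = off
    fit.genes = ds.genes
    fit.abundance = ave_log_cpm(ds)
    if prior_count > 0:
        aug, aug_off = add_prior_counts(ds, prior_count)
        sfit = fit_levenberg(
            aug, dm, aug_off.expand(), phi, weights=w, tol=tol, maxit=maxit
        )
        fit.coefficients_shrunk = sfit.coefficients
    else:
        fit.coefficients_shrunk = fit.coefficients
    return fit
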