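"""Effective-library-size normalization, expression filtering and transforms.

TMM (trimmed mean of M-values) estimates a scaling factor for each sample
relative to a reference sample by doubly trimming genewise log-ratios (M)
and average abundances (A) and taking a precision-weighted mean of the
surviving M values.  TMMwsp (TMM with singleton pairing) rescues genes with
a positive count in only one of the two libraries by pairing them across
libraries, which stabilizes the factors for sparse data.

The resulting factors multiply the raw library sizes to give effective
library sizes (ELS); log ELS values become GLM offsets downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datamodel import CompressedTable, CountDataset, resolve_offsets
from . import glm as _glm

__all__ = [
    "NormFactors",
    "tmm_pair",
    "tmmwsp_pair",
    "norm_lib_sizes",
    "filter_by_expr",
    "cpm_log2",
    "ave_log_cpm",
    "scale_offset",
]


@dataclass
class NormFactors:
    factors: np.ndarray
    method: str

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f) & (f > 0)):
            raise ValueError("normalization factors must be positive and finite")
        self.factors = f

    def __iter__(self):
        return iter(self.factors)


def _trim_keep(values, trim_fraction):
    """Nearest-rank double-tail trim mask; ties on the boundary are kept."""
    n = values.size
    lo = np.floor(n * trim_fraction) + 1
    hi = n + 1 - lo
    r = rankdata(values, method="average")
    return (r >= lo) & (r <= hi)


def tmm_pair(
    obs,
    ref,
    obs_libsize,
    ref_libsize,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM log2 scaling factor of one library against a reference library.

    Genes with a zero count in either library are discarded.  The remaining
    genewise statistics are ``M = log2((y/N)/(y_r/N_r))`` and
    ``A = 0.5 log2((y/N)(y_r/N_r))``; the most extreme ``logratio_trim``
    fraction of M and ``abundance_trim`` fraction of A are dropped from each
    tail, and the result is the precision-weighted mean of the surviving M
    values (weights are inverse approximate binomial variances).
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("count vectors must have the same length")
    if obs_libsize <= 0 or ref_libsize <= 0:
        raise ValueError("library sizes must be positive")

    pos = (obs > 0) & (ref > 0)
    y, yr = obs[pos], ref[pos]
    return _tmm_core(
        y, yr, obs_libsize, ref_libsize, logratio_trim, abundance_trim, weighted
    )


def _tmm_core(y, yr, N, Nr, logratio_trim, abundance_trim, weighted):
    p = y / N
    pr = yr / Nr
    M = np.log2(p / pr)
    A = 0.5 * np.log2(p * pr)
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, y, yr = M[fin], A[fin], y[fin], yr[fin]
    if M.size < 1:
        warnings.warn("no genes survive TMM trimming; returning log2 factor 0")
        return 0.0
    # degenerate case: essentially identical relative expression everywhere
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    keep = _trim_keep(M, logratio_trim) & _trim_keep(A, abundance_trim)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; returning log2 factor 0")
        return 0.0
    if weighted:
        w = 1.0 / ((N - y[keep]) / (N * y[keep]) + (Nr - yr[keep]) / (Nr * yr[keep]))
        f = float(np.sum(w * M[keep]) / np.sum(w))
    else:
        f = float(np.mean(M[keep]))
    if not np.isfinite(f):
        f = 0.0
    if abs(f) < 1e-10:
        f = 0.0
    return f


def tmmwsp_pair(obs, ref, obs_libsize, ref_libsize, **kwargs) -> float:
    """TMM with singleton pairing: log2 factor for sparse libraries.

    Genes positive in both libraries are handled as in TMM.  Singleton genes
    (positive in exactly one library) are sorted by decreasing count within
    each side and paired largest-with-largest across sides to form synthetic
    shared genes; unpaired leftovers are discarded.  Ties in the sort are
    broken by gene index (stable sort), for determinism.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("count vectors must have the same length")
    both = (obs > 0) & (ref > 0)
    only_obs = (obs > 0) & (ref == 0)
    only_ref = (ref > 0) & (obs == 0)

    y_list = [obs[both]]
    yr_list = [ref[both]]
    s_obs = np.sort(obs[only_obs], kind="stable")[::-1]
    s_ref = np.sort(ref[only_ref], kind="stable")[::-1]
    npair = min(s_obs.size, s_ref.size)
    if npair > 0:
        y_list.append(s_obs[:npair])
        yr_list.append(s_ref[:npair])
    y = np.concatenate(y_list)
    yr = np.concatenate(yr_list)
    if y.size == 0:
        warnings.warn("no usable genes for TMMwsp; returning log2 factor 0")
        return 0.0
    return _tmm_core(
        y,
        yr,
        obs_libsize,
        ref_libsize,
        kwargs.get("logratio_trim", 0.3),
        kwargs.get("abundance_trim", 0.05),
        kwargs.get("weighted", True),
    )


def norm_lib_sizes(ds: CountDataset, method: str = "TMM") -> NormFactors:
    """Estimate per-sample normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile normalized count is
    closest to the mean upper quartile (ties broken by lowest sample index).
    """
    method_l = method.lower()
    n = ds.n_samples
    if method_l == "none":
        return NormFactors(np.ones(n), "none")
    if method_l not in ("tmm", "tmmwsp"):
        raise ValueError(f"unknown normalization method {method!r}")
    if n < 2:
        raise ValueError("TMM methods require at least 2 samples")
    counts = ds.counts
    lib = ds.lib_size
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(counts.sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    pair = tmm_pair if method_l == "tmm" else tmmwsp_pair
    logf = np.array(
        [pair(counts[:, i], counts[:, ref], lib[i], lib[ref]) for i in range(n)]
    )
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(factors, method_l)


def filter_by_expr(
    ds: CountDataset,
    design=None,
    group=None,
    min_count: float = 10,
    min_total_count: float = 15,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> np.ndarray:
    """Keep genes with enough counts to support differential testing.

    A gene is kept if it reaches CPM >= ``min_count / median(ELS) * 1e6`` in
    at least as many samples as the smallest group, and if its total count
    is at least ``min_total_count``.  For very large groups the required
    sample count grows only by ``min_prop`` per extra sample beyond
    ``large_n``.  Comparisons carry a 1e-14 tolerance to guard float noise
    at exact boundaries.
    """
    if group is not None:
        _, counts_per_group = np.unique(np.asarray(group), return_counts=True)
        k = counts_per_group.min()
    elif design is not None:
        X = design.values if hasattr(design, "values") else np.atleast_2d(
            np.asarray(design, dtype=float)
        )
        if X.shape[0] != ds.n_samples and X.shape[1] == ds.n_samples:
            X = X.T
        # smallest positive replication count of a one-way expansion
        _, inverse, counts_per = np.unique(
            X, axis=0, return_inverse=True, return_counts=True
        )
        k = counts_per.min()
    else:
        k = ds.n_samples
    k = float(k)
    if k == 1 and (group is not None):
        warnings.warn("all groups are singletons; filtering with k = 1")
    if k > large_n:
        k = large_n + (k - large_n) * min_prop

    els = ds.effective_lib_size
    cutoff = min_count / np.median(els) * 1e6
    cpm = ds.counts / els[None, :] * 1e6
    tol = 1e-14
    keep_cpm = (cpm >= cutoff).sum(axis=1) >= k - tol
    keep_total = ds.counts.sum(axis=1) >= min_total_count - tol
    return keep_cpm & keep_total


def _prior_adjusted(ds: CountDataset, prior_count: float):
    els = ds.effective_lib_size
    prior = prior_count * els / els.mean() if prior_count > 0 else np.zeros_like(els)
    return els, prior


def cpm_log2(ds: CountDataset, prior_count: float = 2.0) -> np.ndarray:
    """log2 counts-per-million with library-size-proportional prior counts."""
    els, prior = _prior_adjusted(ds, prior_count)
    return np.log2((ds.counts + prior[None, :]) / (els + 2.0 * prior)[None, :] * 1e6)


def ave_log_cpm(
    ds: CountDataset, prior_count: float = 2.0, dispersion: float = 0.05
) -> np.ndarray:
    """Average abundance of each gene as log2 CPM.

    Computed from a per-gene intercept-only NB fit on prior-augmented counts
    with correspondingly adjusted offsets, so unequal library sizes are
    handled by the model rather than by averaging ratios.  With equal ELS
    this equals ``log2((ybar + prior)/(N + 2 prior) * 1e6)`` exactly.
    """
    els, prior = _prior_adjusted(ds, prior_count)
    aug = ds.counts + prior[None, :]
    offs = np.log(els + 2.0 * prior)
    w = None if ds.weights is None else ds.weights.expand()
    beta, _, _, _ = _glm.fit_one_group(
        aug, np.broadcast_to(offs, aug.shape), dispersion, weights=w
    )
    return (beta + np.log(1e6)) / np.log(2.0)


def scale_offset(ds: CountDataset, offset) -> CompressedTable:
    """Recenter an external offset table onto the library-size scale.

    A single additive constant shifts the offsets so that their mean equals
    the mean log library size; differences between offsets (the
    normalization content) are preserved exactly.
    """
    if isinstance(offset, CompressedTable):
        tab = offset
    else:
        arr = np.asarray(offset, dtype=float)
        if arr.ndim == 1:
            tab = CompressedTable(arr, (ds.n_genes, ds.n_samples), "per_sample")
        else:
            tab = CompressedTable(arr, (ds.n_genes, ds.n_samples))
    if not np.all(np.isfinite(np.asarray(tab.payload))):
        raise ValueError("external offsets must be finite")
    shift = np.mean(np.log(ds.lib_size)) - float(np.mean(tab.expand()))
    return CompressedTable(tab.payload + shift, tab.shape, tab.kind)
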