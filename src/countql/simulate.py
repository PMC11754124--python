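"""Synthetic count generators with known truth.

Counts are generated from the quadratic mean-variance model
``var(y) = sigma2 mu + psi mu^2`` by explicit gamma-mixed quasi-Poisson
sampling: a gamma draw with squared coefficient of variation ``psi``
perturbs the gene's true abundance, and the technical layer is a scaled
Poisson draw with variance inflation ``sigma2`` (a Poisson count multiplied
by ``sigma2`` on rate ``lambda/sigma2``, which yields fractional counts
when ``sigma2 != 1``).  With ``sigma2 = 1`` the counts are exactly NB with
``phi = psi``; with ``phi = 0`` and ``sigma2 = 1`` they are Poisson.

Every generator returns the truth needed for parameter-recovery tests and
is bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import CountDataset, DesignMatrix, make_dataset

__all__ = [
    "SimTruth",
    "simulate_nb",
    "simulate_fig_poisson",
    "simulate_splice",
    "simulate_meth",
    "simulate_resamples",
]


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    phi: np.ndarray  # true NB-dispersion per gene
    sigma2: np.ndarray  # true quasi-dispersion per gene
    logfc: np.ndarray  # true log2 fold changes per gene (contrast scale)
    is_de: np.ndarray  # DE indicator per gene
    composition: np.ndarray  # per-sample composition factors
    seed: int
    mean: Optional[np.ndarray] = None  # expected counts, genes x samples


def _draw_counts(rng, mean, phi, sigma2):
    """Gamma-mixed quasi-Poisson draws matching var = s2*mu + psi*mu^2."""
    psi = phi * sigma2
    lam = np.array(mean, dtype=float)
    mix = psi > 0
    if np.any(mix):
        shape = np.empty_like(psi)
        shape[mix] = 1.0 / psi[mix]
        g = np.ones_like(lam)
        g[mix] = rng.gamma(shape[mix, None], 1.0, size=lam[mix].shape) * psi[mix, None]
        lam = lam * g
    s2 = np.broadcast_to(sigma2[:, None], lam.shape)
    counts = s2 * rng.poisson(lam / s2)
    return counts.astype(float)


def simulate_nb(
    n_genes: int,
    n_samples: int,
    design=None,
    group: Optional[Sequence] = None,
    baseline_logcpm: Union[Callable, tuple] = (-2.0, 10.0),
    bcv_trend: Union[float, Callable] = 0.1,
    sigma2: Union[float, np.ndarray] = 1.0,
    lib_sizes: Union[float, Sequence[float]] = 1e6,
    de_fraction: float = 0.0,
    logfc_sd: float = 1.0,
    logfc_values: Optional[np.ndarray] = None,
    seed: int = 0,
):
    """Simulate a two-condition (or arbitrary-design) NB dataset.

    ``baseline_logcpm`` is either a (lo, hi) log2-CPM uniform range or a
    callable ``rng, n -> values``; ``bcv_trend`` is a constant BCV or a
    callable of abundance (log2 CPM) returning BCV.  A ``de_fraction`` of
    genes receive a nonzero log2 fold change on the last design coefficient
    (drawn N(0, logfc_sd) unless ``logfc_values`` supplies them).

    Returns ``(CountDataset, SimTruth)``.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        if group is None:
            group = ["A"] * n_samples
        dm = DesignMatrix.from_group(group)
    else:
        dm = design if isinstance(design, DesignMatrix) else DesignMatrix(
            np.atleast_2d(np.asarray(design, float)),
            [f"coef{j+1}" for j in range(np.atleast_2d(np.asarray(design)).shape[1])],
        )
    X = dm.values
    p = X.shape[1]

    if callable(baseline_logcpm):
        base = np.asarray(baseline_logcpm(rng, n_genes), dtype=float)
    else:
        lo, hi = baseline_logcpm
        base = rng.uniform(lo, hi, size=n_genes)

    if callable(bcv_trend):
        bcv = np.asarray(bcv_trend(base), dtype=float)
    else:
        bcv = np.full(n_genes, float(bcv_trend))
    phi = bcv**2
    s2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (n_genes,)).astype(float)

    is_de = np.zeros(n_genes, dtype=bool)
    logfc = np.zeros(n_genes)
    if de_fraction > 0 and p > 1:
        n_de = int(round(de_fraction * n_genes))
        idx = rng.choice(n_genes, size=n_de, replace=False)
        is_de[idx] = True
        if logfc_values is not None:
            logfc[idx] = np.resize(np.asarray(logfc_values, float), n_de)
        else:
            logfc[idx] = rng.normal(0.0, logfc_sd, size=n_de)

    lib = np.broadcast_to(np.asarray(lib_sizes, dtype=float), (n_samples,)).astype(float)
    # beta on the log2-CPM scale; for a one-way group-means design every
    # coefficient is its group's log2-CPM, otherwise the first column acts
    # as the intercept.  The last coefficient carries the DE logFC.
    beta2 = np.zeros((n_genes, p))
    is_indicator = np.all((X == 0) | (X == 1)) and np.all(X.sum(axis=1) == 1)
    if is_indicator:
        beta2[:, :] = base[:, None]
    else:
        beta2[:, 0] = base
    beta2[:, -1] += logfc
    log2cpm = beta2 @ X.T
    mean = 2.0**log2cpm / 1e6 * lib[None, :]

    counts = _draw_counts(rng, mean, phi, s2)
    ds = make_dataset(
        counts,
        group=group if group is not None else None,
        lib_size=lib,
    )
    truth = SimTruth(
        phi=phi,
        sigma2=s2,
        logfc=logfc,
        is_de=is_de,
        composition=np.ones(n_samples),
        seed=seed,
        mean=mean,
    )
    return ds, truth


def simulate_fig_poisson(
    n_samples: int = 100,
    n_genes: int = 10_000,
    mean_range: tuple = (2.0**-5, 2.0**7),
    seed: int = 0,
):
    """Pure-Poisson benchmark: gene means log-uniform over ``mean_range``,
    constant across samples, quasi-dispersion 1 and NB-dispersion 0.

    This is the canonical design for checking that bias-adjusted mean
    deviances estimate the quasi-dispersion without bias at every count
    size.  Returns ``(CountDataset, SimTruth)``.
    """
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_genes))
    counts = rng.poisson(lam[:, None], size=(n_genes, n_samples)).astype(float)
    # equal nominal library sizes: the fits see flat offsets
    ds = make_dataset(counts, lib_size=np.full(n_samples, lam.sum()))
    truth = SimTruth(
        phi=np.zeros(n_genes),
        sigma2=np.ones(n_genes),
        logfc=np.zeros(n_genes),
        is_de=np.zeros(n_genes, dtype=bool),
        composition=np.ones(n_samples),
        seed=seed,
        mean=np.broadcast_to(lam[:, None], counts.shape).copy(),
    )
    return ds, truth


def simulate_splice(
    n_genes: int = 200,
    exons_per_gene: int = 5,
    n_per_group: int = 3,
    gene_logfc: float = 0.0,
    switched_exons: int = 0,
    switch_logfc: float = 2.0,
    baseline_logcpm: tuple = (3.0, 8.0),
    bcv: float = 0.1,
    lib_size: float = 1e6,
    seed: int = 0,
):
    """Exon-level two-group dataset with optional usage switches.

    Every exon of a gene shares the gene's log2 fold change; in genes with
    ``switched_exons > 0``, that many exons (the first ones) get an extra
    ``switch_logfc`` in group B.  Returns ``(CountDataset, SimTruth)`` where
    the dataset's gene annotation carries the exon-to-gene map in
    ``gene_id``.
    """
    rng = np.random.default_rng(seed)
    E = n_genes * exons_per_gene
    gene_ids = np.repeat([f"g{i+1}" for i in range(n_genes)], exons_per_gene)
    base = rng.uniform(*baseline_logcpm, size=E)
    logfc = np.full(E, float(gene_logfc))
    switched = np.zeros(E, dtype=bool)
    if switched_exons > 0:
        within = np.tile(np.arange(exons_per_gene), n_genes)
        switched = within < switched_exons
        logfc = logfc + switched * switch_logfc
    group = ["A"] * n_per_group + ["B"] * n_per_group
    n = len(group)
    grpB = np.array([g == "B" for g in group], dtype=float)
    log2cpm = base[:, None] + logfc[:, None] * grpB[None, :]
    mean = 2.0**log2cpm / 1e6 * lib_size
    phi = np.full(E, bcv**2)
    counts = _draw_counts(rng, mean, phi, np.ones(E))
    ds = make_dataset(
        counts,
        group=group,
        lib_size=np.full(n, lib_size),
        genes=pd.DataFrame({"id": [f"e{k+1}" for k in range(E)], "gene_id": gene_ids}),
    )
    truth = SimTruth(
        phi=phi,
        sigma2=np.ones(E),
        logfc=logfc,
        is_de=switched,
        composition=np.ones(n),
        seed=seed,
        mean=mean,
    )
    return ds, truth


def simulate_meth(
    n_loci: int = 300,
    n_per_group: int = 3,
    coverage: float = 50.0,
    base_logit: float = 0.0,
    group_logratio: float = 1.0,
    de_fraction: float = 0.2,
    bcv: float = 0.1,
    seed: int = 0,
):
    """Paired methylated/unmethylated counts with known group log-ratios.

    Each locus in each sample gets total coverage ~ Poisson(coverage)
    split between Me and Un according to a logit that shifts by
    ``group_logratio`` (natural log) in group B at differential loci.
    Columns are ordered sample1-Me, sample1-Un, ...
    Returns ``(CountDataset, SimTruth)``.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groupB = np.repeat([0.0, 1.0], n_per_group)
    is_de = rng.random(n_loci) < de_fraction
    delta = np.where(is_de, group_logratio, 0.0)
    logit = base_logit + delta[:, None] * groupB[None, :]
    pme = 1.0 / (1.0 + np.exp(-logit))
    bio = rng.gamma(1.0 / bcv**2, bcv**2, size=(n_loci, n))
    total = rng.poisson(coverage * bio)
    me = rng.binomial(total, pme)
    un = total - me
    counts = np.empty((n_loci, 2 * n))
    counts[:, 0::2] = me
    counts[:, 1::2] = un
    names = []
    for i in range(n):
        g = "A" if groupB[i] == 0 else "B"
        names.append(f"{g}{i+1}-Me")
        names.append(f"{g}{i+1}-Un")
    lib = np.repeat(counts[:, 0::2].sum(axis=0) + counts[:, 1::2].sum(axis=0), 2)
    ds = make_dataset(
        pd.DataFrame(counts, columns=names),
        lib_size=np.maximum(lib, 1.0),
    )
    truth = SimTruth(
        phi=np.full(n_loci, bcv**2),
        sigma2=np.ones(n_loci),
        logfc=delta / np.log(2.0),
        is_de=is_de,
        composition=np.ones(2 * n),
        seed=seed,
    )
    return ds, truth


def simulate_resamples(
    n_transcripts: int = 200,
    n_samples: int = 4,
    n_resamples: int = 100,
    mean_range: tuple = (5.0, 500.0),
    inflation: Union[float, np.ndarray] = 1.0,
    seed: int = 0,
):
    """Per-sample technical resample matrices with known variance inflation.

    Resample counts are drawn with variance ``inflation * mean`` (a scaled
    Poisson), emulating bootstrap/Gibbs draws from a transcript quantifier
    under read-to-transcript ambiguity.  Returns
    ``(point-estimate CountDataset, list of transcripts x R matrices,
    true inflation per transcript)``.
    """
    rng = np.random.default_rng(seed)
    infl = np.broadcast_to(np.asarray(inflation, dtype=float), (n_transcripts,)).astype(float)
    mean = np.exp(
        rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=(n_transcripts, n_samples))
    )
    resamples = []
    for s in range(n_samples):
        lam = mean[:, s][:, None] / infl[:, None]
        draws = infl[:, None] * rng.poisson(lam, size=(n_transcripts, n_resamples))
        resamples.append(draws.astype(float))
    counts = np.column_stack([r.mean(axis=1) for r in resamples])
    ds = make_dataset(np.maximum(counts, 0.0))
    return ds, resamples, infl
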