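"""Applied analyses built on the quasi-NB engine.

Differential exon usage (exon-vs-gene log-fold-change comparison with
Simes and F-style gene summaries), methylation design expansion, read-to-
transcript-ambiguity overdispersion from quantifier resamples and the
resulting divided counts, pseudo-bulk aggregation of single-cell counts,
the NB-to-normal mid-p z-score bridge, and MDS/plot data extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import CountDataset, DesignMatrix, make_dataset
from .inference import _contrast_matrix, _null_space_basis, bh_adjust
from .quasi import QLFit, ql_fit

__all__ = [
    "SpliceResult",
    "RTAEstimate",
    "diff_splice",
    "model_matrix_meth",
    "estimate_rta_overdispersion",
    "divide_counts",
    "pseudo_bulk",
    "zscore_nbinom",
    "mds_leading_logfc",
    "md_plot_data",
]

_LOG2 = np.log(2.0)


@dataclass
class SpliceResult:
    """Exon-level and gene-level differential-usage results."""

    exon_table: pd.DataFrame
    gene_table: pd.DataFrame
    n_single_exon_dropped: int


def _simes(p: np.ndarray) -> float:
    p = np.sort(p[np.isfinite(p)])
    m = p.size
    if m == 0:
        return np.nan
    return float(np.min(p * m / np.arange(1, m + 1)))


def diff_splice(
    ds: CountDataset,
    design,
    contrast=None,
    coef=None,
    gene_key: str = "gene_id",
    dispersion: Optional[float] = None,
) -> SpliceResult:
    """Differential exon usage: compare each exon's log-fold-change to the
    fold change of its parent gene.

    A quasi-NB fit on the exon counts gives per-exon contrast coefficients
    ``beta_e`` with precisions ``w_e = 1/SE_e^2``; the gene value is the
    precision-weighted mean, and the exon statistic is
    ``t_e = (beta_e - betabar_g)/SE_e * sqrt(m/(m-1))`` on the posterior-df
    t distribution.  Gene-level p-values come from (a) the mean of ``t_e^2``
    on an (m-1, posterior df) F reference and (b) Simes' combination of the
    exon p-values, which is more sensitive when only a minority of exons
    change.  Single-exon genes are dropped (count reported).
    """
    if gene_key not in ds.genes.columns:
        raise ValueError(f"gene annotation lacks a {gene_key!r} column")
    qfit = ql_fit(ds, design, dispersion=dispersion)
    fit = qfit.glm
    C = _contrast_matrix(fit.design.n_coef, contrast, coef)
    if C.shape[1] != 1:
        raise ValueError("differential exon usage requires a single contrast")
    c = C[:, 0]

    beta = np.where(np.isfinite(fit.coefficients), fit.coefficients, 0.0)
    b = beta @ c  # natural-log contrast per exon
    # observed-information variance of the contrast, scaled by posterior s2
    X = fit.design.values
    phim = fit.phi[:, None]
    wwork = fit.weight_matrix() * fit.fitted / (1.0 + phim * fit.fitted)
    info = np.einsum("gn,ni,nj->gij", wwork, X, X, optimize=True)
    try:
        cov_c = np.einsum(
            "i,gij,j->g", c, np.linalg.inv(info + 1e-12 * np.eye(X.shape[1])), c
        )
    except np.linalg.LinAlgError:
        cov_c = np.full(fit.n_genes, np.nan)
    se2 = cov_c * np.clip(qfit.s2_post, 1e-300, None)
    se = np.sqrt(np.clip(se2, 1e-300, None))

    genes = ds.genes[gene_key].to_numpy()
    df_post = qfit.df_post

    grp = pd.DataFrame(
        {
            "gene": genes,
            "b": b,
            "w": 1.0 / se2,
            "se": se,
            "df": df_post,
            "exon": np.arange(ds.n_genes),
        }
    )
    sizes = grp.groupby("gene")["b"].transform("size").to_numpy()
    multi = sizes >= 2
    n_dropped = int((~multi).sum())
    grp = grp[multi]

    wsum = grp.groupby("gene")["w"].transform("sum")
    bw = grp["b"] * grp["w"]
    bbar = grp.assign(bw=bw).groupby("gene")["bw"].transform("sum") / wsum
    m = grp.groupby("gene")["b"].transform("size").to_numpy()
    t = ((grp["b"] - bbar) / grp["se"]).to_numpy() * np.sqrt(m / (m - 1.0))
    p_exon = 2.0 * stats.t.sf(np.abs(t), grp["df"].to_numpy())

    exon_table = pd.DataFrame(
        {
            "exon_id": ds.genes["id"].to_numpy()[grp["exon"].to_numpy()],
            "gene_id": grp["gene"].to_numpy(),
            "logFC": grp["b"].to_numpy() / _LOG2,
            "rel_logFC": (grp["b"] - bbar).to_numpy() / _LOG2,
            "statistic": t,
            "PValue": p_exon,
            "weight": grp["w"].to_numpy(),
        }
    )
    exon_table["FDR"] = bh_adjust(p_exon)

    rows = []
    for gene, sub in exon_table.groupby("gene_id", sort=False):
        tg = sub["statistic"].to_numpy()
        mg = tg.size
        dfg = float(np.mean(grp.loc[grp["gene"] == gene, "df"]))
        Fg = float(np.mean(tg**2))
        if np.isinf(dfg):
            p_F = float(stats.chi2.sf(Fg * (mg - 1), mg - 1))
        else:
            p_F = float(stats.f.sf(Fg, mg - 1, dfg))
        rows.append(
            {
                "gene_id": gene,
                "n_exons": mg,
                "F": Fg,
                "PValue.F": p_F,
                "PValue.Simes": _simes(sub["PValue"].to_numpy()),
            }
        )
    gene_table = pd.DataFrame(rows)
    gene_table["FDR.F"] = bh_adjust(gene_table["PValue.F"].to_numpy())
    gene_table["FDR.Simes"] = bh_adjust(gene_table["PValue.Simes"].to_numpy())
    return SpliceResult(exon_table, gene_table, n_dropped)


def model_matrix_meth(design) -> DesignMatrix:
    """Expand a sample-level design for paired methylated/unmethylated counts.

    For ``n`` samples and a full-rank ``n x p`` design ``X``, the output has
    ``2n`` rows ordered sample1-Me, sample1-Un, sample2-Me, ... and
    ``n + p`` columns: per-sample indicators absorbing read coverage,
    followed by ``X``'s row on methylated rows (0 on unmethylated rows)
    representing group-specific log-ratios of methylated to unmethylated
    reads.
    """
    if isinstance(design, DesignMatrix):
        X = design.values
        names = list(design.names)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        names = [f"coef{j + 1}" for j in range(X.shape[1])]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("sample design matrix is rank-deficient")
    out = np.zeros((2 * n, n + p))
    for i in range(n):
        out[2 * i, i] = 1.0
        out[2 * i + 1, i] = 1.0
        out[2 * i, n:] = X[i]
    cols = [f"sample{i + 1}" for i in range(n)] + [f"Me:{nm}" for nm in names]
    return DesignMatrix(out, cols)


@dataclass
class RTAEstimate:
    """Read-to-transcript-ambiguity overdispersions from technical resamples."""

    overdispersion: np.ndarray  # per transcript, >= 1
    n_samples: int
    resamples_per_sample: Sequence[int]
    df_pooled: float


def estimate_rta_overdispersion(resamples: Sequence[np.ndarray], prior_df: float = 3.0) -> RTAEstimate:
    """Estimate per-transcript overdispersion from bootstrap/Gibbs resamples.

    Each element of ``resamples`` is a transcripts x R_s matrix of resampled
    counts for one sample (R_s >= 2).  The pooled quasi-Poisson statistic
    ``sum_s sum_r (y_tsr - ybar_ts)^2 / ybar_ts`` over samples with positive
    mean, divided by the pooled df ``sum_s (R_s - 1)``, is moderated towards
    1 with ``prior_df`` pseudo-df and floored at 1.
    """
    mats = [np.atleast_2d(np.asarray(r, dtype=float)) for r in resamples]
    T = mats[0].shape[0]
    for m in mats:
        if m.shape[0] != T:
            raise ValueError("all resample tables must cover the same transcripts")
        if m.shape[1] < 2:
            raise ValueError("each sample needs at least 2 resamples")
    num = np.zeros(T)
    df = 0.0
    for m in mats:
        R = m.shape[1]
        mean = m.mean(axis=1)
        pos = mean > 0
        ss = np.zeros(T)
        ss[pos] = ((m[pos] - mean[pos, None]) ** 2).sum(axis=1) / mean[pos]
        num += ss
        df += R - 1
    stat = num / df
    od = (df * stat + prior_df * 1.0) / (df + prior_df)
    od = np.maximum(od, 1.0)
    return RTAEstimate(
        overdispersion=od,
        n_samples=len(mats),
        resamples_per_sample=[m.shape[1] for m in mats],
        df_pooled=df,
    )


def divide_counts(ds: CountDataset, overdispersion) -> CountDataset:
    """Divide transcript counts by their ambiguity overdispersions.

    The divided counts are fractional and follow the ordinary NB
    mean-variance relationship; library sizes are recomputed from the
    divided counts (equivalently, rescaled by the count-weighted mean
    overdispersion) so they reflect the true precision of each sample.
    """
    od = np.asarray(overdispersion, dtype=float)
    if od.shape != (ds.n_genes,):
        raise ValueError("need one overdispersion per transcript")
    if np.any(od < 1):
        raise ValueError("overdispersions must be >= 1")
    divided = ds.counts / od[:, None]
    samples = ds.samples.drop(columns=["lib_size", "norm_factor"], errors="ignore")
    return make_dataset(divided, samples=samples, genes=ds.genes)


def pseudo_bulk(ds: CountDataset, sample_labels, cluster_labels) -> CountDataset:
    """Sum single-cell counts into one column per (sample, cluster) pair.

    Column sums are conserved exactly; pairs with no cells are absent.
    Cell counts per pseudo-bulk column are recorded in the sample table.
    """
    sample_labels = np.asarray(sample_labels)
    cluster_labels = np.asarray(cluster_labels)
    if sample_labels.size != ds.n_samples or cluster_labels.size != ds.n_samples:
        raise ValueError("labels must align with cells (dataset columns)")
    keys = pd.DataFrame({"sample": sample_labels, "cluster": cluster_labels})
    groups = keys.groupby(["sample", "cluster"], sort=True).indices
    cols = []
    recs = []
    for (samp, clus), idx in groups.items():
        cols.append(ds.counts[:, idx].sum(axis=1))
        recs.append(
            {"name": f"{samp}|{clus}", "sample": samp, "cluster": clus, "n_cells": len(idx)}
        )
    counts = np.column_stack(cols)
    samples = pd.DataFrame(recs).set_index("name")
    return make_dataset(counts, samples=samples, genes=ds.genes)


def _log_mid_p(y_int, mu, phi, upper: bool):
    """log mid-p tail probability at integer y under NB(mu, phi)."""
    pois = phi == 0
    a = np.where(pois, 1.0, 1.0 / np.where(pois, 1.0, phi))
    pr = a / (a + mu)
    if upper:
        lcdf_excl = np.where(
            pois,
            stats.poisson.logsf(y_int, mu),
            stats.nbinom.logsf(y_int, a, pr),
        )
    else:
        lcdf_excl = np.where(
            pois,
            stats.poisson.logcdf(y_int - 1, mu),
            stats.nbinom.logcdf(y_int - 1, a, pr),
        )
        lcdf_excl = np.where(y_int < 1, -np.inf, lcdf_excl)
    lpmf = np.where(
        pois,
        stats.poisson.logpmf(y_int, mu),
        stats.nbinom.logpmf(y_int, a, pr),
    )
    return np.logaddexp(lcdf_excl, lpmf + np.log(0.5))


def zscore_nbinom(y, mu, phi):
    """Normal deviates equivalent to NB counts via mid-p tail probabilities.

    For integer ``y`` the mid-p probability ``P(Y < y) + 0.5 P(Y = y)`` is
    converted to a standard-normal quantile, working in the smaller tail in
    log space so very extreme quantiles remain finite.  Non-integer values
    interpolate the two neighbouring integers' mid-p values linearly.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    y, mu, phi = np.broadcast_arrays(y, mu, phi)
    shape = y.shape
    y, mu, phi = y.ravel(), mu.ravel(), phi.ravel()

    lo = np.floor(y)
    frac = y - lo

    def _z_from(y_int):
        llow = _log_mid_p(y_int, mu, phi, upper=False)
        lupp = _log_mid_p(y_int, mu, phi, upper=True)
        use_low = llow <= lupp
        z = np.empty(y_int.shape)
        z[use_low] = special.ndtri_exp(llow[use_low])
        z[~use_low] = -special.ndtri_exp(lupp[~use_low])
        return z, llow, lupp

    z0, llow0, lupp0 = _z_from(lo)
    isint = frac == 0
    if isint.all():
        return z0.reshape(shape)
    z1, llow1, lupp1 = _z_from(lo + 1)
    # interpolate mid-p linearly, in the smaller tail's log space
    lw0 = np.log1p(-frac, where=frac < 1, out=np.full_like(frac, -np.inf))
    lw1 = np.log(frac, where=frac > 0, out=np.full_like(frac, -np.inf))
    llow = np.logaddexp(lw0 + llow0, lw1 + llow1)
    lupp = np.logaddexp(lw0 + lupp0, lw1 + lupp1)
    use_low = llow <= lupp
    zi = np.empty_like(z0)
    zi[use_low] = special.ndtri_exp(llow[use_low])
    zi[~use_low] = -special.ndtri_exp(lupp[~use_low])
    z = np.where(isint, z0, zi)
    return z.reshape(shape)


def mds_leading_logfc(logcpm, top: int = 500, dims: int = 2):
    """Multidimensional scaling on leading log-fold-change distances.

    The distance between two samples is the root-mean-square of the ``top``
    largest absolute log2-CPM differences between them; samples are embedded
    by classical principal coordinates and per-dimension fractions of
    variance explained are reported.

    Returns ``(distance matrix, coordinates, variance_explained)``.
    """
    logcpm = np.asarray(logcpm, dtype=float)
    G, n = logcpm.shape
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    top = min(top, G)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(logcpm[:, i, None] - logcpm[:, i + 1 :])
        if diff.size:
            part = np.partition(diff, G - top, axis=0)[G - top :]
            D[i, i + 1 :] = np.sqrt((part**2).mean(axis=0))
    D = D + D.T

    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    dims = min(dims, n - 1)
    coords = evecs[:, :dims] * np.sqrt(pos[:dims])[None, :]
    total = pos.sum()
    var_explained = pos[:dims] / total if total > 0 else np.zeros(dims)
    return D, coords, var_explained


def md_plot_data(tbl, fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene logFC vs average abundance with a significance mask."""
    df = tbl.table
    sig = np.nan_to_num(df["FDR"].to_numpy(), nan=1.0) <= fdr
    return pd.DataFrame(
        {
            "logCPM": df["logCPM"].to_numpy(),
            "logFC": df["logFC"].to_numpy(),
            "significant": sig,
            "direction": np.sign(df["logFC"].to_numpy()) * sig,
        }
    )
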