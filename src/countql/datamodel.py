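"""Core containers for count data, designs, and repeat-structured tables.

The central object is :class:`CountDataset`, which holds a genes x samples
matrix of (possibly fractional) read counts together with per-sample records
(library size, normalization factor, experimental covariates) and per-gene
annotation.  Offsets and observation weights are stored as
:class:`CompressedTable` objects so that scalar / row / column repeat
structure is kept explicit and memory-free until expansion is required.

All offsets are natural-log effective library sizes; reported fold changes
are converted to log2 only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CompressedTable",
    "CountDataset",
    "DesignMatrix",
    "make_dataset",
    "resolve_offsets",
    "subset_dataset",
]


class CompressedTable:
    """A genes x samples table stored via its repeat structure.

    The payload is one of: a scalar, a per-sample (row-repeated) vector, a
    per-gene (column-repeated) vector, or a full matrix.  Expansion to a
    dense matrix is exact, and element lookup on the compressed form agrees
    with lookup after expansion for every index.
    """

    KINDS = ("scalar", "per_sample", "per_gene", "full")

    def __init__(self, payload, shape: tuple[int, int], kind: Optional[str] = None):
        payload = np.asarray(payload, dtype=float)
        n_genes, n_samples = int(shape[0]), int(shape[1])
        if kind is None:
            if payload.ndim == 0:
                kind = "scalar"
            elif payload.ndim == 1:
                if payload.size == n_samples and payload.size != n_genes:
                    kind = "per_sample"
                elif payload.size == n_genes:
                    kind = "per_gene"
                else:
                    raise ValueError(
                        f"1-d payload of length {payload.size} matches neither "
                        f"{n_genes} genes nor {n_samples} samples"
                    )
            elif payload.ndim == 2:
                kind = "full"
            else:
                raise ValueError("payload must be scalar, 1-d or 2-d")
        if kind not in self.KINDS:
            raise ValueError(f"unknown repeat kind {kind!r}")
        if kind == "scalar" and payload.ndim != 0:
            payload = payload.reshape(())
        if kind == "per_sample" and payload.shape != (n_samples,):
            raise ValueError("per-sample payload length mismatch")
        if kind == "per_gene" and payload.shape != (n_genes,):
            raise ValueError("per-gene payload length mismatch")
        if kind == "full" and payload.shape != (n_genes, n_samples):
            raise ValueError("full payload shape mismatch")
        self.payload = payload
        self.kind = kind
        self.shape = (n_genes, n_samples)

    def expand(self) -> np.ndarray:
        """Return the dense genes x samples matrix (always a fresh array)."""
        g, s = self.shape
        if self.kind == "scalar":
            return np.full((g, s), float(self.payload))
        if self.kind == "per_sample":
            return np.broadcast_to(self.payload, (g, s)).copy()
        if self.kind == "per_gene":
            return np.broadcast_to(self.payload[:, None], (g, s)).copy()
        return self.payload.copy()

    def subset(self, gene_index=None, sample_index=None) -> "CompressedTable":
        """Subset without expansion where the repeat structure permits."""
        g, s = self.shape
        gi = np.arange(g) if gene_index is None else np.atleast_1d(np.asarray(gene_index))
        si = np.arange(s) if sample_index is None else np.atleast_1d(np.asarray(sample_index))
        if gi.dtype == bool:
            gi = np.flatnonzero(gi)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        new_shape = (len(gi), len(si))
        if self.kind == "scalar":
            return CompressedTable(self.payload, new_shape, "scalar")
        if self.kind == "per_sample":
            return CompressedTable(self.payload[si], new_shape, "per_sample")
        if self.kind == "per_gene":
            return CompressedTable(self.payload[gi], new_shape, "per_gene")
        return CompressedTable(self.payload[np.ix_(gi, si)], new_shape, "full")

    def __getitem__(self, idx):
        return self.expand()[idx]

    def __repr__(self):  # pragma: no cover
        return f"CompressedTable(kind={self.kind!r}, shape={self.shape})"


@dataclass
class DesignMatrix:
    """A samples x coefficients design matrix with named coefficients."""

    values: np.ndarray
    names: Sequence[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("design must be 2-d")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("coefficient name count mismatch")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("design matrix is not of full column rank")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_coef(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_group(cls, group: Sequence, intercept: bool = False) -> "DesignMatrix":
        """One-way layout design from group labels.

        With ``intercept=False`` (the default, a group-means parameterization)
        each coefficient is the log mean of one group.
        """
        group = pd.Categorical(group)
        levels = list(group.categories)
        n = len(group)
        codes = np.asarray(group.codes)
        if intercept:
            cols = [np.ones(n)]
            names = ["(Intercept)"]
            for j, lev in enumerate(levels[1:], start=1):
                cols.append((codes == j).astype(float))
                names.append(str(lev))
        else:
            cols = [(codes == j).astype(float) for j in range(len(levels))]
            names = [str(lev) for lev in levels]
        return cls(np.column_stack(cols), names)


def _as_design(design, n_samples: int) -> DesignMatrix:
    if isinstance(design, DesignMatrix):
        dm = design
    else:
        arr = np.atleast_2d(np.asarray(design, dtype=float))
        if arr.shape[0] != n_samples and arr.shape[1] == n_samples:
            arr = arr.T
        dm = DesignMatrix(arr, [f"coef{j + 1}" for j in range(arr.shape[1])])
    if dm.n_samples != n_samples:
        raise ValueError(
            f"design has {dm.n_samples} rows but dataset has {n_samples} samples"
        )
    return dm


@dataclass
class CountDataset:
    """Counts with aligned sample records, gene annotation, offsets, weights."""

    counts: np.ndarray
    samples: pd.DataFrame
    genes: pd.DataFrame
    offset: Optional[CompressedTable] = None
    weights: Optional[CompressedTable] = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def lib_size(self) -> np.ndarray:
        return self.samples["lib_size"].to_numpy(dtype=float)

    @property
    def norm_factor(self) -> np.ndarray:
        return self.samples["norm_factor"].to_numpy(dtype=float)

    @property
    def effective_lib_size(self) -> np.ndarray:
        return self.lib_size * self.norm_factor

    def weight_matrix(self) -> np.ndarray:
        if self.weights is None:
            return np.ones_like(self.counts)
        return self.weights.expand()

    def __getitem__(self, idx) -> "CountDataset":
        gene_index, sample_index = idx if isinstance(idx, tuple) else (idx, None)
        return subset_dataset(self, gene_index, sample_index)


def make_dataset(
    counts,
    samples: Union[pd.DataFrame, dict, None] = None,
    genes: Union[pd.DataFrame, dict, None] = None,
    group: Optional[Sequence] = None,
    lib_size: Optional[Sequence[float]] = None,
    norm_factor: Optional[Sequence[float]] = None,
) -> CountDataset:
    """Assemble counts plus annotation into a validated :class:`CountDataset`.

    Counts may be fractional but must be finite and non-negative.  Library
    sizes default to column sums; normalization factors default to 1.
    An all-zero sample (library size 0) is rejected because its log offset
    would be undefined downstream.
    """
    if isinstance(counts, pd.DataFrame):
        if genes is None:
            genes = pd.DataFrame({"id": counts.index.astype(str)})
        sample_names = list(counts.columns.astype(str))
        counts = counts.to_numpy(dtype=float)
    else:
        sample_names = None
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-d table")

    bad = ~np.isfinite(counts) | (counts < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid count at gene {g}, sample {s}: {counts[g, s]!r} "
            "(counts must be finite and non-negative)"
        )

    n_genes, n_samples = counts.shape

    if samples is None:
        samples = pd.DataFrame(index=range(n_samples))
    elif isinstance(samples, dict):
        samples = pd.DataFrame(samples)
    else:
        samples = samples.copy()
    if sample_names is not None and samples.index.equals(pd.RangeIndex(n_samples)):
        samples.index = sample_names
    if len(samples) != n_samples:
        raise ValueError(
            f"sample table has {len(samples)} rows but counts have {n_samples} columns"
        )
    if group is not None:
        if len(group) != n_samples:
            raise ValueError("group labels do not match the number of samples")
        samples["group"] = list(group)

    if lib_size is None:
        if "lib_size" not in samples.columns:
            samples["lib_size"] = counts.sum(axis=0)
    else:
        if len(np.atleast_1d(lib_size)) != n_samples:
            raise ValueError("lib_size length mismatch")
        samples["lib_size"] = np.asarray(lib_size, dtype=float)
    ls = samples["lib_size"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ls) & (ls > 0)):
        i = int(np.flatnonzero(~(np.isfinite(ls) & (ls > 0)))[0])
        raise ValueError(
            f"sample {i} has non-positive library size {ls[i]!r}; "
            "all-zero samples must be removed before analysis"
        )

    if norm_factor is None:
        if "norm_factor" not in samples.columns:
            samples["norm_factor"] = 1.0
    else:
        samples["norm_factor"] = np.asarray(norm_factor, dtype=float)
    nf = samples["norm_factor"].to_numpy(dtype=float)
    if not np.all(np.isfinite(nf) & (nf > 0)):
        raise ValueError("normalization factors must be positive and finite")

    if genes is None:
        genes = pd.DataFrame({"id": [f"gene{i + 1}" for i in range(n_genes)]})
    elif isinstance(genes, dict):
        genes = pd.DataFrame(genes)
    else:
        genes = genes.copy()
    if "id" not in genes.columns:
        genes.insert(0, "id", [f"gene{i + 1}" for i in range(n_genes)])
    if len(genes) != n_genes:
        raise ValueError(
            f"gene table has {len(genes)} rows but counts have {n_genes} rows"
        )
    genes = genes.reset_index(drop=True)

    return CountDataset(counts=counts, samples=samples, genes=genes)


def resolve_offsets(ds: CountDataset) -> CompressedTable:
    """Resolve the natural-log effective-library-size offsets for a dataset.

    Precedence is total: an explicit offset table wins; otherwise the offset
    is ``log(lib_size * norm_factor)`` repeated down each column.
    """
    if ds.offset is not None:
        return ds.offset
    els = ds.effective_lib_size
    return CompressedTable(np.log(els), (ds.n_genes, ds.n_samples), "per_sample")


def _normalize_index(index, n: int) -> np.ndarray:
    if index is None:
        return np.arange(n)
    if isinstance(index, slice):
        return np.arange(n)[index]
    idx = np.asarray(index)
    if idx.dtype == bool:
        if idx.size != n:
            raise IndexError("boolean index length mismatch")
        return np.flatnonzero(idx)
    idx = np.atleast_1d(idx.astype(int))
    if idx.size and (idx.min() < -n or (idx.size and idx.max() >= n)):
        raise IndexError(f"index out of range for axis of length {n}")
    return idx % n if idx.size else idx


def subset_dataset(ds: CountDataset, gene_index=None, sample_index=None) -> CountDataset:
    """Subset all aligned components of a dataset consistently."""
    gi = _normalize_index(gene_index, ds.n_genes)
    si = _normalize_index(sample_index, ds.n_samples)
    out = CountDataset(
        counts=ds.counts[np.ix_(gi, si)],
        samples=ds.samples.iloc[si].copy(),
        genes=ds.genes.iloc[gi].reset_index(drop=True),
        offset=None if ds.offset is None else ds.offset.subset(gi, si),
        weights=None if ds.weights is None else ds.weights.subset(gi, si),
    )
    return out
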