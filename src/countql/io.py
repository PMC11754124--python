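"""Readers and writers for the tabular formats the pipeline touches.

Supported inputs: plain tab-separated count tables (with automatic
detection of leading annotation columns, including the featureCounts
dialect), MatrixMarket sparse matrices with features/barcodes sidecars, and
Bismark-style methylation coverage files.  Results are written as
tab-separated tables at full float precision.

Readers reject malformed input rather than silently coercing it, and all
produced datasets pass :func:`make_dataset` validation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountDataset, make_dataset

__all__ = [
    "ResultTable",
    "read_counts_tsv",
    "read_mtx",
    "read_bismark_coverage",
    "write_results",
]

# featureCounts-style annotation columns (case-insensitive)
_ANNOTATION_NAMES = {"geneid", "gene_id", "chr", "start", "end", "strand", "length", "id"}


@dataclass
class ResultTable:
    """Per-gene differential results: logFC (log2), logCPM, statistic,
    PValue and BH-adjusted FDR, aligned with gene annotation."""

    table: pd.DataFrame
    genes: Optional[pd.DataFrame] = None
    statistic: str = "F"
    sorted: bool = False

    def __len__(self):
        return len(self.table)

    def __getitem__(self, col):
        return self.table[col]

    def to_frame(self) -> pd.DataFrame:
        if self.genes is not None and len(self.genes) == len(self.table):
            return pd.concat(
                [self.genes.reset_index(drop=True), self.table.reset_index(drop=True)],
                axis=1,
            )
        return self.table.copy()


def read_counts_tsv(path, gene_id: Optional[str] = None) -> CountDataset:
    """Read a tab-separated count table.

    Comment lines starting with ``#`` are skipped.  Leading non-numeric
    columns, and leading columns with featureCounts-style names (Geneid,
    Chr, Start, End, Strand, Length), become gene annotation; the remaining
    columns must be numeric counts.  Ragged rows and duplicated sample
    names are rejected.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    if len(set(header)) != width:
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicated sample names {dup}")
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise ValueError(
                f"{path}: line {i} has {len(parts)} fields, expected {width}"
            )
        rows.append(parts)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=header)

    def _numeric(col):
        try:
            pd.to_numeric(df[col])
            return True
        except (ValueError, TypeError):
            return False

    n_ann = 0
    for col in header:
        if col.lower() in _ANNOTATION_NAMES or not _numeric(col):
            n_ann += 1
        else:
            break
    if gene_id is not None:
        if gene_id not in header:
            raise ValueError(f"{path}: gene-id column {gene_id!r} not found")
        n_ann = max(n_ann, header.index(gene_id) + 1)
    if n_ann >= width:
        raise ValueError(f"{path}: no count columns detected")
    ann = df.iloc[:, :n_ann].copy()
    body = df.iloc[:, n_ann:].apply(pd.to_numeric)
    for col in body.columns:
        if not np.issubdtype(body[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric count column {col!r}")
    genes = ann if n_ann else None
    if genes is not None:
        id_col = gene_id or header[0]
        genes = genes.rename(columns={id_col: "id"})
    counts = pd.DataFrame(
        body.to_numpy(dtype=float), columns=body.columns
    )
    counts.index = (
        genes["id"].astype(str) if genes is not None else pd.RangeIndex(len(body))
    )
    ds = make_dataset(counts, genes=genes)
    return ds


def read_mtx(directory, matrix="matrix.mtx", features="features.tsv", barcodes="barcodes.tsv") -> CountDataset:
    """Read a MatrixMarket count matrix with feature/barcode sidecars.

    Gene ids stay unique even when gene symbols are duplicated; 1-based
    MatrixMarket indices map to internal 0-based positions.
    """
    from scipy.io import mmread

    mtx_path = os.path.join(directory, matrix)
    mat = mmread(mtx_path)
    counts = np.asarray(mat.todense(), dtype=float) if hasattr(mat, "todense") else np.asarray(mat, dtype=float)
    n_genes, n_samples = counts.shape

    feat = pd.read_csv(
        os.path.join(directory, features), sep="\t", header=None, dtype=str
    )
    if len(feat) != n_genes:
        raise ValueError(
            f"{features}: {len(feat)} rows but matrix declares {n_genes} genes"
        )
    cols = ["id", "symbol", "feature_type"][: feat.shape[1]]
    feat.columns = cols + [f"col{j}" for j in range(feat.shape[1] - len(cols))]

    bc = pd.read_csv(
        os.path.join(directory, barcodes), sep="\t", header=None, dtype=str
    )
    if len(bc) != n_samples:
        raise ValueError(
            f"{barcodes}: {len(bc)} rows but matrix declares {n_samples} samples"
        )
    samples = pd.DataFrame(index=bc.iloc[:, 0].astype(str))
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        # empty droplets/barcodes get a nominal library size so the
        # container stays valid; they should be filtered before analysis
        import warnings

        warnings.warn(f"{int((lib == 0).sum())} barcode(s) have zero counts")
        lib = np.maximum(lib, 1.0)
    return make_dataset(counts, samples=samples, genes=feat, lib_size=lib)


def read_bismark_coverage(paths: Sequence[str], sample_names: Optional[Sequence[str]] = None) -> CountDataset:
    """Collate Bismark-style coverage files into paired Me/Un count columns.

    Each file holds rows of chrom, position(s), percent-methylated,
    count-methylated, count-unmethylated.  Loci are matched across files by
    chrom+position (treated as an opaque 1-based key; no coordinate
    arithmetic); loci absent from a file get zero counts.  Output columns
    are ordered sample1-Me, sample1-Un, sample2-Me, ...; both columns of a
    sample share the sample's total library size.
    """
    if sample_names is None:
        sample_names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    if len(sample_names) != len(paths):
        raise ValueError("sample_names must match paths")

    per_sample = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] == 6:
            chrom, pos = df[0], df[1]
            me, un = df[4], df[5]
        elif df.shape[1] == 5:
            chrom, pos = df[0], df[1]
            me, un = df[3], df[4]
        else:
            raise ValueError(f"{path}: expected 5 or 6 tab-separated columns")
        key = chrom.astype(str) + ":" + pos.astype(str)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate locus {dup}")
        tab = pd.DataFrame(
            {
                "Me": pd.to_numeric(me).to_numpy(dtype=float),
                "Un": pd.to_numeric(un).to_numpy(dtype=float),
                "chrom": chrom.to_numpy(),
                "pos": pd.to_numeric(pos).to_numpy(),
            },
            index=key,
        )
        per_sample.append(tab)

    all_keys = pd.concat([t[["chrom", "pos"]] for t in per_sample])
    all_keys = all_keys[~all_keys.index.duplicated()]
    all_keys = all_keys.sort_values(["chrom", "pos"], kind="stable")
    loci = all_keys.index

    cols = {}
    lib = []
    for name, tab in zip(sample_names, per_sample):
        me = tab["Me"].reindex(loci, fill_value=0.0)
        un = tab["Un"].reindex(loci, fill_value=0.0)
        cols[f"{name}-Me"] = me.to_numpy()
        cols[f"{name}-Un"] = un.to_numpy()
        lib.extend([me.sum() + un.sum()] * 2)
    counts = pd.DataFrame(cols, index=loci)
    genes = pd.DataFrame(
        {
            "id": loci,
            "chrom": all_keys["chrom"].to_numpy(),
            "pos": all_keys["pos"].to_numpy(),
        }
    )
    return make_dataset(counts, genes=genes, lib_size=np.asarray(lib, dtype=float))


def write_results(tbl: ResultTable, path) -> None:
    """Write a result table as TSV at full precision; NaN p-values as NA."""
    df = tbl.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.15g")
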