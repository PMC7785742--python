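"""Readers and writers for the plain-text interchange formats.

Counts travel as dense CSV/TSV (genes x cells, header row of cell ids,
first column gene ids) or as MatrixMarket triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecar files; partitions as two-column TSV
(cell, cluster); gene annotation comes from a GTF file.  A sidecar JSON
next to each written counts table records the transformation state.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import Partition
from .preprocess import CountsMatrix, GeneAnnotation

logger = logging.getLogger("scamine")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path: str | Path,
    genes: str | Path | None = None,
    barcodes: str | Path | None = None,
    layer_tag: str = "raw",
) -> CountsMatrix:
    """Read a genes x cells counts table.

    Dense CSV/TSV is detected from the extension; a ``.mtx`` file needs
    ``genes`` and ``barcodes`` row/column name files (one id per line,
    first tab-separated field used).
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes is None or barcodes is None:
            raise ValueError("MatrixMarket input requires genes and barcodes files")
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense(), dtype=np.float64)
        gene_ids = _read_id_column(genes)
        cell_ids = _read_id_column(barcodes)
        return CountsMatrix(values, gene_ids, cell_ids, layer_tag=layer_tag)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return CountsMatrix(
        df.to_numpy(dtype=np.float64),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        layer_tag=layer_tag,
    )


def _read_id_column(path: str | Path) -> list[str]:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_counts(counts: CountsMatrix, path: str | Path) -> None:
    """Write a dense counts table plus a sidecar JSON with the layer tag."""
    path = Path(path)
    pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.cell_ids).to_csv(
        path, sep=_sep_for(path), index_label="gene"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"layer_tag": counts.layer_tag, "n_genes": counts.n_genes,
                   "n_cells": counts.n_cells}, fh)


def read_partition(path: str | Path) -> Partition:
    """Read a cell -> cluster assignment (TSV/CSV, optional header)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("partition file needs cell and cluster columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"cell", "cell_id", "barcode"}:
        df = df.iloc[1:]
    return Partition.from_labels(
        [str(c) for c in df.iloc[:, 0]], [str(v) for v in df.iloc[:, 1]]
    )


def write_partition(partition: Partition, path: str | Path) -> None:
    pd.DataFrame({"cell": partition.cell_ids, "cluster": partition.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_annotation(gtf_path: str | Path) -> GeneAnnotation:
    """Build a gene_id -> (symbol, biotype, chromosome) lookup from a GTF.

    Only ``gene`` feature lines are used; the ``gene_id``, ``gene_name``
    and ``gene_biotype`` attributes must be present (``gene_name`` falls
    back to the id).
    """
    import pyranges

    gr = pyranges.read_gtf(str(gtf_path)).df
    genes = gr[gr["Feature"] == "gene"]
    if genes.empty:
        raise ValueError(f"{gtf_path}: no gene lines in GTF")
    records: dict[str, tuple[str, str, str]] = {}
    names = genes["gene_name"] if "gene_name" in genes else genes["gene_id"]
    biotypes = genes["gene_biotype"] if "gene_biotype" in genes else pd.Series("", index=genes.index)
    for gid, name, biotype, chrom in zip(
        genes["gene_id"], names, biotypes, genes["Chromosome"]
    ):
        sym = name if isinstance(name, str) and name else str(gid)
        records[str(gid)] = (sym, str(biotype), str(chrom))
    return GeneAnnotation(records=records)
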