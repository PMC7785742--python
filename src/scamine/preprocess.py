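"""Counts-matrix container, gene/cell filtering and input normalization.

The autoencoder input table can be raw counts, log10-transformed counts,
or counts normalized with one of five schemes commonly used for RNA-seq
library-size correction: centered log-ratio (CLR), relative log
expression (RLE), full-quantile (FQ), sum scaling (SUM) and weighted
trimmed mean of M-values (TMM).  Upstream of that sit the standard
filters: keep protein-coding genes minus ribosomal/mitochondrial ones,
drop cells with fewer than 250 detected genes (a gene counts as detected
at >= 3 UMIs), and select the informative genes (most dispersed, then
most expressed among those).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("scamine")

NORMALIZATION_METHODS = ("log10", "clr", "rle", "fq", "sum", "tmm")


@dataclass
class CountsMatrix:
    """Genes x cells expression matrix with identifier bookkeeping.

    ``layer_tag`` records the transformation state: ``raw`` or one of
    :data:`NORMALIZATION_METHODS`.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.layer_tag == "raw" and (self.values < 0).any():
            raise ValueError("raw counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, rows: np.ndarray) -> "CountsMatrix":
        return replace(
            self,
            values=self.values[rows, :],
            gene_ids=[self.gene_ids[i] for i in np.atleast_1d(rows)],
        )

    def subset_cells(self, cols: np.ndarray) -> "CountsMatrix":
        return replace(
            self,
            values=self.values[:, cols],
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(cols)],
        )


@dataclass
class GeneAnnotation:
    """Gene id -> (symbol, biotype, chromosome) lookup built from a GTF."""

    records: Mapping[str, tuple[str, str, str]] = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def symbol(self, gene_id: str) -> str:
        return self.records[gene_id][0]

    def biotype(self, gene_id: str) -> str:
        return self.records[gene_id][1]


_RIBO_PREFIXES = ("RPS", "RPL", "MRPS", "MRPL")


def _is_ribosomal(symbol: str) -> bool:
    return symbol.upper().startswith(_RIBO_PREFIXES)


def _is_mitochondrial(symbol: str) -> bool:
    return symbol.upper().startswith("MT-")


def annotate_and_filter_genes(
    counts: CountsMatrix, annotation: GeneAnnotation
) -> CountsMatrix:
    """Keep protein-coding genes, drop ribosomal/mitochondrial ones.

    Gene ids are replaced by their annotated symbols; ids sharing a symbol
    are disambiguated with ``.1``, ``.2``, ... suffixes.  Unannotated ids
    are dropped (count logged).
    """
    if counts.layer_tag != "raw":
        raise ValueError("gene filtering operates on raw counts")
    keep: list[int] = []
    symbols: list[str] = []
    unannotated = 0
    for i, gid in enumerate(counts.gene_ids):
        if gid not in annotation:
            unannotated += 1
            continue
        sym = annotation.symbol(gid)
        if annotation.biotype(gid) != "protein_coding":
            continue
        if _is_ribosomal(sym) or _is_mitochondrial(sym):
            continue
        keep.append(i)
        symbols.append(sym)
    if unannotated:
        logger.info("dropped %d unannotated gene ids", unannotated)
    if not keep:
        raise ValueError("no genes survive the annotation filter")
    seen: dict[str, int] = {}
    unique_symbols: list[str] = []
    for sym in symbols:
        if sym in seen:
            seen[sym] += 1
            unique_symbols.append(f"{sym}.{seen[sym]}")
        else:
            seen[sym] = 0
            unique_symbols.append(sym)
    out = counts.subset_genes(np.asarray(keep, dtype=int))
    return replace(out, gene_ids=unique_symbols)


def filter_cells_by_detection(
    counts: CountsMatrix, min_genes: int = 250, min_umi: int = 3
) -> CountsMatrix:
    """Remove cells with fewer than ``min_genes`` detected genes.

    A gene is detected in a cell when its count is at least ``min_umi``
    (3 UMIs by default).
    """
    if counts.layer_tag != "raw":
        raise ValueError("cell filtering operates on raw counts")
    detected = (counts.values >= min_umi).sum(axis=0)
    keep = np.flatnonzero(detected >= min_genes)
    if keep.size == 0:
        raise ValueError("all cells removed by the detection filter")
    removed = counts.n_cells - keep.size
    if removed:
        logger.info("removed %d cell(s) with < %d detected genes", removed, min_genes)
    return counts.subset_cells(keep)


def select_informative_genes(
    counts: CountsMatrix, n_dispersed: int = 10000, n_expressed: int = 5000
) -> CountsMatrix:
    """Two-stage informative-gene selection.

    Rank genes by dispersion (variance / mean across cells; zero-mean
    genes rank last), keep the top ``n_dispersed``; among survivors rank
    by total counts and keep the top ``n_expressed``.  The original
    relative gene order is preserved in the output.
    """
    if n_expressed > n_dispersed:
        raise ValueError("n_expressed must not exceed n_dispersed")
    if counts.n_cells < 2:
        raise ValueError("dispersion needs at least two cells")
    if counts.n_genes <= n_expressed:
        logger.warning(
            "only %d genes available (<= n_expressed=%d); keeping all",
            counts.n_genes, n_expressed,
        )
        return counts
    mean = counts.values.mean(axis=1)
    var = counts.values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), -np.inf)
    # stable: among ties keep earlier genes first
    disp_order = np.argsort(-dispersion, kind="stable")[: min(n_dispersed, counts.n_genes)]
    totals = counts.values[disp_order, :].sum(axis=1)
    expr_order = np.argsort(-totals, kind="stable")[:n_expressed]
    keep = np.sort(disp_order[expr_order])
    return counts.subset_genes(keep)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------


def _check_no_zero_cells(counts: CountsMatrix, method: str) -> None:
    totals = counts.values.sum(axis=0)
    zeros = np.flatnonzero(totals == 0)
    if zeros.size:
        raise ValueError(
            f"{method}: cell {counts.cell_ids[zeros[0]]!r} has all-zero counts"
        )


def _log10(x: np.ndarray) -> np.ndarray:
    return np.log10(x + 1.0)


def _clr(x: np.ndarray) -> np.ndarray:
    # per cell: ln((x+1) / geometric mean over genes of (x+1))
    logx = np.log(x + 1.0)
    return logx - logx.mean(axis=0, keepdims=True)


def _rle(x: np.ndarray, cell_ids: list[str]) -> np.ndarray:
    nonzero_all = (x > 0).all(axis=1)
    if nonzero_all.any():
        ref_rows = nonzero_all
    else:
        frac = (x > 0).mean(axis=1)
        ref_rows = frac >= 0.5
        if not ref_rows.any():
            raise ValueError("rle: no gene is expressed in >= 50% of cells")
        logger.warning(
            "rle: no gene nonzero in all cells; using %d genes nonzero in >= 50%%",
            int(ref_rows.sum()),
        )
    xr = x[ref_rows]
    # geometric mean over the cells where the reference gene is observed
    logx = np.where(xr > 0, np.log(np.where(xr > 0, xr, 1.0)), np.nan)
    ref = np.exp(np.nanmean(logx, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = xr / ref[:, None]
    factors = np.median(ratios, axis=0)
    bad = np.flatnonzero(~np.isfinite(factors) | (factors <= 0))
    if bad.size:
        raise ValueError(f"rle: degenerate size factor for cell {cell_ids[bad[0]]!r}")
    return x / factors[None, :]


def _fq(x: np.ndarray) -> np.ndarray:
    # target distribution: mean across cells of the sorted per-cell vectors
    target = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x, dtype=np.float64)
    grid = np.arange(n, dtype=np.float64)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, target)
    return out


def _sum(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sum: all-zero cell")
    return x * (np.median(totals) / totals)[None, :]


def tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M-values scaling factor of ``obs`` vs ``ref``.

    M (log2 expression ratio) and A (log2 average abundance) are computed
    over genes nonzero in both libraries, the most extreme
    ``logratio_trim`` tails of M and ``abs_expr_trim`` tails of A are
    discarded, and the remaining M-values are averaged with
    inverse-asymptotic-variance weights.  Returns ``2**weighted_mean``.
    """
    obs = np.asarray(obs, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    n_obs, n_ref = obs.sum(), ref.sum()
    if n_obs == 0 or n_ref == 0:
        raise ValueError("tmm: all-zero library")
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    if m.size == 0 or np.allclose(m, m[0]):
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m, method="average")
    ra = rankdata(a, method="average")
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    w = (n_obs - o[keep]) / (n_obs * o[keep]) + (n_ref - r[keep]) / (n_ref * r[keep])
    f = np.sum(m[keep] / w) / np.sum(1.0 / w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _tmm(x: np.ndarray, cell_ids: list[str]) -> np.ndarray:
    lib = x.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f75 = np.quantile(x / lib[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [tmm_factor(x[:, j], x[:, ref_idx]) for j in range(x.shape[1])]
    )
    return x / (lib * factors)[None, :] * lib.mean()


def normalize_counts(counts: CountsMatrix, method: str) -> CountsMatrix:
    """Apply one of the supported transformations to raw counts.

    ``log10`` is ``log10(x + 1)``; ``clr`` is the per-cell centered
    log-ratio with a pseudocount of 1 (natural log); ``rle``, ``sum`` and
    ``tmm`` rescale each cell by a library-size factor; ``fq`` forces all
    cells onto the mean quantile distribution.
    """
    if counts.layer_tag != "raw":
        raise ValueError("normalization operates on raw counts")
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization {method!r}; expected one of {NORMALIZATION_METHODS}"
        )
    x = counts.values
    if method == "log10":
        out = _log10(x)
    elif method == "clr":
        _check_no_zero_cells(counts, "clr")
        out = _clr(x)
    elif method == "rle":
        _check_no_zero_cells(counts, "rle")
        out = _rle(x, counts.cell_ids)
    elif method == "fq":
        out = _fq(x)
    elif method == "sum":
        out = _sum(x)
    else:
        _check_no_zero_cells(counts, "tmm")
        out = _tmm(x, counts.cell_ids)
    return replace(counts, values=out, layer_tag=method)
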