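"""QCC and QCM cluster-stability metrics with the dual >= 0.5 gate.

Both metrics score, per cell, how stably that cell keeps its companions
across autoencoder runs:

* QCC (Quality Control of Cluster) compares each run's latent-space
  partition against the *reference* partition.  For cell ``i`` with
  reference companions ``C(i)`` (members of its reference cluster minus
  itself) and run-``r`` companions ``S_r(i)``, the per-run score is the
  directed overlap ``|C(i) & S_r(i)| / |C(i)|`` (0 for a singleton
  reference cluster), averaged over runs.  A QCC of 1 means the cell sat
  with all of its reference companions in every run; 0 means it never
  met any of them.

* QCM (Quality Control of Model) ignores the reference and measures the
  reproducibility of the model itself over random pairs of runs: for a
  run pair the per-cell score is the Jaccard overlap of the two
  companion sets (1 when both are empty, 0 when exactly one is),
  averaged over sampled pairs.

A reference cluster counts as *explained* by the latent space when the
cluster means of both metrics reach 0.5 — i.e. at least half of the
companion structure survives in at least half of the runs/pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import Partition, RunEnsemble

logger = logging.getLogger("scamine")

PASS_THRESHOLD = 0.5


@dataclass
class ScoreTable:
    """Per-cell QCC/QCM scores and the per-cluster pass/fail summary."""

    cells: pd.DataFrame      # columns: cell, reference_cluster, qcc, qcm
    clusters: pd.DataFrame   # columns: cluster, n_cells, mean_qcc, mean_qcm, passes
    threshold: float
    n_runs: int
    n_pairs: int

    def passing_clusters(self) -> set[int]:
        return set(self.clusters.loc[self.clusters["passes"], "cluster"])

    def to_tsv(self, cells_path: str | Path, clusters_path: str | Path) -> None:
        self.cells.to_csv(cells_path, sep="\t", index=False)
        self.clusters.to_csv(clusters_path, sep="\t", index=False)


def _align_ensemble_labels(reference: Partition, ensemble: RunEnsemble) -> list[np.ndarray]:
    """Return each run's label vector reordered to the reference cell order."""
    ref_cells = reference.cell_ids
    ens_cells = ensemble.cell_ids
    if ref_cells == ens_cells:
        return [p.labels for p in ensemble.partitions]
    if set(ref_cells) != set(ens_cells):
        raise ValueError("reference and ensemble cell ids do not match")
    order = [ens_cells.index(c) for c in ref_cells]
    return [p.labels[order] for p in ensemble.partitions]


def _companion_overlap(ref_labels: np.ndarray, run_labels: np.ndarray) -> np.ndarray:
    """Directed per-cell companion overlap of one run against the reference."""
    n = ref_labels.size
    ref_sizes = np.bincount(ref_labels)[ref_labels]          # |cluster(i)| incl. i
    joint = (
        pd.crosstab(ref_labels, run_labels)
        .reindex(index=np.unique(ref_labels), columns=np.unique(run_labels), fill_value=0)
        .to_numpy()
    )
    # map each cell to its (ref, run) contingency count
    ref_index = {v: i for i, v in enumerate(np.unique(ref_labels))}
    run_index = {v: i for i, v in enumerate(np.unique(run_labels))}
    ri = np.array([ref_index[v] for v in ref_labels])
    qi = np.array([run_index[v] for v in run_labels])
    shared = joint[ri, qi] - 1                               # companions in common
    scores = np.zeros(n)
    nonsingleton = ref_sizes > 1
    scores[nonsingleton] = shared[nonsingleton] / (ref_sizes[nonsingleton] - 1)
    return scores


def qcc_scores(reference: Partition, ensemble: RunEnsemble) -> np.ndarray:
    """Per-cell QCC: mean over runs of the directed companion overlap."""
    run_labels = _align_ensemble_labels(reference, ensemble)
    acc = np.zeros(len(reference.cell_ids))
    for labels in run_labels:
        acc += _companion_overlap(reference.labels, labels)
    return acc / len(run_labels)


def _companion_jaccard(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-cell Jaccard overlap of companion sets between two partitions."""
    sizes_a = np.bincount(a)[a]
    sizes_b = np.bincount(b)[b]
    joint = (
        pd.crosstab(a, b)
        .reindex(index=np.unique(a), columns=np.unique(b), fill_value=0)
        .to_numpy()
    )
    ai = {v: i for i, v in enumerate(np.unique(a))}
    bi = {v: i for i, v in enumerate(np.unique(b))}
    shared = joint[
        np.array([ai[v] for v in a]), np.array([bi[v] for v in b])
    ] - 1
    union = (sizes_a - 1) + (sizes_b - 1) - shared
    scores = np.zeros(a.size)
    both_empty = union == 0
    scores[both_empty] = 1.0
    nz = ~both_empty
    scores[nz] = shared[nz] / union[nz]
    return scores


def qcm_scores(
    ensemble: RunEnsemble, n_pairs: int | None = None, seed: int = 0
) -> np.ndarray:
    """Per-cell QCM: mean companion Jaccard over sampled run pairs.

    Pairs are distinct unordered run pairs drawn uniformly; when
    ``n_pairs`` reaches the total number of pairs (default cap 100) all
    pairs are evaluated.
    """
    n = ensemble.n_runs
    if n < 2:
        raise ValueError("QCM needs at least 2 runs")
    all_pairs = list(combinations(range(n), 2))
    if n_pairs is None:
        n_pairs = min(100, len(all_pairs))
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs >= len(all_pairs):
        pairs = all_pairs
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[i] for i in idx]
    labels = [p.labels for p in ensemble.partitions]
    acc = np.zeros(len(ensemble.cell_ids))
    for r, q in pairs:
        acc += _companion_jaccard(labels[r], labels[q])
    return acc / len(pairs)


def summarize_by_cluster(
    reference: Partition,
    qcc: np.ndarray,
    qcm: np.ndarray,
    threshold: float = PASS_THRESHOLD,
    n_runs: int = 0,
    n_pairs: int = 0,
) -> ScoreTable:
    """Cluster-level means and the dual-gate decision (both means >= threshold)."""
    qcc = np.asarray(qcc, dtype=np.float64)
    qcm = np.asarray(qcm, dtype=np.float64)
    if qcc.shape != (len(reference.cell_ids),) or qcm.shape != qcc.shape:
        raise ValueError("score vectors must align with the reference cells")
    cells = pd.DataFrame(
        {
            "cell": reference.cell_ids,
            "reference_cluster": reference.labels,
            "qcc": qcc,
            "qcm": qcm,
        }
    )
    rows = []
    for c in range(reference.k):
        members = reference.cluster_members(c)
        if members.size == 0:
            raise ValueError(f"reference cluster {c} is empty")
        mq, mm = float(qcc[members].mean()), float(qcm[members].mean())
        rows.append(
            {
                "cluster": c,
                "n_cells": int(members.size),
                "mean_qcc": mq,
                "mean_qcm": mm,
                "passes": bool(mq >= threshold and mm >= threshold),
            }
        )
    return ScoreTable(
        cells=cells,
        clusters=pd.DataFrame(rows),
        threshold=threshold,
        n_runs=n_runs,
        n_pairs=n_pairs,
    )


def plot_scores(table: ScoreTable, out_prefix: str | Path) -> list[Path]:
    """Violin plots of per-cell QCC/QCM by cluster and a mean-score scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    paths: list[Path] = []
    for metric in ("qcc", "qcm"):
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = [
            table.cells.loc[table.cells["reference_cluster"] == c, metric].to_numpy()
            for c in sorted(table.cells["reference_cluster"].unique())
        ]
        ax.violinplot(groups, showmeans=True)
        ax.axhline(table.threshold, color="red", linestyle="--", linewidth=1)
        ax.set_xlabel("reference cluster")
        ax.set_ylabel(metric.upper())
        ax.set_ylim(-0.05, 1.05)
        p = out_prefix.with_name(out_prefix.name + f"_{metric}_violin.png")
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table.clusters["mean_qcm"], table.clusters["mean_qcc"])
    for _, row in table.clusters.iterrows():
        ax.annotate(str(int(row["cluster"])), (row["mean_qcm"], row["mean_qcc"]))
    ax.axhline(table.threshold, color="red", linestyle="--", linewidth=1)
    ax.axvline(table.threshold, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("mean QCM")
    ax.set_ylabel("mean QCC")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    p = out_prefix.with_name(out_prefix.name + "_qcm_qcc_scatter.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
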