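"""Cluster-specific latent-marker mining from the frequency matrix.

For each reference cluster that passes the QCC/QCM gate, every latent
feature — and its negation, since the *absence* of a feature can mark a
cluster — is scored by its best split of the cells: candidate thresholds
sweep the observed frequency values, the above-threshold cell set is
tested for enrichment in the cluster with a hypergeometric tail
p-value, and the threshold minimizing that p-value is kept.  Features
are ranked per cluster by p-value and a small marker panel is assembled
greedily, each added feature maximizing additional coverage of
still-unmarked cluster cells weighted by its specificity.

This is a deliberately simple single-feature split statistic in the
spirit of marker-panel tools built on the XL-mHG test; it trades their
exhaustive search for determinism and transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ensemble import FrequencyMatrix, Partition

logger = logging.getLogger("scamine")


@dataclass
class MarkerResult:
    """Best-split statistics of one (cluster, feature, direction) candidate."""

    cluster: int
    feature: str
    direction: str  # "positive" or "negation"
    threshold: float
    tp: float   # fraction of cluster cells above threshold
    tn: float   # fraction of non-cluster cells at-or-below threshold
    p_value: float
    bh_q: float = 1.0
    rank: int = 0


@dataclass
class MarkerReport:
    results: list[MarkerResult]
    panels: dict[int, list[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": r.cluster,
                    "rank": r.rank,
                    "feature": r.feature,
                    "direction": r.direction,
                    "threshold": r.threshold,
                    "TP": r.tp,
                    "TN": r.tn,
                    "p": r.p_value,
                    "BH_q": r.bh_q,
                }
                for r in self.results
            ]
        )

    def to_tsv(self, markers_path: str | Path, panels_path: str | Path) -> None:
        self.to_frame().to_csv(markers_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"cluster": c, "panel_rank": i + 1, "feature": f}
                for c, feats in sorted(self.panels.items())
                for i, f in enumerate(feats)
            ]
        ).to_csv(panels_path, sep="\t", index=False)


def best_split(values: np.ndarray, in_cluster: np.ndarray) -> tuple[float, float, float, float]:
    """Best threshold for separating a cluster on one value vector.

    Sweeps every observed value ``t``; the above-threshold set is
    ``values > t``.  Returns ``(threshold, tp, tn, p)`` where ``tp`` is
    the fraction of cluster cells above the threshold, ``tn`` the
    fraction of other cells at-or-below it, and ``p`` the hypergeometric
    upper-tail probability of drawing at least the observed number of
    cluster cells in the above-threshold set.  Ties in ``p`` prefer the
    split with larger ``tp + tn``, then the lower threshold.  A constant
    vector admits no split and scores ``p = 1``.
    """
    values = np.asarray(values, dtype=np.float64)
    in_cluster = np.asarray(in_cluster, dtype=bool)
    n = values.size
    n_c = int(in_cluster.sum())
    if n_c == 0 or n_c == n:
        raise ValueError("cluster must be a proper non-empty subset of cells")
    best = (float(values[0]), 0.0, 0.0, 1.0)
    for t in np.unique(values):
        above = values > t
        big_k = int(above.sum())
        small_k = int((above & in_cluster).sum())
        p = float(hypergeom.sf(small_k - 1, n, n_c, big_k))
        tp = small_k / n_c
        tn = int((~above & ~in_cluster).sum()) / (n - n_c)
        cand = (float(t), tp, tn, p)
        if (p, -(tp + tn), t) < (best[3], -(best[1] + best[2]), best[0]):
            best = cand
    return best


def rank_latent_markers(
    freq: FrequencyMatrix,
    reference: Partition,
    passing_clusters: set[int],
    max_panel: int = 4,
) -> MarkerReport:
    """Rank latent features (and negations) per passing cluster.

    For each cluster in ``passing_clusters`` every feature is evaluated
    in both directions (the negation scores ``1 - values``); the better
    direction is kept.  Features are ranked by ascending p-value (ties:
    larger TP+TN, then feature id) and Benjamini-Hochberg q-values are
    attached for reporting.  A greedy panel of up to ``max_panel``
    features is built per cluster: each added feature maximizes (newly
    covered cluster-cell fraction) x (its TN), stopping when no feature
    adds coverage.
    """
    if freq.cell_ids != reference.cell_ids:
        raise ValueError("frequency matrix and reference partition cells differ")
    unknown = passing_clusters - set(range(reference.k))
    if unknown:
        raise ValueError(f"unknown clusters in passing set: {sorted(unknown)}")
    results: list[MarkerResult] = []
    panels: dict[int, list[str]] = {}
    for c in range(reference.k):
        if c not in passing_clusters:
            logger.info("cluster %d skipped (did not pass the QCC/QCM gate)", c)
            continue
        in_c = reference.labels == c
        cluster_results: list[MarkerResult] = []
        for j, feat in enumerate(freq.feature_ids):
            v = freq.values[:, j]
            pos = best_split(v, in_c)
            neg = best_split(1.0 - v, in_c)
            if (neg[3], -(neg[1] + neg[2])) < (pos[3], -(pos[1] + pos[2])):
                t, tp, tn, p = neg
                direction = "negation"
            else:
                t, tp, tn, p = pos
                direction = "positive"
            cluster_results.append(
                MarkerResult(
                    cluster=c, feature=feat, direction=direction,
                    threshold=t, tp=tp, tn=tn, p_value=p,
                )
            )
        cluster_results.sort(key=lambda r: (r.p_value, -(r.tp + r.tn), r.feature))
        pvals = np.array([r.p_value for r in cluster_results])
        qvals = _benjamini_hochberg(pvals)
        for i, r in enumerate(cluster_results):
            r.rank = i + 1
            r.bh_q = float(qvals[i])
        panels[c] = _greedy_panel(cluster_results, freq, in_c, max_panel)
        results.extend(cluster_results)
    return MarkerReport(results=results, panels=panels)


def _benjamini_hochberg(p_sorted: np.ndarray) -> np.ndarray:
    """BH q-values for p-values already sorted ascending."""
    m = p_sorted.size
    q = p_sorted * m / np.arange(1, m + 1)
    return np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)


def _greedy_panel(
    ranked: list[MarkerResult],
    freq: FrequencyMatrix,
    in_cluster: np.ndarray,
    max_panel: int,
) -> list[str]:
    col = {f: j for j, f in enumerate(freq.feature_ids)}
    covered = np.zeros(in_cluster.sum(), dtype=bool)
    panel: list[str] = []
    remaining = list(ranked)
    for _ in range(max_panel):
        best_gain, best_r, best_cov = 0.0, None, None
        for r in remaining:
            v = freq.values[:, col[r.feature]]
            if r.direction == "negation":
                v = 1.0 - v
            above = (v > r.threshold)[in_cluster]
            gain = float((above & ~covered).mean()) * r.tn
            if gain > best_gain + 1e-12:
                best_gain, best_r, best_cov = gain, r, above
        if best_r is None:
            break
        panel.append(best_r.feature)
        covered |= best_cov
        remaining.remove(best_r)
    return panel
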