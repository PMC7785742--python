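"""End-to-end mining workflow: normalize, mask, run the ensemble, score, mine.

`sca_workflow` wires the modules together the way the command-line
interface does: optional input normalization, connectivity-mask
construction against the dataset genes, restriction of the counts to the
masked genes, the multi-run ensemble with latent clustering, QCC/QCM
scoring against the reference partition, the latent frequency matrix,
and marker mining for the clusters passing the dual gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autoencoder import TrainingConfig
from .ensemble import FrequencyMatrix, Partition, RunEnsemble, build_frequency_matrix, run_ensemble
from .knowledge import ConnectivityMask, KnowledgeMap, build_mask
from .markers import MarkerReport, rank_latent_markers
from .metrics import ScoreTable, qcc_scores, qcm_scores, summarize_by_cluster
from .preprocess import CountsMatrix, normalize_counts

logger = logging.getLogger("scamine")


@dataclass
class WorkflowResult:
    mask: ConnectivityMask
    ensemble: RunEnsemble
    frequency: FrequencyMatrix
    scores: ScoreTable
    markers: MarkerReport


def sca_workflow(
    counts: CountsMatrix,
    knowledge: KnowledgeMap,
    reference: Partition,
    variant: str = "sca",
    norm: str | None = "log10",
    n_runs: int = 10,
    k: int | None = None,
    master_seed: int = 0,
    config: TrainingConfig | None = None,
    min_targets: int = 2,
    n_pairs: int | None = None,
    max_panel: int = 4,
    kl_weight: float = 1e-3,
) -> WorkflowResult:
    """Run the full mining workflow and return every intermediate product.

    ``k`` defaults to the number of reference clusters.  ``norm`` of
    ``None`` or ``"raw"`` feeds raw counts to the autoencoder.
    """
    if counts.cell_ids != reference.cell_ids:
        order = {c: i for i, c in enumerate(counts.cell_ids)}
        if set(reference.cell_ids) != set(order):
            raise ValueError("counts and reference partition cells differ")
        idx = np.array([order[c] for c in reference.cell_ids])
        counts = counts.subset_cells(idx)
    if norm not in (None, "raw"):
        counts = normalize_counts(counts, norm)
    mask = build_mask(knowledge, counts.gene_ids, min_targets=min_targets)
    rows = np.flatnonzero(mask.mask.sum(axis=1) > 0)
    masked_counts = counts.subset_genes(rows)
    mask = ConnectivityMask(
        genes=list(masked_counts.gene_ids),
        features=mask.features,
        mask=mask.mask[rows, :],
    )
    k = k or reference.k
    cfg = config or TrainingConfig()
    ensemble = run_ensemble(
        masked_counts, mask, cfg, n_runs=n_runs, k=k,
        master_seed=master_seed, variant=variant, kl_weight=kl_weight,
    )
    qcc = qcc_scores(reference, ensemble)
    qcm = qcm_scores(ensemble, n_pairs=n_pairs, seed=master_seed)
    scores = summarize_by_cluster(
        reference, qcc, qcm, n_runs=n_runs,
        n_pairs=n_pairs or min(100, n_runs * (n_runs - 1) // 2),
    )
    frequency = build_frequency_matrix(ensemble)
    markers = rank_latent_markers(
        frequency, reference, scores.passing_clusters(), max_panel=max_panel
    )
    return WorkflowResult(
        mask=mask, ensemble=ensemble, frequency=frequency,
        scores=scores, markers=markers,
    )
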