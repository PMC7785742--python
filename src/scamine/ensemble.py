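"""Multi-run SCA execution, latent-space clustering and the frequency matrix.

Because each autoencoder run starts from a random initialization, the
mining workflow never relies on a single fit: the model is trained many
times, each run's latent space is clustered, and stability of the
resulting partitions is what the QCC/QCM metrics score.  Across the same
runs, a cells x latent-features frequency matrix records how often each
latent node is active per cell; it is the input to marker mining.

Latent clustering defaults to seeded k-means with k equal to the number
of reference clusters; any callable with the signature
``(values, k, seed) -> labels`` can be injected in its place, since the
downstream metrics are defined over partitions regardless of the
clustering algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .autoencoder import LatentMatrix, TrainedModel, TrainingConfig, encode, train_sca, train_vsca
from .knowledge import ConnectivityMask
from .preprocess import CountsMatrix

logger = logging.getLogger("scamine")


@dataclass
class Partition:
    """A hard clustering of cells: one integer label in 0..k-1 per cell."""

    cell_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.cell_ids),):
            raise ValueError("one label per cell required")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in 0..k-1")

    @staticmethod
    def from_labels(cell_ids: Sequence[str], raw_labels: Sequence) -> "Partition":
        """Build a Partition from arbitrary hashable labels (compacted to 0..k-1)."""
        uniq = {}
        labels = np.empty(len(raw_labels), dtype=np.int64)
        for i, lab in enumerate(raw_labels):
            labels[i] = uniq.setdefault(lab, len(uniq))
        return Partition(list(cell_ids), labels, k=max(len(uniq), 1))

    def cluster_members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class RunEnsemble:
    """The (latent matrix, latent partition) pairs of n independent runs."""

    runs: list[tuple[LatentMatrix, Partition]]
    master_seed: int
    run_seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("an ensemble needs at least 2 runs")
        cells = self.runs[0][1].cell_ids
        for latent, part in self.runs:
            if part.cell_ids != cells or latent.cell_ids != cells:
                raise ValueError("all runs must share the identical cell ordering")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def cell_ids(self) -> list[str]:
        return self.runs[0][1].cell_ids

    @property
    def partitions(self) -> list[Partition]:
        return [p for _, p in self.runs]


@dataclass
class FrequencyMatrix:
    """Cells x latent-features activation frequencies across runs."""

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    activation_threshold: float
    n_runs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("frequency shape does not match id lists")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids).to_csv(
            path, sep="\t", index_label="cell"
        )


def cluster_latent(latent: LatentMatrix, k: int, seed: int = 0) -> Partition:
    """Seeded k-means on the latent activations.

    A degenerate latent matrix (all cells identical) yields a single
    cluster with a warning instead of a k-means failure.
    """
    n_cells = len(latent.cell_ids)
    if k > n_cells:
        raise ValueError("k cannot exceed the number of cells")
    if k < 1:
        raise ValueError("k must be >= 1")
    values = latent.values
    if np.allclose(values, values[0][None, :]):
        logger.warning("degenerate latent matrix (all cells identical): one cluster")
        return Partition(list(latent.cell_ids), np.zeros(n_cells, dtype=np.int64), k=1)
    if k == 1:
        return Partition(list(latent.cell_ids), np.zeros(n_cells, dtype=np.int64), k=1)
    km = KMeans(n_clusters=k, random_state=int(seed) % (2 ** 32), n_init=1)
    raw = km.fit_predict(values)
    return Partition.from_labels(list(latent.cell_ids), raw)


Clusterer = Callable[[LatentMatrix, int, int], Partition]


def derive_run_seeds(master_seed: int, n: int) -> list[int]:
    """Splittable per-run seeds: independent streams, reproducible from the master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_ensemble(
    counts: CountsMatrix,
    mask: ConnectivityMask,
    config: TrainingConfig,
    n_runs: int,
    k: int,
    master_seed: int,
    variant: str = "sca",
    kl_weight: float = 1e-3,
    clusterer: Clusterer | None = None,
) -> RunEnsemble:
    """Train ``n_runs`` independent models and cluster each latent space.

    Run ``i`` uses a seed derived from ``master_seed`` via a splittable
    scheme, so the whole ensemble is reproducible end-to-end.  A run that
    diverges (non-finite loss) is retried once with a fresh derived seed.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if k < 2:
        raise ValueError("k must be >= 2")
    if variant not in ("sca", "vsca"):
        raise ValueError("variant must be 'sca' or 'vsca'")
    cluster_fn = clusterer or cluster_latent
    # extra seeds reserved for the one-retry policy
    seeds = derive_run_seeds(master_seed, 2 * n_runs)
    runs: list[tuple[LatentMatrix, Partition]] = []
    used_seeds: list[int] = []
    for i in range(n_runs):
        for attempt, seed in enumerate((seeds[i], seeds[n_runs + i])):
            cfg = replace(config, seed=seed)
            try:
                if variant == "sca":
                    model = train_sca(counts, mask, cfg)
                else:
                    model = train_vsca(counts, mask, cfg, kl_weight=kl_weight)
                break
            except FloatingPointError:
                if attempt == 1:
                    raise RuntimeError(f"run {i} failed to converge after retry")
                logger.warning("run %d diverged; retrying with a fresh seed", i)
        latent = encode(model, counts, run_id=i)
        part = cluster_fn(latent, k, seed)
        runs.append((latent, part))
        used_seeds.append(seed)
    return RunEnsemble(runs=runs, master_seed=master_seed, run_seeds=used_seeds)


def build_frequency_matrix(
    ensemble: RunEnsemble, activation_threshold: float = 0.0
) -> FrequencyMatrix:
    """Fraction of runs in which each latent node is active per cell.

    A node counts as active in a run when its post-activation latent
    value exceeds ``activation_threshold`` (strictly); with the default
    threshold 0 this is the fraction of runs with a positive post-ReLU
    activation.
    """
    if not ensemble.runs:
        raise ValueError("empty ensemble")
    first = ensemble.runs[0][0]
    acc = np.zeros_like(first.values, dtype=np.float64)
    for latent, _ in ensemble.runs:
        if latent.feature_ids != first.feature_ids:
            raise ValueError("runs disagree on latent features")
        acc += latent.values > activation_threshold
    acc /= ensemble.n_runs
    return FrequencyMatrix(
        values=acc,
        feature_ids=list(first.feature_ids),
        cell_ids=list(first.cell_ids),
        activation_threshold=activation_threshold,
        n_runs=ensemble.n_runs,
    )
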