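import numpy as np
import pytest

from scamine import (
    ConnectivityMask,
    CountsMatrix,
    LatentMatrix,
    Partition,
    RunEnsemble,
    SyntheticSpec,
    build_mask,
    generate_synthetic_dataset,
    normalize_counts,
)


def make_counts(values, layer_tag="raw", gene_prefix="g", cell_prefix="c"):
    values = np.asarray(values, dtype=float)
    return CountsMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{cell_prefix}{j}" for j in range(values.shape[1])],
        layer_tag=layer_tag,
    )


def forced_ensemble(partitions, n_features=3, master_seed=0):
    """RunEnsemble whose latent matrices are placeholders and whose
    partitions are given explicitly (for metric endpoint tests)."""
    cells = partitions[0].cell_ids
    runs = []
    for i, p in enumerate(partitions):
        lat = LatentMatrix(
            np.ones((len(cells), n_features)),
            [f"F{k}" for k in range(n_features)],
            list(cells),
            run_id=i,
        )
        runs.append((lat, p))
    return RunEnsemble(runs=runs, master_seed=master_seed,
                       run_seeds=list(range(len(partitions))))


@pytest.fixture
def planted_toy():
    """Two disjoint 10-gene programs, 60 cells, strong block expression."""
    spec = SyntheticSpec(
        n_clusters=2, n_cells_per_cluster=30, n_genes=100, n_explained=2,
        program_size=10, seed=42, depth_sigma=0.0,
    )
    return generate_synthetic_dataset(spec)


@pytest.fixture
def planted_training(planted_toy):
    """log10-normalized counts restricted to mask genes, plus the mask."""
    counts = normalize_counts(planted_toy.counts, "log10")
    mask = build_mask(planted_toy.knowledge, counts.gene_ids)
    rows = np.flatnonzero(mask.mask.sum(axis=1) > 0)
    restricted = counts.subset_genes(rows)
    mask = ConnectivityMask(
        genes=list(restricted.gene_ids),
        features=mask.features,
        mask=mask.mask[rows, :],
    )
    return restricted, mask, planted_toy


def knowledge_file(tmp_path, lines, name="knowledge.tsv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
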