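"""Biological-knowledge tables and the autoencoder connectivity mask.

A knowledge table links latent-space features (transcription factors,
miRNAs, kinases, gene signatures) to their target genes with a literature
reference per edge.  The tables are plain UTF-8 TSV files with columns
``feature_id``, ``gene_symbol``, ``reference`` (further columns are
ignored).  Several tables can be merged into one latent space (the SSCA
construction); the merged map is then intersected with the genes actually
present in a counts matrix to yield the binary genes x features
connectivity mask that constrains the autoencoder weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("scamine")

#: first-column values that identify a header line rather than an edge
_HEADER_KEYWORDS = {
    "feature", "feature_id", "featureid", "id", "source", "tf", "mirna",
    "kinase", "signature", "node",
}


@dataclass
class KnowledgeMap:
    """Latent feature -> target-gene relation with per-edge provenance.

    Parameters
    ----------
    features
        Ordered feature identifiers (one latent node each).
    edges
        Mapping ``feature -> set of target gene symbols``; every feature
        has at least one target.
    provenance
        Mapping ``(feature, gene) -> literature reference string``.
    """

    features: list[str]
    edges: dict[str, set[str]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != len(set(self.features)):
            raise ValueError("duplicate feature identifiers")
        for f in self.features:
            targets = self.edges.get(f, set())
            if not targets:
                raise ValueError(f"feature {f!r} has no target genes")
            if not f:
                raise ValueError("empty feature identifier")
            if any(not g for g in targets):
                raise ValueError(f"feature {f!r} has an empty gene symbol")

    @property
    def n_edges(self) -> int:
        return sum(len(self.edges[f]) for f in self.features)


@dataclass
class ConnectivityMask:
    """Binary genes x features incidence matrix for the masked autoencoder.

    ``mask[g, f] = 1`` iff gene ``g`` is a curated target of feature ``f``.
    Row order matches the counts-matrix gene order exactly; every feature
    column has at least one nonzero entry.
    """

    genes: list[str]
    features: list[str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.shape != (len(self.genes), len(self.features)):
            raise ValueError("mask shape does not match gene/feature lists")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        if len(self.features) and (self.mask.sum(axis=0) == 0).any():
            raise ValueError("mask has a feature with no connected gene")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.mask, index=self.genes, columns=self.features).to_csv(
            path, sep="\t", index_label="gene"
        )


def parse_knowledge_table(path: str | Path, strict: bool = False) -> KnowledgeMap:
    """Parse a tab-delimited feature/gene/reference table.

    Lines starting with ``#`` are comments; a first line whose first field
    is a recognized header keyword is skipped.  The third (reference)
    column is compulsory: a line without it raises under ``strict`` and is
    accepted with a warning (empty provenance) otherwise.  Duplicate
    (feature, gene) rows collapse to a single edge, so line order never
    affects the result.
    """
    path = Path(path)
    features: list[str] = []
    edges: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], str] = {}

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].strip().lower() in _HEADER_KEYWORDS:
                continue
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise ValueError(
                    f"{path.name}:{lineno}: expected at least feature and gene columns"
                )
            if len(cols) < 3 or not cols[2].strip():
                if strict:
                    raise ValueError(
                        f"{path.name}:{lineno}: reference column is compulsory"
                    )
                logger.warning(
                    "%s:%d: missing reference column (accepted, strict=False)",
                    path.name, lineno,
                )
                ref = ""
            else:
                ref = cols[2].strip()
            feat, gene = cols[0].strip(), cols[1].strip()
            if feat not in edges:
                features.append(feat)
                edges[feat] = set()
            if gene not in edges[feat]:
                edges[feat].add(gene)
                provenance[(feat, gene)] = ref
    if not features:
        raise ValueError(f"{path}: no knowledge edges")
    return KnowledgeMap(features=features, edges=edges, provenance=provenance)


def merge_knowledge(
    maps: Sequence[KnowledgeMap], labels: Sequence[str] | None = None
) -> KnowledgeMap:
    """Union of several knowledge sources (the SSCA latent space).

    Feature identifiers appearing in more than one source are kept as
    separate latent nodes and disambiguated as ``"<id>|<label>"`` so that
    distinct entities sharing a name (e.g. a TF and a signature) are never
    silently pooled.  ``labels`` default to ``src1, src2, ...``.
    """
    if not maps:
        raise ValueError("merge_knowledge requires at least one KnowledgeMap")
    if labels is None:
        labels = [f"src{i + 1}" for i in range(len(maps))]
    if len(labels) != len(maps):
        raise ValueError("one label per source map required")
    if len(maps) == 1:
        return maps[0]

    counts: dict[str, int] = {}
    for m in maps:
        for f in m.features:
            counts[f] = counts.get(f, 0) + 1

    features: list[str] = []
    edges: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], str] = {}
    for m, label in zip(maps, labels):
        for f in m.features:
            name = f if counts[f] == 1 else f"{f}|{label}"
            if name in edges:  # collision within one source label
                raise ValueError(f"feature {name!r} duplicated after renaming")
            features.append(name)
            edges[name] = set(m.edges[f])
            for g in m.edges[f]:
                provenance[(name, g)] = m.provenance.get((f, g), "")
    return KnowledgeMap(features=features, edges=edges, provenance=provenance)


def build_mask(
    kmap: KnowledgeMap,
    genes: Sequence[str],
    min_targets: int = 2,
    case_insensitive: bool = False,
) -> ConnectivityMask:
    """Intersect a KnowledgeMap with the dataset genes to get the mask.

    Features whose matched-target count falls below ``min_targets`` are
    dropped with a warning (a one-gene latent node degenerates to a gene
    copy).  Gene matching is exact and case-sensitive unless
    ``case_insensitive`` is set.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    if case_insensitive:
        index = {g.upper(): i for i, g in enumerate(genes)}
        lookup = lambda g: index.get(g.upper())  # noqa: E731
    else:
        index = {g: i for i, g in enumerate(genes)}
        lookup = index.get

    kept_features: list[str] = []
    columns: list[np.ndarray] = []
    dropped = 0
    for f in kmap.features:
        col = np.zeros(len(genes), dtype=np.int8)
        for g in kmap.edges[f]:
            i = lookup(g)
            if i is not None:
                col[i] = 1
        if int(col.sum()) >= min_targets:
            kept_features.append(f)
            columns.append(col)
        else:
            dropped += 1
            logger.warning(
                "feature %s dropped: %d matched target(s) < min_targets=%d",
                f, int(col.sum()), min_targets,
            )
    if not kept_features:
        raise ValueError("knowledge does not overlap dataset genes")
    mask = np.column_stack(columns)
    logger.info(
        "connectivity mask: %d features kept, %d dropped, %d edges matched",
        len(kept_features), dropped, int(mask.sum()),
    )
    return ConnectivityMask(genes=genes, features=kept_features, mask=mask)
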