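"""GO protein-complex aggregation of screen hits and heatmap clustering.

Hits are mapped onto Pombase-style GO complex annotations to build a
complex x (context, phenotype) counts matrix: each entry is the number of
distinct hit genes annotated to that complex for that column. A gene
annotated to a complex under several evidence codes counts once; a gene in
m complexes contributes to m rows. The matrix is ordered by hierarchical
clustering with a silhouette-guided column cut (rows stay uncut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from ._errors import ClusteringDegenerateWarning

_ANNOT_COLS = [
    "gene_systematic_id",
    "gene_name",
    "go_complex_id",
    "go_complex_name",
    "evidence_code",
]


@dataclass
class AnnotationTable:
    """Gene -> GO complex annotation with dual-key (name/systematic) lookup."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ANNOT_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        self.df = self.df[_ANNOT_COLS].astype(str)
        # name -> systematic id map; lookup by either key resolves identically
        self._by_name = dict(
            zip(self.df["gene_name"], self.df["gene_systematic_id"])
        )
        self._systematic = set(self.df["gene_systematic_id"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def resolve(self, gene: str) -> str | None:
        """Systematic id for a gene given by name or systematic id."""
        if gene in self._systematic:
            return gene
        return self._by_name.get(gene)

    def complexes_of(self, systematic_id: str) -> set[str]:
        sub = self.df[self.df["gene_systematic_id"] == systematic_id]
        return set(sub["go_complex_id"])

    def complex_name(self, complex_id: str) -> str:
        sub = self.df[self.df["go_complex_id"] == complex_id]
        return sub["go_complex_name"].iloc[0] if len(sub) else complex_id


def count_go_complexes(
    hits: Mapping[tuple[str, str], set[str]],
    annot: AnnotationTable,
) -> pd.DataFrame:
    """Complex x (context, phenotype) matrix of distinct-hit-gene counts.

    ``hits`` maps each (context, phenotype) column to its hit gene set (names
    or systematic ids). Genes that cannot be resolved against the annotation
    are logged and excluded. Rows are restricted to complexes hit at least
    once; an empty hit map yields an empty matrix.
    """
    columns = sorted(hits)
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for col in columns:
        seen: dict[str, set[str]] = {}
        for gene in hits[col]:
            sid = annot.resolve(gene)
            if sid is None:
                warnings.warn(
                    f"gene {gene!r} not in annotation; excluded from counts",
                    stacklevel=2,
                )
                continue
            for cx in annot.complexes_of(sid):
                seen.setdefault(cx, set()).add(sid)
        for cx, genes in seen.items():
            counts.setdefault(cx, {})[col] = len(genes)
    index = sorted(counts)
    mat = pd.DataFrame(0, index=index, columns=pd.MultiIndex.from_tuples(
        columns, names=["context", "phenotype"]
    ) if columns else [], dtype=int)
    for cx, row in counts.items():
        for col, v in row.items():
            mat.loc[cx, col] = v
    return mat


def build_hit_table(
    complex_gene_lists: Mapping[str, Sequence[str]],
    hits: Mapping[tuple[str, str], set[str]],
    *,
    screened_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene hit status table for named complexes.

    Rows are (complex, gene); columns are contexts. Entries: ``loss``,
    ``gain``, ``both`` (hit for loss and gain in the same context),
    ``not_hit``, or ``not_screened`` when the gene is absent from the screen
    library. Gene lists may include manual additions beyond the annotation.
    """
    contexts = sorted({c for c, _ in hits})
    rows = []
    for cx_name, genes in sorted(complex_gene_lists.items()):
        for gene in genes:
            row: dict[str, str] = {"complex": cx_name, "gene": gene}
            screened = screened_genes is None or gene in screened_genes
            for ctx in contexts:
                if not screened:
                    row[ctx] = "not_screened"
                    continue
                loss = gene in hits.get((ctx, "loss"), set())
                gain = gene in hits.get((ctx, "gain"), set())
                row[ctx] = (
                    "both" if loss and gain
                    else "loss" if loss
                    else "gain" if gain
                    else "not_hit"
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=["complex", "gene", *contexts])


def _silhouette_best_k(
    points: np.ndarray, link: np.ndarray, k_range: Sequence[int]
) -> tuple[int, dict[int, float]]:
    scores: dict[int, float] = {}
    for k in k_range:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(points, labels, metric="euclidean"))
    if not scores:
        return 1, scores
    # max score; ties broken toward the smaller k for determinism
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


@dataclass(frozen=True)
class ClusterResult:
    """Row/column leaf orders and the silhouette-cut column labels."""

    row_order: list
    col_order: list
    col_labels: dict
    k: int
    silhouette_scores: dict[int, float]


def cluster_counts(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster the counts matrix; cut columns by silhouette.

    Euclidean distance with complete linkage on both axes. Columns are cut at
    the k in 2..min(6, n_cols-1) maximizing the mean silhouette score; the
    row dendrogram is ordered but left uncut. Input row/column order does not
    affect the result: rows and columns are canonicalized by label before
    clustering, so the output is deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to cluster")
    mat = matrix.sort_index(axis=0).sort_index(axis=1)
    values = mat.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn(
            "constant counts matrix; returning label order",
            ClusteringDegenerateWarning,
            stacklevel=2,
        )
        return ClusterResult(
            row_order=list(mat.index),
            col_order=list(mat.columns),
            col_labels={c: 1 for c in mat.columns},
            k=1,
            silhouette_scores={},
        )
    row_link = hierarchy.linkage(values, method="complete", metric="euclidean")
    col_link = hierarchy.linkage(
        values.T, method="complete", metric="euclidean"
    )
    row_order = [
        mat.index[i] for i in hierarchy.leaves_list(row_link)
    ]
    col_order = [
        mat.columns[i] for i in hierarchy.leaves_list(col_link)
    ]
    k_range = range(2, min(6, mat.shape[1] - 1) + 1)
    k, scores = _silhouette_best_k(values.T, col_link, list(k_range))
    if k == 1:
        labels = {c: 1 for c in mat.columns}
    else:
        flat = hierarchy.fcluster(col_link, t=k, criterion="maxclust")
        labels = {c: int(lbl) for c, lbl in zip(mat.columns, flat)}
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        col_labels=labels,
        k=k,
        silhouette_scores=scores,
    )
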