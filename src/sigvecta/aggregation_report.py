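"""Collection-level aggregation: gene matrix, PCA, clustering, report bundle.

A signature collection is aggregated by treating each signature as a column
vector and concatenating the columns with an outer join on gene symbols;
genes absent from a signature are filled with 0, meaning "no change in
expression".  On top of that matrix:

* row filters keep the genes with the greatest sum of change across
  signatures (top n per tail) or the greatest row variance;
* PCA treats signatures as observations and genes as mean-centered,
  unscaled features, keeping the top three components;
* heatmap row/column orders come from average-linkage hierarchical
  clustering on cosine distance (the default of interactive clustergram
  tools);
* :func:`build_report` orchestrates all matrices (genes, enrichment terms,
  compounds), the PCA block, optional sub-collection selection and metadata
  categorization, and writes a manifest + TSV bundle.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .core_io import (
    AggregateMatrix,
    CompoundSignatureLibrary,
    GeneSetLibrary,
    SignatureCollection,
    write_report_matrix,
)
from .enrichment import EnrichmentConfig, build_enrichment_matrix
from .compound_match import build_compound_matrix

logger = logging.getLogger("sigvecta")

__all__ = [
    "ReportConfig",
    "PCAResult",
    "ReportBundle",
    "build_gene_matrix",
    "filter_rows",
    "pca_signatures",
    "cluster_order",
    "build_report",
    "write_report",
]


@dataclass
class ReportConfig:
    """Knobs of the report pipeline (echoed into the manifest)."""

    alpha: float = 0.01
    seed: int = 0
    gene_filter_statistic: str = "sum_change"
    gene_top_n_per_tail: int = 10
    significant_genes_only: bool = False
    top_terms: int = 50
    n_calibration_draws: int = 300
    top_k_compounds: int = 50
    min_overlap: int = 10
    cluster_linkage: str = "average"
    cluster_metric: str = "cosine"


@dataclass
class PCAResult:
    signature_ids: list[str]
    coordinates: np.ndarray  # n_signatures × 3
    variance_explained: np.ndarray  # length 3, non-increasing, sums to ≤ 1
    categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)


@dataclass
class ReportBundle:
    tag: str
    pca: PCAResult
    gene_matrix: AggregateMatrix
    enrichment_matrix: AggregateMatrix
    compound_matrix: AggregateMatrix
    config: dict
    timestamp: str = ""


def build_gene_matrix(
    collection: SignatureCollection,
    significant_only: bool = False,
    alpha: float = 0.01,
) -> AggregateMatrix:
    """Gene × signature matrix of CD coefficients (outer join, zero fill).

    Rows are the lexicographically sorted union of genes across signatures;
    a zero cell means the gene is absent from that signature (no change).
    With ``significant_only`` the stored vector is restricted to genes with
    BH-adjusted p ≤ alpha before joining.
    """
    collection.require_nonempty()
    row_labels = collection.gene_union()
    row_index = {g: i for i, g in enumerate(row_labels)}
    values = np.zeros((len(row_labels), len(collection)))
    for j, sig in enumerate(collection):
        for g, c in sig.gene_coeffs.items():
            if significant_only:
                padj = sig.adjusted_pvalues.get(g)
                if padj is None or padj > alpha:
                    continue
            values[row_index[g], j] = c
    return AggregateMatrix(
        row_labels=row_labels, column_labels=collection.ids, values=values
    )


def filter_rows(
    matrix: AggregateMatrix,
    statistic: str,
    top_n_per_tail: int | None = None,
    top_n: int | None = None,
) -> AggregateMatrix:
    """Keep the most informative rows of an aggregate matrix.

    ``sum_change`` ranks rows by row sum and keeps the ``top_n_per_tail``
    most positive and most negative rows (both tails); ``variance`` keeps
    the ``top_n`` rows with the greatest row variance.  Ties are broken by
    row label.  Original row order is preserved among kept rows.
    """
    n_rows = len(matrix.row_labels)
    if statistic == "sum_change":
        if top_n_per_tail is None or top_n_per_tail < 1:
            raise ValueError("sum_change filtering requires top_n_per_tail ≥ 1")
        if 2 * top_n_per_tail >= n_rows:
            warnings.warn(
                f"requested 2×{top_n_per_tail} rows of {n_rows}; keeping all",
                stacklevel=2,
            )
            return AggregateMatrix(
                list(matrix.row_labels), list(matrix.column_labels), matrix.values.copy()
            )
        sums = matrix.values.sum(axis=1)
        by_desc = sorted(range(n_rows), key=lambda i: (-sums[i], matrix.row_labels[i]))
        by_asc = sorted(range(n_rows), key=lambda i: (sums[i], matrix.row_labels[i]))
        keep = set(by_desc[:top_n_per_tail]) | set(by_asc[:top_n_per_tail])
    elif statistic == "variance":
        if top_n is None or top_n < 1:
            raise ValueError("variance filtering requires top_n ≥ 1")
        if top_n >= n_rows:
            warnings.warn(
                f"requested {top_n} rows of {n_rows}; keeping all", stacklevel=2
            )
            return AggregateMatrix(
                list(matrix.row_labels), list(matrix.column_labels), matrix.values.copy()
            )
        variances = matrix.values.var(axis=1)
        order = sorted(range(n_rows), key=lambda i: (-variances[i], matrix.row_labels[i]))
        keep = set(order[:top_n])
    else:
        raise ValueError("statistic must be 'sum_change' or 'variance'")
    kept = [i for i in range(n_rows) if i in keep]
    return AggregateMatrix(
        row_labels=[matrix.row_labels[i] for i in kept],
        column_labels=list(matrix.column_labels),
        values=matrix.values[kept],
    )


def pca_signatures(matrix: AggregateMatrix) -> PCAResult:
    """Three-component PCA of the signatures (columns) of a gene matrix.

    Signatures are observations, genes are features; features are
    mean-centered but not variance-scaled.  With fewer than three
    signatures (or features) the missing components are zero-padded.
    Component signs are fixed by making the largest-magnitude gene loading
    positive so coordinates are reproducible.
    """
    X = matrix.values.T.astype(float)  # signatures × genes
    n, n_features = X.shape
    if n == 0:
        raise ValueError("matrix has no signature columns")
    if n < 3:
        warnings.warn(
            f"only {n} signatures; missing PCA components padded with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, 3))
    ve = np.zeros(3)
    k = min(3, n, n_features)
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    if k >= 1 and total_var > 1e-12:
        pca = PCA(n_components=k, svd_solver="full")
        Y = pca.fit_transform(X)
        comps = pca.components_
        for j in range(k):
            i = int(np.argmax(np.abs(comps[j])))
            if comps[j, i] < 0:
                Y[:, j] = -Y[:, j]
        coords[:, :k] = Y
        ve[:k] = pca.explained_variance_ratio_
    return PCAResult(
        signature_ids=list(matrix.column_labels),
        coordinates=coords,
        variance_explained=ve,
    )


def _cosine_distance_matrix(V: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance; zero-norm vectors are distance 1 to everything."""
    norms = np.linalg.norm(V, axis=1)
    D = np.ones((V.shape[0], V.shape[0]))
    ok = norms > 0.0
    if ok.any():
        G = V[ok] @ V[ok].T
        denom = np.outer(norms[ok], norms[ok])
        D[np.ix_(ok, ok)] = 1.0 - G / denom
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cluster_order(matrix: AggregateMatrix, axis: str) -> np.ndarray:
    """Dendrogram leaf order for heatmap display.

    Average-linkage agglomerative clustering on cosine distance; the input
    vectors are pre-sorted by label so the ordering is deterministic under
    any permutation of the input (label-determinism).
    """
    if axis == "rows":
        vectors, labels = matrix.values, matrix.row_labels
    elif axis == "columns":
        vectors, labels = matrix.values.T, matrix.column_labels
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    if len(labels) < 2:
        raise ValueError(f"clustering needs at least 2 {axis}")
    order0 = sorted(range(len(labels)), key=lambda i: labels[i])
    D = _cosine_distance_matrix(np.asarray(vectors, dtype=float)[order0])
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return np.array([order0[i] for i in leaves])


def _safe_orders(matrix: AggregateMatrix) -> AggregateMatrix:
    """Attach cluster orders where the axis allows it, identity otherwise."""
    n_rows, n_cols = matrix.shape
    row_order = cluster_order(matrix, "rows") if n_rows >= 2 else np.arange(n_rows)
    col_order = cluster_order(matrix, "columns") if n_cols >= 2 else np.arange(n_cols)
    matrix.row_order = row_order
    matrix.column_order = col_order
    return matrix


def build_report(
    collection: SignatureCollection,
    library: GeneSetLibrary,
    compound_library: CompoundSignatureLibrary,
    config: ReportConfig | None = None,
    subset: list[str] | None = None,
    category: str | None = None,
) -> ReportBundle:
    """Assemble the full multi-view report for a signature collection.

    Optionally restricts to a subset of signature ids (custom report) and
    attaches a metadata-field category to every PCA point.  The bundle holds
    the PCA block and three clustered matrices: filtered gene coefficients,
    enrichment combined scores, and compound similarities.  Fully
    deterministic given ``config.seed``.
    """
    collection.require_nonempty()
    config = config or ReportConfig()
    if subset is not None:
        collection = collection.subset(subset)
    categories = None
    if category is not None:
        available = collection.metadata_fields()
        if category not in available:
            raise ValueError(
                f"unknown metadata field {category!r}; available fields: {available}"
            )
        categories = [str(s.metadata.get(category, "")) for s in collection]

    full_gene = build_gene_matrix(
        collection, significant_only=config.significant_genes_only, alpha=config.alpha
    )
    pca = pca_signatures(full_gene)
    pca.categories = categories

    if config.gene_filter_statistic == "variance":
        gene_matrix = filter_rows(
            full_gene, "variance", top_n=2 * config.gene_top_n_per_tail
        )
    else:
        gene_matrix = filter_rows(
            full_gene, "sum_change", top_n_per_tail=config.gene_top_n_per_tail
        )
    enr_config = EnrichmentConfig(
        top_terms=config.top_terms,
        n_calibration_draws=config.n_calibration_draws,
        seed=config.seed,
    )
    enrichment_matrix = build_enrichment_matrix(
        collection, library, alpha=config.alpha, config=enr_config
    )
    compound_matrix = build_compound_matrix(
        collection, compound_library, top_k=config.top_k_compounds,
        min_overlap=config.min_overlap,
    )
    for m in (gene_matrix, enrichment_matrix, compound_matrix):
        if m.values.size:
            _safe_orders(m)
    return ReportBundle(
        tag=collection.tag,
        pca=pca,
        gene_matrix=gene_matrix,
        enrichment_matrix=enrichment_matrix,
        compound_matrix=compound_matrix,
        config=asdict(config),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, str]:
    """Write the bundle as a JSON manifest plus three matrix TSVs.

    Returns the mapping of matrix names to written file names.  The manifest
    is byte-reproducible for identical inputs and seed except for its
    ``timestamp`` field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, matrix in (
        ("genes", bundle.gene_matrix),
        ("enrichment", bundle.enrichment_matrix),
        ("compounds", bundle.compound_matrix),
    ):
        fname = f"{name}.tsv"
        path = out / fname
        if matrix.values.size:
            write_report_matrix(matrix, path)
        else:  # degenerate collection: keep the bundle complete with a header
            with open(path, "w") as fh:
                fh.write("\t".join([""] + list(matrix.column_labels)) + "\n")
        files[name] = fname
    manifest = {
        "tag": bundle.tag,
        "config": bundle.config,
        "files": files,
        "pca": {
            "signature_ids": bundle.pca.signature_ids,
            "coordinates": [[float(v) for v in row] for row in bundle.pca.coordinates],
            "variance_explained": [float(v) for v in bundle.pca.variance_explained],
            "categories": bundle.pca.categories,
        },
        "clustering": {
            name: {
                "row_order": None if m.row_order is None else [int(i) for i in m.row_order],
                "column_order": None
                if m.column_order is None
                else [int(i) for i in m.column_order],
            }
            for name, m in (
                ("genes", bundle.gene_matrix),
                ("enrichment", bundle.enrichment_matrix),
                ("compounds", bundle.compound_matrix),
            )
        },
        "timestamp": bundle.timestamp,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return files
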