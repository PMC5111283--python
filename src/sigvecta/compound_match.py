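"""Cosine-similarity matching against compound signature libraries.

A query signature is compared with every compound-induced signature of a
LINCS-L1000-style library by cosine similarity on the intersection of the
query's genes with the library's gene space.  Compounds with positive
similarity *mimic* the query expression pattern; compounds with negative
similarity *reverse* it.  The cosine distance d ∈ [0, 2] and the similarity
s = 1 − d ∈ [1, −1] carry the same information; this module reports s.

Per signature the top 50 mimickers (descending s, s > 0) and top 50
reversers (ascending s, s < 0) are kept; a collection-level compound ×
signature matrix holds the signed similarities with zeros for compounds
absent from a signature's lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import AggregateMatrix, CompoundSignatureLibrary, GeneSignature, SignatureCollection

logger = logging.getLogger("sigvecta")

__all__ = [
    "CompoundMatch",
    "cosine_similarity",
    "search_compounds",
    "build_compound_matrix",
]

DEFAULT_MIN_OVERLAP = 10


@dataclass
class CompoundMatch:
    compound_id: str
    similarity: float
    mode: str  # "mimic" or "reverse"
    n_overlap: int


def _shared_query_vector(
    query: GeneSignature, gene_space: tuple[str, ...], min_overlap: int
):
    """Query coefficients on the query ∩ library gene intersection, or None."""
    mask = np.array([g in query.gene_coeffs for g in gene_space], dtype=bool)
    n_overlap = int(mask.sum())
    if n_overlap < min_overlap:
        warnings.warn(
            f"gene overlap {n_overlap} below the minimum {min_overlap}; "
            "match skipped",
            stacklevel=3,
        )
        return None, None, n_overlap
    v = np.array([query.gene_coeffs[g] for g, m in zip(gene_space, mask) if m])
    return mask, v, n_overlap


def cosine_similarity(
    query: GeneSignature,
    gene_space,
    compound_vector,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float | None:
    """Cosine similarity s ∈ [−1, 1] over the shared gene space.

    Returns None (with a warning) when the overlap is below ``min_overlap``
    or either restricted vector has zero norm.
    """
    gene_space = tuple(g.upper() for g in gene_space)
    mask, v, _ = _shared_query_vector(query, gene_space, min_overlap)
    if mask is None:
        return None
    u = np.asarray(compound_vector, dtype=float)[mask]
    vnorm = np.linalg.norm(v)
    unorm = np.linalg.norm(u)
    if vnorm == 0.0 or unorm == 0.0:
        warnings.warn("zero-norm vector on the shared gene space; match skipped",
                      stacklevel=2)
        return None
    return float(np.clip(v @ u / (vnorm * unorm), -1.0, 1.0))


def search_compounds(
    query: GeneSignature,
    library: CompoundSignatureLibrary,
    top_k: int = 50,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[list[CompoundMatch], list[CompoundMatch]]:
    """Top mimickers and reversers of a query signature.

    Mimickers are the ``top_k`` compounds by descending similarity with
    s > 0; reversers the ``top_k`` by ascending similarity with s < 0.
    Compounds with s = 0 exactly appear in neither list.  Ties are broken by
    compound id.
    """
    if len(library) == 0:
        raise ValueError("compound library is empty")
    mask, v, n_overlap = _shared_query_vector(query, library.gene_space, min_overlap)
    if mask is None:
        return [], []
    vnorm = np.linalg.norm(v)
    if vnorm == 0.0:
        warnings.warn("query has zero norm on the shared gene space", stacklevel=2)
        return [], []
    ids = library.compound_ids
    U = np.stack([library.vectors[c][mask] for c in ids], axis=1)
    unorms = np.linalg.norm(U, axis=0)
    valid = unorms > 0.0
    sims = np.zeros(len(ids))
    sims[valid] = np.clip((U[:, valid].T @ v) / (unorms[valid] * vnorm), -1.0, 1.0)
    matches = [
        (cid, float(s))
        for cid, s, ok in zip(ids, sims, valid)
        if ok
    ]
    mimickers = sorted(
        ((cid, s) for cid, s in matches if s > 0.0), key=lambda t: (-t[1], t[0])
    )[:top_k]
    reversers = sorted(
        ((cid, s) for cid, s in matches if s < 0.0), key=lambda t: (t[1], t[0])
    )[:top_k]
    return (
        [CompoundMatch(cid, s, "mimic", n_overlap) for cid, s in mimickers],
        [CompoundMatch(cid, s, "reverse", n_overlap) for cid, s in reversers],
    )


def build_compound_matrix(
    collection: SignatureCollection,
    library: CompoundSignatureLibrary,
    top_k: int = 50,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> AggregateMatrix:
    """Compound × signature matrix of signed similarities.

    Rows are the union of compounds appearing in any signature's mimic or
    reverse list (sorted); cells hold the similarity (positive for
    mimickers, negative for reversers) and 0 for compounds absent from a
    signature's lists.
    """
    collection.require_nonempty()
    per_signature: list[dict[str, float]] = []
    for sig in collection:
        mimickers, reversers = search_compounds(sig, library, top_k, min_overlap)
        per_signature.append(
            {m.compound_id: m.similarity for m in mimickers + reversers}
        )
    row_labels = sorted({cid for cells in per_signature for cid in cells})
    row_index = {cid: i for i, cid in enumerate(row_labels)}
    values = np.zeros((len(row_labels), len(collection)))
    for j, cells in enumerate(per_signature):
        for cid, s in cells.items():
            values[row_index[cid], j] = s
    return AggregateMatrix(
        row_labels=row_labels, column_labels=collection.ids, values=values
    )
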