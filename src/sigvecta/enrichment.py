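"""Enrichment-vector analysis over gene-set libraries.

Each signature is split into up- and down-regulated gene sets and each set is
tested against every term of a gene-set library.  Terms are prioritized by
the combined score c = ln(p) · z, the Enrichr-style statistic that multiplies
the log of the hypergeometric upper-tail p-value by a z-score for the
deviation of the term's rank from its expected rank under random queries of
the same size.  A strongly enriched term has both a small p (ln p ≪ 0) and a
much-better-than-expected rank (z < 0), so c is large and positive.

Expected ranks are not published constants; they are calibrated here by
Monte Carlo: random query sets are drawn from the background universe, all
terms are ranked by ascending p each draw (ties broken by term name), and
the per-term mean and standard deviation of the rank are recorded.  To bound
cost, calibrations are bucketed by query size rounded to the nearest 10.

Per signature and direction only the top 50 terms by combined score are
retained; the retained records across a collection are assembled into a
term × signature matrix (outer join, zeros for missing pairs) with columns
``<signature_id>|up`` and ``<signature_id>|down``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import AggregateMatrix, GeneSetLibrary, SignatureCollection
from .chdir import split_up_down

logger = logging.getLogger("sigvecta")

__all__ = [
    "EnrichmentConfig",
    "EnrichmentRecord",
    "RankCalibration",
    "hypergeom_p",
    "calibrate_ranks",
    "enrich_gene_set",
    "build_enrichment_matrix",
]

_P_FLOOR = 1e-300  # keeps ln(p) finite


@dataclass
class EnrichmentConfig:
    top_terms: int = 50
    n_calibration_draws: int = 300
    sigma_floor: float = 0.1
    bucket_width: int = 10
    seed: int = 0


@dataclass
class EnrichmentRecord:
    """One term's enrichment result for one query (direction-tagged)."""

    term: str
    overlap: int
    p: float
    rank: int
    z: float
    combined: float
    direction: str


@dataclass
class RankCalibration:
    """Per-term null rank statistics for random queries of a given size."""

    terms: tuple[str, ...]  # lexicographic order
    mean_rank: np.ndarray
    sd_rank: np.ndarray
    query_size: int
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.mean_rank = np.asarray(self.mean_rank, dtype=float)
        self.sd_rank = np.asarray(self.sd_rank, dtype=float)


def hypergeom_p(background: int, term_size: int, query_size: int, overlap: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ overlap).

    ``background`` is the universe size N, ``term_size`` the number of
    successes K in the universe, ``query_size`` the number of draws q.
    """
    _check_counts(background, term_size, query_size, overlap)
    p = float(stats.hypergeom.sf(overlap - 1, background, term_size, query_size))
    return min(max(p, _P_FLOOR), 1.0)


def _check_counts(N: int, K: int, q: int, x: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"term size {K} outside [0, background {N}]")
    if not (0 <= q <= N):
        raise ValueError(f"query size {q} outside [0, background {N}]")
    if x < 0 or x > K or x > q:
        raise ValueError(f"overlap {x} inconsistent with term {K} / query {q}")


def _membership(library: GeneSetLibrary):
    """Lexicographic term list, sorted gene-union list and bool membership matrix."""
    terms = sorted(library.sets)
    union = sorted(library.gene_union())
    index = {g: i for i, g in enumerate(union)}
    M = np.zeros((len(terms), len(union)), dtype=bool)
    for t, term in enumerate(terms):
        for g in library.sets[term]:
            M[t, index[g]] = True
    return terms, union, M


def _ranks_by_p(p: np.ndarray) -> np.ndarray:
    """1-based ranks by ascending p; ties broken by lexicographic term order.

    ``p`` must be aligned with lexicographically sorted terms, so a stable
    sort realizes the tie-break.
    """
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=int)
    ranks[order] = np.arange(1, p.size + 1)
    return ranks


def calibrate_ranks(
    library: GeneSetLibrary,
    query_size: int,
    n_draws: int = 300,
    seed: int = 0,
    sigma_floor: float = 0.1,
) -> RankCalibration:
    """Monte-Carlo null distribution of per-term ranks for random queries.

    Draws ``n_draws`` uniform gene sets of size ``query_size`` from the
    background universe, ranks all terms by ascending hypergeometric p each
    draw, and records each term's mean and standard deviation of rank (the
    standard deviation is floored to avoid division blow-ups for terms with
    near-constant rank).
    """
    if n_draws < 50:
        raise ValueError("n_draws must be at least 50")
    if query_size > library.background_size:
        raise ValueError("query size exceeds the background universe")
    if query_size < 1:
        raise ValueError("query size must be positive")
    terms, union, M = _membership(library)
    N = library.background_size
    U = len(union)
    term_sizes = np.array([len(library.sets[t]) for t in terms])
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(len(terms))
    rank_sumsq = np.zeros(len(terms))
    for _ in range(n_draws):
        # genes outside the library union can never overlap a term; indices
        # 0..U-1 of the N-element universe are the union genes
        draw = rng.choice(N, size=query_size, replace=False)
        qvec = np.zeros(U, dtype=np.int64)
        qvec[draw[draw < U]] = 1
        overlaps = M @ qvec
        p = stats.hypergeom.sf(overlaps - 1, N, term_sizes, query_size)
        ranks = _ranks_by_p(np.clip(p, _P_FLOOR, 1.0))
        rank_sum += ranks
        rank_sumsq += ranks.astype(float) ** 2
    mu = rank_sum / n_draws
    var = np.maximum(rank_sumsq / n_draws - mu**2, 0.0)
    sd = np.maximum(np.sqrt(var), sigma_floor)
    return RankCalibration(
        terms=tuple(terms),
        mean_rank=mu,
        sd_rank=sd,
        query_size=query_size,
        n_draws=n_draws,
        seed=seed,
    )


def enrich_gene_set(
    query: set[str],
    library: GeneSetLibrary,
    calibration: RankCalibration,
    direction: str = "up",
    top_terms: int = 50,
) -> list[EnrichmentRecord]:
    """Enrichment of one gene set against a library, top terms by combined score.

    Query genes outside the library's gene union are dropped (warned); an
    empty query after the intersection yields an empty result.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    terms, union, M = _membership(library)
    if tuple(terms) != calibration.terms:
        raise ValueError("calibration does not match this library")
    query_upper = {g.upper() for g in query}
    kept = query_upper & set(union)
    n_dropped = len(query_upper) - len(kept)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} query genes outside the library background were dropped",
            stacklevel=2,
        )
    if not kept:
        warnings.warn("query is empty after background intersection", stacklevel=2)
        return []
    index = {g: i for i, g in enumerate(union)}
    qvec = np.zeros(len(union), dtype=np.int64)
    for g in kept:
        qvec[index[g]] = 1
    q = len(kept)
    N = library.background_size
    term_sizes = np.array([len(library.sets[t]) for t in terms])
    overlaps = M @ qvec
    p = np.clip(stats.hypergeom.sf(overlaps - 1, N, term_sizes, q), _P_FLOOR, 1.0)
    ranks = _ranks_by_p(p)
    z = (ranks - calibration.mean_rank) / calibration.sd_rank
    combined = np.log(p) * z
    records = [
        EnrichmentRecord(
            term=terms[t],
            overlap=int(overlaps[t]),
            p=float(p[t]),
            rank=int(ranks[t]),
            z=float(z[t]),
            combined=float(combined[t]),
            direction=direction,
        )
        for t in range(len(terms))
    ]
    records.sort(key=lambda r: (-r.combined, r.term))
    return records[:top_terms]


def _bucket(query_size: int, width: int) -> int:
    return max(1, int(round(query_size / width)) * width)


def build_enrichment_matrix(
    collection: SignatureCollection,
    library: GeneSetLibrary,
    alpha: float = 0.01,
    config: EnrichmentConfig | None = None,
) -> AggregateMatrix:
    """Term × signature combined-score matrix for a whole collection.

    The enrichment runs twice per signature — once for the up- and once for
    the down-regulated genes — giving columns ``<id>|up`` and ``<id>|down``.
    Rows are the union of retained terms (outer join); absent pairs are 0.
    """
    collection.require_nonempty()
    config = config or EnrichmentConfig()
    calibrations: dict[int, RankCalibration] = {}
    columns: list[str] = []
    column_records: list[list[EnrichmentRecord]] = []
    for sig in collection:
        up, down = split_up_down(sig, alpha)
        for direction, genes in (("up", up), ("down", down)):
            columns.append(f"{sig.id}|{direction}")
            if not genes:
                column_records.append([])
                continue
            q_eff = len({g for g in genes} & set(library.gene_union()))
            if q_eff == 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    column_records.append([])
                continue
            bucket = _bucket(q_eff, config.bucket_width)
            if bucket not in calibrations:
                cal_seed = (config.seed * 100003 + bucket) % (2**31)
                calibrations[bucket] = calibrate_ranks(
                    library,
                    query_size=min(bucket, library.background_size),
                    n_draws=config.n_calibration_draws,
                    seed=cal_seed,
                    sigma_floor=config.sigma_floor,
                )
            records = enrich_gene_set(
                genes, library, calibrations[bucket], direction, config.top_terms
            )
            column_records.append(records)
    row_labels = sorted({r.term for records in column_records for r in records})
    row_index = {t: i for i, t in enumerate(row_labels)}
    values = np.zeros((len(row_labels), len(columns)))
    for j, records in enumerate(column_records):
        for r in records:
            values[row_index[r.term], j] = r.combined
    return AggregateMatrix(row_labels=row_labels, column_labels=columns, values=values)
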