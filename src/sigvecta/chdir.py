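"""Characteristic-direction differential expression.

The characteristic direction (CD) is a multivariate differential-expression
statistic: regularized linear discriminant analysis finds the hyperplane that
maximally separates control from perturbation samples in gene-expression
space, and each gene's coefficient on the unit normal of that hyperplane is
its differential-expression score.  Compared with per-gene statistics this
puts less weight on the magnitude of change of an individual gene and more on
its direction of change relative to the other genes.

Computation (genes ≫ samples is the typical regime):

1. center the samples by the global mean;
2. project onto the right-singular directions of the centered data that carry
   numerically nonzero singular values — this is lossless (both the pooled
   within-class scatter and the class-mean difference live in that span) and
   makes the solve O(n_samples³);
3. form the pooled within-class covariance Σ in the reduced space and shrink
   it toward a scaled identity, Σ̃ = (1−γ)·Σ + γ·ν·I with ν = trace(Σ)/r;
4. solve Σ̃ b = μ_perturbation − μ_control, map back to gene space and
   normalize to unit Euclidean norm.

A positive coefficient means higher expression in the perturbation class.

Per-gene significance is not part of the CD statistic itself; here it comes
from a pooled permutation null on the per-gene class mean difference (the
gene-space quantity whose multivariate alignment the CD coefficient
measures): class labels are permuted preserving class sizes (the observed
labeling and its mirror excluded), the mean differences are recomputed, all
permuted values across genes are pooled into one null sample, and each
observed difference is scored against the normal tail of that null.  The
unit-norm CD coefficients themselves make a poor test statistic: the
normalization spreads their magnitude over all genes, so the pooled
empirical tail cannot resolve p-values small enough to survive multiple
testing at the sample sizes typical of deposited studies.  Nominal p-values
are Benjamini–Hochberg adjusted and thresholded (default 0.01) to split the
signature into up- and down-regulated gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionDataset, GeneSignature

logger = logging.getLogger("sigvecta")

__all__ = [
    "ChdirConfig",
    "characteristic_direction",
    "signature_pvalues",
    "bh_adjust",
    "split_up_down",
    "compute_signature",
]


@dataclass
class ChdirConfig:
    """Parameters of the CD pipeline.

    gamma : shrinkage weight in [0, 1] toward the scaled identity (default
        0.5); γ = 0 is the unregularized LDA solve and fails when the pooled
        covariance is singular.
    n_permutations : label permutations for the significance null (default
        1000; the space is enumerated exhaustively when smaller).
    alpha : BH-adjusted p-value threshold for calling a gene differentially
        expressed (default 0.01).
    """

    gamma: float = 0.5
    n_permutations: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


def _cd_vector(X: np.ndarray, pert_mask: np.ndarray, gamma: float) -> np.ndarray:
    """Unit CD vector for a genes × samples matrix and a perturbation mask."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Y = Xc.T  # samples × genes
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise ValueError("expression matrix has no variation between samples")
    tol = s[0] * max(Y.shape) * np.finfo(float).eps
    r = max(1, int(np.sum(s > tol)))
    V = Vt[:r].T  # genes × r
    R = Y @ V  # samples × r
    Rp = R[pert_mask]
    Rc = R[~pert_mask]
    n1, n2 = Rc.shape[0], Rp.shape[0]
    Sc = np.atleast_2d(np.cov(Rc, rowvar=False, ddof=1))
    Sp = np.atleast_2d(np.cov(Rp, rowvar=False, ddof=1))
    pooled = ((n1 - 1) * Sc + (n2 - 1) * Sp) / (n1 + n2 - 2)
    nu = float(np.trace(pooled)) / r
    shrunk = (1.0 - gamma) * pooled + gamma * nu * np.eye(r)
    dmu = Rp.mean(axis=0) - Rc.mean(axis=0)
    try:
        b_reduced = np.linalg.solve(shrunk, dmu)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular shrunken covariance; increase gamma above 0"
        ) from exc
    if not np.all(np.isfinite(b_reduced)):
        raise ValueError("singular shrunken covariance; increase gamma above 0")
    b = V @ b_reduced
    nrm = np.linalg.norm(b)
    if nrm == 0.0:
        raise ValueError("control and perturbation class means coincide")
    return b / nrm


def characteristic_direction(
    dataset: ExpressionDataset,
    config: ChdirConfig | None = None,
    signature_id: str = "signature",
    metadata: dict[str, str] | None = None,
) -> GeneSignature:
    """Compute the coefficient-only CD signature of a labeled dataset.

    Requires ≥ 2 samples per class and ≥ 2 genes.  The returned coefficient
    vector has unit Euclidean norm; positive coefficients mark genes with
    higher expression in the perturbation samples.
    """
    config = config or ChdirConfig()
    if dataset.n_genes < 2:
        raise ValueError("characteristic direction needs at least 2 genes")
    X = dataset.values.to_numpy(float)
    b = _cd_vector(X, dataset.perturbation_mask, config.gamma)
    meta = {"species": dataset.species, "platform": dataset.platform_id}
    if metadata:
        meta.update(metadata)
    return GeneSignature(
        id=signature_id,
        gene_coeffs={str(g).upper(): float(v) for g, v in zip(dataset.values.index, b)},
        metadata=meta,
    )


def _permutation_masks(
    n: int, n_pert: int, n_permutations: int, seed: int, observed: np.ndarray
):
    """Label assignments (perturbation masks) preserving class sizes.

    The observed labeling and its mirror (label swap) are excluded so the
    null is not contaminated by the signal being tested.  The space of
    distinct assignments is enumerated exhaustively when it has at most
    ``n_permutations`` elements, otherwise sampled with replacement.
    """
    total = comb(n, n_pert)
    if total < 10:
        raise ValueError(
            f"only {total} distinct label permutations are possible; "
            "class sizes are too small for a permutation null"
        )

    def _is_observed(mask: np.ndarray) -> bool:
        return bool(np.array_equal(mask, observed) or np.array_equal(~mask, observed))

    if total <= n_permutations:
        for idx in combinations(range(n), n_pert):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if not _is_observed(mask):
                yield mask
    else:
        rng = np.random.default_rng(seed)
        yielded = 0
        while yielded < n_permutations:
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_pert, replace=False)] = True
            if _is_observed(mask):
                continue
            yielded += 1
            yield mask


def signature_pvalues(
    dataset: ExpressionDataset,
    signature: GeneSignature,
    config: ChdirConfig | None = None,
) -> dict[str, float]:
    """Per-gene nominal p-values from a pooled permutation null.

    The per-gene statistic is the class mean difference
    m_g = mean(perturbation) − mean(control).  For each class-size-preserving
    label permutation (observed labeling and its mirror excluded) the mean
    differences are recomputed and pooled across genes into one null sample;
    p_g is the two-sided normal tail of |m_g| at the null's standard
    deviation.  Pooling across genes assumes roughly comparable per-gene
    noise, which holds for log-scale expression.  Deterministic given
    ``config.seed``.
    """
    config = config or ChdirConfig()
    if signature is not None:
        missing = [
            g for g in dataset.values.index if str(g).upper() not in signature.gene_coeffs
        ]
        if missing:
            raise ValueError(
                "signature was not computed on this dataset "
                f"(missing genes, e.g. {missing[:3]})"
            )
    X = dataset.values.to_numpy(float)
    genes = [str(g).upper() for g in dataset.values.index]
    observed = dataset.perturbation_mask
    n = dataset.n_samples
    n_pert = int(observed.sum())
    m_obs = X[:, observed].mean(axis=1) - X[:, ~observed].mean(axis=1)
    null_parts = []
    for mask in _permutation_masks(
        n, n_pert, config.n_permutations, config.seed, observed
    ):
        null_parts.append(X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1))
    null_sd = float(np.concatenate(null_parts).std())
    if null_sd == 0.0:
        raise ValueError("permutation null is degenerate (no variation)")
    p = 2.0 * norm.sf(np.abs(m_obs) / null_sd)
    p = np.clip(p, 1e-300, 1.0)
    return dict(zip(genes, p.tolist()))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    Adjusted p_(i) = min over j ≥ i of min(1, p_(j)·m/j) on the ascending
    sort; every input must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def split_up_down(
    signature: GeneSignature, alpha: float = 0.01
) -> tuple[set[str], set[str]]:
    """Split a signature into significant up- and down-regulated gene sets.

    up = {g : b_g > 0, p_adj ≤ α};  down = {g : b_g < 0, p_adj ≤ α}.
    Zero-coefficient genes belong to neither set.
    """
    if not signature.adjusted_pvalues:
        raise ValueError("signature has no adjusted p-values")
    up, down = set(), set()
    for g, c in signature.gene_coeffs.items():
        padj = signature.adjusted_pvalues.get(g)
        if padj is None or padj > alpha:
            continue
        if c > 0:
            up.add(g)
        elif c < 0:
            down.add(g)
    return up, down


def compute_signature(
    dataset: ExpressionDataset,
    config: ChdirConfig | None = None,
    signature_id: str = "signature",
    metadata: dict[str, str] | None = None,
) -> GeneSignature:
    """Full CD pipeline: coefficients, permutation p-values, BH adjustment."""
    config = config or ChdirConfig()
    sig = characteristic_direction(dataset, config, signature_id, metadata)
    pvals = signature_pvalues(dataset, sig, config)
    genes = list(pvals)
    padj = bh_adjust([pvals[g] for g in genes])
    return GeneSignature(
        id=sig.id,
        gene_coeffs=sig.gene_coeffs,
        pvalues=pvals,
        adjusted_pvalues=dict(zip(genes, padj.tolist())),
        metadata=sig.metadata,
    )
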