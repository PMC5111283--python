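"""Deterministic synthetic data with planted ground truth.

Every stage of the pipeline has a generator here: log-scale expression
matrices with planted differentially expressed genes, gene-set libraries
with a planted enriched term, compound libraries with a planted mimicker and
reverser, and whole signature collections produced by running the CD
pipeline on generated datasets.  The generators emulate the study design the
method targets — a handful of control samples against a handful of
perturbation samples, per-gene Gaussian noise around a gene-specific
baseline, and additive log-scale shifts for truly regulated genes (half up,
half down, so both tails are exercised).  All generators are bit-reproducible
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CONTROL,
    PERTURBATION,
    CompoundSignatureLibrary,
    ExpressionDataset,
    GeneSetLibrary,
    GeneSignature,
    SignatureCollection,
)
from .chdir import ChdirConfig, compute_signature

__all__ = [
    "PlantedTruth",
    "make_expression",
    "make_library",
    "make_compound_library",
    "make_collection",
]


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator (what a perfect analysis recovers)."""

    planted_up: frozenset[str] = frozenset()
    planted_down: frozenset[str] = frozenset()
    planted_term: str | None = None
    planted_mimic: str | None = None
    planted_reverse: str | None = None
    delta: float | None = None
    noise_sd: float | None = None
    seed: int = 0

    @property
    def planted_genes(self) -> frozenset[str]:
        return self.planted_up | self.planted_down


def make_expression(
    n_genes: int = 1000,
    n_control: int = 3,
    n_perturb: int = 3,
    n_planted: int = 50,
    delta: float = 3.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, PlantedTruth]:
    """Log-scale expression with planted shifts in the perturbation class.

    Per-gene baseline means are N(8, 1); each cell adds N(0, σ) noise.  Of
    the ``n_planted`` planted genes, half gain +δ and half −δ in the
    perturbation samples only.  Defaults emulate the typical deposited
    study: ~3 controls vs ~3 perturbations, unit log-scale noise, δ = 3.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    if n_control < 2 or n_perturb < 2:
        raise ValueError("at least 2 samples per class required")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"CTRL_{i}" for i in range(n_control)] + [
        f"PERT_{i}" for i in range(n_perturb)
    ]
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, sigma, size=(n_genes, n_control + n_perturb)
    )
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    n_up = (n_planted + 1) // 2
    up_idx = planted_idx[:n_up]
    down_idx = planted_idx[n_up:]
    pert_cols = slice(n_control, None)
    values[np.ix_(up_idx, range(n_control, n_control + n_perturb))] += delta
    values[np.ix_(down_idx, range(n_control, n_control + n_perturb))] -= delta
    dataset = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        class_labels=pd.Series(
            [CONTROL] * n_control + [PERTURBATION] * n_perturb, index=samples
        ),
        species="human",
        platform_id="synthetic",
    )
    truth = PlantedTruth(
        planted_up=frozenset(genes[i] for i in up_idx),
        planted_down=frozenset(genes[i] for i in down_idx),
        delta=delta,
        noise_sd=sigma,
        seed=seed,
    )
    return dataset, truth


def make_library(
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (10, 50),
    background: list[str] | None = None,
    planted_genes: frozenset[str] | set[str] = frozenset(),
    seed: int = 0,
) -> tuple[GeneSetLibrary, PlantedTruth]:
    """Gene-set library with one planted set containing the planted genes.

    The planted set holds ``planted_genes`` padded with random background
    genes up to a sampled size; all other sets are uniform random draws from
    the background.
    """
    if background is None:
        background = [f"G{i:05d}" for i in range(1000)]
    background = sorted({g.upper() for g in background})
    planted = frozenset(g.upper() for g in planted_genes)
    if not planted <= set(background):
        raise ValueError("planted_genes must be a subset of the background")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(background)):
        raise ValueError("invalid set size range")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_sets)
    planted_pos = int(rng.integers(n_sets)) if planted else -1
    sets: dict[str, frozenset[str]] = {}
    planted_term = None
    non_planted = sorted(set(background) - planted)
    for i in range(n_sets):
        term = f"TERM_{i:04d}"
        if i == planted_pos:
            size = max(int(sizes[i]), len(planted))
            pad = rng.choice(non_planted, size=size - len(planted), replace=False)
            sets[term] = planted | set(pad.tolist())
            planted_term = term
        else:
            draw = rng.choice(background, size=int(sizes[i]), replace=False)
            sets[term] = frozenset(draw.tolist())
    library = GeneSetLibrary(
        name="synthetic", sets=sets, background_size=len(background)
    )
    truth = PlantedTruth(
        planted_up=planted, planted_term=planted_term, seed=seed
    )
    return library, truth


def make_compound_library(
    base_signature: GeneSignature,
    n_compounds: int = 200,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[CompoundSignatureLibrary, PlantedTruth]:
    """Compound library with a planted mimicker and reverser of a base signature.

    The planted mimic is the base vector plus N(0, noise_sd) noise
    (renormalized); the planted reverse is the negated base plus noise; the
    remaining ``n_compounds`` decoys are i.i.d. N(0, 1) vectors renormalized.
    """
    gene_space = sorted(base_signature.gene_coeffs)
    base = np.array([base_signature.gene_coeffs[g] for g in gene_space])
    G = len(gene_space)
    rng = np.random.default_rng(seed)

    def _unit(v: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(v)
        if nrm == 0.0:
            raise ValueError("degenerate zero vector generated")
        return v / nrm

    mimic_vec = _unit(base + rng.normal(0.0, noise_sd, G)) if noise_sd > 0 else base.copy()
    reverse_vec = (
        _unit(-base + rng.normal(0.0, noise_sd, G)) if noise_sd > 0 else -base
    )
    decoys = rng.normal(0.0, 1.0, size=(n_compounds, G))
    total = n_compounds + 2
    special = rng.choice(total, size=2, replace=False)
    mimic_pos, reverse_pos = int(special[0]), int(special[1])
    vectors: dict[str, np.ndarray] = {}
    mimic_id = reverse_id = None
    decoy_iter = iter(range(n_compounds))
    for i in range(total):
        cid = f"C{i:04d}"
        if i == mimic_pos:
            vectors[cid] = mimic_vec
            mimic_id = cid
        elif i == reverse_pos:
            vectors[cid] = reverse_vec
            reverse_id = cid
        else:
            vectors[cid] = _unit(decoys[next(decoy_iter)])
    library = CompoundSignatureLibrary(gene_space=tuple(gene_space), vectors=vectors)
    truth = PlantedTruth(
        planted_mimic=mimic_id,
        planted_reverse=reverse_id,
        noise_sd=noise_sd,
        seed=seed,
    )
    return library, truth


def make_collection(
    n_signatures: int = 6,
    n_genes: int = 200,
    n_planted: int = 20,
    delta: float = 3.0,
    sigma: float = 1.0,
    n_control: int = 3,
    n_perturb: int = 3,
    seed: int = 0,
    config: ChdirConfig | None = None,
    tag: str = "synthetic-collection",
) -> tuple[SignatureCollection, list[PlantedTruth]]:
    """A whole signature collection from generated datasets run through CD.

    Each signature comes from an independent planted expression dataset
    processed by the full pipeline (CD coefficients, permutation p-values,
    BH adjustment), with alternating ``cell_line`` metadata so the
    categorization features have something to group by.
    """
    signatures: list[GeneSignature] = []
    truths: list[PlantedTruth] = []
    for i in range(n_signatures):
        sub_seed = (seed * 1009 + i) % (2**31)
        dataset, truth = make_expression(
            n_genes=n_genes,
            n_control=n_control,
            n_perturb=n_perturb,
            n_planted=n_planted,
            delta=delta,
            sigma=sigma,
            seed=sub_seed,
        )
        cfg = config or ChdirConfig()
        cfg = ChdirConfig(
            gamma=cfg.gamma,
            n_permutations=cfg.n_permutations,
            alpha=cfg.alpha,
            seed=sub_seed,
        )
        sig = compute_signature(
            dataset,
            cfg,
            signature_id=f"SIG_{i:03d}",
            metadata={
                "organism": "human",
                "cell_line": "lineA" if i % 2 == 0 else "lineB",
            },
        )
        signatures.append(sig)
        truths.append(truth)
    return SignatureCollection(tag=tag, signatures=signatures), truths
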