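"""Domain types and file formats for signature-collection analysis.

The analysis works on four kinds of objects:

* :class:`ExpressionDataset` — a log-scale genes × samples matrix with
  control/perturbation labels, the raw material for differential expression;
* :class:`GeneSignature` — a unit-norm signed gene-coefficient vector (the
  characteristic-direction output) with per-gene significance and metadata;
* :class:`GeneSetLibrary` — a GMT-backed collection of named gene sets over a
  declared background universe, used for enrichment;
* :class:`CompoundSignatureLibrary` — a genes × compounds coefficient matrix
  (a LINCS-L1000-style resource) used for mimic/reverse matching.

Gene symbols are uppercased at every ingress so that human, mouse and rat
data share one canonical namespace after ortholog mapping.  All file formats
are plain text: TSV matrices, GMT libraries, JSON signatures/collections.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sigvecta")

SPECIES = ("human", "mouse", "rat")
CONTROL = "control"
PERTURBATION = "perturbation"

__all__ = [
    "SPECIES",
    "CONTROL",
    "PERTURBATION",
    "ExpressionDataset",
    "OrthologTable",
    "GeneSignature",
    "SignatureCollection",
    "GeneSetLibrary",
    "CompoundSignatureLibrary",
    "AggregateMatrix",
    "read_expression",
    "collapse_probes",
    "map_orthologs",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "read_compound_library",
    "write_compound_library",
    "read_signature_json",
    "write_signature_json",
    "read_collection_json",
    "write_collection_json",
    "write_report_matrix",
    "read_report_matrix",
]


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Log-scale expression values (rows = probes or genes, columns = samples).

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix; no missing values (rows with missing cells are dropped
        by :func:`read_expression` before construction).
    class_labels : mapping or pandas.Series
        Sample id → ``"control"`` or ``"perturbation"``; at least two samples
        per class.
    species : str
        One of ``"human"``, ``"mouse"``, ``"rat"``.
    """

    values: pd.DataFrame
    class_labels: pd.Series
    species: str
    platform_id: str = ""
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unsupported species {self.species!r}; "
                f"supported species are: {', '.join(SPECIES)}"
            )
        self.class_labels = pd.Series(self.class_labels).reindex(self.values.columns)
        if self.class_labels.isna().any():
            missing = list(self.values.columns[self.class_labels.isna()])
            raise ValueError(f"class labels missing for samples: {missing}")
        bad = set(self.class_labels.unique()) - {CONTROL, PERTURBATION}
        if bad:
            raise ValueError(
                f"class labels must be {CONTROL!r} or {PERTURBATION!r}, got {sorted(bad)}"
            )
        counts = self.class_labels.value_counts()
        if counts.get(CONTROL, 0) < 2 or counts.get(PERTURBATION, 0) < 2:
            raise ValueError("at least 2 samples per class required (≥2 per class)")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row identifiers: {dupes[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def control_samples(self) -> list[str]:
        return list(self.class_labels.index[self.class_labels == CONTROL])

    @property
    def perturbation_samples(self) -> list[str]:
        return list(self.class_labels.index[self.class_labels == PERTURBATION])

    @property
    def perturbation_mask(self) -> np.ndarray:
        return (self.class_labels == PERTURBATION).to_numpy()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression(
    path: str | Path,
    labels: Mapping[str, str] | Sequence[str],
    species: str,
    platform_id: str = "",
) -> ExpressionDataset:
    """Read a tab-separated expression matrix (header row of sample ids).

    Rows containing any non-numeric or missing cell are dropped and counted
    in ``n_dropped_rows``.  ``labels`` is either a mapping sample id → class
    or a sequence aligned with the file's column order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row identifiers in {path}: {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_expression: dropped %d rows with missing values", n_dropped)
    numeric = numeric.loc[keep]
    if not isinstance(labels, Mapping):
        if len(labels) != numeric.shape[1]:
            raise ValueError(
                f"got {len(labels)} labels for {numeric.shape[1]} samples"
            )
        labels = dict(zip(numeric.columns, labels))
    return ExpressionDataset(
        values=numeric.astype(float),
        class_labels=pd.Series(labels),
        species=species,
        platform_id=platform_id,
        n_dropped_rows=n_dropped,
    )


def collapse_probes(
    dataset: ExpressionDataset, probe_map: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probe-level rows to gene symbols, averaging multi-probe genes.

    Probes absent from ``probe_map`` are dropped (the drop count is
    accumulated in ``n_dropped_rows``).  Gene symbols are uppercased.
    """
    mapped = {p: g.upper() for p, g in probe_map.items()}
    in_map = dataset.values.index.isin(mapped)
    n_dropped = int((~in_map).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not in_map.any():
        raise ValueError("no probe in the dataset is present in the probe map")
    kept = dataset.values.loc[in_map]
    genes = [mapped[p] for p in kept.index]
    collapsed = kept.groupby(genes, sort=True).mean()
    collapsed.index.name = dataset.values.index.name
    return ExpressionDataset(
        values=collapsed,
        class_labels=dataset.class_labels,
        species=dataset.species,
        platform_id=dataset.platform_id,
        n_dropped_rows=dataset.n_dropped_rows + n_dropped,
    )


# ---------------------------------------------------------------------------
# Ortholog mapping
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """Deterministic (species, symbol) → human symbol map (many-to-one allowed).

    Keys are normalized to (lowercase species, uppercase symbol); targets are
    uppercase.
    """

    mapping: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        self.mapping = {
            (sp.lower(), sym.upper()): tgt.upper()
            for (sp, sym), tgt in self.mapping.items()
        }

    def get(self, species: str, symbol: str) -> str | None:
        return self.mapping.get((species.lower(), symbol.upper()))

    @classmethod
    def read(cls, path: str | Path) -> "OrthologTable":
        """Read a three-column TSV: species, symbol, human_symbol."""
        mapping: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if parts[0].lower() == "species" and i == 1:
                    continue  # optional header
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}, line {i}: expected 3 tab-separated fields"
                    )
                mapping[(parts[0], parts[1])] = parts[2]
        return cls(mapping)


def map_orthologs(
    genes: Iterable[str], species: str, table: OrthologTable
) -> dict[str, str]:
    """Map gene symbols of a species to human orthologs.

    Human input maps to itself (uppercased).  Symbols without a table entry
    are dropped and the drop count logged.  Two inputs may map to the same
    human symbol; downstream averaging (``collapse_probes``) resolves this.
    """
    if species not in SPECIES:
        raise ValueError(
            f"unsupported species {species!r}; supported species are: "
            f"{', '.join(SPECIES)}"
        )
    if species == "human":
        return {g: g.upper() for g in genes}
    out: dict[str, str] = {}
    n_dropped = 0
    for g in genes:
        target = table.get(species, g)
        if target is None:
            n_dropped += 1
        else:
            out[g] = target
    if n_dropped:
        logger.info("map_orthologs: dropped %d symbols without orthologs", n_dropped)
    return out


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV probe → gene symbol map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0].lower() == "probe" and i == 1:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}, line {i}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Gene signatures and collections
# ---------------------------------------------------------------------------

@dataclass
class GeneSignature:
    """A signed per-gene differential-expression vector.

    ``gene_coeffs`` holds the components of the unit normal of the
    class-separating hyperplane; a positive coefficient means higher
    expression in the perturbation samples.  ``pvalues`` and
    ``adjusted_pvalues`` (Benjamini–Hochberg) hold per-gene significance and
    may be empty for coefficient-only signatures.
    """

    id: str
    gene_coeffs: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    adjusted_pvalues: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_coeffs = {g.upper(): float(v) for g, v in self.gene_coeffs.items()}
        self.pvalues = {g.upper(): float(v) for g, v in self.pvalues.items()}
        self.adjusted_pvalues = {
            g.upper(): float(v) for g, v in self.adjusted_pvalues.items()
        }
        if not self.gene_coeffs:
            raise ValueError("signature has no gene coefficients")
        for name, pv in (("pvalues", self.pvalues), ("adjusted_pvalues", self.adjusted_pvalues)):
            for g, p in pv.items():
                if not (0.0 < p <= 1.0):
                    raise ValueError(f"{name}[{g}] = {p} outside (0, 1]")
        for g, padj in self.adjusted_pvalues.items():
            p = self.pvalues.get(g)
            if p is not None and padj < p - 1e-12:
                raise ValueError(f"adjusted p-value below nominal p for {g}")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_coeffs)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(list(self.gene_coeffs.values())))

    def validate(self, atol: float = 1e-9) -> None:
        """Check the unit-norm invariant of a pipeline-produced signature."""
        if abs(self.norm - 1.0) > atol:
            raise ValueError(
                f"signature {self.id!r} coefficient norm {self.norm} is not 1"
            )

    def negated(self, new_id: str | None = None) -> "GeneSignature":
        """The signature with every coefficient sign flipped."""
        return GeneSignature(
            id=new_id or f"{self.id}:neg",
            gene_coeffs={g: -c for g, c in self.gene_coeffs.items()},
            pvalues=dict(self.pvalues),
            adjusted_pvalues=dict(self.adjusted_pvalues),
            metadata=dict(self.metadata),
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.gene_coeffs, name=self.id)


@dataclass
class SignatureCollection:
    """A tagged, ordered set of gene signatures — the unit of analysis."""

    tag: str
    signatures: list[GeneSignature]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.signatures]
        if len(set(ids)) != len(ids):
            raise ValueError("signature ids must be unique within a collection")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.signatures]

    def require_nonempty(self) -> None:
        if not self.signatures:
            raise ValueError(f"collection {self.tag!r} is empty")

    def subset(self, ids: Iterable[str]) -> "SignatureCollection":
        wanted = set(ids)
        kept = [s for s in self.signatures if s.id in wanted]
        if not kept:
            raise ValueError("subset selects zero signatures")
        return SignatureCollection(tag=self.tag, signatures=kept, provenance=self.provenance)

    def metadata_fields(self) -> list[str]:
        fields: set[str] = set()
        for s in self.signatures:
            fields.update(s.metadata)
        return sorted(fields)

    def gene_union(self) -> list[str]:
        genes: set[str] = set()
        for s in self.signatures:
            genes.update(s.gene_coeffs)
        return sorted(genes)


def _signature_to_obj(sig: GeneSignature) -> dict:
    return {
        "id": sig.id,
        "metadata": dict(sig.metadata),
        "genes": [
            [
                g,
                sig.gene_coeffs[g],
                sig.pvalues.get(g),
                sig.adjusted_pvalues.get(g),
            ]
            for g in sorted(sig.gene_coeffs)
        ],
    }


def _signature_from_obj(obj: dict) -> GeneSignature:
    if "id" not in obj or "genes" not in obj:
        raise ValueError("signature JSON must contain 'id' and 'genes'")
    coeffs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    padj: dict[str, float] = {}
    for row in obj["genes"]:
        g, c = row[0], float(row[1])
        coeffs[g] = c
        if len(row) > 2 and row[2] is not None:
            pvals[g] = float(row[2])
        if len(row) > 3 and row[3] is not None:
            padj[g] = float(row[3])
    return GeneSignature(
        id=str(obj["id"]),
        gene_coeffs=coeffs,
        pvalues=pvals,
        adjusted_pvalues=padj,
        metadata={str(k): str(v) for k, v in obj.get("metadata", {}).items()},
    )


def write_signature_json(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_signature_to_obj(sig), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_signature_json(path: str | Path) -> GeneSignature:
    with open(path) as fh:
        return _signature_from_obj(json.load(fh))


def write_collection_json(collection: SignatureCollection, path: str | Path) -> None:
    obj = {
        "tag": collection.tag,
        "provenance": collection.provenance,
        "signatures": [_signature_to_obj(s) for s in collection.signatures],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_collection_json(path: str | Path) -> SignatureCollection:
    with open(path) as fh:
        obj = json.load(fh)
    if "tag" not in obj or "signatures" not in obj:
        raise ValueError("collection JSON must contain 'tag' and 'signatures'")
    return SignatureCollection(
        tag=str(obj["tag"]),
        signatures=[_signature_from_obj(s) for s in obj["signatures"]],
        provenance=str(obj.get("provenance", "")),
    )


# ---------------------------------------------------------------------------
# Gene-set libraries (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetLibrary:
    """Named gene sets over a declared background universe."""

    name: str
    sets: dict[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        self.sets = {t: frozenset(g.upper() for g in s) for t, s in self.sets.items()}
        if self.background_size <= 0:
            raise ValueError("background_size must be positive")
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            if len(genes) > self.background_size:
                raise ValueError(
                    f"gene set {term!r} larger than the background universe"
                )

    @property
    def terms(self) -> list[str]:
        return list(self.sets)

    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out.update(s)
        return frozenset(out)


def read_gmt(
    path: str | Path,
    name: str | None = None,
    background_size: int | None = None,
) -> GeneSetLibrary:
    """Parse a GMT file (term, description, gene symbols…, tab-separated).

    Gene symbols are uppercased; empty gene fields are skipped.  The
    background universe defaults to the union of all genes in the file.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}, line {i}: GMT lines need ≥ 3 tab-separated "
                    f"fields (term, description, genes…)"
                )
            term = parts[0]
            if term in sets:
                raise ValueError(f"{path}, line {i}: duplicate term name {term!r}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}, line {i}: gene set {term!r} is empty")
            sets[term] = genes
    if background_size is None:
        background_size = len(frozenset().union(*sets.values())) if sets else 0
    return GeneSetLibrary(
        name=name or Path(path).stem, sets=sets, background_size=background_size
    )


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in library.sets.items():
            fh.write("\t".join([term, ""] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Compound signature libraries
# ---------------------------------------------------------------------------

@dataclass
class CompoundSignatureLibrary:
    """Compound × gene coefficient matrix for mimic/reverse matching."""

    gene_space: tuple[str, ...]
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.gene_space = tuple(g.upper() for g in self.gene_space)
        if len(set(self.gene_space)) != len(self.gene_space):
            raise ValueError("gene_space contains duplicate symbols")
        self.vectors = {c: np.asarray(v, dtype=float) for c, v in self.vectors.items()}
        for cid, v in self.vectors.items():
            if v.shape != (len(self.gene_space),):
                raise ValueError(
                    f"vector for {cid!r} has length {v.shape}, expected "
                    f"{len(self.gene_space)}"
                )
            if not np.any(v):
                raise ValueError(f"vector for {cid!r} is all zeros")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=list(self.gene_space))


def read_compound_library(path: str | Path) -> CompoundSignatureLibrary:
    """Read a TSV with gene symbols in column 1 and compound ids as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CompoundSignatureLibrary(
        gene_space=tuple(df.index),
        vectors={str(c): df[c].to_numpy(float) for c in df.columns},
    )


def write_compound_library(library: CompoundSignatureLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["gene"] + list(library.vectors)) + "\n")
        frame = library.to_frame()
        for gene, row in zip(frame.index, frame.to_numpy()):
            fh.write("\t".join([gene] + [f"{v:.12g}" for v in row]) + "\n")


# ---------------------------------------------------------------------------
# Aggregate matrices (TSV round-trip at 12 significant digits)
# ---------------------------------------------------------------------------

@dataclass
class AggregateMatrix:
    """A labeled dense matrix (rows × signatures) with optional cluster orders."""

    row_labels: list[str]
    column_labels: list[str]
    values: np.ndarray
    row_order: np.ndarray | None = None
    column_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_labels)} row and {len(self.column_labels)} column labels"
            )
        for axis_name, order, n in (
            ("row", self.row_order, len(self.row_labels)),
            ("column", self.column_order, len(self.column_labels)),
        ):
            if order is not None:
                order = np.asarray(order)
                if sorted(order.tolist()) != list(range(n)):
                    raise ValueError(f"{axis_name}_order is not a permutation of 0..{n - 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.column_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AggregateMatrix":
        return cls(
            row_labels=[str(r) for r in frame.index],
            column_labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(float),
        )


def write_report_matrix(matrix: AggregateMatrix, path: str | Path) -> None:
    """Write a TSV (row labels in column 1, signature ids as header).

    Values are written with 12 significant digits; the matching reader
    round-trips them exactly at that precision.
    """
    if matrix.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(matrix.column_labels)) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            fh.write("\t".join([label] + [f"{v:.12g}" for v in row]) + "\n")


def read_report_matrix(path: str | Path) -> AggregateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AggregateMatrix.from_frame(df)
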