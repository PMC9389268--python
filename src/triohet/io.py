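"""Readers and writers for the pipeline's external formats.

Count matrices (TSV or MatrixMarket), sample design tables, gene length
tables, and term->gene annotations (GMT or two-column TSV). Every reader
validates strictly and raises a named error on malformed input; nothing is
silently coerced. Gene and sample identifiers are opaque strings.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class TrioHetError(Exception):
    """Base class for all package errors."""


class MissingFileError(TrioHetError):
    pass


class DuplicateIdError(TrioHetError):
    pass


class InvalidCountError(TrioHetError):
    """Negative, NaN or non-integer entry in a count matrix."""


class UnknownRoleError(TrioHetError):
    pass


class DesignMismatchError(TrioHetError):
    """Design references samples absent from the count matrix (or vice versa)."""


class MalformedAnnotationError(TrioHetError):
    pass


class MissingLengthError(TrioHetError):
    pass


class Role(str, enum.Enum):
    """Genotype role of a sample in the trio design."""

    FEMALE_PARENT = "female_parent"
    MALE_PARENT = "male_parent"
    HYBRID = "hybrid"


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer fragment counts."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise InvalidCountError("counts must be a 2-D matrix")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidCountError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise InvalidCountError("need at least 1 gene and 1 sample")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        _validate_integer_counts(counts, self.gene_ids, self.sample_ids)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def column_totals(self) -> np.ndarray:
        """Per-sample library sizes (column sums)."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    role: Role
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise TrioHetError(
                f"replicate must be a positive integer, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class GeneModelTable:
    """Gene id -> gene length in base pairs (strictly positive)."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for gid, length in self.lengths.items():
            if not (isinstance(length, (int, np.integer)) and length > 0):
                raise MissingLengthError(
                    f"gene {gid!r} has invalid length {length!r}; lengths must "
                    "be positive integers"
                )

    def __getitem__(self, gene_id: str) -> int:
        try:
            return self.lengths[gene_id]
        except KeyError:
            raise MissingLengthError(f"no length for gene {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.lengths


@dataclass(frozen=True)
class AnnotationMap:
    """Flat term -> gene-set annotation (GO/KEGG style, no term hierarchy)."""

    terms: Mapping[str, frozenset[str]]
    term_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise MalformedAnnotationError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DuplicateIdError(f"duplicate {kind} id {x!r}")
        seen.add(x)


def _validate_integer_counts(
    counts: np.ndarray, gene_ids: Sequence[str], sample_ids: Sequence[str]
) -> None:
    arr = np.asarray(counts)
    if arr.dtype.kind == "f":
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise InvalidCountError(
                f"non-finite count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
            )
        frac = arr != np.floor(arr)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise InvalidCountError(
                f"non-integer count {arr[g, s]} at gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r}"
            )
    elif arr.dtype.kind not in "iu":
        raise InvalidCountError(f"counts have non-numeric dtype {arr.dtype}")
    neg = arr < 0
    if neg.any():
        g, s = np.argwhere(neg)[0]
        raise InvalidCountError(
            f"negative count {arr[g, s]} at gene {gene_ids[g]!r}, "
            f"sample {sample_ids[s]!r}"
        )


def _require_file(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise MissingFileError(f"no such file: {p}")
    return p


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix.

    TSV dialect: first column gene id, header row of sample ids, tab
    separated, no missing values. MatrixMarket: integer coordinate ``.mtx``
    with ``<stem>.genes.txt`` and ``<stem>.samples.txt`` id sidecars.
    """
    p = _require_file(path)
    if format == "tsv":
        df = pd.read_csv(p, sep="\t", header=0, index_col=0, dtype=str)
        if df.isna().any().any():
            raise InvalidCountError(f"missing value in count matrix {p}")
        try:
            values = df.astype(float).to_numpy()
        except ValueError as exc:
            raise InvalidCountError(f"non-numeric count in {p}: {exc}") from None
        return CountMatrix(
            gene_ids=tuple(str(g) for g in df.index),
            sample_ids=tuple(str(s) for s in df.columns),
            counts=values,
        )
    if format == "mtx":
        mat = scipy.io.mmread(p)
        genes = _read_id_sidecar(p.with_suffix("").with_suffix(".genes.txt"))
        samples = _read_id_sidecar(p.with_suffix("").with_suffix(".samples.txt"))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        return CountMatrix(gene_ids=genes, sample_ids=samples, counts=dense)
    raise ValueError(f"unknown count matrix format {format!r}")


def _read_id_sidecar(path: Path) -> tuple[str, ...]:
    p = _require_file(path)
    return tuple(
        line.strip() for line in p.read_text().splitlines() if line.strip()
    )


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    p = Path(path)
    if format == "tsv":
        cm.to_frame().to_csv(p, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(p, scipy.sparse.coo_matrix(cm.counts), field="integer")
        p.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(cm.gene_ids) + "\n"
        )
        p.with_suffix("").with_suffix(".samples.txt").write_text(
            "\n".join(cm.sample_ids) + "\n"
        )
    else:
        raise ValueError(f"unknown count matrix format {format!r}")


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a sample design TSV with columns sample_id, role, replicate."""
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype=str)
    required = {"sample_id", "role", "replicate"}
    if not required.issubset(df.columns):
        raise TrioHetError(
            f"design {p} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: list[SampleDesign] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise DuplicateIdError(f"duplicate sample_id {sid!r} in design {p}")
        seen.add(sid)
        try:
            role = Role(str(row["role"]))
        except ValueError:
            raise UnknownRoleError(
                f"unknown role {row['role']!r} for sample {sid!r}; expected one "
                f"of {[r.value for r in Role]}"
            ) from None
        out.append(SampleDesign(sample_id=sid, role=role, replicate=int(row["replicate"])))
    return out


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "role": [d.role.value for d in design],
            "replicate": [d.replicate for d in design],
        }
    ).to_csv(path, sep="\t", index=False)


def validate_design_against_counts(
    design: Sequence[SampleDesign], cm: CountMatrix, min_replicates: int = 1
) -> None:
    """Cross-validate a design against a count matrix.

    Raises if a design sample is absent from the matrix, or a role is
    missing / under-replicated for the trio analysis.
    """
    missing = [d.sample_id for d in design if d.sample_id not in cm.sample_ids]
    if missing:
        raise DesignMismatchError(
            f"design samples absent from count matrix: {missing}"
        )
    by_role: dict[Role, int] = {}
    for d in design:
        by_role[d.role] = by_role.get(d.role, 0) + 1
    for role in Role:
        if by_role.get(role, 0) < min_replicates:
            raise DesignMismatchError(
                f"role {role.value!r} has {by_role.get(role, 0)} samples; "
                f"need >= {min_replicates}"
            )


def samples_for_role(design: Sequence[SampleDesign], role: Role) -> list[str]:
    return [d.sample_id for d in design if d.role == role]


def read_gene_lengths(path: str | Path) -> GeneModelTable:
    """Read a gene length TSV with columns gene_id, length_bp."""
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length_bp"}.issubset(df.columns):
        raise TrioHetError(f"{p} must have columns gene_id, length_bp")
    _check_unique(list(df["gene_id"]), "gene")
    return GeneModelTable(
        lengths={str(g): int(l) for g, l in zip(df["gene_id"], df["length_bp"])}
    )


def write_gene_lengths(table: GeneModelTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.lengths), "length_bp": list(table.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path, format: str = "gmt") -> AnnotationMap:
    """Read a term->gene annotation.

    ``gmt``: Broad dialect, one term per line: term_id, description, genes...
    ``tsv2col``: header-less rows gene_id<TAB>term_id.
    """
    p = _require_file(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    if format == "gmt":
        for lineno, line in enumerate(p.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise MalformedAnnotationError(
                    f"{p}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not term:
                raise MalformedAnnotationError(f"{p}:{lineno}: empty term id")
            if term in terms:
                raise DuplicateIdError(f"{p}:{lineno}: duplicate term {term!r}")
            if not genes:
                raise MalformedAnnotationError(f"{p}:{lineno}: term {term!r} has no genes")
            terms[term] = set(genes)
            names[term] = desc
    elif format == "tsv2col":
        for lineno, line in enumerate(p.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise MalformedAnnotationError(
                    f"{p}:{lineno}: expected gene_id<TAB>term_id"
                )
            gene, term = parts
            terms.setdefault(term, set()).add(gene)
            names.setdefault(term, term)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationMap(
        terms={t: frozenset(g) for t, g in terms.items()}, term_names=names
    )


def write_annotation_gmt(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            name = ann.term_names.get(term, term)
            genes = "\t".join(sorted(ann.terms[term]))
            fh.write(f"{term}\t{name}\t{genes}\n")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
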