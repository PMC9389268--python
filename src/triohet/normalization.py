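"""Library-size normalization, FPKM, and expression-presence filtering.

FPKM (fragments per kilobase of gene model per million mapped fragments)
is computed directly from the count matrix, gene lengths, and per-sample
totals:

    fpkm[g, s] = counts[g, s] * 1e9 / (totals[s] * length_bp[g])

Size factors use the median-of-ratios estimator: for genes with nonzero
counts in every sample, each sample's factor is the median ratio of its
counts to the per-gene geometric mean, rescaled so the factors have
geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneModelTable,
    MissingLengthError,
    Role,
    SampleDesign,
    TrioHetError,
    samples_for_role,
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples FPKM matrix, same ids and shape as its source counts."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    fpkm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fpkm, dtype=float)
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise TrioHetError("fpkm shape does not match ids")
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise TrioHetError("FPKM values must be finite and non-negative")
        object.__setattr__(self, "fpkm", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fpkm, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def genotype_means(self, design: Sequence[SampleDesign]) -> pd.DataFrame:
        """Mean FPKM per genotype role (columns female_parent/male_parent/hybrid)."""
        df = self.to_frame()
        out = {}
        for role in Role:
            cols = samples_for_role(design, role)
            if cols:
                out[role.value] = df[cols].mean(axis=1)
        return pd.DataFrame(out)


def compute_fpkm(
    counts: CountMatrix,
    lengths: GeneModelTable,
    totals: Mapping[str, int] | Sequence[int] | None = None,
) -> ExpressionMatrix:
    """FPKM from counts, gene lengths and per-sample totals.

    ``totals`` defaults to the matrix column sums (total counted fragments
    per sample); an explicit mapping/sequence overrides this, e.g. with
    externally determined totals of mapped fragments.
    """
    for g in counts.gene_ids:
        if g not in lengths:
            raise MissingLengthError(f"no length for gene {g!r}")
    if totals is None:
        tot = counts.column_totals().astype(float)
    elif isinstance(totals, Mapping):
        tot = np.array([float(totals[s]) for s in counts.sample_ids])
    else:
        tot = np.asarray(totals, dtype=float)
        if tot.shape != (len(counts.sample_ids),):
            raise TrioHetError("totals length does not match sample count")
    if (tot <= 0).any():
        bad = counts.sample_ids[int(np.argmax(tot <= 0))]
        raise TrioHetError(f"non-positive total for sample {bad!r}")
    length_bp = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    fpkm = counts.counts * 1e9 / (tot[None, :] * length_bp[:, None])
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, fpkm)


def size_factors_median_ratio(counts: CountMatrix) -> dict[str, float]:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every sample enter the reference
    geometric mean; all-zero (or any-zero) genes are excluded by
    construction. Raises if no gene is nonzero in all samples.
    """
    arr = counts.counts.astype(float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise TrioHetError(
            "size factors undefined: no gene has nonzero counts in every sample"
        )
    ref = arr[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return dict(zip(counts.sample_ids, factors.tolist()))


def filter_expressed(
    fpkm: ExpressionMatrix,
    design: Sequence[SampleDesign],
    min_fpkm: float = 0.0,
    scope: str = "all_genotypes",
) -> set[str]:
    """Genes whose mean FPKM within a genotype exceeds ``min_fpkm``.

    scope='all_genotypes' requires the mean to exceed the threshold in every
    genotype (genes "identified" in all three trio members); 'any_genotype'
    requires it in at least one.
    """
    if min_fpkm < 0:
        raise TrioHetError("min_fpkm must be >= 0")
    if scope not in ("any_genotype", "all_genotypes"):
        raise TrioHetError(f"unknown scope {scope!r}")
    means = fpkm.genotype_means(design)
    above = means > min_fpkm
    keep = above.all(axis=1) if scope == "all_genotypes" else above.any(axis=1)
    return set(keep.index[keep])
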