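"""Heterosis statistics at the phenotype and expression level.

Heterosis (hybrid vigor) is quantified relative to three parental
reference points: the high-value parent HP, the mid-parent value
MP = (P_f + P_m)/2, and the low-value parent LP:

    OPH% = (F1 - HP)/HP * 100      (over-high-parent heterosis)
    MPH% = (F1 - MP)/MP * 100      (mid-parent heterosis)
    BPH% = (F1 - LP)/LP * 100      (over-low-parent heterosis)

Per-gene expression heterosis uses genotype-mean FPKM: the fold change
FC = F1/MP and the heterosis percent H = (F1 - MP)/MP * 100 = (FC - 1)*100.

The module also covers two bench-side formulas of the same workflow: leaf
K+ content from a flame-photometry concentration reading, and relative
qPCR expression by the 2^-ddCt method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import TrioHetError


@dataclass(frozen=True)
class HeterosisIndices:
    """OPH/MPH/BPH percentages for one trait or gene."""

    oph: float
    mph: float
    bph: float


def heterosis_indices(f1: float, p_f: float, p_m: float) -> HeterosisIndices:
    """Heterosis of a hybrid value relative to its two parent values.

    For positive values with distinct parents, OPH <= MPH <= BPH always
    (the reference decreases from the high parent to the low parent).
    """
    hp, lp = max(p_f, p_m), min(p_f, p_m)
    mp = (p_f + p_m) / 2.0
    if hp == 0 or lp == 0 or mp == 0:
        raise TrioHetError("heterosis indices undefined for zero parent values")
    return HeterosisIndices(
        oph=(f1 - hp) / hp * 100.0,
        mph=(f1 - mp) / mp * 100.0,
        bph=(f1 - lp) / lp * 100.0,
    )


@dataclass(frozen=True)
class ExpressionHeterosis:
    """Per-gene hybrid vs mid-parent expression summary.

    ``h_pct`` is identically (fc - 1) * 100.
    """

    gene_id: str
    f1_fpkm: float
    mp_fpkm: float
    fc: float
    h_pct: float


def expression_heterosis(
    f1_fpkm: float, mp_fpkm: float, gene_id: str = ""
) -> ExpressionHeterosis:
    """Fold change and heterosis percent of hybrid vs mid-parent expression."""
    if not mp_fpkm > 0:
        raise TrioHetError(
            f"mid-parent FPKM must be positive, got {mp_fpkm} for {gene_id!r}"
        )
    fc = f1_fpkm / mp_fpkm
    return ExpressionHeterosis(
        gene_id=gene_id,
        f1_fpkm=f1_fpkm,
        mp_fpkm=mp_fpkm,
        fc=fc,
        h_pct=(fc - 1.0) * 100.0,
    )


def expression_heterosis_table(
    genotype_means: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Table of F1, MP, FC and H% per gene from genotype-mean FPKM.

    ``genotype_means`` has columns female_parent, male_parent, hybrid
    (e.g. from :meth:`ExpressionMatrix.genotype_means`). Genes whose
    mid-parent mean is zero are dropped. FC and H% are reported at full
    precision; round to 2 decimals for display.
    """
    df = genotype_means if genes is None else genotype_means.loc[list(genes)]
    mp = (df["female_parent"] + df["male_parent"]) / 2.0
    keep = mp > 0
    f1 = df.loc[keep, "hybrid"]
    mp = mp[keep]
    fc = f1 / mp
    return pd.DataFrame(
        {
            "gene_id": f1.index,
            "F1": f1.to_numpy(),
            "MP": mp.to_numpy(),
            "FC": fc.to_numpy(),
            "H_pct": ((fc - 1.0) * 100.0).to_numpy(),
        }
    ).reset_index(drop=True)


def kplus_content(c_ppm: float, volume_ml: float, dry_weight_g: float) -> float:
    """Leaf K+ content (percent of dry weight) from a flame-photometry reading.

    ``c_ppm`` is the K+ concentration from the standard curve, ``volume_ml``
    the volume of extract measured, ``dry_weight_g`` the dry sample weight;
    K+% = C*V / (G*1e6) * 100.
    """
    if not dry_weight_g > 0:
        raise TrioHetError("dry sample weight must be positive")
    if c_ppm < 0 or volume_ml <= 0:
        raise TrioHetError("concentration must be >= 0 and volume > 0")
    return c_ppm * volume_ml / (dry_weight_g * 1e6) * 100.0


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt is target minus reference-gene Ct within each sample; ddCt is the
    sample dCt minus the calibrator dCt; the fold change is 2^-ddCt.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise TrioHetError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)
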