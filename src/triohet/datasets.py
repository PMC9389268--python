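"""Small built-in reference data.

``potassium_gene_table`` holds the published expression summary for
potassium-heterosis-related genes in a tobacco hybrid trio (F1 of the
cross G70 x GDH11 against its two inbred parents): per gene the reported
inheritance category, hybrid mean FPKM (F1), mid-parent mean FPKM (MP),
their fold change (FC, printed to 2 decimals) and the expression-heterosis
percent (H_pct, printed to 2 decimals). It serves as a worked-example
fixture for the expression-heterosis arithmetic.
"""

from __future__ import annotations

import pandas as pd

_POTASSIUM_GENE_ROWS = [
    # (category, gene_id, description, F1, MP, FC, H_pct)
    ("over_dominant", "LOC107784880", "Laccase-12-like", 17.60, 8.10, 2.17, 117.24),
    ("over_dominant", "LOC107779045", "Sodium/hydrogen exchanger 3-like", 0.21, 0.10, 2.03, 103.23),
    ("over_dominant", "LOC107787287", "Monocopper oxidase-like protein SKU5", 1.34, 0.94, 1.43, 42.96),
    ("over_dominant", "LOC107760542", "Probable potassium transporter 17", 12.60, 3.74, 3.37, 236.99),
    ("over_dominant", "LOC107759178", "Solute carrier family 40 member 3", 124.56, 65.82, 1.89, 89.26),
    ("over_dominant", "LOC107758984", "Tabacum protein detoxification 42-like", 4.83, 2.82, 1.71, 71.39),
    ("over_dominant", "LOC107795534", "Triosephosphate isomerase", 22.25, 12.21, 1.82, 82.28),
    ("over_dominant", "LOC107783543", "Oxalate--CoA ligase-like", 1.23, 0.83, 1.49, 48.59),
    ("over_dominant", "LOC107791078", "Calcium uniporter protein 5", 4.01, 1.96, 2.05, 104.94),
    ("over_dominant", "LOC107790202", "Probable glutamate carboxypeptidase 2", 1.10, 0.54, 2.02, 102.45),
    ("over_dominant", "LOC107762391", "Glutamate receptor 2.2-like", 7.86, 5.48, 1.44, 43.58),
    ("over_dominant", "LOC107796561", "Glutamate receptor 2.8-like", 1.51, 0.84, 1.79, 79.37),
    ("over_dominant", "LOC107810988", "Calmodulin-binding protein 60 D-like", 10.83, 7.22, 1.50, 50.03),
    ("over_dominant", "LOC107769099", "MLO-like protein 6", 1.33, 0.73, 1.82, 82.19),
    ("over_dominant", "LOC107800917", "Calcium-transporting ATPase 2", 6.17, 3.25, 1.90, 89.74),
    ("over_dominant", "LOC107771176", "Calmodulin-binding protein 60 B-like", 0.12, 0.08, 1.64, 64.44),
    ("over_dominant", "LOC107765993", "Uncharacterized LOC107765993", 56.00, 19.93, 2.81, 180.95),
    ("over_dominant", "LOC107825481", "Calcium-dependent protein kinase 28-like", 5.39, 2.21, 2.45, 144.60),
    ("dominant", "LOC107812584", "Potassium transporter 5-like", 6.55, 2.96, 2.21, 121.05),
    ("dominant", "LOC107777935", "L-ascorbate oxidase homolog", 99.27, 50.36, 1.97, 97.15),
    ("dominant", "LOC107792406", "L-ascorbate oxidase homolog", 1.15, 0.46, 2.49, 149.10),
    ("dominant", "LOC107782957", "Uncharacterized LOC107782957", 0.74, 0.28, 2.64, 163.91),
    ("dominant", "LOC107803414", "Heat shock cognate 70 kDa protein 1-like", 77.18, 38.92, 1.98, 98.30),
    ("dominant", "LOC107809995", "Calcineurin subunit B-like", 0.51, 0.32, 1.59, 58.55),
    ("dominant", "LOC107769668", "Alpha-amylase-like", 2.39, 1.84, 1.30, 29.84),
    ("dominant", "LOC107793486", "Uncharacterized LOC107793486", 21.86, 13.28, 1.65, 64.65),
    ("dominant", "LOC107783728", "Peroxygenase-like", 6.09, 4.32, 1.41, 41.16),
    ("dominant", "LOC107800970", "Uncharacterized LOC107800970", 51.60, 18.09, 2.85, 185.21),
]


def potassium_gene_table() -> pd.DataFrame:
    """Published K+-heterosis gene summary as a DataFrame.

    Columns: category, gene_id, description, F1, MP, FC, H_pct. F1 and MP
    are genotype-mean FPKM printed to 2 decimals; FC and H_pct are the
    published 2-decimal values, so recomputing them from F1 and MP
    reproduces FC exactly after rounding and H_pct only approximately
    (the printed inputs are themselves rounded).
    """
    return pd.DataFrame(
        _POTASSIUM_GENE_ROWS,
        columns=["category", "gene_id", "description", "F1", "MP", "FC", "H_pct"],
    )
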