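"""Hypergeometric term enrichment of a gene list.

Builds a toy annotation with one genuinely over-represented term and runs
the enrichment test against an expressed-gene background.
"""

import numpy as np

from triohet import enrich
from triohet.io import AnnotationMap

rng = np.random.default_rng(0)
background = {f"g{i}" for i in range(400)}
study = set(rng.choice(sorted(background), 40, replace=False))

terms = {"T_real": frozenset(sorted(study)[:20]) | frozenset(sorted(background)[:20])}
for i in range(10):
    terms[f"T_rand{i}"] = frozenset(rng.choice(sorted(background), 40, replace=False))
ann = AnnotationMap(terms=terms)

table = enrich(study, background, ann)
print(table[["term_id", "k", "n", "M", "N", "fold", "p", "q"]].head(5).to_string(index=False))
print("\nk of n study genes carry the term, M of N background genes do; "
      "fold > 1 with small q marks a term over-represented in the study set.")
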