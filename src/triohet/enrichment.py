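"""Hypergeometric over-representation of annotation terms in gene lists.

For a study set of n genes drawn from a background of N genes of which M
carry a term, the enrichment p-value is the upper tail
P(X >= k) with X ~ Hypergeometric(N, M, n), where k is the number of study
genes carrying the term. q-values are Benjamini-Hochberg across the
reported terms. Terms are flat gene sets (no ontology hierarchy); the
background defaults to the expressed-gene set intersected with the
annotation's gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import AnnotationMap, TrioHetError


def hypergeom_tail(k: int, n: int, M: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, M, n).

    ``k``: study hits, ``n``: study size, ``M``: term size in background,
    ``N``: background size. k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise TrioHetError(
            f"invalid hypergeometric bounds: k={k}, n={n}, M={M}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def enrich(
    study_genes: set[str],
    background_genes: set[str],
    ann: AnnotationMap,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Term over-representation of ``study_genes`` within ``background_genes``.

    Genes outside the background are dropped from each term (the count of
    dropped annotation genes is in ``result.attrs['n_dropped']``). One row
    per term with M >= min_term_size after restriction; columns term_id,
    term_name, k, n, M, N, fold, p, q, sorted by (p, term_id).
    """
    if not study_genes:
        raise TrioHetError("study set is empty")
    stray = study_genes - background_genes
    if stray:
        raise TrioHetError(
            f"{len(stray)} study genes outside the background, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N = len(background_genes)
    n = len(study_genes)
    rows = []
    n_dropped = 0
    for term_id in sorted(ann.terms):
        genes = ann.terms[term_id] & background_genes
        n_dropped += len(ann.terms[term_id]) - len(genes)
        M = len(genes)
        if M < min_term_size:
            continue
        assert M <= N and n <= N
        k = len(genes & study_genes)
        p = hypergeom_tail(k, n, M, N)
        fold = (k / n) / (M / N)
        rows.append(
            {
                "term_id": term_id,
                "term_name": ann.term_names.get(term_id, term_id),
                "k": k,
                "n": n,
                "M": M,
                "N": N,
                "fold": fold,
                "p": p,
            }
        )
    out = pd.DataFrame.from_records(
        rows, columns=["term_id", "term_name", "k", "n", "M", "N", "fold", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["q"] = pd.Series(dtype=float)
    out.attrs["n_dropped"] = n_dropped
    return out
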