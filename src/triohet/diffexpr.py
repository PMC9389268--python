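"""Pairwise differential expression between genotype groups.

The default test (``nb_wald``) fits a per-gene negative-binomial model with
variance mu + d*mu^2. Counts are normalized by median-of-ratios size
factors; the overdispersion d is estimated by method of moments on the
normalized counts, pooled within the two groups and floored at 1e-8. The
Wald statistic compares log group means with a delta-method standard error
and is referred to a Student-t distribution with n_a + n_b - 2 degrees of
freedom, which keeps the test calibrated at trio-scale replicate numbers
where the plug-in dispersion is noisy. ``welch_log`` is a simpler
alternative: Welch's t-test on log2(normalized count + 1).

Genes are called up/down at the pipeline's thresholds: p (or BH q) below
``p_thresh`` and fold change above ``fc_thresh`` or below ``1/fc_thresh``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, Role, SampleDesign, TrioHetError, samples_for_role
from .normalization import size_factors_median_ratio

DISPERSION_FLOOR = 1e-8
_LOG_EPS = 0.5  # pseudocount inside the Wald log-mean, symmetric in a/b


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise contrast; ``group_b`` is the numerator of the fold change."""

    group_a: Role
    group_b: Role
    label: str = ""

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise TrioHetError("contrast groups must differ")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.group_b.value}_vs_{self.group_a.value}"
            )


#: The three contrasts of the trio design: hybrid vs each parent, and
#: female vs male parent (the parental contrast has the female parent as
#: numerator).
TRIO_CONTRASTS = (
    ContrastSpec(Role.FEMALE_PARENT, Role.HYBRID, "H_vs_F"),
    ContrastSpec(Role.MALE_PARENT, Role.HYBRID, "H_vs_M"),
    ContrastSpec(Role.MALE_PARENT, Role.FEMALE_PARENT, "F_vs_M"),
)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if not np.all(np.isfinite(arr)) or (arr < 0).any() or (arr > 1).any():
        raise TrioHetError("p-values must be finite and in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_test(
    counts: CountMatrix,
    design: list[SampleDesign],
    contrast: ContrastSpec,
    method: str = "nb_wald",
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    use_q: bool = False,
) -> pd.DataFrame:
    """Differential expression for one contrast.

    Returns one row per tested gene with columns gene_id, mean_a, mean_b,
    log2fc, p, q, call. Genes with zero counts in every sample of both
    groups are excluded (listed in ``result.attrs['untested']``). log2fc is
    log2((mean_b + 1)/(mean_a + 1)) on normalized means.
    """
    cols_a = samples_for_role(design, contrast.group_a)
    cols_b = samples_for_role(design, contrast.group_b)
    if not cols_a or not cols_b:
        missing = contrast.group_a if not cols_a else contrast.group_b
        raise TrioHetError(f"contrast group {missing.value!r} absent from design")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise TrioHetError(
            f"contrast {contrast.label!r} needs >= 2 replicates per group "
            f"(got {len(cols_a)} and {len(cols_b)})"
        )
    df = counts.to_frame()
    sub = df[cols_a + cols_b]
    factors = size_factors_median_ratio(
        CountMatrix(
            counts.gene_ids, tuple(cols_a + cols_b), sub.to_numpy()
        )
    )
    sf = np.array([factors[s] for s in cols_a + cols_b])
    norm = sub.to_numpy(dtype=float) / sf[None, :]
    na, nb = len(cols_a), len(cols_b)
    a, b = norm[:, :na], norm[:, na:]

    tested = (sub.to_numpy() > 0).any(axis=1)
    untested = [g for g, t in zip(counts.gene_ids, tested) if not t]
    a, b = a[tested], b[tested]
    gene_ids = [g for g, t in zip(counts.gene_ids, tested) if t]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))

    if method == "nb_wald":
        p = _nb_wald_p(a, b)
    elif method == "welch_log":
        p = _welch_log_p(a, b)
    else:
        raise TrioHetError(f"unknown DE method {method!r}")

    res = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
        }
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    res = call_degs(res, p_thresh=p_thresh, fc_thresh=fc_thresh, use_q=use_q)
    res.attrs["contrast"] = contrast.label
    res.attrs["group_a"] = contrast.group_a.value
    res.attrs["group_b"] = contrast.group_b.value
    res.attrs["untested"] = untested
    return res


def _nb_wald_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = (va * (na - 1) + vb * (nb - 1)) / (na + nb - 2)
    mbar = (mean_a + mean_b) / 2
    disp = np.maximum(
        (s2 - mbar) / np.maximum(mbar, 1e-12) ** 2, DISPERSION_FLOOR
    )
    se2 = (1.0 / na) * (1.0 / (mean_a + _LOG_EPS) + disp) + (1.0 / nb) * (
        1.0 / (mean_b + _LOG_EPS) + disp
    )
    z = (np.log(mean_b + _LOG_EPS) - np.log(mean_a + _LOG_EPS)) / np.sqrt(se2)
    return 2.0 * stats.t.sf(np.abs(z), df=na + nb - 2)


def _welch_log_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # zero-variance / tied genes: undefined statistic -> p = 1
    return np.where(np.isfinite(p), p, 1.0)


def call_degs(
    results: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    use_q: bool = False,
) -> pd.DataFrame:
    """Assign up/down/ns calls from p (or q) and fold-change thresholds."""
    if fc_thresh <= 1:
        raise TrioHetError("fc_thresh must exceed 1")
    res = results.copy()
    crit = res["q"] if use_q else res["p"]
    fc = 2.0 ** res["log2fc"].to_numpy()
    sig = crit.to_numpy() < p_thresh
    call = np.where(
        sig & (fc > fc_thresh), "up", np.where(sig & (fc < 1.0 / fc_thresh), "down", "ns")
    )
    res["call"] = call
    res.attrs.update(results.attrs)
    return res


def deg_set(results: pd.DataFrame) -> set[str]:
    """Gene ids called up or down in one contrast."""
    mask = results["call"] != "ns"
    return set(results.loc[mask, "gene_id"])


def overlap_counts(deg_sets: dict[str, set[str]]) -> dict[str, dict[str, int]]:
    """Exclusive region counts of the Venn partition of 2-4 named sets.

    Region keys are '&'-joined sorted set names; each region counts elements
    in exactly those sets and no others. ``totals`` holds per-set sizes.
    """
    names = sorted(deg_sets)
    if not 2 <= len(names) <= 4:
        raise TrioHetError("overlap_counts needs between 2 and 4 sets")
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(deg_sets[n] for n in members))
            outside = set().union(
                *(deg_sets[n] for n in names if n not in members)
            )
            regions["&".join(members)] = len(inside - outside)
    totals = {n: len(deg_sets[n]) for n in names}
    return {"regions": regions, "totals": totals}
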