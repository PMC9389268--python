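"""Differential-expression testing, BH adjustment, DEG calls and overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triohet.diffexpr import (
    ContrastSpec,
    bh_adjust,
    call_degs,
    de_test,
    deg_set,
    overlap_counts,
)
from triohet.io import CountMatrix, Role, SampleDesign, TrioHetError
from triohet.simulate import SimConfig, simulate_trio


def _two_group(counts_a, counts_b):
    """Build a matrix + design with F-parent group A and hybrid group B."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    cm = CountMatrix(
        tuple(f"g{i}" for i in range(a.shape[0])),
        tuple(f"A{j}" for j in range(a.shape[1]))
        + tuple(f"B{j}" for j in range(b.shape[1])),
        np.hstack([a, b]),
    )
    design = [
        SampleDesign(f"A{j}", Role.FEMALE_PARENT, j + 1) for j in range(a.shape[1])
    ] + [SampleDesign(f"B{j}", Role.HYBRID, j + 1) for j in range(b.shape[1])]
    return cm, design


HF = ContrastSpec(Role.FEMALE_PARENT, Role.HYBRID, "H_vs_F")


@pytest.mark.parametrize("method", ["nb_wald", "welch_log"])
def test_identical_groups_are_null(method):
    rng = np.random.default_rng(1)
    block = rng.integers(1, 500, (30, 3))
    cm, design = _two_group(block, block)
    res = de_test(cm, design, HF, method=method)
    np.testing.assert_allclose(res["log2fc"], 0.0)
    assert (res["call"] == "ns").all()
    np.testing.assert_allclose(res["p"], 1.0)


def test_group_swap_equivariance():
    """Swapping the contrast orientation negates log2fc and keeps p."""
    cfg = SimConfig(n_genes=80, n_reps=3, pattern_fractions={"conserved": 0.5, "P11": 0.5}, seed=5)
    counts, design, _, _ = simulate_trio(cfg)
    fwd = de_test(counts, design, ContrastSpec(Role.FEMALE_PARENT, Role.HYBRID))
    rev = de_test(counts, design, ContrastSpec(Role.HYBRID, Role.FEMALE_PARENT))
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
    np.testing.assert_allclose(fwd["p"], rev["p"])


def test_library_scaling_leaves_calls_unchanged():
    cfg = SimConfig(n_genes=100, n_reps=3, pattern_fractions={"conserved": 0.8, "P11": 0.2}, seed=6)
    counts, design, _, _ = simulate_trio(cfg)
    res = de_test(counts, design, HF)
    scaled = CountMatrix(
        counts.gene_ids, counts.sample_ids, counts.counts * 7
    )
    res_scaled = de_test(scaled, design, HF)
    assert (res["call"] == res_scaled["call"]).all()


def test_all_zero_genes_reported_untested():
    a = np.array([[0, 0, 0], [5, 6, 7]])
    b = np.array([[0, 0, 0], [5, 6, 7]])
    cm, design = _two_group(a, b)
    res = de_test(cm, design, HF)
    assert res.attrs["untested"] == ["g0"]
    assert list(res["gene_id"]) == ["g1"]


def test_insufficient_replicates_raises():
    cm, design = _two_group(np.array([[1], [2]]), np.array([[1, 2], [3, 4]]))
    with pytest.raises(TrioHetError, match="replicates"):
        de_test(cm, design, HF)


def test_absent_group_raises():
    cm, design = _two_group(np.array([[1, 2], [3, 4]]), np.array([[1, 2], [3, 4]]))
    with pytest.raises(TrioHetError, match="male_parent"):
        de_test(cm, design, ContrastSpec(Role.MALE_PARENT, Role.HYBRID))


def _bh_brute_force(p):
    """Literal O(m^2) step-up: q_(i) = min_{j>=i} m*p_(j)/j, clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([1.0]), [1.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_brute_force(ps):
    np.testing.assert_allclose(bh_adjust(ps), _bh_brute_force(ps), atol=1e-12)


def test_bh_monotone_in_rank():
    rng = np.random.default_rng(7)
    p = rng.random(200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(TrioHetError):
        bh_adjust([0.5, 1.5])


@pytest.mark.parametrize(
    "p,log2fc,expected",
    [
        (0.01, np.log2(3), "up"),
        (0.01, np.log2(1.5), "ns"),
        (0.2, np.log2(10), "ns"),
        (0.01, np.log2(0.2), "down"),
    ],
)
def test_call_degs_threshold_rule(p, log2fc, expected):
    res = pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc], "p": [p], "q": [p]})
    assert call_degs(res)["call"].iloc[0] == expected


def test_call_degs_requires_fc_above_one():
    res = pd.DataFrame({"gene_id": ["g"], "log2fc": [0.0], "p": [1.0], "q": [1.0]})
    with pytest.raises(TrioHetError):
        call_degs(res, fc_thresh=1.0)


def test_overlap_counts_hand_example():
    out = overlap_counts({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}})
    assert out["regions"]["A&B&C"] == 1
    assert out["regions"]["A"] == 1
    assert out["regions"]["B"] == 1
    assert out["regions"]["C"] == 0
    assert out["totals"] == {"A": 3, "B": 3, "C": 1}


def test_overlap_counts_disjoint_sets():
    out = overlap_counts({"A": {1}, "B": {2}})
    assert out["regions"] == {"A": 1, "B": 1, "A&B": 0}


def test_overlap_counts_matches_membership_enumeration():
    """Region counts agree with brute-force per-element membership tally."""
    rng = np.random.default_rng(8)
    names = ["A", "B", "C", "D"]
    sets = {n: set(rng.integers(0, 60, 40).tolist()) for n in names}
    out = overlap_counts(sets)
    universe = set().union(*sets.values())
    brute: dict[str, int] = {}
    for x in universe:
        members = tuple(n for n in names if x in sets[n])
        brute["&".join(members)] = brute.get("&".join(members), 0) + 1
    for key, count in out["regions"].items():
        assert count == brute.get(key, 0)


def test_overlap_counts_set_limit():
    with pytest.raises(TrioHetError):
        overlap_counts({str(i): {i} for i in range(5)})


def test_threshold_monotonicity():
    """DEG sets at fc_thresh=4 are subsets of those at fc_thresh=2."""
    cfg = SimConfig(n_genes=200, n_reps=3, pattern_fractions={"conserved": 0.7, "P11": 0.2, "P8": 0.1}, seed=13)
    counts, design, _, _ = simulate_trio(cfg)
    loose = deg_set(de_test(counts, design, HF, fc_thresh=2.0))
    strict = deg_set(de_test(counts, design, HF, fc_thresh=4.0))
    assert strict <= loose
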