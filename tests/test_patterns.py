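"""Inheritance-pattern classification: exhaustive oracle and symmetries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triohet.io import Role, TrioHetError
from triohet.patterns import (
    CATEGORY3,
    CATEGORY5,
    assign_patterns,
    classify_pattern,
    sign_trio,
    summarize_patterns,
    swap_parents,
)

# Independent truth table, written out by hand from the pattern definitions:
# s_HF (hybrid vs female parent), s_HM (hybrid vs male parent), s_FM
# (female vs male parent); '+' = first member significantly higher.
HAND_TRUTH = {
    ("-", "+", "+"): "P1",   # F > H > M
    ("+", "-", "-"): "P2",   # M > H > F
    ("+", "0", "-"): "P3",   # H = M > F
    ("-", "0", "+"): "P4",   # F > H = M
    ("0", "-", "-"): "P5",   # M > H = F
    ("0", "+", "+"): "P6",   # H = F > M
    ("-", "-", "+"): "P7",   # below both, F > M
    ("-", "-", "0"): "P8",   # below both, F = M
    ("-", "-", "-"): "P9",   # below both, F < M
    ("+", "+", "+"): "P10",  # above both, F > M
    ("+", "+", "0"): "P11",  # above both, F = M
    ("+", "+", "-"): "P12",  # above both, F < M
    ("0", "0", "0"): "conserved",
}

ALL_TRIOS = list(itertools.product("+-0", repeat=3))


def test_exhaustive_27_trio_enumeration():
    """Every sign trio maps to exactly one label; 13 trios carry a pattern
    or conserved label, the remaining 14 are ambiguous."""
    labels = {t: classify_pattern(t) for t in ALL_TRIOS}
    for trio, expected in HAND_TRUTH.items():
        assert labels[trio] == expected
    ambiguous = [t for t, l in labels.items() if l == "ambiguous"]
    assert len(ambiguous) == 27 - len(HAND_TRUTH) == 14
    assert set(HAND_TRUTH) == {t for t, l in labels.items() if l != "ambiguous"}


def test_parent_swap_symmetry():
    """Relabeling parents maps P1<->P2, P3<->P6, P4<->P5, P7<->P9,
    P10<->P12 and fixes P8, P11, conserved and ambiguous."""
    expected_map = {
        "P1": "P2", "P2": "P1", "P3": "P6", "P6": "P3", "P4": "P5",
        "P5": "P4", "P7": "P9", "P9": "P7", "P8": "P8", "P10": "P12",
        "P12": "P10", "P11": "P11", "conserved": "conserved",
        "ambiguous": "ambiguous",
    }
    for trio in ALL_TRIOS:
        assert classify_pattern(swap_parents(trio)) == expected_map[
            classify_pattern(trio)
        ]


def test_category_mapping_is_total_and_fixed():
    assert {CATEGORY5[f"P{i}"] for i in (1, 2)} == {"additive"}
    assert {CATEGORY5[f"P{i}"] for i in (3, 4)} == {"paternal_dominant"}
    assert {CATEGORY5[f"P{i}"] for i in (5, 6)} == {"maternal_dominant"}
    assert {CATEGORY5[f"P{i}"] for i in (7, 8, 9)} == {"below_low_parent"}
    assert {CATEGORY5[f"P{i}"] for i in (10, 11, 12)} == {"above_high_parent"}
    assert {CATEGORY3[CATEGORY5[f"P{i}"]] for i in (3, 4, 5, 6)} == {"dominant"}
    assert {CATEGORY3[CATEGORY5[f"P{i}"]] for i in range(7, 13)} == {"over_dominant"}


def test_invalid_sign_rejected():
    with pytest.raises(TrioHetError):
        classify_pattern(("+", "x", "0"))


def _de_table(calls, group_a, group_b):
    t = pd.DataFrame(
        {
            "gene_id": list(calls),
            "log2fc": 0.0,
            "p": 0.0,
            "q": 0.0,
            "call": list(calls.values()),
        }
    )
    t.attrs["group_a"] = group_a
    t.attrs["group_b"] = group_b
    return t


def test_sign_trio_direct_mapping():
    hf = _de_table({"g": "up"}, "female_parent", "hybrid")
    hm = _de_table({"g": "up"}, "male_parent", "hybrid")
    fm = _de_table({"g": "ns"}, "male_parent", "female_parent")
    assert sign_trio("g", hf, hm, fm) == ("+", "+", "0")


def test_sign_trio_all_ns():
    hf = _de_table({"g": "ns"}, "female_parent", "hybrid")
    hm = _de_table({"g": "ns"}, "male_parent", "hybrid")
    fm = _de_table({"g": "ns"}, "male_parent", "female_parent")
    assert sign_trio("g", hf, hm, fm) == ("0", "0", "0")


def test_sign_trio_orientation_autocorrected():
    """A parent-vs-hybrid table gives the same trio as hybrid-vs-parent."""
    hf_fwd = _de_table({"g": "up"}, "female_parent", "hybrid")
    hf_rev = _de_table({"g": "down"}, "hybrid", "female_parent")
    hm = _de_table({"g": "up"}, "male_parent", "hybrid")
    fm = _de_table({"g": "down"}, "male_parent", "female_parent")
    assert sign_trio("g", hf_fwd, hm, fm) == sign_trio("g", hf_rev, hm, fm) == (
        "+",
        "+",
        "-",
    )


def test_sign_trio_wrong_contrast_pair_raises():
    hf = _de_table({"g": "up"}, "female_parent", "hybrid")
    with pytest.raises(TrioHetError):
        sign_trio("g", hf, hf, hf)


def test_assign_patterns_universe_is_deg_union():
    hf = _de_table({"g1": "up", "g2": "ns", "g3": "ns"}, "female_parent", "hybrid")
    hm = _de_table({"g1": "up", "g2": "ns", "g3": "ns"}, "male_parent", "hybrid")
    fm = _de_table({"g1": "ns", "g2": "down", "g3": "ns"}, "male_parent", "female_parent")
    out = assign_patterns(hf, hm, fm)
    assert set(out["gene_id"]) == {"g1", "g2"}
    row = out.set_index("gene_id")
    assert row.loc["g1", "pattern"] == "P11"
    assert row.loc["g2", "pattern"] == "ambiguous"


def test_summarize_patterns_arithmetic():
    assignments = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "pattern": ["P1"] + ["P3"] * 3 + ["P10"] * 6,
        }
    )
    assignments["category5"] = assignments["pattern"].map(CATEGORY5)
    assignments["category3"] = assignments["category5"].map(CATEGORY3)
    summary = summarize_patterns(assignments)
    props = summary.proportions("category3")
    assert props == pytest.approx(
        {"additive": 0.1, "dominant": 0.3, "over_dominant": 0.6}
    )
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)


def test_summarize_all_conserved_flags_zero_denominator():
    assignments = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "pattern": ["conserved", "conserved"],
            "category5": ["none", "none"],
            "category3": ["none", "none"],
        }
    )
    summary = summarize_patterns(assignments)
    assert summary.n_classified == 0
    assert all(v == 0.0 for v in summary.proportions("category3").values())


def test_summarize_empty_raises():
    with pytest.raises(TrioHetError):
        summarize_patterns(pd.DataFrame(columns=["gene_id", "pattern", "category5", "category3"]))
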