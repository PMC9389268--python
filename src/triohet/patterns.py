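"""Inheritance-pattern classification of hybrid gene expression.

Every gene gets a trio of significant-direction signs from the three
pairwise contrasts of the trio design — hybrid vs female parent (H vs F),
hybrid vs male parent (H vs M), and female vs male parent (F vs M) — where
``+`` means the first member is significantly higher, ``-`` significantly
lower, and ``0`` not significant. The sign trio maps deterministically onto
twelve inheritance patterns:

========  ==============================  =================
pattern   expression ordering             (s_HF, s_HM, s_FM)
========  ==============================  =================
P1        F > H > M (additive)            (-, +, +)
P2        M > H > F (additive)            (+, -, -)
P3        H = M, F < M (paternal dom.)    (+, 0, -)
P4        H = M, F > M (paternal dom.)    (-, 0, +)
P5        H = F, F < M (maternal dom.)    (0, -, -)
P6        H = F, F > M (maternal dom.)    (0, +, +)
P7-P9     H below both parents            (-, -, +/0/-)
P10-P12   H above both parents            (+, +, +/0/-)
========  ==============================  =================

(0, 0, 0) is "conserved"; the remaining trios are "ambiguous". The five
categories are additive (P1-P2), paternal dominant (P3-P4), maternal
dominant (P5-P6), below-low-parent (P7-P9) and above-high-parent
(P10-P12); the three-way grouping is additive / dominant (P3-P6) /
over-dominant (P7-P12).

Classification is driven by significance calls, not raw means: a gene
numerically between its parents but not significantly different from
either is conserved, not additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import Role, TrioHetError

Sign = str  # one of "+", "-", "0"

PLUS, MINUS, ZERO = "+", "-", "0"

#: Normative trio -> pattern mapping. Within each dominant pair the lower
#: index is the "hybrid equals the higher parent" case; within the
#: over/under-dominant triples the middle index is the equal-parents case.
PATTERN_TABLE: dict[tuple[Sign, Sign, Sign], str] = {
    (MINUS, PLUS, PLUS): "P1",
    (PLUS, MINUS, MINUS): "P2",
    (PLUS, ZERO, MINUS): "P3",
    (MINUS, ZERO, PLUS): "P4",
    (ZERO, MINUS, MINUS): "P5",
    (ZERO, PLUS, PLUS): "P6",
    (MINUS, MINUS, PLUS): "P7",
    (MINUS, MINUS, ZERO): "P8",
    (MINUS, MINUS, MINUS): "P9",
    (PLUS, PLUS, PLUS): "P10",
    (PLUS, PLUS, ZERO): "P11",
    (PLUS, PLUS, MINUS): "P12",
    (ZERO, ZERO, ZERO): "conserved",
}

CATEGORY5 = {
    "P1": "additive",
    "P2": "additive",
    "P3": "paternal_dominant",
    "P4": "paternal_dominant",
    "P5": "maternal_dominant",
    "P6": "maternal_dominant",
    "P7": "below_low_parent",
    "P8": "below_low_parent",
    "P9": "below_low_parent",
    "P10": "above_high_parent",
    "P11": "above_high_parent",
    "P12": "above_high_parent",
    "conserved": "none",
    "ambiguous": "none",
}

CATEGORY3 = {
    "additive": "additive",
    "paternal_dominant": "dominant",
    "maternal_dominant": "dominant",
    "below_low_parent": "over_dominant",
    "above_high_parent": "over_dominant",
    "none": "none",
}

ALL_PATTERNS = [f"P{i}" for i in range(1, 13)] + ["conserved", "ambiguous"]


def classify_pattern(trio: tuple[Sign, Sign, Sign]) -> str:
    """Map a (s_HF, s_HM, s_FM) sign trio to its pattern label."""
    for s in trio:
        if s not in (PLUS, MINUS, ZERO):
            raise TrioHetError(f"invalid sign {s!r}; expected '+', '-' or '0'")
    return PATTERN_TABLE.get(tuple(trio), "ambiguous")


def _call_to_sign(call: str, flip: bool) -> Sign:
    if call == "ns":
        return ZERO
    sign = PLUS if call == "up" else MINUS
    if flip:
        sign = MINUS if sign == PLUS else PLUS
    return sign


def _orient(table: pd.DataFrame, first: Role, second: Role) -> bool:
    """Whether the table's up-call means `first` is higher. Returns flip flag."""
    ga, gb = table.attrs.get("group_a"), table.attrs.get("group_b")
    if (ga, gb) == (second.value, first.value):
        return False  # numerator is `first`: up already means first higher
    if (ga, gb) == (first.value, second.value):
        return True  # numerator is `second`: flip
    raise TrioHetError(
        f"DE table contrasts {ga!r} vs {gb!r}; expected the "
        f"{first.value}/{second.value} pair"
    )


def sign_trio(
    gene_id: str,
    de_hf: pd.DataFrame,
    de_hm: pd.DataFrame,
    de_fm: pd.DataFrame,
) -> tuple[Sign, Sign, Sign]:
    """Significant-direction signs for one gene from the three DE tables.

    Orientation is auto-corrected from each table's contrast metadata, so
    tables fit either as hybrid-vs-parent or parent-vs-hybrid. A gene absent
    from a table (untested there) contributes a ``0``.
    """
    flips = (
        _orient(de_hf, Role.HYBRID, Role.FEMALE_PARENT),
        _orient(de_hm, Role.HYBRID, Role.MALE_PARENT),
        _orient(de_fm, Role.FEMALE_PARENT, Role.MALE_PARENT),
    )
    signs = []
    for table, flip in zip((de_hf, de_hm, de_fm), flips):
        rows = table.loc[table["gene_id"] == gene_id, "call"]
        call = rows.iloc[0] if len(rows) else "ns"
        signs.append(_call_to_sign(call, flip))
    return tuple(signs)


def assign_patterns(
    de_hf: pd.DataFrame,
    de_hm: pd.DataFrame,
    de_fm: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pattern assignment for a gene universe (default: union of DEGs).

    Returns columns gene_id, s_HF, s_HM, s_FM, pattern, category5,
    category3.
    """
    flips = (
        _orient(de_hf, Role.HYBRID, Role.FEMALE_PARENT),
        _orient(de_hm, Role.HYBRID, Role.MALE_PARENT),
        _orient(de_fm, Role.FEMALE_PARENT, Role.MALE_PARENT),
    )
    call_maps = [
        dict(zip(t["gene_id"], t["call"])) for t in (de_hf, de_hm, de_fm)
    ]
    if universe is None:
        universe = set()
        for t in (de_hf, de_hm, de_fm):
            universe |= set(t.loc[t["call"] != "ns", "gene_id"])
    genes = sorted(universe)
    records = []
    for g in genes:
        trio = tuple(
            _call_to_sign(cm.get(g, "ns"), flip)
            for cm, flip in zip(call_maps, flips)
        )
        pattern = classify_pattern(trio)
        cat5 = CATEGORY5[pattern]
        records.append(
            {
                "gene_id": g,
                "s_HF": trio[0],
                "s_HM": trio[1],
                "s_FM": trio[2],
                "pattern": pattern,
                "category5": cat5,
                "category3": CATEGORY3[cat5],
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["gene_id", "s_HF", "s_HM", "s_FM", "pattern", "category5", "category3"],
    )


@dataclass(frozen=True)
class PatternSummary:
    """Counts and proportions per pattern and per category.

    ``n_classified`` (the proportion denominator) excludes conserved and
    ambiguous genes unless the summary was built with
    ``include_unclassified=True``.
    """

    pattern_counts: dict[str, int]
    category5_counts: dict[str, int]
    category3_counts: dict[str, int]
    n_total: int
    n_classified: int

    def proportions(self, which: str = "category3") -> dict[str, float]:
        counts = {
            "pattern": self.pattern_counts,
            "category5": self.category5_counts,
            "category3": self.category3_counts,
        }[which]
        if self.n_classified == 0:
            return {k: 0.0 for k in counts if k != "none"}
        return {
            k: v / self.n_classified for k, v in counts.items() if k != "none"
        }

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "pattern_counts": self.pattern_counts,
            "category5_counts": self.category5_counts,
            "category3_counts": self.category3_counts,
            "category5_proportions": self.proportions("category5"),
            "category3_proportions": self.proportions("category3"),
        }


def summarize_patterns(
    assignments: pd.DataFrame, include_unclassified: bool = False
) -> PatternSummary:
    """Aggregate per-gene assignments into pattern/category tallies."""
    if len(assignments) == 0:
        raise TrioHetError("no genes to summarize")
    pattern_counts = {
        p: int((assignments["pattern"] == p).sum()) for p in ALL_PATTERNS
    }
    cat5_counts: dict[str, int] = {}
    cat3_counts: dict[str, int] = {}
    for cat in set(CATEGORY5.values()):
        cat5_counts[cat] = int((assignments["category5"] == cat).sum())
    for cat in set(CATEGORY3.values()):
        cat3_counts[cat] = int((assignments["category3"] == cat).sum())
    n_total = len(assignments)
    classified = assignments["category3"] != "none"
    n_classified = n_total if include_unclassified else int(classified.sum())
    return PatternSummary(
        pattern_counts=pattern_counts,
        category5_counts=cat5_counts,
        category3_counts=cat3_counts,
        n_total=n_total,
        n_classified=n_classified,
    )


def swap_parents(trio: tuple[Sign, Sign, Sign]) -> tuple[Sign, Sign, Sign]:
    """Sign trio after relabeling the parents (F <-> M).

    H-vs-F and H-vs-M swap places; the parent contrast flips sign. Useful
    for symmetry checks: the induced pattern map is P1<->P2, P3<->P6,
    P4<->P5, P7<->P9, P10<->P12, with P8 and P11 fixed.
    """
    s_hf, s_hm, s_fm = trio
    neg = {PLUS: MINUS, MINUS: PLUS, ZERO: ZERO}
    return (s_hm, s_hf, neg[s_fm])
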