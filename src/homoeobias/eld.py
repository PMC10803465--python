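"""Expression-level dominance (ELD) classification.

Each gene pair is classified from three trinary differential-expression
calls: focal group (hybrid or allotetraploid) versus parent K, focal versus
parent T, and parent K versus parent T (all oriented first-over-second).
The 27 call patterns map onto the classical twelve categories:

- additivity (I, XII): focal between two differing parents;
- T-dominance (II, XI): focal matches parent T while parents differ;
- K-dominance (IV, IX): focal matches parent K while parents differ;
- transgressive up-regulation (V, VI, VIII): focal above both parents;
- transgressive down-regulation (III, VII, X): focal below both parents.

A focal group not differing from either parent is "No Change" regardless of
the parental contrast.  Twelve patterns fit none of the above — six where the
focal differs from exactly one parent although the parents do not differ, and
six that are internally contradictory (e.g. focal above the higher parent but
below the lower).  These are labelled AMBIGUOUS and reported separately (or
optionally folded into No Change).
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataModelError
from .norm import DOWN, NS, UP

CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")
NO_CHANGE = "NO_CHANGE"
AMBIGUOUS = "AMBIGUOUS"

ADD, T_DOM, K_DOM, TUR, TDR, NC = "ADD", "T_DOM", "K_DOM", "TUR", "TDR", "NC"
COLLAPSED_LABELS = (ADD, T_DOM, K_DOM, TUR, TDR, NC)

#: category -> collapsed five-way label (+ NC)
COLLAPSE_MAP: dict[str, str] = {
    "I": ADD, "XII": ADD,
    "II": T_DOM, "XI": T_DOM,
    "IV": K_DOM, "IX": K_DOM,
    "V": TUR, "VI": TUR, "VIII": TUR,
    "III": TDR, "VII": TDR, "X": TDR,
    NO_CHANGE: NC,
    AMBIGUOUS: AMBIGUOUS,
}


def _build_decision_table() -> dict[tuple[str, str, str], str]:
    table: dict[tuple[str, str, str], str] = {}
    for kvt in (UP, DOWN, NS):
        table[(NS, NS, kvt)] = NO_CHANGE
    # parents differ, K < T (K-over-T call DOWN)
    table[(UP, NS, DOWN)] = "II"     # focal = higher parent T
    table[(NS, DOWN, DOWN)] = "IX"   # focal = lower parent K
    table[(DOWN, DOWN, DOWN)] = "III"  # below both
    table[(UP, UP, DOWN)] = "VIII"   # above both
    table[(UP, DOWN, DOWN)] = "I"    # between: additive
    # parents differ, K > T (K-over-T call UP)
    table[(NS, UP, UP)] = "IV"       # focal = higher parent K
    table[(DOWN, NS, UP)] = "XI"     # focal = lower parent T
    table[(DOWN, DOWN, UP)] = "X"
    table[(UP, UP, UP)] = "V"
    table[(DOWN, UP, UP)] = "XII"
    # parents equal
    table[(UP, UP, NS)] = "VI"
    table[(DOWN, DOWN, NS)] = "VII"
    for pattern in product((UP, DOWN, NS), repeat=3):
        table.setdefault(pattern, AMBIGUOUS)
    return table


DECISION_TABLE = _build_decision_table()


def classify_eld(call_pvk: str, call_pvt: str, call_kvt: str, ambiguous_mode: str = "strict") -> str:
    """Category for one gene from the three calls (focal/K, focal/T, K/T).

    ``ambiguous_mode="fold_into_nc"`` reports the twelve unassignable
    patterns as No Change instead of AMBIGUOUS.
    """
    key = (call_pvk, call_pvt, call_kvt)
    for c in key:
        if c not in (UP, DOWN, NS):
            raise DataModelError(f"invalid call symbol {c!r}")
    cat = DECISION_TABLE[key]
    if cat == AMBIGUOUS and ambiguous_mode == "fold_into_nc":
        return NO_CHANGE
    return cat


def collapse(category: str) -> str:
    """Collapsed label (ADD / T_DOM / K_DOM / TUR / TDR / NC / AMBIGUOUS)."""
    try:
        return COLLAPSE_MAP[category]
    except KeyError:
        raise DataModelError(f"unknown category {category!r}") from None


def classify_records(
    calls: pd.DataFrame, group: str, ambiguous_mode: str = "strict"
) -> pd.DataFrame:
    """Classify a table of per-pair calls (columns PvK, PvT, KvT).

    Returns a frame with ``group``, ``category`` and ``collapsed`` columns,
    indexed like ``calls``.
    """
    cats = [
        classify_eld(r.PvK, r.PvT, r.KvT, ambiguous_mode=ambiguous_mode)
        for r in calls.itertuples()
    ]
    out = pd.DataFrame(index=calls.index)
    out["group"] = group
    out["category"] = cats
    out["collapsed"] = [collapse(c) for c in cats]
    return out


def category_counts(labels: pd.Series, order: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts and proportions per label (proportions sum to 1)."""
    if len(labels) == 0:
        raise DataModelError("no records to count")
    counts = labels.value_counts()
    if order is None:
        order = [l for l in list(CATEGORIES) + [NO_CHANGE, AMBIGUOUS] + list(COLLAPSED_LABELS)
                 if l in counts.index]
        order += [l for l in counts.index if l not in order]
    counts = counts.reindex(order).fillna(0).astype(int)
    return pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})


def transition_table(
    src: pd.Series,
    dst: pd.Series,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate label transitions between two classifications of the
    same gene universe (rows = source, columns = destination)."""
    only_src = src.index.difference(dst.index)
    only_dst = dst.index.difference(src.index)
    if len(only_src) or len(only_dst):
        raise DataModelError(
            f"gene universes differ: only in source {only_src[:5].tolist()}, "
            f"only in destination {only_dst[:5].tolist()}"
        )
    dst = dst.reindex(src.index)
    if labels is None:
        labels = list(COLLAPSED_LABELS) + [AMBIGUOUS]
    seen = set(src) | set(dst)
    unknown = seen - set(labels)
    if unknown:
        raise DataModelError(f"labels outside the table's label set: {sorted(unknown)}")
    tab = pd.crosstab(src, dst)
    tab = tab.reindex(index=labels, columns=labels, fill_value=0)
    tab.index.name = "from"
    tab.columns.name = "to"
    return tab
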