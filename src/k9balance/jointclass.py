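"""Joint RNA x K9 direction classification and up/down balance tests."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JointClassTable",
    "classify_joint",
    "balance_chi_square",
    "proportion_summary",
    "category_balance",
]


class JointClassError(ValueError):
    pass


QUADRANTS = (
    ("up", "up"),
    ("up", "down"),
    ("down", "up"),
    ("down", "down"),
)


@dataclass
class JointClassTable:
    """Per-feature joint calls plus quadrant counts.

    ``table`` holds rna_call/k9_call for the shared feature universe;
    ``quadrants`` maps (rna_call, k9_call) -> count over features significant
    in both assays.
    """

    table: pd.DataFrame
    quadrants: Dict[Tuple[str, str], int]

    @property
    def n_both_significant(self) -> int:
        return sum(self.quadrants.values())


def classify_joint(rna_results: pd.DataFrame, k9_results: pd.DataFrame) -> JointClassTable:
    """Quadrant classification of features significant in both assays.

    Both inputs need a ``call`` column over a shared feature universe; the
    quadrant table covers the intersection restricted to features whose call
    is up or down in BOTH assays.
    """
    shared = rna_results.index.intersection(k9_results.index)
    if len(shared) == 0:
        raise JointClassError("RNA and K9 results share no features")
    table = pd.DataFrame(
        {
            "rna_call": rna_results.loc[shared, "call"],
            "k9_call": k9_results.loc[shared, "call"],
        }
    )
    both = table[(table["rna_call"] != "ns") & (table["k9_call"] != "ns")]
    quadrants = {q: 0 for q in QUADRANTS}
    for (r, k), n in both.value_counts(["rna_call", "k9_call"]).items():
        quadrants[(r, k)] = int(n)
    return JointClassTable(table=table, quadrants=quadrants)


def balance_chi_square(up_count: int, down_count: int) -> Tuple[float, float]:
    """1-df goodness-of-fit chi-square against an equal 50/50 split.

    No continuity correction; p is the upper tail of chi2(1).
    """
    if up_count < 0 or down_count < 0:
        raise JointClassError("counts must be non-negative")
    n = up_count + down_count
    if n == 0:
        raise JointClassError("up + down must be >= 1")
    expected = n / 2.0
    chi2 = (up_count - expected) ** 2 / expected + (down_count - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def proportion_summary(up_count: int, down_count: int) -> Tuple[int, int]:
    """Integer up/down percentages, rounded half away from zero."""
    n = up_count + down_count
    if n < 1:
        raise JointClassError("up + down must be >= 1")
    pct_up = math.floor(100.0 * up_count / n + 0.5)
    pct_down = math.floor(100.0 * down_count / n + 0.5)
    return pct_up, pct_down


def category_balance(calls: pd.Series, categories: pd.DataFrame) -> pd.DataFrame:
    """Per-category up/down balance table with chi-square p-values.

    ``calls`` maps feature -> up/down/ns; ``categories`` is a two-column
    frame (feature, category), one row per membership.  Categories whose
    up+down total is zero are dropped.
    """
    rows = []
    for category, grp in categories.groupby("category", sort=True):
        feats = grp["feature"]
        sub = calls.reindex(feats).dropna()
        up = int((sub == "up").sum())
        down = int((sub == "down").sum())
        if up + down == 0:
            continue
        chi2, p = balance_chi_square(up, down)
        pct_up, pct_down = proportion_summary(up, down)
        rows.append(
            {
                "category": category,
                "up": up,
                "down": down,
                "percent_up": pct_up,
                "percent_down": pct_down,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "up", "down", "percent_up", "percent_down", "chi2", "p"]
    )
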