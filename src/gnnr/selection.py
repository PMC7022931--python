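"""Variable-selection rules and recovery scoring.

Because the eps-smoothed solver never returns exactly-zero coefficients,
selection is threshold based: the biomarker-set workflow keeps variables
whose median absolute coefficient over time points exceeds 1e-2, and the
recovery analysis ranks variables by |coefficient| per time point and
keeps the top n (160 at the first time point, 200 at the others, under
the default simulation design).  Recovery ratios score a selection
against the generator's ground truth per (group, time point); the ratio
on the never-discriminative groups is the false-recovery diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .data import VariableGroundTruth

__all__ = [
    "SelectionResult",
    "select_by_median_coef",
    "select_top_n",
    "recovery_ratios",
    "overlap_counts",
    "DEFAULT_MEDIAN_THRESHOLD",
    "DEFAULT_TOP_N",
]

DEFAULT_MEDIAN_THRESHOLD = 1e-2
DEFAULT_TOP_N = (160, 200, 200, 200)


@dataclass
class SelectionResult:
    """Selected variable index sets per time point plus provenance."""

    per_time: list[np.ndarray]
    rule: str
    method: str = ""

    def union(self) -> np.ndarray:
        return np.unique(np.concatenate([s for s in self.per_time])) if self.per_time else np.array([], int)


def select_by_median_coef(B: np.ndarray, threshold: float = DEFAULT_MEDIAN_THRESHOLD) -> np.ndarray:
    """Variables whose median |coefficient| over time points exceeds
    ``threshold`` (strict), sorted ascending."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if not np.isfinite(B).all():
        raise ValueError("coefficient matrix contains non-finite entries")
    med = np.median(np.abs(B), axis=1)
    return np.flatnonzero(med > threshold)


def select_top_n(B: np.ndarray, n_per_time: Sequence[int]) -> SelectionResult:
    """Per time point, the n variables with the largest |coefficient|.

    Ties are broken toward the smaller variable index.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    d, T = B.shape
    n_per_time = list(n_per_time)
    if len(n_per_time) != T:
        raise ValueError(f"need one n per time point ({T}), got {len(n_per_time)}")
    per_time = []
    for t, n in enumerate(n_per_time):
        if not 0 <= n <= d:
            raise ValueError(f"n={n} out of range for d={d}")
        # stable sort on (-|b|, index): ties go to the smaller index
        order = np.argsort(-np.abs(B[:, t]), kind="stable")
        per_time.append(np.sort(order[:n]))
    return SelectionResult(per_time=per_time, rule=f"topn:{','.join(map(str, n_per_time))}")


def recovery_ratios(
    selection: SelectionResult | Sequence[Sequence[int]], truth: VariableGroundTruth
) -> np.ndarray:
    """Fraction of each ground-truth group recovered at each time point.

    Entry (g, t) = |selected_t intersect group g| / |group g|, rows in
    ascending group-id order (the background group row is the
    false-recovery diagnostic).
    """
    per_time = selection.per_time if isinstance(selection, SelectionResult) else [
        np.asarray(s, dtype=int) for s in selection
    ]
    groups = truth.groups
    out = np.zeros((len(groups), len(per_time)))
    for gi, g in enumerate(groups):
        members = truth.members(g)
        if len(members) == 0:
            raise ValueError(f"group {g} has no members")
        for t, sel in enumerate(per_time):
            out[gi, t] = np.isin(members, sel).mean()
    return out


def overlap_counts(sets: Mapping[str, Sequence]) -> dict[tuple[str, ...], int]:
    """Cardinality of every region of the Venn partition of 2-4 named sets.

    Keys are the sorted tuples of set names whose exact intersection
    (minus all other sets) the region is; all 2^k - 1 regions are
    reported, empty ones with count 0.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("overlap_counts needs 2-4 named sets")
    as_sets = {k: set(map(int, np.asarray(list(sets[k]), dtype=int).ravel())) if len(sets[k]) else set() for k in names}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(as_sets[k] for k in combo))
            outside = set.union(*(as_sets[k] for k in names if k not in combo), set())
            counts[combo] = len(inside - outside)
    return counts
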