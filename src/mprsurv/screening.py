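"""Screening table: reconciling model-predicted and actual treatment.

Cross-classifies each subject's actual treatment status against the
allocation model's prediction at a probability cut-off (default 0.5, with
probability exactly at the cut-off classified as "treat").  Cell labels
follow the epidemiological convention:

    a  not treated, predicted not-treat   (true negatives)
    b  not treated, predicted treat       (false positives)
    c  treated,     predicted treat       (true positives)
    d  treated,     predicted not-treat   (false negatives)

Sensitivity = c/(c+d), specificity = a/(a+b); the false-positive and
false-negative rates are their complements.  Survival is stratified by
screening cell and by quartile of allocation probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .km import KMCurve, km_estimate

CELLS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class ScreeningTable:
    a: int
    b: int
    c: int
    d: int
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "cutoff": self.cutoff}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predicted_not_treat": [self.a, self.d],
                "predicted_treat": [self.b, self.c],
            },
            index=pd.Index(["not_treated", "treated"], name="truth"),
        )


def assign_cells(probs, treated_flags, cutoff: float = 0.5) -> np.ndarray:
    """Per-subject screening-cell label ('a'..'d')."""
    probs = np.asarray(probs, dtype=float)
    treated = np.asarray(treated_flags).astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != treated.shape:
        raise ValueError("probs and treated_flags must have equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    predicted = probs >= cutoff
    cells = np.empty(probs.shape, dtype=object)
    cells[(treated == 0) & ~predicted] = "a"
    cells[(treated == 0) & predicted] = "b"
    cells[(treated == 1) & predicted] = "c"
    cells[(treated == 1) & ~predicted] = "d"
    return cells


def build_screening_table(probs, treated_flags, cutoff: float = 0.5) -> ScreeningTable:
    cells = assign_cells(probs, treated_flags, cutoff)
    return ScreeningTable(
        a=int((cells == "a").sum()),
        b=int((cells == "b").sum()),
        c=int((cells == "c").sum()),
        d=int((cells == "d").sum()),
        cutoff=cutoff,
    )


def screening_metrics(table: ScreeningTable) -> dict[str, float]:
    """Sensitivity, specificity and error rates as fractions in [0, 1].

    ``sensitivity + fn_rate = 1`` and ``specificity + fp_rate = 1`` hold
    exactly by construction.
    """
    pos = table.c + table.d
    neg = table.a + table.b
    if pos == 0 or neg == 0:
        raise ZeroDivisionError("screening metrics undefined: empty truth margin")
    sensitivity = table.c / pos
    specificity = table.a / neg
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "fp_rate": 1.0 - specificity,
        "fn_rate": 1.0 - sensitivity,
    }


def survival_by_cell(
    cohort: pd.DataFrame, cell_labels, level: float = 0.95
) -> dict[str, KMCurve]:
    """One KM curve per occupied screening cell; empty cells are omitted
    with a warning."""
    cells = np.asarray(cell_labels)
    if cells.shape[0] != len(cohort):
        raise ValueError("cell labels must match the cohort length")
    curves: dict[str, KMCurve] = {}
    for cell in CELLS:
        mask = cells == cell
        if not mask.any():
            warnings.warn(f"screening cell {cell!r} is empty; curve omitted")
            continue
        curves[cell] = km_estimate(
            cohort.loc[mask, "time"], cohort.loc[mask, "event"], level
        )
    return curves


def quartile_assign(probs) -> np.ndarray:
    """Quartile group (1 = lowest probability .. 4 = highest) by rank.

    Ties break by input order (stable sort); group sizes differ by at most
    one, with any remainder allocated to the upper groups — n = 855 splits
    as 213/214/214/214.
    """
    probs = np.asarray(probs, dtype=float)
    n = probs.size
    if n < 4:
        raise ValueError("at least 4 subjects are required for quartiles")
    order = np.argsort(probs, kind="stable")
    q, r = divmod(n, 4)
    sizes = [q] * (4 - r) + [q + 1] * r
    groups = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        groups[order[start : start + size]] = g
        start += size
    return groups


def survival_by_quartile(
    cohort: pd.DataFrame, probs, level: float = 0.95
) -> dict[int, KMCurve]:
    """KM curve per allocation-probability quartile."""
    groups = quartile_assign(probs)
    return {
        g: km_estimate(
            cohort.loc[groups == g, "time"], cohort.loc[groups == g, "event"], level
        )
        for g in (1, 2, 3, 4)
    }
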