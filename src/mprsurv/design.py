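"""Categorical factor coding shared by the survival and allocation models.

Every model in the package works on dummy (treatment-contrast) designs built
from a fixed set of cohort factors.  The reference level of each factor is the
first entry of :data:`FACTOR_LEVELS` and carries an implicit coefficient of
zero; dummy columns are named ``"factor:level"`` so coefficient maps can be
resolved against them by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical level order for every cohort factor, reference level first.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "treatment": ("palliative", "surgery", "chemotherapy", "radiotherapy", "combined"),
    "who": ("normal", "light_work", "no_work", "wbc"),
    "age_group": ("<40", "40-", "50-", "60-", "70-"),
    "sex": ("male", "female"),
    "cell": ("squamous", "small", "adeno", "other"),
    "sodium": (">=136", "<136", "unknown"),
    "albumen": (">=3.5", "<3.5", "unknown"),
    "metastases": ("absent", "present", "unknown"),
    "smoking": ("never", "current", "ex", "unknown"),
}

INTERCEPT = "intercept"


class DesignError(ValueError):
    """A factor, level or coefficient name could not be resolved."""


def column_name(factor: str, level: str) -> str:
    return f"{factor}:{level}"


@dataclass(frozen=True)
class DesignSpec:
    """The coding of one linear predictor: which factors, which columns.

    ``columns`` always starts with the intercept; each remaining entry is a
    ``"factor:level"`` dummy for a non-reference level.
    """

    factors: tuple[str, ...]
    columns: tuple[str, ...]
    reference: dict[str, str] = field(default_factory=dict)

    def row(self, profile: dict[str, str]) -> np.ndarray:
        """Design row for a single covariate profile.

        Factors absent from ``profile`` sit at their reference level.
        """
        for factor, level in profile.items():
            if factor not in FACTOR_LEVELS:
                raise DesignError(f"unknown factor {factor!r}")
            if level not in FACTOR_LEVELS[factor]:
                raise DesignError(f"unknown level {level!r} for factor {factor!r}")
        x = np.zeros(len(self.columns))
        x[0] = 1.0
        for j, col in enumerate(self.columns[1:], start=1):
            factor, level = col.split(":", 1)
            if profile.get(factor, self.reference.get(factor)) == level:
                x[j] = 1.0
        return x


def validate_levels(cohort: pd.DataFrame, factors: list[str] | tuple[str, ...]) -> None:
    """Raise if any value of a factor column is outside its canonical levels."""
    for factor in factors:
        if factor not in FACTOR_LEVELS:
            raise DesignError(f"unknown factor {factor!r}")
        if factor not in cohort.columns:
            raise DesignError(f"cohort has no column {factor!r}")
        bad = set(cohort[factor].unique()) - set(FACTOR_LEVELS[factor])
        if bad:
            raise DesignError(f"unknown level(s) {sorted(bad)} in factor {factor!r}")


def build_design(
    cohort: pd.DataFrame,
    factors: list[str] | tuple[str, ...],
    *,
    require_occupied: bool = False,
) -> tuple[np.ndarray, DesignSpec]:
    """Dummy-code ``factors`` from the cohort into an (n, p) design matrix.

    The first column is the intercept.  With ``require_occupied`` a
    non-reference level with zero subjects raises, since its coefficient would
    be unidentifiable in a fit.
    """
    validate_levels(cohort, factors)
    n = len(cohort)
    cols: list[str] = [INTERCEPT]
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    reference: dict[str, str] = {}
    for factor in factors:
        levels = FACTOR_LEVELS[factor]
        reference[factor] = levels[0]
        values = cohort[factor].to_numpy()
        for level in levels[1:]:
            indicator = (values == level).astype(float)
            if require_occupied and indicator.sum() == 0:
                raise DesignError(
                    f"level {level!r} of factor {factor!r} has no subjects; "
                    "coefficient not identifiable"
                )
            cols.append(column_name(factor, level))
            blocks.append(indicator[:, None])
    X = np.hstack(blocks)
    return X, DesignSpec(tuple(factors), tuple(cols), reference)


def linear_predictor(cohort: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Evaluate ``intercept + Σ coef · dummy`` row-wise from a named map.

    Coefficient names are ``"intercept"`` or ``"factor:level"``; every name
    must resolve against the cohort columns and canonical levels.
    """
    eta = np.full(len(cohort), float(coefs.get(INTERCEPT, 0.0)))
    for name, value in coefs.items():
        if name == INTERCEPT:
            continue
        if ":" not in name:
            raise DesignError(f"coefficient name {name!r} is not 'factor:level'")
        factor, level = name.split(":", 1)
        if factor not in FACTOR_LEVELS or level not in FACTOR_LEVELS[factor]:
            raise DesignError(f"coefficient {name!r} does not match any factor level")
        if factor not in cohort.columns:
            raise DesignError(f"cohort has no column {factor!r}")
        eta += float(value) * (cohort[factor].to_numpy() == level)
    return eta
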