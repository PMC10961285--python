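"""Synthetic cohort generation with the structure the analysis assumes.

The study data are not deposited, so cohorts are simulated: covariates from
their published marginal counts, treatment either multinomial with the
published group sizes (``treatment_only`` mode) or allocated by the logistic
treatment model (``full`` mode), and survival from the Weibull
multi-parameter regression hazard λγt^{γ−1} with λ = exp(x'β),
γ = exp(z'α).  Subjects enter uniformly over a 12-month accrual window and
are administratively censored when the study closes 20 months after first
entry, so individual censoring times lie in (8, 20].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tables
from .design import FACTOR_LEVELS, DesignError, linear_predictor

COHORT_COLUMNS = (
    "id",
    "time",
    "event",
    "treatment",
    "treated",
    "who",
    "age_group",
    "sex",
    "cell",
    "sodium",
    "albumen",
    "metastases",
    "smoking",
)

MODES = ("treatment_only", "full")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters; immutable so a config fully identifies a cohort.

    ``category_freqs`` entries may be counts (summing to ``n``) or proportions
    (summing to 1).  ``treated_split`` gives the therapy mix among treated
    subjects and must cover exactly the non-palliative categories.
    """

    n: int
    mode: str
    scale_coefs: dict[str, float]
    shape_coefs: dict[str, float]
    logit_coefs: dict[str, float] | None = None
    category_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    treated_split: dict[str, float] = field(default_factory=dict)
    accrual_months: float = tables.ACCRUAL_MONTHS
    max_followup_months: float = tables.MAX_FOLLOWUP_MONTHS
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n <= 0:
            raise ConfigError(f"n must be a positive integer, got {self.n!r}")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.accrual_months < self.max_followup_months:
            raise ConfigError(
                "accrual window must be positive and shorter than the study span"
            )
        if self.mode == "full" and not self.logit_coefs:
            raise ConfigError("full mode requires logit_coefs")
        for factor, freqs in self.category_freqs.items():
            if factor not in FACTOR_LEVELS:
                raise ConfigError(f"unknown factor {factor!r} in category_freqs")
            bad = set(freqs) - set(FACTOR_LEVELS[factor])
            if bad:
                raise ConfigError(f"unknown level(s) {sorted(bad)} for {factor!r}")
            if any(v < 0 for v in freqs.values()):
                raise ConfigError(f"negative frequency in factor {factor!r}")
            total = sum(freqs.values())
            if not (
                np.isclose(total, 1.0, atol=1e-9) or np.isclose(total, self.n, atol=1e-9)
            ):
                raise ConfigError(
                    f"frequencies for {factor!r} sum to {total}, "
                    f"expected 1 (proportions) or n={self.n} (counts)"
                )
        if self.treated_split:
            active = set(FACTOR_LEVELS["treatment"][1:])
            if set(self.treated_split) != active:
                raise ConfigError(
                    f"treated_split must cover exactly {sorted(active)}"
                )
            if not np.isclose(sum(self.treated_split.values()), 1.0, atol=1e-9):
                raise ConfigError("treated_split proportions must sum to 1")


def _probs(freqs: dict[str, float], levels: tuple[str, ...]) -> np.ndarray:
    p = np.array([freqs.get(level, 0.0) for level in levels], dtype=float)
    return p / p.sum()


def _default_freqs(n: int) -> dict[str, dict[str, float]]:
    # published counts are kept verbatim at the study size; any other n
    # carries the same margins as proportions
    freqs = {k: dict(v) for k, v in tables.CATEGORY_FREQS.items()}
    if n != tables.COHORT_N:
        for factor, table in freqs.items():
            total = sum(table.values())
            freqs[factor] = {k: v / total for k, v in table.items()}
    return freqs


def default_treatment_only_config(n: int = tables.COHORT_N, seed: int = 0) -> CohortConfig:
    """The published treatment-only model as the data-generating truth."""
    return CohortConfig(
        n=n,
        mode="treatment_only",
        scale_coefs=dict(tables.TREATMENT_ONLY_SCALE),
        shape_coefs=dict(tables.TREATMENT_ONLY_SHAPE),
        category_freqs=_default_freqs(n),
        treated_split=_default_split(),
        seed=seed,
    )


def default_full_config(n: int = tables.COHORT_N, seed: int = 0) -> CohortConfig:
    """The published multi-factor survival and allocation models as truth."""
    return CohortConfig(
        n=n,
        mode="full",
        scale_coefs=dict(tables.FULL_SCALE),
        shape_coefs=dict(tables.FULL_SHAPE),
        logit_coefs=dict(tables.ALLOCATION_COEFS),
        category_freqs=_default_freqs(n),
        treated_split=_default_split(),
        seed=seed,
    )


def _default_split() -> dict[str, float]:
    sizes = tables.TREATMENT_GROUP_SIZES
    treated = sum(v for k, v in sizes.items() if k != "palliative")
    return {k: v / treated for k, v in sizes.items() if k != "palliative"}


def sample_weibull(
    rng: np.random.Generator, lam: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """Exact inverse-transform draw: T = (−log U / λ)^{1/γ}."""
    lam = np.asarray(lam, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(lam <= 0) or np.any(gamma <= 0):
        raise ValueError("Weibull scale and shape must be positive")
    u = rng.uniform(size=np.broadcast(lam, gamma).shape)
    return (-np.log(u) / lam) ** (1.0 / gamma)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort table; identical config + seed gives identical rows."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    data: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for factor in COHORT_COLUMNS[5:]:
        levels = FACTOR_LEVELS[factor]
        freqs = config.category_freqs.get(factor)
        if freqs is None:
            # factor irrelevant to the configured models: reference level
            data[factor] = np.full(n, levels[0], dtype=object)
        else:
            data[factor] = rng.choice(levels, size=n, p=_probs(freqs, levels))
    frame = pd.DataFrame(data)

    split_levels = tuple(k for k in FACTOR_LEVELS["treatment"][1:])
    split_p = _probs(config.treated_split or _default_split(), split_levels)

    if config.mode == "treatment_only":
        levels = FACTOR_LEVELS["treatment"]
        sizes = config.category_freqs.get(
            "treatment", {k: float(v) for k, v in tables.TREATMENT_GROUP_SIZES.items()}
        )
        p = _probs(sizes, levels)
        frame["treatment"] = rng.choice(levels, size=n, p=p)
    else:
        from scipy.special import expit

        eta = linear_predictor(frame, config.logit_coefs)
        treated = rng.uniform(size=n) < expit(eta)
        therapy = rng.choice(split_levels, size=n, p=split_p)
        frame["treatment"] = np.where(treated, therapy, "palliative")
    frame["treated"] = (frame["treatment"] != "palliative").astype(int)

    try:
        lam = np.exp(linear_predictor(frame, config.scale_coefs))
        gamma = np.exp(linear_predictor(frame, config.shape_coefs))
    except DesignError as err:
        raise ConfigError(str(err)) from err
    t_true = sample_weibull(rng, lam, gamma)

    entry = rng.uniform(0.0, config.accrual_months, size=n)
    censor = config.max_followup_months - entry
    frame["time"] = np.minimum(t_true, censor)
    frame["event"] = (t_true <= censor).astype(int)
    return frame[list(COHORT_COLUMNS)]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV against the fixed schema."""
    frame = pd.read_csv(path, dtype={f: str for f in COHORT_COLUMNS[3:]})
    frame["treated"] = frame["treated"].astype(int)
    validate_cohort(frame)
    return frame[list(COHORT_COLUMNS)]


def validate_cohort(frame: pd.DataFrame) -> None:
    """Schema check: columns, positive times, binary events, level vocabulary."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"cohort is missing column(s) {missing}")
    if len(frame) == 0:
        raise ConfigError("cohort is empty")
    if (frame["time"] <= 0).any():
        bad = frame.index[frame["time"] <= 0].tolist()[:5]
        raise ConfigError(f"nonpositive survival time at row(s) {bad}")
    if not frame["event"].isin([0, 1]).all():
        raise ConfigError("event must be 0/1")
    for factor in COHORT_COLUMNS[3:4] + COHORT_COLUMNS[5:]:
        bad = set(frame[factor].unique()) - set(FACTOR_LEVELS[factor])
        if bad:
            raise ConfigError(f"unknown level(s) {sorted(bad)} in column {factor!r}")
    expected = (frame["treatment"] != "palliative").astype(int)
    if not (frame["treated"] == expected).all():
        raise ConfigError("treated flag inconsistent with treatment category")


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """A copy of ``config`` with a different seed (for replicate experiments)."""
    return replace(config, seed=seed)
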