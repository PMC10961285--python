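"""Reference constants of the 855-subject population lung-cancer cohort.

These are the published summary quantities that parameterise the default
synthetic cohorts: treatment-group sizes, covariate marginal counts, the
fitted Weibull multi-parameter regression (MPR) coefficient sets, and the
logistic treatment-allocation coefficients.  Coefficient maps are keyed by
dummy-column name (``"factor:level"``) with ``"intercept"`` for the constant;
reference levels (the first level of each factor in
:data:`mprsurv.design.FACTOR_LEVELS`) carry an implicit zero.

Time is measured in months from diagnosis throughout.
"""

from __future__ import annotations

COHORT_N = 855

#: Subjects per treatment category (palliative = no curative-intent therapy).
TREATMENT_GROUP_SIZES: dict[str, int] = {
    "palliative": 441,
    "surgery": 79,
    "chemotherapy": 45,
    "radiotherapy": 256,
    "combined": 34,
}

#: Of the 256 radiotherapy subjects, only this many were treated with curative
#: intent; the remainder received radiotherapy for symptom relief.
CURATIVE_RADIOTHERAPY = 21

#: Deaths observed by the administrative censoring date.
DEATHS_OBSERVED = 673

#: Entry window (months) and maximum span from first entry to study end.
ACCRUAL_MONTHS = 12.0
MAX_FOLLOWUP_MONTHS = 20.0

# --- Weibull MPR, treatment as the only covariate -------------------------
# hazard λγt^{γ-1}, λ = exp(x'β) (scale), γ = exp(z'α) (shape)

TREATMENT_ONLY_SCALE: dict[str, float] = {
    "intercept": -1.280,
    "treatment:surgery": -3.909,
    "treatment:chemotherapy": -0.499,
    "treatment:radiotherapy": -1.261,
    "treatment:combined": -4.058,
}

TREATMENT_ONLY_SHAPE: dict[str, float] = {
    "intercept": -0.194,
    "treatment:surgery": 0.593,
    "treatment:chemotherapy": 0.072,
    "treatment:radiotherapy": 0.337,
    "treatment:combined": 0.968,
}

# --- Weibull MPR, stepwise multi-factor solution --------------------------
# Six factors in the scale, four in the shape.  The cohort's performance
# status was graded on five levels when this model was fitted; the two most
# severe grades collapse into the four-level `wbc` category used here and the
# bed/chair-bound coefficient is retained for it (see docs/methods.md).

FULL_SCALE: dict[str, float] = {
    "intercept": -4.029,
    "treatment:surgery": -1.829,
    "treatment:chemotherapy": -0.341,
    "treatment:radiotherapy": -0.894,
    "treatment:combined": -4.088,
    "metastases:present": 1.465,
    "metastases:unknown": 0.936,
    "albumen:<3.5": 0.707,
    "albumen:unknown": 0.327,
    "who:light_work": 0.130,
    "who:no_work": 0.614,
    "who:wbc": 1.624,
    "cell:small": 0.707,
    "cell:adeno": 0.334,
    "cell:other": 0.235,
    "sodium:<136": 0.324,
    "sodium:unknown": -0.051,
}

FULL_SHAPE: dict[str, float] = {
    "intercept": 0.094,
    "treatment:surgery": 0.191,
    "treatment:chemotherapy": -0.036,
    "treatment:radiotherapy": 0.254,
    "treatment:combined": 0.837,
    "metastases:present": -0.234,
    "metastases:unknown": -0.182,
    "albumen:<3.5": -0.116,
    "albumen:unknown": 0.054,
    "smoking:current": 0.171,
    "smoking:ex": 0.151,
    "smoking:unknown": 0.089,
}

# --- Logistic treatment-allocation model ----------------------------------
# Pr(treated) = expit(x'β).  The covariate coefficients are negative: the
# probability of curative-intent therapy falls with worsening performance
# status, age, non-squamous/non-small cell type, metastatic disease and low
# albumen.  The intercept is positive: it anchors the best-prognosis
# reference subject (normal status, <40, squamous, no metastases, albumen
# ≥3.5) near-certain to be treated, which is what the treated margin 414/855
# and a 0.5 cut-off producing a balanced screening table require.  (With a
# negative intercept of the same magnitude every allocation probability would
# fall below 0.07 and the model could not reproduce those margins.)

ALLOCATION_COEFS: dict[str, float] = {
    "intercept": 3.0315,
    "who:light_work": -0.3051,
    "who:no_work": -0.9918,
    "who:wbc": -2.2077,
    "age_group:40-": 0.0888,
    "age_group:50-": -0.7097,
    "age_group:60-": -1.2798,
    "age_group:70-": -1.5085,
    "cell:small": 0.2771,
    "cell:adeno": -0.7248,
    "cell:other": -0.9961,
    "metastases:present": -0.3840,
    "metastases:unknown": -1.1209,
    "albumen:<3.5": -0.4989,
    "albumen:unknown": -0.9589,
}

#: Factors offered to the allocation model's forward selection.
ALLOCATION_FACTORS = ("who", "age_group", "cell", "metastases", "albumen")

#: The nine candidate factors of the survival analysis.
SURVIVAL_CANDIDATE_FACTORS = (
    "treatment",
    "age_group",
    "sex",
    "who",
    "cell",
    "sodium",
    "albumen",
    "metastases",
    "smoking",
)

# --- Covariate marginal distributions -------------------------------------
# Counts where published (each sums to 855); sex, sodium and smoking margins
# were not published and use plausible early-1990s lung-cancer proportions.

CATEGORY_FREQS: dict[str, dict[str, float]] = {
    "who": {"normal": 78, "light_work": 278, "no_work": 286, "wbc": 213},
    "age_group": {"<40": 32, "40-": 89, "50-": 311, "60-": 299, "70-": 124},
    "cell": {"squamous": 247, "small": 121, "adeno": 108, "other": 379},
    "metastases": {"absent": 188, "present": 428, "unknown": 239},
    "albumen": {">=3.5": 458, "<3.5": 315, "unknown": 82},
    "sex": {"male": 0.67, "female": 0.33},
    "sodium": {">=136": 0.68, "<136": 0.22, "unknown": 0.10},
    "smoking": {"never": 0.07, "current": 0.45, "ex": 0.40, "unknown": 0.08},
}


def palliative_care_breakdown(
    group_sizes: dict[str, int] | None = None,
    curative_radiotherapy: int | None = None,
) -> dict[str, float]:
    """Account for palliative-intent care across treatment categories.

    The palliative category excludes radiotherapy given purely for symptom
    relief; adding those subjects gives the total managed with palliative
    intent and its share of the cohort.
    """
    sizes = dict(TREATMENT_GROUP_SIZES if group_sizes is None else group_sizes)
    curative = CURATIVE_RADIOTHERAPY if curative_radiotherapy is None else curative_radiotherapy
    if not 0 <= curative <= sizes["radiotherapy"]:
        raise ValueError("curative radiotherapy count exceeds the radiotherapy group")
    n = sum(sizes.values())
    palliative_radio = sizes["radiotherapy"] - curative
    total = sizes["palliative"] + palliative_radio
    return {
        "palliative_category": sizes["palliative"],
        "palliative_intent_radiotherapy": palliative_radio,
        "palliative_intent_total": total,
        "cohort_n": n,
        "palliative_intent_pct": 100.0 * total / n,
    }
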