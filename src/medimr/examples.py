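"""Worked example: published summary estimates for the education -> kidney-disease study.

A large two-sample MR study of European-ancestry GWAS consortia reported the
effect of genetically predicted education (per SD of 4.2 schooling years) on
diabetic kidney disease (DKD) and chronic kidney disease (CKD), together with
education's effects on cardiometabolic mediators and each mediator's
univariable effect on the outcomes.  Those printed coefficients are enough to
rebuild the whole mediation decomposition by the product-of-coefficients
method, which makes them a compact end-to-end fixture for this package.

Effects of education on quantitative mediators are betas in SD units;
binary-trait effects (T2D, the outcomes) are odds ratios with 95% CIs and are
converted to log-odds internally.
"""

from __future__ import annotations

import numpy as np

from .mediation import MediationResult, from_coefficients

# education -> outcome total effects, OR (95% CI)
TOTAL_EFFECTS = {
    "DKD": (0.5136, (0.4212, 0.6264)),
    "CKD": (0.7092, (0.6188, 0.8129)),
}

# education -> mediator: beta (95% CI) in SD units, except T2D which is an OR
EDUCATION_ON_MEDIATOR = {
    "BMI": (-0.2942, (-0.3187, -0.2698)),
    "WHR": (-0.2157, (-0.2670, -0.1643)),
    "SBP": (-2.8239, (-3.1674, -2.4803)),
    "DBP": (-1.1212, (-1.3088, -0.9336)),
    "fasting glucose": (-0.0917, (-0.1457, -0.0378)),
    "fasting insulin": (-0.0717, (-0.1227, -0.0206)),
    "cigarettes per day": (-0.2799, (-0.3314, -0.2285)),
}
EDUCATION_ON_T2D_OR = (0.6982, (0.6414, 0.7600))

# mediator -> outcome, univariable (education-unadjusted) OR (95% CI)
MEDIATOR_ON_OUTCOME = {
    "DKD": {
        "BMI": (2.4821, (2.1981, 2.8027)),
        "WHR": (3.3604, (2.4326, 4.6419)),
        "T2D": (1.7828, (1.6565, 1.9187)),
        "fasting insulin": (6.7742, (2.5748, 17.8222)),
        "SBP": (1.0221, (1.0146, 1.0297)),
        "fasting glucose": (1.7873, (1.2249, 2.6079)),
        "DBP": (1.0164, (1.0036, 1.0294)),
    },
    "CKD": {
        "BMI": (1.4623, (1.3460, 1.5887)),
        "cigarettes per day": (1.3273, (1.1767, 1.4970)),
        "WHR": (1.3368, (1.1003, 1.6241)),
        "SBP": (1.0198, (1.0147, 1.0249)),
        "T2D": (1.1267, (1.0752, 1.1805)),
        "DBP": (1.0172, (1.0082, 1.0263)),
    },
}


def _se_from_beta_ci(low: float, high: float) -> float:
    return (high - low) / (2 * 1.96)


def worked_example(outcome: str) -> list:
    """Mediation decompositions for every screened mediator of one outcome.

    Returns MediationResults sorted descending by proportion mediated, the
    presentation order of ranked-mediator tables.
    """
    if outcome not in TOTAL_EFFECTS:
        raise KeyError(f"outcome must be one of {sorted(TOTAL_EFFECTS)}")
    or_total, ci_total = TOTAL_EFFECTS[outcome]
    results = []
    for mediator, (or_2, ci_2) in MEDIATOR_ON_OUTCOME[outcome].items():
        if mediator == "T2D":
            or_1, ci_1 = EDUCATION_ON_T2D_OR
            theta_1 = float(np.log(or_1))
            se_1 = (np.log(ci_1[1]) - np.log(ci_1[0])) / (2 * 1.96)
            binary = True
        else:
            theta_1, ci_1 = EDUCATION_ON_MEDIATOR[mediator]
            se_1 = _se_from_beta_ci(*ci_1)
            binary = False
        res = from_coefficients(
            theta_1, se_1, or_2, ci_2, or_total, ci_total,
            exposure="education", mediator=mediator, outcome=outcome,
            theta_1_is_log_or=binary,
        )
        results.append(res)
    return sorted(results, key=lambda r: r.proportion, reverse=True)


def worked_example_table() -> dict:
    """Proportion mediated (%) per mediator and outcome, plus the total-effect
    risk reductions (%), all recomputed from the published coefficients."""
    from .mediation import percent_risk_change

    out = {"proportions": {}, "risk_reduction": {}}
    for outcome in TOTAL_EFFECTS:
        out["proportions"][outcome] = {
            r.mediator: r.proportion * 100.0 for r in worked_example(outcome)
        }
        or_total, _ = TOTAL_EFFECTS[outcome]
        out["risk_reduction"][outcome] = percent_risk_change(float(np.log(or_total)))
    return out
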