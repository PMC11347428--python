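"""Two-step MR mediation: product of coefficients, delta-method SEs, proportion mediated.

Decomposes the total effect of an exposure (education, in SD units of
schooling) on a disease outcome into a direct path and an indirect path
through a mediator:

    indirect   = theta_1 * theta_2        (exposure->mediator times mediator->outcome)
    proportion = indirect / theta_total

with first-order delta-method standard errors throughout.  Binary traits are
carried on the natural-log odds scale; percent risk change is formatted as
``(1 - exp(theta)) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mvmr as mvmr_mod
from . import sumstats, uvmr


class UndefinedProportionError(ZeroDivisionError):
    """The total effect is zero, so the proportion mediated is undefined."""


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    theta_total: float
    se_total: float
    theta_1: float  # exposure -> mediator
    se_1: float
    theta_2: float  # mediator -> outcome
    se_2: float
    step2_variant: str  # "uvmr" or "mvmr_adjusted"
    indirect: float = field(init=False)
    se_indirect: float = field(init=False)
    proportion: float = field(init=False)
    se_proportion: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indirect, self.se_indirect = product_of_coefficients(
            self.theta_1, self.se_1, self.theta_2, self.se_2)
        (self.proportion, self.se_proportion,
         (self.ci_low, self.ci_high)) = proportion_mediated(
            self.indirect, self.se_indirect, self.theta_total, self.se_total)

    @property
    def direct(self) -> float:
        return self.theta_total - self.indirect


def product_of_coefficients(theta_1: float, se_1: float, theta_2: float,
                            se_2: float, exact: bool = False):
    """Indirect effect theta_1*theta_2 with delta-method SE.

    The default SE assumes the two estimates are independent (two-sample
    design): ``sqrt(theta_2^2 se_1^2 + theta_1^2 se_2^2)``.  ``exact=True``
    adds the second-order ``se_1^2 se_2^2`` term of the exact product
    variance.
    """
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive")
    indirect = theta_1 * theta_2
    var = theta_2 ** 2 * se_1 ** 2 + theta_1 ** 2 * se_2 ** 2
    if exact:
        var += se_1 ** 2 * se_2 ** 2
    return indirect, float(np.sqrt(var))


def proportion_mediated(indirect: float, se_indirect: float,
                        theta_total: float, se_total: float):
    """Proportion mediated = indirect / total, with delta-method SE and 95% CI.

    The SE treats the indirect and total estimates as independent:
    ``sqrt(se_ind^2/total^2 + ind^2 se_total^2/total^4)``.
    """
    if theta_total == 0:
        raise UndefinedProportionError("total effect is zero")
    prop = indirect / theta_total
    var = (se_indirect ** 2 / theta_total ** 2
           + indirect ** 2 * se_total ** 2 / theta_total ** 4)
    se = float(np.sqrt(var))
    return float(prop), se, (float(prop - 1.96 * se), float(prop + 1.96 * se))


def percent_risk_change(theta: float, decimals: int = 2) -> float:
    """Percent change in risk implied by a log-OR: (1 - exp(theta)) * 100.

    Positive values are risk reductions (protective effects).
    """
    return round((1.0 - float(np.exp(theta))) * 100.0, decimals)


def _se_from_or_ci(or_low: float, or_high: float) -> float:
    """Back out the log-scale SE from a 95% CI printed on the OR scale."""
    return (np.log(or_high) - np.log(or_low)) / (2 * 1.96)


def from_coefficients(theta_1: float, se_1: float,
                      or_2: float, or_2_ci: tuple,
                      or_total: float, or_total_ci: tuple,
                      exposure: str = "exposure", mediator: str = "mediator",
                      outcome: str = "outcome",
                      theta_1_is_log_or: bool = False) -> MediationResult:
    """Worked-example mode: assemble a MediationResult from published estimates.

    ``theta_1`` is the exposure->mediator effect (SD scale, or log-OR when the
    mediator is binary — pass the OR's natural log and set
    ``theta_1_is_log_or``); mediator->outcome and total effects are given as
    odds ratios with 95% CIs, as disease studies print them.
    """
    res = MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        theta_total=float(np.log(or_total)), se_total=_se_from_or_ci(*or_total_ci),
        theta_1=theta_1, se_1=se_1,
        theta_2=float(np.log(or_2)), se_2=_se_from_or_ci(*or_2_ci),
        step2_variant="uvmr",
    )
    if theta_1_is_log_or:
        res.flags.append("binary-mediator scale caveat")
    return res


def two_step_mediation(exposure: sumstats.SummaryStats,
                       mediator: sumstats.SummaryStats,
                       outcome: sumstats.SummaryStats,
                       step2_variant: str = "uvmr",
                       p_threshold: float = sumstats.DEFAULT_P_THRESHOLD,
                       seed: int = 0) -> MediationResult:
    """Full two-step MR mediation from summary statistics.

    Step 1 uses the exposure's instruments for exposure->mediator and
    exposure->outcome (total effect); step 2 uses the mediator's instruments
    for mediator->outcome, either univariable IVW (``step2_variant='uvmr'``)
    or the mediator's MV-IVW coefficient adjusted for the exposure
    (``'mvmr_adjusted'``).
    """
    if step2_variant not in ("uvmr", "mvmr_adjusted"):
        raise ValueError("step2_variant must be 'uvmr' or 'mvmr_adjusted'")

    exp_iv = sumstats.select_instruments(exposure, p_threshold=p_threshold)
    med_iv = sumstats.select_instruments(mediator, p_threshold=p_threshold)

    h_total = sumstats.harmonize([_restrict(exposure, exp_iv)], outcome)
    total = uvmr.ivw(h_total)

    h_step1 = sumstats.harmonize([_restrict(exposure, exp_iv)], mediator)
    step1 = uvmr.ivw(h_step1)

    if step2_variant == "uvmr":
        h_step2 = sumstats.harmonize([_restrict(mediator, med_iv)], outcome)
        step2 = uvmr.ivw(h_step2)
    else:
        union = pd.unique(np.concatenate([exp_iv.table["SNP"].to_numpy(),
                                          med_iv.table["SNP"].to_numpy()]))
        h_mv = sumstats.harmonize(
            [_restrict_ids(mediator, union), _restrict_ids(exposure, union)],
            outcome)
        step2 = mvmr_mod.mvmr_ivw(h_mv)[0]  # mediator listed first

    res = MediationResult(
        exposure=exposure.trait_name, mediator=mediator.trait_name,
        outcome=outcome.trait_name,
        theta_total=total.beta, se_total=total.se,
        theta_1=step1.beta, se_1=step1.se,
        theta_2=step2.beta, se_2=step2.se,
        step2_variant=step2_variant,
    )
    if mediator.trait_type == "binary":
        res.flags.append("binary-mediator scale caveat")
    return res


def _restrict(stats: sumstats.SummaryStats, iv: sumstats.SummaryStats):
    return _restrict_ids(stats, iv.table["SNP"])


def _restrict_ids(stats: sumstats.SummaryStats, ids):
    tab = stats.table[stats.table["SNP"].isin(set(ids))].reset_index(drop=True)
    return sumstats.SummaryStats(trait_name=stats.trait_name, table=tab,
                                 trait_type=stats.trait_type,
                                 unit_note=stats.unit_note)
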