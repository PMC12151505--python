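"""Two-step MR mediation: product-of-coefficients decomposition.

The structural model is X -> M -> Y with a direct path X -> Y:

    M = a*X + e1          (exposure -> mediator)
    Y = c'*X + b*M + e3   (direct + mediator -> outcome)

Three MR legs estimate ``a`` (X->M), ``b`` (M->Y) and the *total* effect
(X->Y).  The indirect effect is the product ``a*b``; the direct effect
``c'`` is recovered by subtraction on the log-odds scale (difference
method), so the decomposition ``total = c' + a*b`` holds exactly by
construction.  The proportion mediated is ``indirect/total``, a signed
fraction that can leave [0, 1] under inconsistent mediation (opposing
signs), which is flagged rather than truncated.

The SE of the product uses the first-order delta method,
``sqrt(a^2 se_b^2 + b^2 se_a^2)``; legs are treated as independent
(non-overlapping GWAS samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .estimators import MREstimate

__all__ = [
    "MediationModel",
    "UndefinedProportionError",
    "MediationRoleError",
    "indirect_effect",
    "total_effect",
    "proportion_mediated",
    "delta_se_indirect",
    "run_two_step",
    "mediation_frame",
]


class UndefinedProportionError(ValueError):
    """Proportion mediated requested with a zero total effect."""


class MediationRoleError(ValueError):
    """The three MR legs do not share consistent exposure/mediator/outcome roles."""


@dataclass
class MediationModel:
    """Structural coefficients and the mediated-effect decomposition.

    All effects are on the log-odds / beta scale; odds ratios are a
    reporting transform only.  ``sign_inconsistent`` marks opposing signs
    of indirect and total effect (proportion outside [0, 1]).
    """

    exposure_name: str
    mediator_name: str
    outcome_name: str
    a: float
    se_a: float
    b: float
    se_b: float
    c_prime: float
    se_c: float
    indirect: float
    se_indirect: float
    total: float
    se_total: float
    proportion: float
    sign_inconsistent: bool

    @property
    def proportion_percent(self) -> float:
        """Proportion mediated as a percentage, rounded to 2 decimals."""
        return round(self.proportion * 100.0, 2)


def indirect_effect(a: float, b: float) -> float:
    """Mediated (indirect) effect: the product of coefficients ``a*b``."""
    return a * b


def total_effect(c_prime: float, indirect: float) -> float:
    """Overall effect: sum of the direct and indirect effects."""
    return c_prime + indirect


def proportion_mediated(indirect: float, total: float) -> float:
    """Signed fraction ``indirect/total`` of the total effect mediated.

    May lie outside [0, 1] when indirect and total effects oppose in sign
    (inconsistent mediation); callers flag that case rather than clamp it.
    """
    if total == 0:
        raise UndefinedProportionError("total effect is 0: proportion undefined")
    return indirect / total


def delta_se_indirect(a: float, se_a: float, b: float, se_b: float) -> float:
    """First-order delta-method SE of the product ``a*b``."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    return math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)


def _check_roles(est: MREstimate, exposure: str, outcome: str, leg: str) -> None:
    got_exp = est.extra.get("exposure")
    got_out = est.extra.get("outcome")
    if got_exp is not None and got_exp != exposure:
        raise MediationRoleError(
            f"{leg} leg: expected exposure {exposure!r}, estimate carries {got_exp!r}"
        )
    if got_out is not None and got_out != outcome:
        raise MediationRoleError(
            f"{leg} leg: expected outcome {outcome!r}, estimate carries {got_out!r}"
        )


def run_two_step(
    est_xm: MREstimate,
    est_my: MREstimate,
    est_xy: MREstimate,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MediationModel:
    """Compose three primary (IVW) MR estimates into a mediation model.

    ``est_xm`` estimates a (X->M), ``est_my`` estimates b (M->Y), and
    ``est_xy`` the total effect (X->Y).  The direct effect is
    ``total - a*b`` (difference method).  When the estimates carry trait
    names in ``extra`` their roles are checked for consistency.
    """
    _check_roles(est_xm, exposure_name, mediator_name, "X->M")
    _check_roles(est_my, mediator_name, outcome_name, "M->Y")
    _check_roles(est_xy, exposure_name, outcome_name, "X->Y")

    a, se_a = est_xm.beta, est_xm.se
    b, se_b = est_my.beta, est_my.se
    total, se_total = est_xy.beta, est_xy.se
    indirect = indirect_effect(a, b)
    se_ind = delta_se_indirect(a, se_a, b, se_b)
    c_prime = total - indirect
    se_c = math.sqrt(se_total**2 + se_ind**2)  # independent two-sample legs
    proportion = proportion_mediated(indirect, total)
    return MediationModel(
        exposure_name=exposure_name,
        mediator_name=mediator_name,
        outcome_name=outcome_name,
        a=a,
        se_a=se_a,
        b=b,
        se_b=se_b,
        c_prime=c_prime,
        se_c=se_c,
        indirect=indirect,
        se_indirect=se_ind,
        total=total,
        se_total=se_total,
        proportion=proportion,
        sign_inconsistent=(indirect != 0 and (indirect > 0) != (total > 0)),
    )


def mediation_frame(model: MediationModel) -> pd.DataFrame:
    """One-row report table for the mediation decomposition."""
    return pd.DataFrame(
        [
            {
                "exposure": model.exposure_name,
                "mediator": model.mediator_name,
                "outcome": model.outcome_name,
                "a": model.a,
                "se_a": model.se_a,
                "b": model.b,
                "se_b": model.se_b,
                "c_prime": model.c_prime,
                "se_c": model.se_c,
                "indirect": model.indirect,
                "se_indirect": model.se_indirect,
                "total": model.total,
                "se_total": model.se_total,
                "proportion": model.proportion,
                "proportion_percent": model.proportion_percent,
                "sign_inconsistent": model.sign_inconsistent,
            }
        ]
    )
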