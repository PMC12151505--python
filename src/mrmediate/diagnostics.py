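"""Heterogeneity, pleiotropy and per-SNP sensitivity diagnostics.

Cochran's Q is computed around the fitted IVW (origin) or MR-Egger
(intercept) line with inverse outcome-variance weights; I-squared is the
usual ``max(0, (Q - df)/Q)``.  The Egger intercept test reuses the
MR-Egger fit, so the two are consistent by construction.  The single-SNP
and leave-one-out tables are the plotting-ready data behind per-SNP
forest plots: one Wald ratio per instrument, and one IVW re-estimate per
omitted instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    Z95,
    InsufficientInstrumentsError,
    _egger_fit,
    _ivw_fit,
    ivw,
    mr_egger,
    wald_ratio,
)
from .instruments import HarmonizedDataset

__all__ = [
    "HeterogeneityResult",
    "PleiotropyResult",
    "SingleSnpRow",
    "LeaveOneOutRow",
    "cochran_q",
    "egger_intercept_test",
    "single_snp_table",
    "leave_one_out",
    "heterogeneity_frame",
    "single_snp_frame",
    "leave_one_out_frame",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q around one fitted line, with df, p and I-squared."""

    method: str
    Q: float
    df: int
    pvalue: float
    i2: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept, SE and p: directional-pleiotropy evidence."""

    intercept: float
    intercept_se: float
    pvalue: float


@dataclass(frozen=True)
class SingleSnpRow:
    """One instrument's Wald ratio with a 95% CI on the effect scale."""

    snp_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    """IVW estimate with one instrument omitted."""

    omitted_snp_id: str
    beta: float
    se: float
    pvalue: float


def cochran_q(data: HarmonizedDataset, method: str = "ivw") -> HeterogeneityResult:
    """Heterogeneity of per-SNP effects around the ``method`` fit.

    ``Q = sum_j w_j (beta_Yj - yhat_j)^2`` with ``w_j = 1/se_Yj^2`` and
    yhat from the origin-constrained (ivw, df = J-1) or intercept
    (mr_egger, df = J-2) weighted fit; p from the chi-square reference.
    """
    j = data.n_snp
    bx, _, by, sy = data.arrays()
    if method == "ivw":
        if j < 2:
            raise InsufficientInstrumentsError("cochran_q(ivw) requires >= 2 instruments")
        _, _, q = _ivw_fit(bx, by, sy)
        df = j - 1
    elif method == "mr_egger":
        if j < 3:
            raise InsufficientInstrumentsError(
                "cochran_q(mr_egger) requires >= 3 instruments"
            )
        *_, q = _egger_fit(bx, by, sy)
        df = j - 2
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    pvalue = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(method=method, Q=q, df=df, pvalue=pvalue, i2=i2)


def egger_intercept_test(data: HarmonizedDataset) -> PleiotropyResult:
    """Directional horizontal pleiotropy test via the MR-Egger intercept."""
    est = mr_egger(data)
    return PleiotropyResult(
        intercept=est.extra["egger_intercept"],
        intercept_se=est.extra["egger_intercept_se"],
        pvalue=est.extra["egger_intercept_p"],
    )


def single_snp_table(data: HarmonizedDataset) -> list[SingleSnpRow]:
    """Per-SNP Wald ratios with 95% CIs, in input order (forest-plot data)."""
    if data.n_snp < 1:
        raise InsufficientInstrumentsError("single_snp_table requires >= 1 instrument")
    rows = []
    for pair in data.pairs:
        r = wald_ratio(pair)
        rows.append(
            SingleSnpRow(
                snp_id=r.snp_id,
                beta=r.ratio,
                se=r.se_ratio,
                ci_low=r.ratio - Z95 * r.se_ratio,
                ci_high=r.ratio + Z95 * r.se_ratio,
            )
        )
    return rows


def leave_one_out(
    data: HarmonizedDataset, model: str = "multiplicative_random"
) -> list[LeaveOneOutRow]:
    """IVW re-estimated J times, each time omitting one instrument."""
    if data.n_snp < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 instruments")
    rows = []
    ids = data.snp_ids
    for omit in ids:
        est = ivw(data.subset([s for s in ids if s != omit]), model=model)
        rows.append(
            LeaveOneOutRow(
                omitted_snp_id=omit, beta=est.beta, se=est.se, pvalue=est.pvalue
            )
        )
    return rows


def heterogeneity_frame(results: list[HeterogeneityResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def single_snp_frame(rows: list[SingleSnpRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def leave_one_out_frame(rows: list[LeaveOneOutRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
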