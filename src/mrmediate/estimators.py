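"""Causal-effect estimators for two-sample Mendelian randomization.

Implements the per-SNP Wald ratio and the five-estimator battery reported
in standard MR forest plots:

* **IVW** (inverse-variance weighted) — weighted least squares of the
  outcome effects on the exposure effects through the origin, weights
  1/se_outcome^2; the primary method.  The multiplicative random-effects
  variant inflates the SE by ``max(1, sqrt(Q/(J-1)))``.
* **MR-Egger** — the same regression with a free intercept; a nonzero
  intercept is evidence of directional horizontal pleiotropy, the slope
  is the pleiotropy-adjusted causal effect.  Instruments are re-signed so
  every exposure effect is non-negative before fitting (the orientation
  convention the intercept is defined under).
* **Weighted median** — the weight-0.5 quantile of the per-SNP Wald
  ratios with inverse-variance weights; consistent when valid instruments
  carry at least half the weight.
* **Simple / weighted mode** — the argmax of a (precision-weighted)
  Gaussian kernel density over the Wald ratios; consistent when the
  largest homogeneous cluster of instruments is valid.

Median and mode standard errors come from a parametric bootstrap that
perturbs both exposure and outcome effects by their reported SEs.
All estimates are returned as :class:`MREstimate` with odds-ratio and
95% CI reporting transforms attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .instruments import HarmonizedDataset, HarmonizedPair

__all__ = [
    "MREstimate",
    "RatioEstimate",
    "MethodFailure",
    "MRSettings",
    "InsufficientInstrumentsError",
    "DegenerateInstrumentError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
    "run_all_methods",
    "METHOD_ORDER",
]

logger = logging.getLogger(__name__)

Z95 = 1.959964  # normal 97.5% quantile at working precision

METHOD_ORDER = ("mr_egger", "weighted_median", "ivw", "simple_mode", "weighted_mode")


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the method's minimum."""


class DegenerateInstrumentError(ValueError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio estimate with first-order standard error."""

    snp_id: str
    ratio: float
    se_ratio: float


@dataclass
class MREstimate:
    """One method's causal estimate in forest-plot layout.

    ``beta`` is on the log-odds scale for binary outcomes (outcome units
    otherwise); ``or_``/``ci_low``/``ci_high`` are the exponential
    reporting transform ``exp(beta -/+ z*se)`` at ``ci_level``.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    ci_level: float = 0.95
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - z * self.se))
        self.ci_high = float(np.exp(self.beta + z * self.se))


@dataclass(frozen=True)
class MethodFailure:
    """Placeholder for a method that could not run on this dataset."""

    method: str
    error: str


@dataclass
class MRSettings:
    """Settings shared by the five-method battery."""

    ivw_model: str = "multiplicative_random"
    phi: float = 1.0
    n_boot: int = 1000
    seed: int = 0
    ci_level: float = 0.95


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else np.finfo(float).tiny
    return float(max(2.0 * stats.norm.sf(abs(beta / se)), np.finfo(float).tiny))


def wald_ratio(pair: HarmonizedPair) -> RatioEstimate:
    """Per-SNP causal estimate ``beta_outcome / beta_exposure``.

    The SE is the first-order approximation ``se_outcome / |beta_exposure|``
    (exposure uncertainty ignored, the standard two-sample simplification).
    """
    if pair.beta_exposure == 0:
        raise DegenerateInstrumentError(
            f"{pair.snp_id}: beta_exposure is 0, Wald ratio undefined"
        )
    return RatioEstimate(
        snp_id=pair.snp_id,
        ratio=pair.beta_outcome / pair.beta_exposure,
        se_ratio=pair.se_outcome / abs(pair.beta_exposure),
    )


def _ratio_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    if np.any(bx == 0):
        raise DegenerateInstrumentError("beta_exposure contains zeros")
    return by / bx, sy / np.abs(bx)


def _ivw_fit(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Origin-constrained WLS: slope, fixed-effect SE and Cochran Q."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(data: HarmonizedDataset, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate (regression through the origin).

    ``model='fixed'`` uses the weighted-LS standard error with residual
    scale fixed at 1; ``'multiplicative_random'`` (default) inflates it by
    ``max(1, sqrt(Q/(J-1)))``.  The point estimate is identical under both.
    With a single instrument the estimate degrades to the Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown ivw model {model!r}")
    j = data.n_snp
    if j == 0:
        raise InsufficientInstrumentsError("ivw requires at least 1 instrument")
    if j == 1:
        logger.info(
            "ivw on a single instrument (%s): degrading to the Wald ratio",
            data.pairs[0].snp_id,
        )
        r = wald_ratio(data.pairs[0])
        return MREstimate(
            method="ivw",
            beta=r.ratio,
            se=r.se_ratio,
            pvalue=_normal_p(r.ratio, r.se_ratio),
            n_snp=1,
            extra={"model": model, "note": "single instrument: Wald ratio"},
        )
    bx, _, by, sy = data.arrays()
    beta, se_fixed, q = _ivw_fit(bx, by, sy)
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * max(1.0, float(np.sqrt(q / (j - 1))))
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        pvalue=_normal_p(beta, se),
        n_snp=j,
        extra={"model": model, "Q": q, "se_fixed": se_fixed},
    )


def _egger_fit(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Weighted LS of by on bx with intercept after orienting bx >= 0.

    Returns (slope, se_slope, intercept, se_intercept, Q_egger).  SEs use
    multiplicative residual scaling ``max(1, Q/(J-2))`` on the variance.
    """
    j = len(bx)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    xtwx_inv = np.linalg.inv(design.T @ design)
    scale = max(1.0, q / (j - 2))
    se_intercept = float(np.sqrt(scale * xtwx_inv[0, 0]))
    se_slope = float(np.sqrt(scale * xtwx_inv[1, 1]))
    return slope, se_slope, intercept, se_intercept, q


def mr_egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression: pleiotropy-adjusted slope plus intercept test.

    p-values use the t reference with J-2 degrees of freedom; the
    intercept, its SE and p are carried in ``extra``.
    """
    j = data.n_snp
    if j < 3:
        raise InsufficientInstrumentsError(
            f"mr_egger requires at least 3 instruments, got {j}"
        )
    bx, _, by, sy = data.arrays()
    slope, se_slope, intercept, se_intercept, q = _egger_fit(bx, by, sy)
    df = j - 2
    p_slope = float(max(2.0 * stats.t.sf(abs(slope / se_slope), df), np.finfo(float).tiny)) if se_slope > 0 else (1.0 if slope == 0 else np.finfo(float).tiny)
    if se_intercept > 0:
        p_int = float(max(2.0 * stats.t.sf(abs(intercept / se_intercept), df), np.finfo(float).tiny))
    else:
        p_int = 1.0 if intercept == 0 else float(np.finfo(float).tiny)
    return MREstimate(
        method="mr_egger",
        beta=slope,
        se=se_slope,
        pvalue=p_slope,
        n_snp=j,
        extra={
            "egger_intercept": intercept,
            "egger_intercept_se": se_intercept,
            "egger_intercept_p": p_int,
            "Q": q,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _mode_point(ratios: np.ndarray, weights: Optional[np.ndarray], phi: float) -> float:
    """Grid argmax of the Gaussian kernel density of ``ratios``.

    Bandwidth is the modified Silverman rule
    ``phi * 0.9 * min(sd, IQR/1.349) * J**(-1/5)``; the density is
    evaluated on a 512-point uniform grid spanning the ratio range padded
    by 3 bandwidths, ties broken by the smallest grid index.  When the
    ratios are all identical the common value is returned directly.
    """
    j = len(ratios)
    if np.all(ratios == ratios[0]):
        return float(ratios[0])
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349)
    if spread == 0:  # degenerate IQR with non-identical ratios
        spread = sd
    h = phi * 0.9 * spread * j ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    if weights is None:
        w = np.full(j, 1.0 / j)
    else:
        w = weights / np.sum(weights)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[int(np.argmax(dens))])


def _parametric_bootstrap(
    data: HarmonizedDataset,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """SD of ``point_fn`` over resamples perturbing both betas by their SEs.

    ``point_fn(ratios, se_ratios)`` maps one resampled instrument set to a
    scalar estimate.  Returns NaN when ``n_boot`` is 0 (point-estimate-only
    use, e.g. large simulation studies).
    """
    if n_boot == 0:
        return float("nan")
    bx = np.array([p.beta_exposure for p in data.pairs])
    sx = np.array([p.se_exposure for p in data.pairs])
    by = np.array([p.beta_outcome for p in data.pairs])
    sy = np.array([p.se_outcome for p in data.pairs])
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for i in range(n_boot):
        bx_star = bx + rng.normal(0.0, sx)
        by_star = by + rng.normal(0.0, sy)
        bx_star[bx_star == 0] = np.finfo(float).tiny  # avoid exact zeros
        ratios = by_star / bx_star
        se_ratios = sy / np.abs(bx_star)
        estimates[i] = point_fn(ratios, se_ratios)
    return float(np.std(estimates, ddof=1))


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate over the per-SNP Wald ratios.

    Weights are inverse squared ratio SEs; the estimate interpolates the
    ratio at cumulative weight 0.5.  SE by parametric bootstrap (``seed``
    mandatory for reproducibility; ``n_boot=0`` skips it, SE = NaN).
    """
    if data.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median requires at least 3 instruments, got {data.n_snp}"
        )
    bx, _, by, sy = data.arrays()
    ratios, se_ratios = _ratio_arrays(bx, by, sy)
    beta = _weighted_median_point(ratios, se_ratios**-2)
    se = _parametric_bootstrap(
        data, lambda r, s: _weighted_median_point(r, s**-2), n_boot, seed
    )
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        pvalue=_normal_p(beta, se) if np.isfinite(se) else float("nan"),
        n_snp=data.n_snp,
        extra={"n_boot": n_boot, "seed": seed},
    )


def _mode_estimate(
    data: HarmonizedDataset,
    method: str,
    weighted: bool,
    phi: float,
    n_boot: int,
    seed: int,
) -> MREstimate:
    if data.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"{method} requires at least 3 instruments, got {data.n_snp}"
        )
    if phi <= 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    bx, _, by, sy = data.arrays()
    ratios, se_ratios = _ratio_arrays(bx, by, sy)
    beta = _mode_point(ratios, se_ratios**-2 if weighted else None, phi)
    se = _parametric_bootstrap(
        data,
        lambda r, s: _mode_point(r, s**-2 if weighted else None, phi),
        n_boot,
        seed,
    )
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        pvalue=_normal_p(beta, se) if np.isfinite(se) else float("nan"),
        n_snp=data.n_snp,
        extra={"phi": phi, "n_boot": n_boot, "seed": seed},
    )


def simple_mode(
    data: HarmonizedDataset, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Mode of the unweighted kernel density of Wald ratios."""
    return _mode_estimate(data, "simple_mode", False, phi, n_boot, seed)


def weighted_mode(
    data: HarmonizedDataset, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Mode of the precision-weighted kernel density of Wald ratios."""
    return _mode_estimate(data, "weighted_mode", True, phi, n_boot, seed)


def run_all_methods(
    data: HarmonizedDataset, settings: Optional[MRSettings] = None
) -> list[Union[MREstimate, MethodFailure]]:
    """Run the five-method battery in forest-plot order.

    Order: MR-Egger, weighted median, IVW, simple mode, weighted mode
    (IVW flagged primary in ``extra``).  A method that cannot run on this
    dataset contributes a :class:`MethodFailure` entry instead of aborting
    the battery.
    """
    if settings is None:
        settings = MRSettings()
    results: list[Union[MREstimate, MethodFailure]] = []
    for method in METHOD_ORDER:
        try:
            if method == "ivw":
                est = ivw(data, model=settings.ivw_model)
                est.extra["primary"] = True
            elif method == "mr_egger":
                est = mr_egger(data)
            elif method == "weighted_median":
                est = weighted_median(data, n_boot=settings.n_boot, seed=settings.seed)
            elif method == "simple_mode":
                est = simple_mode(
                    data, phi=settings.phi, n_boot=settings.n_boot, seed=settings.seed
                )
            else:
                est = weighted_mode(
                    data, phi=settings.phi, n_boot=settings.n_boot, seed=settings.seed
                )
            est.ci_level = settings.ci_level
            est.__post_init__()  # refresh CI at the requested level
            est.extra.setdefault("settings", settings)
            results.append(est)
        except (InsufficientInstrumentsError, DegenerateInstrumentError) as exc:
            results.append(MethodFailure(method=method, error=str(exc)))
    return results
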