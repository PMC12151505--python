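"""End-to-end orchestration: forward MR, reverse MR, mediation legs.

One :class:`AnalysisConfig` drives the whole design.  Each *leg* is an
exposure->outcome MR: instruments are selected from the leg's exposure
table (p-value screen, weak-instrument screen, optional LD clumping),
harmonized against the outcome table, then run through the five-method
battery and diagnostics.  The mediation analysis composes the primary
(IVW by default) estimates of the X->Y, X->M and M->Y legs into the
product-of-coefficients decomposition, and additionally runs the reverse
(Y->X) leg as a directionality check.

For the mediator->outcome leg, SNPs associated with the exposure at the
selection threshold are excluded by default (``exclude_exposure_associated``):
an exposure instrument reaches the outcome through the direct path c' as
well, so keeping it would bias the mediator effect b toward total/a.

Every stage records per-SNP exclusions and survival counts; identical
config and seed yield byte-identical report tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    HeterogeneityResult,
    LeaveOneOutRow,
    PleiotropyResult,
    SingleSnpRow,
    cochran_q,
    egger_intercept_test,
    heterogeneity_frame,
    leave_one_out,
    leave_one_out_frame,
    single_snp_frame,
    single_snp_table,
)
from .estimators import (
    InsufficientInstrumentsError,
    MethodFailure,
    MREstimate,
    MRSettings,
    run_all_methods,
)
from .gwas_io import SummaryTable, read_summary_table
from .instruments import (
    LDMatrix,
    filter_by_pvalue,
    filter_weak,
    greedy_clump,
    harmonize,
    read_ld_matrix,
)
from .mediation import MediationModel, mediation_frame, run_two_step

__all__ = [
    "AnalysisConfig",
    "LegResult",
    "AnalysisReport",
    "PipelineError",
    "ConfigurationError",
    "analyze_leg",
    "run_forward_mr",
    "run_reverse_mr",
    "run_mediation_analysis",
    "estimates_frame",
    "write_leg",
    "write_report",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid or inconsistent analysis configuration."""


class PipelineError(RuntimeError):
    """A leg could not be completed; carries per-stage survival counts."""

    def __init__(self, message: str, survival: Optional[dict] = None):
        super().__init__(message)
        self.survival = survival or {}


@dataclass
class AnalysisConfig:
    """All knobs of the analysis, mirroring the CLI flags.

    ``seed`` feeds every bootstrap; it is mandatory whenever bootstrap
    methods run (``n_boot > 0``).
    """

    exposure_path: Optional[str] = None
    outcome_path: Optional[str] = None
    mediator_path: Optional[str] = None
    ld_path: Optional[str] = None
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    exposure_trait_type: str = "quantitative"
    mediator_trait_type: str = "quantitative"
    outcome_trait_type: str = "binary"
    p_threshold: float = 1e-5
    clump: bool = False
    r2_max: float = 0.001
    f_min: float = 10.0
    palindrome_policy: str = "infer_by_eaf"
    eaf_window: float = 0.08
    n_boot: int = 1000
    seed: Optional[int] = None
    ci_level: float = 0.95
    phi: float = 1.0
    ivw_model: str = "multiplicative_random"
    primary_method: str = "ivw"
    exclude_exposure_associated: bool = True
    out_dir: Optional[str] = None

    def settings(self) -> MRSettings:
        if self.n_boot > 0 and self.seed is None:
            raise ConfigurationError("seed is required when bootstrap methods run")
        return MRSettings(
            ivw_model=self.ivw_model,
            phi=self.phi,
            n_boot=self.n_boot,
            seed=self.seed if self.seed is not None else 0,
            ci_level=self.ci_level,
        )


@dataclass
class LegResult:
    """One exposure->outcome MR with its diagnostics and accounting."""

    name: str
    exposure_name: str
    outcome_name: str
    estimates: list = field(default_factory=list)
    heterogeneity: list[HeterogeneityResult] = field(default_factory=list)
    pleiotropy: Optional[PleiotropyResult] = None
    single_snp: list[SingleSnpRow] = field(default_factory=list)
    loo: list[LeaveOneOutRow] = field(default_factory=list)
    survival: dict = field(default_factory=dict)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)
    n_snp: int = 0
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def primary_estimate(self, method: str = "ivw") -> MREstimate:
        for est in self.estimates:
            if isinstance(est, MREstimate) and est.method == method:
                return est
        raise PipelineError(f"leg {self.name!r} has no successful {method!r} estimate")


@dataclass
class AnalysisReport:
    """All legs plus the mediation decomposition and run metadata."""

    legs: dict[str, LegResult]
    mediation: Optional[MediationModel] = None
    mediation_error: Optional[str] = None
    config: Optional[AnalysisConfig] = None
    version: str = __version__


def _select_instruments(
    exposure: SummaryTable,
    config: AnalysisConfig,
    ld: Optional[LDMatrix],
    exclude_snp_ids=(),
) -> tuple[SummaryTable, dict, list]:
    """p-value screen -> F screen -> clumping -> explicit exclusions."""
    survival = {"input": len(exposure)}
    exclusions: list[tuple[str, str, str]] = []

    def note(before: SummaryTable, after: SummaryTable, stage: str, reason: str):
        kept = set(after.snp_ids)
        for s in before.snp_ids:
            if s not in kept:
                exclusions.append((s, stage, reason))

    t = filter_by_pvalue(exposure, config.p_threshold)
    note(exposure, t, "pvalue_filter", f"p >= {config.p_threshold:g}")
    survival["pvalue_filter"] = len(t)

    t2 = filter_weak(t, config.f_min)
    note(t, t2, "weak_filter", f"F < {config.f_min:g}")
    survival["weak_filter"] = len(t2)
    t = t2

    if config.clump:
        if ld is None:
            raise ConfigurationError("clumping requested but no LD matrix provided")
        t2 = greedy_clump(t, ld, config.r2_max)
        note(t, t2, "clump", f"r2 > {config.r2_max:g} with a kept SNP")
        survival["clump"] = len(t2)
        t = t2

    if exclude_snp_ids:
        drop = set(exclude_snp_ids)
        t2 = t.subset(s for s in t.snp_ids if s not in drop)
        note(t, t2, "exposure_overlap", "associated with the upstream exposure")
        survival["exposure_overlap"] = len(t2)
        t = t2

    return t, survival, exclusions


def analyze_leg(
    exposure: SummaryTable,
    outcome: SummaryTable,
    config: AnalysisConfig,
    ld: Optional[LDMatrix] = None,
    exclude_snp_ids=(),
    name: Optional[str] = None,
) -> LegResult:
    """Run one full MR leg from in-memory tables.

    Raises :class:`PipelineError` (with survival counts) when no
    instrument survives selection or harmonization.
    """
    leg = LegResult(
        name=name or f"{exposure.trait_name}->{outcome.trait_name}",
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
    )
    selected, survival, exclusions = _select_instruments(
        exposure, config, ld, exclude_snp_ids
    )
    leg.survival = survival
    leg.exclusions = exclusions
    if len(selected) == 0:
        raise PipelineError(
            f"leg {leg.name!r}: no instruments survived selection "
            f"(survival: {survival})",
            survival,
        )

    data = harmonize(
        selected,
        outcome,
        palindrome_policy=config.palindrome_policy,
        eaf_window=config.eaf_window,
    )
    leg.exclusions.extend((s, "harmonize", reason) for s, reason in data.exclusions)
    leg.survival["harmonize"] = data.n_snp
    if data.n_snp == 0:
        raise PipelineError(
            f"leg {leg.name!r}: no instruments survived harmonization "
            f"(survival: {leg.survival})",
            leg.survival,
        )
    leg.n_snp = data.n_snp

    estimates = run_all_methods(data, config.settings())
    for est in estimates:
        if isinstance(est, MREstimate):
            est.extra["exposure"] = exposure.trait_name
            est.extra["outcome"] = outcome.trait_name
    leg.estimates = estimates

    for het_method, j_min in (("ivw", 2), ("mr_egger", 3)):
        if data.n_snp >= j_min:
            leg.heterogeneity.append(cochran_q(data, het_method))
    if data.n_snp >= 3:
        leg.pleiotropy = egger_intercept_test(data)
        leg.loo = leave_one_out(data, model=config.ivw_model)
    leg.single_snp = single_snp_table(data)
    return leg


def _load_tables(config: AnalysisConfig, need_mediator: bool):
    if config.exposure_path is None or config.outcome_path is None:
        raise ConfigurationError("exposure_path and outcome_path are required")
    exposure = read_summary_table(
        config.exposure_path, config.exposure_name, config.exposure_trait_type
    )
    outcome = read_summary_table(
        config.outcome_path, config.outcome_name, config.outcome_trait_type
    )
    mediator = None
    if need_mediator:
        if config.mediator_path is None:
            raise ConfigurationError("mediator_path is required for mediation analysis")
        mediator = read_summary_table(
            config.mediator_path, config.mediator_name, config.mediator_trait_type
        )
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    return exposure, mediator, outcome, ld


def run_forward_mr(config: AnalysisConfig) -> LegResult:
    """Exposure -> outcome MR from the configured paths, with outputs."""
    exposure, _, outcome, ld = _load_tables(config, need_mediator=False)
    leg = analyze_leg(exposure, outcome, config, ld, name="forward")
    if config.out_dir:
        write_leg(leg, Path(config.out_dir) / "forward")
    return leg


def run_reverse_mr(config: AnalysisConfig) -> LegResult:
    """Outcome -> exposure MR: identical machinery with roles swapped."""
    exposure, _, outcome, ld = _load_tables(config, need_mediator=False)
    leg = analyze_leg(outcome, exposure, config, ld, name="reverse")
    if config.out_dir:
        write_leg(leg, Path(config.out_dir) / "reverse")
    return leg


def _try_leg(report: AnalysisReport, key: str, **kwargs) -> Optional[LegResult]:
    try:
        leg = analyze_leg(**kwargs)
    except (PipelineError, ConfigurationError) as exc:
        leg = LegResult(
            name=kwargs.get("name", key),
            exposure_name=kwargs["exposure"].trait_name,
            outcome_name=kwargs["outcome"].trait_name,
            survival=getattr(exc, "survival", {}),
            error=str(exc),
        )
        logger.warning("leg %s failed: %s", key, exc)
    report.legs[key] = leg
    return leg


def run_mediation_analysis(
    config: AnalysisConfig,
    tables: Optional[tuple[SummaryTable, SummaryTable, SummaryTable]] = None,
    ld: Optional[LDMatrix] = None,
) -> AnalysisReport:
    """Full design: X->Y, reverse Y->X, X->M, M->Y and the decomposition.

    ``tables`` (exposure, mediator, outcome) may be passed in memory;
    otherwise they are read from the configured paths.  The mediation
    model is computed only when the three forward legs all succeed.
    """
    if tables is not None:
        exposure, mediator, outcome = tables
        if config.ld_path and ld is None:
            ld = read_ld_matrix(config.ld_path)
    else:
        exposure, mediator, outcome, ld = _load_tables(config, need_mediator=True)

    report = AnalysisReport(legs={}, config=config)
    leg_xy = _try_leg(
        report, "exposure_outcome",
        exposure=exposure, outcome=outcome, config=config, ld=ld,
        name=f"{exposure.trait_name}->{outcome.trait_name}",
    )
    _try_leg(
        report, "reverse",
        exposure=outcome, outcome=exposure, config=config, ld=ld,
        name=f"{outcome.trait_name}->{exposure.trait_name}",
    )
    leg_xm = _try_leg(
        report, "exposure_mediator",
        exposure=exposure, outcome=mediator, config=config, ld=ld,
        name=f"{exposure.trait_name}->{mediator.trait_name}",
    )
    exclude = ()
    if config.exclude_exposure_associated:
        exclude = tuple(
            filter_by_pvalue(exposure, config.p_threshold).snp_ids
        )
    leg_my = _try_leg(
        report, "mediator_outcome",
        exposure=mediator, outcome=outcome, config=config, ld=ld,
        exclude_snp_ids=exclude,
        name=f"{mediator.trait_name}->{outcome.trait_name}",
    )

    forward_legs = (leg_xy, leg_xm, leg_my)
    if all(leg is not None and not leg.failed for leg in forward_legs):
        try:
            report.mediation = run_two_step(
                leg_xm.primary_estimate(config.primary_method),
                leg_my.primary_estimate(config.primary_method),
                leg_xy.primary_estimate(config.primary_method),
                exposure_name=exposure.trait_name,
                mediator_name=mediator.trait_name,
                outcome_name=outcome.trait_name,
            )
        except (ValueError, PipelineError) as exc:
            report.mediation_error = str(exc)
    else:
        failed = [leg.name for leg in forward_legs if leg is not None and leg.failed]
        report.mediation_error = f"leg(s) failed: {', '.join(failed)}"

    if config.out_dir:
        write_report(report, config.out_dir)
    return report


# ---------------------------------------------------------------------------
# table exports


def estimates_frame(estimates) -> pd.DataFrame:
    """Forest-plot layout: method, n_snp, beta, se, pvalue, or, ci bounds."""
    rows = []
    for est in estimates:
        if isinstance(est, MethodFailure):
            rows.append(
                {
                    "method": est.method,
                    "n_snp": np.nan,
                    "beta": np.nan,
                    "se": np.nan,
                    "pvalue": np.nan,
                    "or": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "status": f"failed: {est.error}",
                }
            )
        else:
            rows.append(
                {
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "pvalue": est.pvalue,
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "status": "primary" if est.extra.get("primary") else "ok",
                }
            )
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_leg(leg: LegResult, out_dir) -> None:
    """Write one leg's TSV tables (estimates, diagnostics, exclusions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(estimates_frame(leg.estimates), out / "estimates.tsv")
    if leg.heterogeneity:
        _write_tsv(heterogeneity_frame(leg.heterogeneity), out / "heterogeneity.tsv")
    if leg.pleiotropy is not None:
        _write_tsv(
            pd.DataFrame([vars(leg.pleiotropy)]), out / "pleiotropy.tsv"
        )
    if leg.single_snp:
        _write_tsv(single_snp_frame(leg.single_snp), out / "single_snp.tsv")
    if leg.loo:
        _write_tsv(leave_one_out_frame(leg.loo), out / "leave_one_out.tsv")
    _write_tsv(
        pd.DataFrame(leg.exclusions, columns=["snp", "stage", "reason"]),
        out / "exclusions.tsv",
    )


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write every leg plus mediation.tsv and run_summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, leg in report.legs.items():
        if not leg.failed:
            write_leg(leg, out / key)
    if report.mediation is not None:
        _write_tsv(mediation_frame(report.mediation), out / "mediation.tsv")
    summary = {
        "version": report.version,
        "config": asdict(report.config) if report.config else None,
        "legs": {
            key: {
                "name": leg.name,
                "exposure": leg.exposure_name,
                "outcome": leg.outcome_name,
                "n_snp": leg.n_snp,
                "survival": leg.survival,
                "error": leg.error,
            }
            for key, leg in report.legs.items()
        },
        "mediation": (
            None
            if report.mediation is None
            else {
                "a": report.mediation.a,
                "b": report.mediation.b,
                "c_prime": report.mediation.c_prime,
                "indirect": report.mediation.indirect,
                "total": report.mediation.total,
                "proportion": report.mediation.proportion,
                "proportion_percent": report.mediation.proportion_percent,
                "sign_inconsistent": report.mediation.sign_inconsistent,
            }
        ),
        "mediation_error": report.mediation_error,
    }
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
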