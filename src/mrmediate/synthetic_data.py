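"""Synthetic three-trait GWAS summary statistics with known truth.

Generates exposure (X), mediator (M) and outcome (Y) summary-statistic
tables directly at the summary level under the structural model

    X  <- gamma_j * G_j
    M  =  a * X   (+ delta_j * G_j for mediator-specific instruments)
    Y  =  c' * X + b * M  (+ alpha_j * G_j horizontal pleiotropy)

so the true marginal SNP effects are ``gamma_j`` on X, ``a*gamma_j +
delta_j`` on M and ``(c' + a*b)*gamma_j + sign(gamma_j)*alpha_j +
b*delta_j`` on Y (pleiotropy oriented to the exposure-increasing allele).
Observed effects add independent Gaussian noise with the standard GWAS
standard error ``se = sqrt(var_trait / (2*maf*(1-maf)*n))``, emulating
three non-overlapping GWAS samples (the two-sample design assumption).

Horizontal pleiotropy ``alpha_j`` acts on the outcome only (InSIDE-style):
mean 0 is balanced, nonzero mean is directional.  Mediator-specific
instruments (``n_mediator_snps`` extra SNPs with direct effects
``delta_j`` on M and no effect on X) are off by default; they are what a
real mediator GWAS contributes and are required for the mediator->outcome
leg of a two-step mediation analysis to be identified.

Defaults mirror the motivating study design: a small microbiome-pathway
exposure GWAS (n = 7,738), a large binary-outcome GWAS (n = 451,025), a
mid-size immune-cell mediator GWAS, 11 exposure instruments, and the
published exposure->mediator / mediator->outcome / direct effects of the
monocyte-mediated pulmonary-fibrosis leg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .gwas_io import AssociationRecord, SummaryTable

__all__ = ["SimulationConfig", "SimulationTruth", "SimulatedStudy", "simulate_study", "truth_report"]

# smallest p-value the generator reports; avoids p = 0 (invalid) at
# astronomically large z-scores
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one simulated three-trait study.

    ``a``, ``b``, ``c_prime`` are the structural coefficients (their
    defaults are the monocyte/pulmonary-fibrosis leg on the log-odds
    scale: a = ln 0.772, b = ln 1.0003, c' = -0.0009240468).
    ``gamma_scale`` is the SD of per-SNP instrument effects on X;
    ``pleiotropy_*`` control the fraction and distribution of direct
    SNP->Y effects; ``n_mediator_snps``/``delta_scale`` add
    mediator-specific instruments.  ``palindrome_fraction`` converts that
    share of SNPs to A/T alleles to exercise harmonization.
    """

    n_snps: int = 11
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_scale: float = 0.1
    a: float = math.log(0.772)
    b: float = math.log(1.0003)
    c_prime: float = -0.0009240468
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    n_mediator_snps: int = 0
    delta_scale: float = 0.1
    n_exposure: int = 7738
    n_mediator: int = 3757
    n_outcome: int = 451025
    var_x: float = 1.0
    var_m: float = 1.0
    var_y: float = 1.0
    palindrome_fraction: float = 0.0
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError(
                f"pleiotropy_fraction must lie in [0, 1], got {self.pleiotropy_fraction}"
            )
        if not (0.0 <= self.palindrome_fraction <= 1.0):
            raise ValueError(
                f"palindrome_fraction must lie in [0, 1], got {self.palindrome_fraction}"
            )
        if self.n_mediator_snps < 0:
            raise ValueError(f"n_mediator_snps must be >= 0, got {self.n_mediator_snps}")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in ("gamma_scale", "delta_scale", "pleiotropy_sd", "var_x", "var_m", "var_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class SimulationTruth:
    """Realized per-SNP effects and implied population quantities."""

    config: SimulationConfig
    gamma: np.ndarray   # SNP -> X effects (0 for mediator-specific SNPs)
    alpha: np.ndarray   # direct SNP -> Y (horizontal pleiotropy)
    delta: np.ndarray   # direct SNP -> M (mediator instruments)
    total: float        # c' + a*b

    @property
    def proportion(self) -> Optional[float]:
        if self.total == 0:
            return None
        return self.config.a * self.config.b / self.total


@dataclass
class SimulatedStudy:
    """Three synthetic summary tables plus the generating truth."""

    exposure_table: SummaryTable
    mediator_table: SummaryTable
    outcome_table: SummaryTable
    truth: SimulationTruth


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    return np.maximum(2.0 * stats.norm.sf(z), _P_FLOOR)


def _make_table(
    name: str,
    trait_type: str,
    snp_ids: list[str],
    effect_alleles: list[str],
    other_alleles: list[str],
    true_beta: np.ndarray,
    maf: np.ndarray,
    n: int,
    var: float,
    rng: np.random.Generator,
) -> SummaryTable:
    se = np.sqrt(var / (2.0 * maf * (1.0 - maf) * n))
    beta = true_beta + rng.normal(0.0, se)
    pvals = _pvalue(beta, se)
    records = [
        AssociationRecord(
            snp_id=snp_ids[j],
            effect_allele=effect_alleles[j],
            other_allele=other_alleles[j],
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(pvals[j]),
            eaf=float(maf[j]),
            n=n,
        )
        for j in range(len(snp_ids))
    ]
    return SummaryTable(trait_name=name, trait_type=trait_type, records=records)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one study; identical config (incl. seed) gives identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    j_exp = config.n_snps
    j_med = config.n_mediator_snps
    j_all = j_exp + j_med

    width = len(str(j_all))
    snp_ids = [f"rs{j + 1:0{width}d}" for j in range(j_all)]
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j_all)

    gamma = np.zeros(j_all)
    gamma[:j_exp] = rng.normal(0.0, config.gamma_scale, size=j_exp)
    delta = np.zeros(j_all)
    if j_med:
        delta[j_exp:] = rng.normal(0.0, config.delta_scale, size=j_med)

    alpha = np.zeros(j_all)
    n_invalid = math.ceil(config.pleiotropy_fraction * j_exp)
    if n_invalid:
        invalid = rng.permutation(j_exp)[:n_invalid]
        alpha[invalid] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid
        )

    effect_alleles = ["A"] * j_all
    other_alleles = ["G"] * j_all
    n_pal = math.ceil(config.palindrome_fraction * j_all)
    if n_pal:
        pal = rng.permutation(j_all)[:n_pal]
        for idx in pal:
            other_alleles[idx] = "T"

    total = config.c_prime + config.a * config.b
    beta_x = gamma
    beta_m = config.a * gamma + delta
    # pleiotropy is applied on the exposure-increasing orientation of each
    # instrument: under balanced pleiotropy (mean 0) the sign alignment is
    # distributionally irrelevant, under directional pleiotropy it makes
    # every invalid instrument's ratio offset share one direction, which is
    # what "directional" means in Wald-ratio space
    orient = np.where(gamma < 0, -1.0, 1.0)
    beta_y = total * gamma + orient * alpha + config.b * delta

    exposure = _make_table(
        config.exposure_name, "quantitative", snp_ids, effect_alleles, other_alleles,
        beta_x, maf, config.n_exposure, config.var_x, rng,
    )
    mediator = _make_table(
        config.mediator_name, "quantitative", snp_ids, effect_alleles, other_alleles,
        beta_m, maf, config.n_mediator, config.var_m, rng,
    )
    outcome = _make_table(
        config.outcome_name, "binary", snp_ids, effect_alleles, other_alleles,
        beta_y, maf, config.n_outcome, config.var_y, rng,
    )
    truth = SimulationTruth(
        config=config, gamma=gamma, alpha=alpha, delta=delta, total=total
    )
    return SimulatedStudy(
        exposure_table=exposure,
        mediator_table=mediator,
        outcome_table=outcome,
        truth=truth,
    )


def truth_report(study: SimulatedStudy) -> dict:
    """Named true quantities of a simulated study (for recovery tests)."""
    cfg = study.truth.config
    report = {
        "a": cfg.a,
        "b": cfg.b,
        "c_prime": cfg.c_prime,
        "total": study.truth.total,
        "proportion": study.truth.proportion,
        "gamma": {s: float(g) for s, g in zip(study.exposure_table.snp_ids, study.truth.gamma)},
        "alpha": {s: float(x) for s, x in zip(study.exposure_table.snp_ids, study.truth.alpha)},
        "delta": {s: float(d) for s, d in zip(study.exposure_table.snp_ids, study.truth.delta)},
    }
    return report
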