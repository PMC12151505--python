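"""Instrument selection and exposure/outcome harmonization.

Instrument selection follows the usual three-stage screen for two-sample
Mendelian randomization:

1. genome-wide association with the exposure at a p-value threshold
   (strict ``p < threshold``; the conventional microbiome-scale choice
   is 1e-5),
2. approximate independence via greedy LD clumping on a pairwise r-squared
   matrix (keep the lowest-p SNP, discard everything correlated with it,
   repeat),
3. a weak-instrument screen on the single-SNP F statistic
   ``F = (beta/se)**2`` with the conventional cutoff F >= 10.

Harmonization aligns the outcome association of every shared SNP to the
exposure's effect allele, flipping signs and frequencies when the allele
order is swapped, resolving strand complements, and handling palindromic
(A/T, C/G) SNPs either by exclusion or by allele-frequency concordance.
Every exclusion is recorded with its reason; nothing is dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gwas_io import AssociationRecord, SummaryTable

__all__ = [
    "LDMatrix",
    "HarmonizedPair",
    "HarmonizedDataset",
    "HarmonizationError",
    "ClumpConfigurationError",
    "filter_by_pvalue",
    "greedy_clump",
    "f_statistic",
    "filter_weak",
    "harmonize",
    "read_ld_matrix",
    "write_ld_matrix",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))


class HarmonizationError(ValueError):
    """No shared SNPs, or structurally impossible harmonization."""


class ClumpConfigurationError(ValueError):
    """A SNP required for clumping is absent from the LD matrix."""


@dataclass
class LDMatrix:
    """Square symmetric matrix of pairwise r-squared values.

    Diagonal is exactly 1; off-diagonals in [0, 1]; symmetric to 1e-12.
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0):
            raise ValueError("r2 matrix is not symmetric (tolerance 1e-12)")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def read_ld_matrix(path) -> LDMatrix:
    """TSV with snp ids as first row and first column, body = r-squared."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(snp_ids=[str(s) for s in frame.index], r2=frame.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects of one SNP on a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None
    palindromic: bool = False
    flipped: bool = False


@dataclass
class HarmonizedDataset:
    """All harmonized pairs for one exposure-outcome leg (J instruments)."""

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        bx = np.array([p.beta_exposure for p in self.pairs])
        sx = np.array([p.se_exposure for p in self.pairs])
        by = np.array([p.beta_outcome for p in self.pairs])
        sy = np.array([p.se_outcome for p in self.pairs])
        return bx, sx, by, sy

    def subset(self, snp_ids) -> "HarmonizedDataset":
        keep = set(snp_ids)
        return HarmonizedDataset(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            pairs=[p for p in self.pairs if p.snp_id in keep],
        )


def filter_by_pvalue(table: SummaryTable, threshold: float) -> SummaryTable:
    """Keep records with ``pvalue < threshold`` (strict), order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return table.subset(r.snp_id for r in table.records if r.pvalue < threshold)


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F statistic, ``(beta/se)**2``."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_weak(table: SummaryTable, f_min: float = 10.0) -> SummaryTable:
    """Keep records with F >= ``f_min``."""
    if f_min < 0:
        raise ValueError(f"f_min must be >= 0, got {f_min}")
    return table.subset(
        r.snp_id for r in table.records if f_statistic(r.beta, r.se) >= f_min
    )


def greedy_clump(table: SummaryTable, ld: LDMatrix, r2_max: float = 0.001) -> SummaryTable:
    """Greedy p-ordered LD clumping.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by lexicographic snp id) and discard every remaining SNP with
    r-squared > ``r2_max`` to it.  The kept set is therefore an independent
    set under the r2_max relation, deterministically.
    """
    if not (0.0 <= r2_max < 1.0):
        raise ValueError(f"r2_max must lie in [0, 1), got {r2_max}")
    missing = [r.snp_id for r in table.records if r.snp_id not in ld]
    if missing:
        raise ClumpConfigurationError(
            f"SNP(s) absent from LD matrix: {', '.join(missing)}"
        )
    remaining = sorted(table.records, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead.snp_id)
        remaining = [
            r for r in remaining if ld.lookup(lead.snp_id, r.snp_id) <= r2_max
        ]
    return table.subset(kept)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_SETS


def _flip_outcome(rec: AssociationRecord) -> AssociationRecord:
    """Swap effect/other allele of an outcome record: negate beta, 1-eaf."""
    return AssociationRecord(
        snp_id=rec.snp_id,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        se=rec.se,
        pvalue=rec.pvalue,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
        n=rec.n,
    )


def _complement_outcome(rec: AssociationRecord) -> AssociationRecord:
    """Re-express an outcome record on the opposite strand (no sign change)."""
    return AssociationRecord(
        snp_id=rec.snp_id,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
        beta=rec.beta,
        se=rec.se,
        pvalue=rec.pvalue,
        eaf=rec.eaf,
        n=rec.n,
    )


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    For each SNP shared between the tables:

    * matching alleles are copied unchanged;
    * swapped alleles negate the outcome beta and reflect its frequency
      (``flipped=True``);
    * alleles matching only after strand complementation are complemented
      first, then treated as above;
    * palindromic SNPs (A/T or C/G) are excluded under policy ``drop``;
      under ``infer_by_eaf`` they are aligned by effect-allele-frequency
      concordance, but excluded when either frequency is missing or lies
      within ``eaf_window`` of 0.5 (frequency uninformative about strand);
    * irreconcilable allele sets are excluded.

    All exclusions are recorded in ``HarmonizedDataset.exclusions`` as
    ``(snp_id, reason)``.  Raises :class:`HarmonizationError` when the
    tables share no SNPs.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    outcome_by_id = {r.snp_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.snp_id in outcome_by_id]
    if not shared:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    pairs: list[HarmonizedPair] = []
    exclusions: list[tuple[str, str]] = []
    for exp in shared:
        out = outcome_by_id[exp.snp_id]
        exp_alleles = (exp.effect_allele, exp.other_allele)
        pal = _is_palindromic(*exp_alleles)

        if pal:
            if frozenset((out.effect_allele, out.other_allele)) != frozenset(exp_alleles):
                exclusions.append((exp.snp_id, "incompatible alleles"))
                continue
            if palindrome_policy == "drop":
                exclusions.append((exp.snp_id, "palindromic (policy drop)"))
                continue
            if exp.eaf is None or out.eaf is None:
                exclusions.append((exp.snp_id, "palindromic with missing eaf"))
                continue
            flipped = out.effect_allele != exp.effect_allele
            aligned = _flip_outcome(out) if flipped else out
            near = lambda f: abs(f - 0.5) <= eaf_window  # noqa: E731
            if near(exp.eaf) or near(aligned.eaf):
                exclusions.append(
                    (exp.snp_id, "palindromic with eaf too close to 0.5")
                )
                continue
            # discordant minor allele => the outcome is reported on the
            # opposite strand: flip orientation once more
            if (exp.eaf < 0.5) != (aligned.eaf < 0.5):
                aligned = _flip_outcome(_complement_outcome(aligned))
                flipped = not flipped
        else:
            out_alleles = (out.effect_allele, out.other_allele)
            comp_alleles = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
            if out_alleles == exp_alleles:
                aligned, flipped = out, False
            elif out_alleles == exp_alleles[::-1]:
                aligned, flipped = _flip_outcome(out), True
            elif comp_alleles == exp_alleles:
                aligned, flipped = _complement_outcome(out), False
            elif comp_alleles == exp_alleles[::-1]:
                aligned, flipped = _flip_outcome(_complement_outcome(out)), True
            else:
                exclusions.append((exp.snp_id, "incompatible alleles"))
                continue

        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=aligned.beta,
                se_outcome=aligned.se,
                eaf_exposure=exp.eaf,
                eaf_outcome=aligned.eaf,
                palindromic=pal,
                flipped=flipped,
            )
        )

    return HarmonizedDataset(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        pairs=pairs,
        exclusions=exclusions,
    )
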