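"""Multivariable MR: joint exposure fits and conditional instrument strength.

The joint instrument set is the union of each exposure's genome-wide
significant SNPs, clumped on the per-SNP minimum p-value across exposures,
restricted to SNPs present in every study and harmonized to a common effect
allele.  ``mvmr_fit`` regresses SNP-outcome betas on the J x K matrix of
exposure betas (no intercept, inverse-variance weights), so each coefficient
is one exposure's effect on the outcome conditional on the others.

The conditional F-statistic for exposure k is the weighted residual sum of
squares from regressing its instrument betas on the other exposures' betas
(weights 1 / se_k², no intercept) divided by J - K + 1: it measures how much
instrument signal exposure k retains once the shared signal is projected out,
and is invariant to jointly rescaling the target's betas and SEs and to the
units of the other exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .estimators import MVMRRegression
from .sumstats import (
    HarmonizedPairs,
    InsufficientInstrumentsError,
    LDTable,
    SumStats,
    clump,
    harmonize_studies,
    is_biallelic_snp,
)
from .uvmr import MREstimate

__all__ = ["MVPairs", "MVMRResult", "mvmr_instruments", "mvmr_fit", "conditional_f"]


@dataclass
class MVPairs:
    """Harmonized per-SNP effects for K exposures and one outcome."""

    snp_ids: list[str]
    exposure_labels: list[str]
    bx: np.ndarray        # (J, K) exposure betas, common effect allele
    se_bx: np.ndarray     # (J, K)
    by: np.ndarray        # (J,)
    se_by: np.ndarray     # (J,)
    dropped: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    @classmethod
    def from_pairs(cls, pairs: HarmonizedPairs,
                   labels: tuple[str, str] = ("exposure", "mediator")) -> "MVPairs":
        """Exposure + mediator columns of three-study pairs as a K=2 design."""
        if not pairs.has_mediator:
            raise ValueError("pairs carry no mediator columns")
        return cls(
            snp_ids=pairs.snp_ids,
            exposure_labels=list(labels),
            bx=np.column_stack([pairs.beta_exposure, pairs.beta_mediator]),
            se_bx=np.column_stack([pairs.se_exposure, pairs.se_mediator]),
            by=pairs.beta_outcome,
            se_by=pairs.se_outcome,
            dropped=list(pairs.dropped),
        )


@dataclass
class MVMRResult:
    estimates: list[MREstimate]       # one per exposure, order of exposure_labels
    exposure_labels: list[str]
    n_snp: int
    conditional_f: dict[str, float]
    residual_scale: float

    def to_dict(self) -> dict:
        return {
            "estimates": {lab: est.to_dict()
                          for lab, est in zip(self.exposure_labels, self.estimates)},
            "n_snp": self.n_snp,
            "conditional_f": self.conditional_f,
            "residual_scale": self.residual_scale,
        }

    def estimate_for(self, label: str) -> MREstimate:
        return self.estimates[self.exposure_labels.index(label)]


def mvmr_instruments(exposures: list[SumStats], outcome: SumStats,
                     ld: LDTable | None = None, p_threshold: float = 5e-8,
                     r2_threshold: float = 0.001, window_bp: int = 10_000_000,
                     palindrome_maf_limit: float = 0.30) -> MVPairs:
    """Joint instrument set for a multivariable fit.

    Union of each exposure's significant biallelic SNPs, restricted to SNPs
    present in every dataset, clumped on the per-SNP minimum p across
    exposures (positions from the first exposure), harmonized to the first
    exposure's effect allele.  Raises
    :class:`~mrmediate.sumstats.InsufficientInstrumentsError` when fewer than
    K + 2 SNPs survive.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least two exposures")
    ld = ld if ld is not None else LDTable()
    k = len(exposures)

    sig: set[str] = set()
    for exp in exposures:
        t = exp.table
        ok = np.array([is_biallelic_snp(ea, oa) for ea, oa
                       in zip(t["effect_allele"], t["other_allele"])])
        sig |= set(t.loc[ok & (t["pval"].to_numpy() < p_threshold), "snp_id"])

    present = sig
    for study in [*exposures, outcome]:
        present = present & set(study.table["snp_id"])
    if len(present) < k + 2:
        raise InsufficientInstrumentsError(len(present), k + 2)

    # clump on min-p across exposures; coordinates from the first exposure
    base = exposures[0].subset(present).table.copy()
    minp = base["pval"].to_numpy().copy()
    pos_of = {s: i for i, s in enumerate(base["snp_id"])}
    for exp in exposures[1:]:
        sub = exp.table[exp.table["snp_id"].isin(present)]
        for s, p in zip(sub["snp_id"], sub["pval"]):
            i = pos_of[s]
            minp[i] = min(minp[i], p)
    base["pval"] = minp
    joint = SumStats(exposures[0].trait_label, base)
    kept = clump(joint, ld, r2_threshold, window_bp)

    subsets = [s.subset(kept) for s in exposures] + [outcome.subset(kept)]
    wide, dropped = harmonize_studies(subsets, palindrome_maf_limit)
    if len(wide) < k + 2:
        raise InsufficientInstrumentsError(len(wide), k + 2)
    return MVPairs(
        snp_ids=wide["snp_id"].tolist(),
        exposure_labels=[e.trait_label for e in exposures],
        bx=wide[[f"beta_{i}" for i in range(k)]].to_numpy(float),
        se_bx=wide[[f"se_{i}" for i in range(k)]].to_numpy(float),
        by=wide[f"beta_{k}"].to_numpy(float),
        se_by=wide[f"se_{k}"].to_numpy(float),
        dropped=dropped,
    )


def mvmr_fit(pairs: MVPairs) -> MVMRResult:
    """Joint WLS fit plus conditional F per exposure."""
    est = MVMRRegression().fit(pairs.bx, pairs.by, pairs.se_by)
    estimates = [
        MREstimate(method="MVMR", beta=float(est.coef_[i]), se=float(est.se_[i]),
                   ci_low=float(est.ci_low_[i]), ci_high=float(est.ci_high_[i]),
                   pval=float(est.pval_[i]), n_snp=int(est.n_snp_))
        for i in range(pairs.n_exposures)
    ]
    cond_f = {lab: conditional_f(pairs, i)
              for i, lab in enumerate(pairs.exposure_labels)}
    return MVMRResult(estimates=estimates,
                      exposure_labels=list(pairs.exposure_labels),
                      n_snp=len(pairs), conditional_f=cond_f,
                      residual_scale=float(est.scale_))


def conditional_f(pairs: MVPairs, exposure_index: int) -> float:
    """Conditional instrument strength of one exposure given the others."""
    j, k = pairs.bx.shape
    if not 0 <= exposure_index < k:
        raise IndexError(f"exposure_index {exposure_index} out of range for K={k}")
    if j < k + 2:
        raise ValueError(f"need at least K + 2 = {k + 2} SNPs, got {j}")
    target = pairs.bx[:, exposure_index]
    se_t = pairs.se_bx[:, exposure_index]
    w = 1.0 / se_t**2
    others = np.delete(pairs.bx, exposure_index, axis=1)
    if others.shape[1] > 0:
        xw = others * np.sqrt(w)[:, None]
        if np.linalg.matrix_rank(xw) < others.shape[1]:
            raise np.linalg.LinAlgError("collinear non-target exposure betas")
        fitted = others @ sm.WLS(target, others, weights=w).fit().params
        resid = target - fitted
    else:
        resid = target
    q_x = float(w @ resid**2)
    return q_x / (j - k + 1)
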