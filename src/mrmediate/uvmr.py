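"""Univariable two-sample MR: the estimator battery plus sensitivity suite.

Thin wrappers mapping :class:`~mrmediate.sumstats.HarmonizedPairs` onto the
estimator classes in :mod:`mrmediate.estimators`, returning small result
records (:class:`MREstimate` and friends) that serialize to JSON/TSV.  The
battery mirrors standard two-sample MR practice: IVW as the primary
estimator, weighted median and MR-Egger as sensitivity analyses, plus
Cochran's Q, the Egger intercept pleiotropy test, leave-one-out influence
checks, and the MR-PRESSO outlier test.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .estimators import (
    EggerRegression,
    IVWRegression,
    MRPresso,
    WeightedMedianEstimator,
)
from .sumstats import HarmonizedPairs, LDTable, SumStats, harmonize, select_instruments

__all__ = [
    "MREstimate",
    "EggerResult",
    "HeterogeneityStats",
    "PressoResult",
    "LeaveOneOutEntry",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "leave_one_out",
    "mr_presso",
    "export_plot_data",
    "uvmr_report",
]


@dataclass
class MREstimate:
    """One causal-effect estimate (outcome units per exposure unit)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EggerResult:
    slope: MREstimate
    intercept_estimate: float
    intercept_se: float
    intercept_pval: float

    def to_dict(self) -> dict:
        return {"slope": self.slope.to_dict(),
                "intercept_estimate": self.intercept_estimate,
                "intercept_se": self.intercept_se,
                "intercept_pval": self.intercept_pval}


@dataclass
class LeaveOneOutEntry:
    left_out_snp: str
    estimate: MREstimate
    flagged: bool


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_snps: list
    corrected: MREstimate
    n_sim: int
    seed: int | None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corrected"] = self.corrected.to_dict()
        return d


def _estimate_from(est, method: str) -> MREstimate:
    return MREstimate(method=method, beta=float(est.beta_), se=float(est.se_),
                      ci_low=float(est.ci_low_), ci_high=float(est.ci_high_),
                      pval=float(est.pval_), n_snp=int(est.n_snp_))


def ratio_estimates(pairs: HarmonizedPairs) -> pd.DataFrame:
    """Per-SNP Wald ratios by/bx with first-order SE se_y/|bx|.

    SNPs with a zero exposure beta are dropped with a warning; an all-zero
    exposure vector is an error.
    """
    bx = pairs.beta_exposure
    nonzero = bx != 0
    if not nonzero.any():
        raise ValueError("all exposure betas are zero; no ratio estimates")
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} SNP(s) with zero "
                      "exposure beta from ratio estimates")
    ids = np.asarray(pairs.snp_ids)[nonzero]
    bx = bx[nonzero]
    by = pairs.beta_outcome[nonzero]
    se = pairs.se_outcome[nonzero]
    return pd.DataFrame({"snp_id": ids, "ratio": by / bx, "se": se / np.abs(bx)})


def ivw(pairs: HarmonizedPairs,
        model: str = "multiplicative_random") -> tuple[MREstimate, HeterogeneityStats]:
    est = IVWRegression(model=model).fit(
        pairs.beta_exposure, pairs.beta_outcome, pairs.se_outcome)
    het = HeterogeneityStats(Q=float(est.q_), df=int(est.q_df_), pval=float(est.q_pval_))
    return _estimate_from(est, "IVW"), het


def egger(pairs: HarmonizedPairs) -> EggerResult:
    est = EggerRegression().fit(pairs.beta_exposure, pairs.beta_outcome,
                                pairs.se_outcome)
    return EggerResult(slope=_estimate_from(est, "Egger"),
                       intercept_estimate=float(est.intercept_),
                       intercept_se=float(est.intercept_se_),
                       intercept_pval=float(est.intercept_pval_))


def weighted_median(pairs: HarmonizedPairs, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(
        pairs.beta_exposure, pairs.beta_outcome, pairs.se_outcome,
        se_x=pairs.se_exposure)
    return _estimate_from(est, "WeightedMedian")


def leave_one_out(pairs: HarmonizedPairs,
                  model: str = "multiplicative_random") -> list[LeaveOneOutEntry]:
    """IVW with each SNP omitted in turn.

    An omission is flagged when it flips the sign of the estimate or moves it
    outside the full-sample confidence interval.
    """
    if len(pairs) < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    full, _ = ivw(pairs, model=model)
    bx, by, se = pairs.beta_exposure, pairs.beta_outcome, pairs.se_outcome
    ids = pairs.snp_ids
    out = []
    for j in range(len(ids)):
        keep = np.arange(len(ids)) != j
        est = IVWRegression(model=model).fit(bx[keep], by[keep], se[keep])
        rec = _estimate_from(est, "IVW")
        flagged = (np.sign(rec.beta) != np.sign(full.beta)
                   or not (full.ci_low <= rec.beta <= full.ci_high))
        out.append(LeaveOneOutEntry(ids[j], rec, bool(flagged)))
    return out


def mr_presso(pairs: HarmonizedPairs, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    est = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha,
                   random_state=seed).fit(pairs.beta_exposure, pairs.beta_outcome,
                                          pairs.se_outcome)
    ids = np.asarray(pairs.snp_ids)
    return PressoResult(
        global_rss=float(est.global_rss_),
        global_pval=float(est.global_pval_),
        outlier_snps=ids[est.outlier_mask_].tolist(),
        corrected=_estimate_from(est.corrected_, "IVW"),
        n_sim=n_sim,
        seed=seed,
    )


def export_plot_data(pairs: HarmonizedPairs,
                     estimates: dict[str, MREstimate]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tables sufficient to redraw the scatter and funnel diagnostic plots.

    Scatter: per-SNP (bx, by, ses) plus one fitted-line slope column per
    method.  Funnel: per-SNP ratio against its precision 1/se_ratio.
    """
    scatter = pd.DataFrame({
        "snp_id": pairs.snp_ids,
        "beta_exposure": pairs.beta_exposure,
        "se_exposure": pairs.se_exposure,
        "beta_outcome": pairs.beta_outcome,
        "se_outcome": pairs.se_outcome,
    })
    for name, est in estimates.items():
        scatter[f"slope_{name}"] = est.beta
    ratios = ratio_estimates(pairs)
    funnel = pd.DataFrame({"snp_id": ratios["snp_id"], "ratio": ratios["ratio"],
                           "precision": 1.0 / ratios["se"]})
    return scatter, funnel


def uvmr_report(exposure: SumStats, outcome: SumStats, ld: LDTable | None = None,
                p_threshold: float = 5e-8, r2_threshold: float = 0.001,
                window_bp: int = 10_000_000, min_variants: int = 10,
                palindrome_maf_limit: float = 0.30,
                n_boot: int = 1000, n_sim: int = 1000,
                seed: int | None = 0) -> dict:
    """Full univariable MR battery for one exposure-outcome pair.

    Selects instruments from the exposure study, harmonizes the outcome to
    them, and runs IVW (both variants), weighted median, MR-Egger with the
    intercept test, leave-one-out, and MR-PRESSO.  Deterministic given
    ``seed``; the result is a JSON-serializable dict.
    """
    ld = ld if ld is not None else LDTable()
    instruments = select_instruments(exposure, ld, p_threshold, r2_threshold,
                                     window_bp, min_variants)
    pairs = harmonize(exposure.subset(instruments.snp_ids), outcome,
                      palindrome_maf_limit=palindrome_maf_limit)
    ivw_mre, het = ivw(pairs, model="multiplicative_random")
    ivw_fixed, _ = ivw(pairs, model="fixed")
    egger_res = egger(pairs)
    wm = weighted_median(pairs, n_boot=n_boot, seed=seed)
    loo = leave_one_out(pairs)
    presso = mr_presso(pairs, n_sim=n_sim, seed=seed)
    return {
        "exposure": exposure.trait_label,
        "outcome": outcome.trait_label,
        "n_instruments": len(instruments),
        "n_harmonized": len(pairs),
        "dropped": list(map(list, pairs.dropped)),
        "ivw": ivw_mre.to_dict(),
        "ivw_fixed": ivw_fixed.to_dict(),
        "heterogeneity": het.to_dict(),
        "egger": egger_res.to_dict(),
        "weighted_median": wm.to_dict(),
        "leave_one_out_flags": [e.left_out_snp for e in loo if e.flagged],
        "presso": presso.to_dict(),
        "params": {"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                   "window_bp": window_bp, "min_variants": min_variants,
                   "palindrome_maf_limit": palindrome_maf_limit,
                   "n_boot": n_boot, "n_sim": n_sim, "seed": seed},
    }
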