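"""Two-step MR causal mediation: screening, decomposition, FDR control.

Step one screens candidate traits: a trait is eligible for mediation analysis
when it causally associates with both the mediator and the outcome (IVW,
BH-FDR within each leg across traits) and is *not* itself caused by the
mediator (reverse IVW using the mediator's instruments).  Step two decomposes
the eligible trait's total effect on the outcome into a direct effect (the
trait's coefficient from a joint multivariable fit adjusting for the
mediator) and an indirect effect, the product of the trait -> mediator effect
(beta1) and the mediator -> outcome effect conditional on the trait (beta2),
with a delta-method (Sobel) standard error and mediation proportion
indirect / total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mvmr import mvmr_fit, mvmr_instruments
from .sumstats import (
    InsufficientInstrumentsError,
    LDTable,
    SumStats,
    harmonize,
    select_instruments,
)
from .uvmr import MREstimate, ivw

__all__ = [
    "ScreenStatus",
    "ScreenResult",
    "MediationResult",
    "fdr_adjust",
    "screen_traits",
    "venn_counts",
    "two_step_mediation",
    "mediation_table",
    "sobel_se",
]

#: |total| below this is treated as zero and the proportion left undefined
_TOTAL_TOL = 1e-12


class ScreenStatus(str, Enum):
    NOT_ASSOC_MEDIATOR = "not_assoc_mediator"
    NOT_ASSOC_OUTCOME = "not_assoc_outcome"
    REVERSE_CAUSED = "reverse_caused"
    ELIGIBLE = "eligible"
    INSUFFICIENT_INSTRUMENTS = "insufficient_instruments"


@dataclass
class ScreenResult:
    trait_label: str
    status: ScreenStatus
    assoc_mediator: tuple[MREstimate, float] | None = None  # (estimate, q)
    assoc_outcome: tuple[MREstimate, float] | None = None
    reverse: tuple[MREstimate, float] | None = None
    n_instruments: int | None = None

    def to_row(self) -> dict:
        row = {"trait": self.trait_label, "status": self.status.value,
               "n_instruments": self.n_instruments}
        for leg, pair in (("mediator", self.assoc_mediator),
                          ("outcome", self.assoc_outcome),
                          ("reverse", self.reverse)):
            if pair is None:
                row.update({f"{leg}_beta": np.nan, f"{leg}_se": np.nan,
                            f"{leg}_p": np.nan, f"{leg}_q": np.nan})
            else:
                est, q = pair
                row.update({f"{leg}_beta": est.beta, f"{leg}_se": est.se,
                            f"{leg}_p": est.pval, f"{leg}_q": q})
        return row


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition for one trait."""

    trait_label: str
    total: MREstimate
    beta1: MREstimate            # trait -> mediator (univariable IVW)
    direct: MREstimate           # trait coefficient, joint MVMR
    beta2: MREstimate            # mediator coefficient, same MVMR fit
    indirect: float
    indirect_se: float
    proportion: float | None     # indirect / total, fraction; None if undefined
    direction_consistent: bool

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_label,
            "total": self.total.to_dict(),
            "beta1": self.beta1.to_dict(),
            "direct": self.direct.to_dict(),
            "beta2": self.beta2.to_dict(),
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "proportion": self.proportion,
            "direction_consistent": self.direction_consistent,
        }


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    pvals = np.asarray(list(pvals), float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def sobel_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Delta-method SE of the product beta1 * beta2."""
    return math.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2)


@dataclass
class _Legs:
    mediator: MREstimate
    outcome: MREstimate
    reverse: MREstimate
    n_instruments: int


def _ivw_leg(exposure: SumStats, outcome: SumStats, instruments,
             palindrome_maf_limit: float) -> MREstimate:
    pairs = harmonize(exposure.subset(instruments.snp_ids), outcome,
                      palindrome_maf_limit=palindrome_maf_limit)
    est, _ = ivw(pairs)
    return est


def screen_traits(traits: list[SumStats], mediator: SumStats, outcome: SumStats,
                  ld: LDTable | None = None, fdr_level: float = 0.05,
                  p_threshold: float = 5e-8, r2_threshold: float = 0.001,
                  window_bp: int = 10_000_000, min_variants: int = 10,
                  palindrome_maf_limit: float = 0.30) -> list[ScreenResult]:
    """Step-one screening of candidate traits.

    Runs IVW trait->mediator, trait->outcome and the reverse
    mediator->trait leg for every trait, applies BH-FDR separately to each
    leg across traits, and assigns one status per trait: traits failing the
    mediator leg are ``not_assoc_mediator``, those failing only the outcome
    leg ``not_assoc_outcome``, those the mediator itself alters
    ``reverse_caused``, the rest ``eligible``.  Traits without enough
    instruments (in the forward legs) are set aside as
    ``insufficient_instruments`` and excluded from the FDR families.
    """
    if len(traits) == 0:
        raise ValueError("need at least one trait to screen")
    ld = ld if ld is not None else LDTable()
    med_instruments = select_instruments(mediator, ld, p_threshold, r2_threshold,
                                         window_bp, min_variants)

    legs: dict[str, _Legs] = {}
    results: dict[str, ScreenResult] = {}
    for trait in traits:
        try:
            instruments = select_instruments(trait, ld, p_threshold, r2_threshold,
                                             window_bp, min_variants)
            legs[trait.trait_label] = _Legs(
                mediator=_ivw_leg(trait, mediator, instruments, palindrome_maf_limit),
                outcome=_ivw_leg(trait, outcome, instruments, palindrome_maf_limit),
                reverse=_ivw_leg(mediator, trait, med_instruments, palindrome_maf_limit),
                n_instruments=len(instruments),
            )
        except InsufficientInstrumentsError as exc:
            results[trait.trait_label] = ScreenResult(
                trait_label=trait.trait_label,
                status=ScreenStatus.INSUFFICIENT_INSTRUMENTS,
                n_instruments=exc.n_available)

    tested = [t.trait_label for t in traits if t.trait_label in legs]
    qs = {leg: dict(zip(tested, fdr_adjust(
        [getattr(legs[lab], leg).pval for lab in tested])))
        for leg in ("mediator", "outcome", "reverse")} if tested else {}

    for lab in tested:
        lg = legs[lab]
        q_med, q_out, q_rev = (qs["mediator"][lab], qs["outcome"][lab],
                               qs["reverse"][lab])
        if q_med >= fdr_level:
            status = ScreenStatus.NOT_ASSOC_MEDIATOR
        elif q_out >= fdr_level:
            status = ScreenStatus.NOT_ASSOC_OUTCOME
        elif q_rev < fdr_level:
            status = ScreenStatus.REVERSE_CAUSED
        else:
            status = ScreenStatus.ELIGIBLE
        results[lab] = ScreenResult(
            trait_label=lab, status=status,
            assoc_mediator=(lg.mediator, float(q_med)),
            assoc_outcome=(lg.outcome, float(q_out)),
            reverse=(lg.reverse, float(q_rev)),
            n_instruments=lg.n_instruments)
    return [results[t.trait_label] for t in traits]


def venn_counts(results: list[ScreenResult], fdr_level: float = 0.05) -> dict:
    """Screening-funnel counts: associated with mediator / outcome / both / eligible."""
    med = out = both = 0
    for r in results:
        if r.assoc_mediator is None:
            continue
        sig_m = r.assoc_mediator[1] < fdr_level
        sig_o = r.assoc_outcome[1] < fdr_level
        med += sig_m
        out += sig_o
        both += sig_m and sig_o
    return {
        "n_traits": len(results),
        "assoc_mediator": int(med),
        "assoc_outcome": int(out),
        "assoc_both": int(both),
        "reverse_caused": sum(r.status is ScreenStatus.REVERSE_CAUSED for r in results),
        "eligible": sum(r.status is ScreenStatus.ELIGIBLE for r in results),
        "insufficient_instruments": sum(
            r.status is ScreenStatus.INSUFFICIENT_INSTRUMENTS for r in results),
    }


def two_step_mediation(trait: SumStats, mediator: SumStats, outcome: SumStats,
                       ld: LDTable | None = None, p_threshold: float = 5e-8,
                       r2_threshold: float = 0.001, window_bp: int = 10_000_000,
                       min_variants: int = 10,
                       palindrome_maf_limit: float = 0.30) -> MediationResult:
    """Step-two decomposition for one (presumed eligible) trait.

    total and beta1 come from univariable IVW on the trait's instruments; the
    direct effect (trait coefficient) and beta2 (mediator coefficient) come
    from one joint multivariable fit of the outcome on trait and mediator
    using the union instrument set.  indirect = beta1 * beta2 with Sobel SE;
    proportion = indirect / total, left undefined (None) when |total| is
    below machine tolerance rather than propagating a NaN.
    """
    ld = ld if ld is not None else LDTable()
    instruments = select_instruments(trait, ld, p_threshold, r2_threshold,
                                     window_bp, min_variants)
    trait_sub = trait.subset(instruments.snp_ids)
    total, _ = ivw(harmonize(trait_sub, outcome,
                             palindrome_maf_limit=palindrome_maf_limit))
    beta1, _ = ivw(harmonize(trait_sub, mediator,
                             palindrome_maf_limit=palindrome_maf_limit))

    mv = mvmr_instruments([trait, mediator], outcome, ld, p_threshold,
                          r2_threshold, window_bp, palindrome_maf_limit)
    fit = mvmr_fit(mv)
    direct = fit.estimates[0]
    beta2 = fit.estimates[1]

    indirect = beta1.beta * beta2.beta
    ind_se = sobel_se(beta1.beta, beta1.se, beta2.beta, beta2.se)
    if abs(total.beta) > _TOTAL_TOL:
        proportion = indirect / total.beta
    else:
        proportion = None
    return MediationResult(
        trait_label=trait.trait_label,
        total=total, beta1=beta1, direct=direct, beta2=beta2,
        indirect=float(indirect), indirect_se=float(ind_se),
        proportion=proportion,
        direction_consistent=bool(np.sign(indirect) == np.sign(total.beta)),
    )


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Flat per-trait decomposition table, ordered by trait label.

    The proportion column is formatted as a percentage with one decimal;
    rows whose indirect effect opposes the total carry a caveat flag.
    """
    rows = []
    for r in sorted(results, key=lambda r: r.trait_label):
        rows.append({
            "trait": r.trait_label,
            "total": r.total.beta, "total_se": r.total.se,
            "direct": r.direct.beta, "direct_se": r.direct.se,
            "beta1": r.beta1.beta, "beta1_se": r.beta1.se,
            "beta2": r.beta2.beta, "beta2_se": r.beta2.se,
            "indirect": r.indirect, "sobel_se": r.indirect_se,
            "proportion_pct": ("" if r.proportion_pct is None
                               else f"{r.proportion_pct:.1f}"),
            "direction_consistent": r.direction_consistent,
        })
    cols = ["trait", "total", "total_se", "direct", "direct_se", "beta1",
            "beta1_se", "beta2", "beta2_se", "indirect", "sobel_se",
            "proportion_pct", "direction_consistent"]
    return pd.DataFrame(rows, columns=cols)
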