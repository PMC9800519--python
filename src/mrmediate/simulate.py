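"""Synthetic three-cohort GWAS summary statistics with known causal truth.

The generating model is linear and structural: exposure X, mediator M,
outcome Y.  SNP j has a true effect gamma_j on X (exposure-causal SNPs) or
delta_j on M only (mediator-only SNPs); the structural coefficients are
alpha (X -> M), beta_m (M -> Y) and tau_prime (the direct X -> Y path), so

    true M effect  = alpha * gamma_j + delta_j
    true Y effect  = tau_prime * gamma_j + beta_m * (alpha * gamma_j + delta_j) + eta_j

with eta_j an optional direct SNP -> Y (pleiotropic) effect on a configured
fraction of exposure SNPs, signed relative to the exposure-increasing allele
so that a nonzero eta_mean is directional pleiotropy.  Observed betas add cohort-specific sampling noise
with the analytic standard error of a per-allele regression coefficient on a
unit-variance trait, se_j = 1 / sqrt(2 p_j (1 - p_j) N); the three cohorts
are non-overlapping so their noise is independent.  Everything is
deterministic given the seed, and the generating effects are returned as a
:class:`SimTruth` ledger (total = tau_prime + alpha * beta_m,
indirect = alpha * beta_m, direct = tau_prime).

Simulation happens directly at the summary level — no individual-level
genotypes — which is exact for this model and orders of magnitude faster.
All SNPs are mutually independent (an empty LD table); clumping is exercised
separately with hand-built LD fixtures.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SumStats

__all__ = [
    "SimConfig",
    "SimTruth",
    "TraitSpec",
    "PanelSim",
    "simulate_summary_stats",
    "simulate_trait_panel",
]

_BASES = np.array(list("ACGT"))
# non-palindromic ordered allele pairs (neither A/T nor G/C)
_SAFE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
               if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})]


@dataclass
class SimConfig:
    """Generating parameters for one three-cohort dataset.

    Defaults describe a strong-instrument consortium-scale study: 150
    exposure-causal SNPs, 100 mediator-only SNPs, 50 null background SNPs,
    three cohorts of 200k samples, partial mediation
    (tau_prime=0.2, alpha=0.3, beta_m=0.5 so the total effect is 0.35 and
    the mediated share 42.9%), and no pleiotropy.
    """

    n_snp_exposure: int = 150
    n_snp_mediator: int = 100
    n_null_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    delta_sd: float = 0.05
    alpha: float = 0.3
    beta_m: float = 0.5
    tau_prime: float = 0.2
    n_x: int = 200_000
    n_m: int = 200_000
    n_y: int = 200_000
    fraction_invalid: float = 0.0
    eta_mean: float = 0.0
    eta_sd: float = 0.0
    palindrome_stress: bool = False
    seed: int = 0

    def validate(self) -> None:
        errs = []
        for name in ("n_snp_exposure", "n_snp_mediator", "n_x", "n_m", "n_y"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0")
        if self.n_null_snps < 0:
            errs.append("n_null_snps must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            errs.append("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.fraction_invalid <= 1:
            errs.append("fraction_invalid must be in [0, 1]")
        for name in ("gamma_sd", "delta_sd"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if self.eta_sd < 0:
            errs.append("eta_sd must be >= 0")
        if errs:
            raise ValueError("invalid SimConfig: " + "; ".join(errs))


@dataclass
class SimTruth:
    """Ground-truth estimands of a simulated dataset."""

    total: float
    direct: float
    indirect: float
    proportion: float            # indirect / total; 0 when total is 0
    per_snp: pd.DataFrame        # snp_id, true_beta_x, true_beta_m, true_beta_y

    def to_dict(self) -> dict:
        return {"total": self.total, "direct": self.direct,
                "indirect": self.indirect, "proportion": self.proportion}


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _observe(true_beta: np.ndarray, maf: np.ndarray, n: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    se = _se(maf, n)
    beta = true_beta + rng.normal(0.0, se)
    return beta, se


def _universe(n_total: int, maf: np.ndarray, rng: np.random.Generator,
              palindrome_stress: bool) -> pd.DataFrame:
    ids = [f"rs{i + 1}" for i in range(n_total)]
    chrom = [str(1 + i % 22) for i in range(n_total)]
    pos = [1_000_000 * (1 + i // 22) for i in range(n_total)]
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), n_total)
    ea = np.array([_SAFE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_SAFE_PAIRS[i][1] for i in pair_idx])
    if palindrome_stress:
        # make ~10% of SNPs strand-ambiguous A/T to exercise harmonization
        amb = rng.random(n_total) < 0.10
        ea[amb], oa[amb] = "A", "T"
    return pd.DataFrame({"snp_id": ids, "chrom": chrom, "pos": pos,
                         "effect_allele": ea, "other_allele": oa, "eaf": maf})


def _cohort(label: str, base: pd.DataFrame, true_beta: np.ndarray, n: int,
            rng: np.random.Generator, eaf_jitter_sd: float = 0.0) -> SumStats:
    beta, se = _observe(true_beta, base["eaf"].to_numpy(), n, rng)
    t = base.copy()
    if eaf_jitter_sd > 0:
        t["eaf"] = np.clip(t["eaf"] + rng.normal(0, eaf_jitter_sd, len(t)),
                           0.01, 0.99)
    t["beta"] = beta
    t["se"] = se
    t["pval"] = _pvals(beta, se)
    t["n"] = n
    return SumStats(label, t)


def simulate_summary_stats(config: SimConfig,
                           ) -> tuple[SumStats, SumStats, SumStats, SimTruth]:
    """Generate (exposure, mediator, outcome) summary statistics plus truth.

    All three cohorts report every SNP in the universe (exposure-causal,
    mediator-only, and null background SNPs), so instrument lookups never
    miss.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_exp, n_med, n_null = (config.n_snp_exposure, config.n_snp_mediator,
                            config.n_null_snps)
    n_total = n_exp + n_med + n_null
    maf = rng.uniform(*config.maf_range, n_total)
    base = _universe(n_total, maf, rng, config.palindrome_stress)

    gamma = np.zeros(n_total)
    gamma[:n_exp] = rng.normal(0.0, config.gamma_sd, n_exp)
    delta = np.zeros(n_total)
    delta[n_exp:n_exp + n_med] = rng.normal(0.0, config.delta_sd, n_med)
    # pleiotropic effects attach to the exposure-increasing allele (their sign
    # follows gamma's), so a nonzero eta_mean is *directional* pleiotropy that
    # survives the exposure-positive orientation used by Egger regression
    eta = np.zeros(n_total)
    if config.fraction_invalid > 0:
        invalid = rng.random(n_exp) < config.fraction_invalid
        draw = rng.normal(config.eta_mean, config.eta_sd, int(invalid.sum()))
        eta[:n_exp][invalid] = np.sign(gamma[:n_exp][invalid]) * draw

    true_x = gamma
    true_m = config.alpha * gamma + delta
    true_y = config.tau_prime * gamma + config.beta_m * true_m + eta

    jit = 0.02 if config.palindrome_stress else 0.0
    exposure = _cohort("exposure", base, true_x, config.n_x, rng)
    mediator = _cohort("mediator", base, true_m, config.n_m, rng, jit)
    outcome = _cohort("outcome", base, true_y, config.n_y, rng, jit)

    indirect = config.alpha * config.beta_m
    total = config.tau_prime + indirect
    truth = SimTruth(
        total=total, direct=config.tau_prime, indirect=indirect,
        proportion=(indirect / total) if total != 0 else 0.0,
        per_snp=pd.DataFrame({"snp_id": base["snp_id"], "true_beta_x": true_x,
                              "true_beta_m": true_m, "true_beta_y": true_y}),
    )
    return exposure, mediator, outcome, truth


@dataclass
class TraitSpec:
    """Designed per-leg effects of one screening-panel trait.

    ``effect_on_mediator`` and ``effect_on_outcome`` are the trait's marginal
    per-instrument effect ratios on mediator and outcome (the quantities the
    forward IVW legs estimate); ``reverse_effect`` is the mediator's effect
    on the trait, realized at the mediator's own instruments.  ``n_snp``
    overrides the trait's instrument count (used to design
    insufficient-instrument traits).
    """

    effect_on_mediator: float = 0.0
    effect_on_outcome: float = 0.0
    reverse_effect: float = 0.0
    n_snp: int | None = None
    label: str | None = None

    def expected_status(self) -> str:
        if self.n_snp is not None and self.n_snp < 10:
            return "insufficient_instruments"
        if self.effect_on_mediator == 0:
            return "not_assoc_mediator"
        if self.effect_on_outcome == 0:
            return "not_assoc_outcome"
        if self.reverse_effect != 0:
            return "reverse_caused"
        return "eligible"


@dataclass
class PanelSim:
    """A simulated screening panel: trait cohorts + shared mediator/outcome."""

    traits: list[SumStats]
    mediator: SumStats
    outcome: SumStats
    expected_status: list[str]
    truth: pd.DataFrame = field(repr=False, default=None)


def simulate_trait_panel(config: SimConfig,
                         trait_specs: list[TraitSpec]) -> PanelSim:
    """Generate a multi-trait screening panel under the structural model.

    Every cohort (each trait, the mediator, the outcome) reports the full SNP
    universe: each trait's own causal SNPs (gamma ~ N(0, gamma_sd²)), the
    mediator's own instruments (delta ~ N(0, delta_sd²)), and shared null
    SNPs.  Trait t's instruments carry true mediator effect
    ``effect_on_mediator * gamma`` and true outcome effect
    ``effect_on_outcome * gamma``; the mediator's instruments carry true
    trait-t effect ``reverse_effect * delta`` (the reverse-causation leg).
    """
    if len(trait_specs) == 0:
        raise ValueError("need at least one trait spec")
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = [spec.n_snp if spec.n_snp is not None else config.n_snp_exposure
              for spec in trait_specs]
    n_med, n_null = config.n_snp_mediator, config.n_null_snps
    n_total = sum(counts) + n_med + n_null
    maf = rng.uniform(*config.maf_range, n_total)
    base = _universe(n_total, maf, rng, config.palindrome_stress)

    # block layout: [trait_0 | trait_1 | ... | mediator | null]
    starts = np.cumsum([0] + counts)
    med_lo, med_hi = starts[-1], starts[-1] + n_med
    delta = rng.normal(0.0, config.delta_sd, n_med)

    true_m = np.zeros(n_total)
    true_m[med_lo:med_hi] = delta
    true_y = np.zeros(n_total)
    true_y[med_lo:med_hi] = config.beta_m * delta

    gammas = []
    for i, spec in enumerate(trait_specs):
        g = rng.normal(0.0, config.gamma_sd, counts[i])
        gammas.append(g)
        lo, hi = starts[i], starts[i + 1]
        true_m[lo:hi] = spec.effect_on_mediator * g
        true_y[lo:hi] = spec.effect_on_outcome * g

    mediator = _cohort("mediator", base, true_m, config.n_m, rng)
    outcome = _cohort("outcome", base, true_y, config.n_y, rng)

    traits, expected, truth_rows = [], [], []
    for i, spec in enumerate(trait_specs):
        label = spec.label or f"trait_{i}"
        true_t = np.zeros(n_total)
        true_t[starts[i]:starts[i + 1]] = gammas[i]
        true_t[med_lo:med_hi] = spec.reverse_effect * delta
        traits.append(_cohort(label, base, true_t, config.n_x, rng))
        expected.append(spec.expected_status())
        truth_rows.append({"trait": label, **asdict(spec),
                           "expected_status": expected[-1]})
    return PanelSim(traits=traits, mediator=mediator, outcome=outcome,
                    expected_status=expected, truth=pd.DataFrame(truth_rows))
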