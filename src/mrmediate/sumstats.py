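"""GWAS summary statistics: containers, I/O, harmonization, clumping, instruments.

A :class:`SumStats` holds one trait's per-SNP association records (identifier,
position, alleles, effect-allele frequency, beta, standard error, p-value,
sample size).  All downstream Mendelian randomization stages consume
:class:`HarmonizedPairs`, which aligns two or three studies' effects to a
common (exposure) effect allele and records every SNP that had to be dropped
and why.  Linkage disequilibrium is consumed as a precomputed pairwise r²
table; an absent pair is treated as r² = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SumStats",
    "LDTable",
    "InstrumentSet",
    "HarmonizedPairs",
    "InsufficientInstrumentsError",
    "ParseReport",
    "read_sumstats",
    "write_sumstats",
    "write_pairs",
    "harmonize",
    "harmonize_studies",
    "clump",
    "select_instruments",
    "per_snp_f",
    "swap_effect_allele",
    "is_palindromic",
    "is_biallelic_snp",
]

#: internal field name -> canonical file header
CANONICAL_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_BASES = frozenset("ACGT")


class InsufficientInstrumentsError(Exception):
    """Fewer instruments survived selection than the study design requires.

    This is the exclusion rule that removes a trait from the study, not a
    crash; callers screening many traits catch it and record the status.
    """

    def __init__(self, n_available: int, min_variants: int):
        self.n_available = int(n_available)
        self.min_variants = int(min_variants)
        super().__init__(
            f"only {n_available} instruments available; "
            f"at least {min_variants} required"
        )


@dataclass
class ParseReport:
    n_rows: int = 0
    n_valid: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return self.n_rows - self.n_valid


@dataclass
class SumStats:
    """Per-SNP association records for one trait/cohort.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele, eaf,
    beta, se, pval, n.  snp_id is unique; se > 0; pval in (0, 1]; eaf in
    [0, 1] or NaN.
    """

    trait_label: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    parse_report: ParseReport | None = None

    def __post_init__(self):
        cols = list(CANONICAL_COLUMNS)
        missing = [c for c in cols if c not in self.table.columns]
        if missing:
            raise ValueError(f"SumStats table missing columns: {missing}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp_id values: {sorted(set(dups))[:5]}")
        self.table = self.table[cols].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def subset(self, snp_ids) -> "SumStats":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        return SumStats(self.trait_label, keep.copy(), dict(self.meta))

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("snp_id")


class LDTable:
    """Symmetric pairwise r² lookup; absent pairs are r² = 0."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise ValueError("self-pairs are implicit (r2 = 1) and never stored")
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path, delimiter: str = "\t") -> "LDTable":
        df = pd.read_csv(path, sep=delimiter)
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ValueError(f"LD table missing column {col!r}")
        table = cls()
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
            table.set(str(a), str(b), float(r2))
        return table


@dataclass
class InstrumentSet:
    """Index SNPs selected as instruments plus the parameters that chose them."""

    snp_ids: list[str]
    selection_params: dict
    per_snp_f: dict[str, float]

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class HarmonizedPairs:
    """Allele-aligned per-SNP effects across two or three studies.

    ``table`` always has snp_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome; beta_mediator/se_mediator are present when a third study was
    harmonized.  ``dropped`` lists (snp_id, reason) for every intersection SNP
    that could not be aligned.
    """

    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def has_mediator(self) -> bool:
        return "beta_mediator" in self.table.columns

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.table["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.table["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(float)

    @property
    def beta_mediator(self) -> np.ndarray:
        return self.table["beta_mediator"].to_numpy(float)

    @property
    def se_mediator(self) -> np.ndarray:
        return self.table["se_mediator"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    beta_mediator=None, se_mediator=None, snp_ids=None):
        """Build pairs directly from effect arrays (synthetic/test use)."""
        beta_exposure = np.asarray(beta_exposure, float)
        n = beta_exposure.size
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(n)]
        data = {
            "snp_id": list(snp_ids),
            "beta_exposure": beta_exposure,
            "se_exposure": np.asarray(se_exposure, float),
            "beta_outcome": np.asarray(beta_outcome, float),
            "se_outcome": np.asarray(se_outcome, float),
        }
        if beta_mediator is not None:
            data["beta_mediator"] = np.asarray(beta_mediator, float)
            data["se_mediator"] = np.asarray(se_mediator, float)
        return cls(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict[str, str] | None = None,
                  delimiter: str = "\t", trait_label: str | None = None) -> SumStats:
    """Read a delimited summary-statistics table into a :class:`SumStats`.

    ``column_map`` maps internal field names (``snp_id`` ... ``n``) to the
    file's header names; unmapped fields use the canonical headers (SNP, CHR,
    POS, EA, OA, EAF, BETA, SE, P, N).  Rows with missing or invalid beta,
    se, alleles, or p-value are dropped and counted in the parse report.

    Raises ``FileNotFoundError``, ``ValueError`` on a missing mapped column or
    when zero valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(CANONICAL_COLUMNS)
    colmap.update(column_map or {})
    raw = pd.read_csv(path, sep=delimiter, dtype={colmap["chrom"]: str})
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"mapped columns absent from header: {missing}")
    df = raw[[colmap[k] for k in CANONICAL_COLUMNS]].copy()
    df.columns = list(CANONICAL_COLUMNS)

    report = ParseReport(n_rows=len(df))
    for col in ("beta", "se", "pval", "eaf", "pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    def _drop(mask: pd.Series, reason: str):
        nonlocal df
        n = int(mask.sum())
        if n:
            report.drop_reasons[reason] += n
            df = df[~mask]

    _drop(df["beta"].isna() | ~np.isfinite(df["beta"]), "invalid-beta")
    _drop(df["se"].isna() | ~(df["se"] > 0), "invalid-se")
    _drop(df["pval"].isna() | ~((df["pval"] > 0) & (df["pval"] <= 1)), "invalid-pval")
    allele_bad = (
        df["effect_allele"].isin(("", "NAN", "NA"))
        | df["other_allele"].isin(("", "NAN", "NA"))
        | (df["effect_allele"] == df["other_allele"])
    )
    _drop(allele_bad, "invalid-alleles")
    _drop(df["eaf"].notna() & ~df["eaf"].between(0, 1), "invalid-eaf")
    _drop(df["snp_id"].isna(), "missing-snp-id")
    _drop(df["snp_id"].duplicated(), "duplicate-snp-id")

    report.n_valid = len(df)
    if report.n_valid == 0:
        raise ValueError(f"zero valid rows in {path} ({report.n_rows} read)")
    df["snp_id"] = df["snp_id"].astype(str)
    df["pos"] = df["pos"].astype("int64")
    stats = SumStats(trait_label or path.stem, df.reset_index(drop=True),
                     meta={"source": str(path)})
    stats.parse_report = report
    return stats


def write_sumstats(stats: SumStats, path, delimiter: str = "\t") -> None:
    """Write canonical-column TSV; round-trips through :func:`read_sumstats`."""
    out = stats.table.rename(columns=CANONICAL_COLUMNS)
    out.to_csv(path, sep=delimiter, index=False)


def write_pairs(pairs: HarmonizedPairs, path, dropped_path=None,
                delimiter: str = "\t") -> None:
    """Write harmonized pairs; optionally the dropped-SNP report alongside."""
    pairs.table.to_csv(path, sep=delimiter, index=False)
    if dropped_path is not None:
        pd.DataFrame(pairs.dropped, columns=["snp_id", "reason"]).to_csv(
            dropped_path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# allele arithmetic
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str | None:
    if all(b in _VALID_BASES for b in allele):
        return "".join(_COMPLEMENT[b] for b in allele)
    return None


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or G/C single-nucleotide pair: strand unresolvable from alleles."""
    return len(ea) == 1 and len(oa) == 1 and _complement(ea) == oa


def is_biallelic_snp(ea: str, oa: str) -> bool:
    return (len(ea) == 1 and len(oa) == 1 and ea != oa
            and ea in _VALID_BASES and oa in _VALID_BASES)


def swap_effect_allele(beta: float, eaf: float | None):
    """Re-express an effect on the other allele: negate beta, complement eaf.

    An involution: applying it twice returns the original (beta, eaf).
    """
    return -beta, (None if eaf is None or np.isnan(eaf) else 1.0 - eaf)


def _match_alleles(ref_ea: str, ref_oa: str, ea: str, oa: str) -> str:
    """Classify a study's allele pair against the reference orientation."""
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = _complement(ea), _complement(oa)
    if cea is not None and coa is not None:
        if (cea, coa) == (ref_ea, ref_oa):
            return "same"
        if (cea, coa) == (ref_oa, ref_ea):
            return "swap"
    return "mismatch"


def harmonize_studies(studies: list[SumStats],
                      palindrome_maf_limit: float = 0.30) -> tuple[pd.DataFrame, list]:
    """Align every study's effects to the first study's effect allele.

    Returns a wide table (snp_id + beta_i/se_i/eaf_i per study, in order) over
    the SNP intersection, and the list of (snp_id, reason) drops.  Palindromic
    SNPs are aligned by effect-allele frequency when min(eaf, 1-eaf) <=
    ``palindrome_maf_limit`` in *all* studies (missing eaf drops them);
    otherwise dropped with reason ``palindromic-ambiguous``.  Non-matching
    allele pairs drop with ``allele-mismatch``.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to harmonize")
    # (ea, oa, beta, se, eaf) per snp, per study; dict lookups dominate runtime
    lookups = []
    for s in studies:
        t = s.table
        lookups.append({snp: rec for snp, rec in zip(
            t["snp_id"],
            zip(t["effect_allele"], t["other_allele"],
                t["beta"].to_numpy(float), t["se"].to_numpy(float),
                t["eaf"].to_numpy(float)))})
    shared = [snp for snp in studies[0].table["snp_id"]
              if all(snp in lk for lk in lookups[1:])]
    if len(shared) == 0:
        raise ValueError("empty SNP intersection across studies")

    dropped: list[tuple[str, str]] = []
    rows = []
    for snp in shared:
        ea0, oa0, b0, s0, f0 = lookups[0][snp]
        out = {"snp_id": snp, "beta_0": b0, "se_0": s0, "eaf_0": f0}
        if is_palindromic(ea0, oa0):
            eafs = [lk[snp][4] for lk in lookups]
            if any(np.isnan(f) for f in eafs) or \
                    any(min(f, 1 - f) > palindrome_maf_limit for f in eafs):
                dropped.append((snp, "palindromic-ambiguous"))
                continue
            ok = True
            for k in range(1, len(lookups)):
                ea, oa, beta, se, eaf = lookups[k][snp]
                if not is_palindromic(ea, oa) or {ea, oa} != {ea0, oa0}:
                    dropped.append((snp, "allele-mismatch"))
                    ok = False
                    break
                # frequency sides agree -> already aligned; disagree -> flip
                if (eaf < 0.5) != (f0 < 0.5):
                    beta, eaf = swap_effect_allele(beta, eaf)
                out[f"beta_{k}"], out[f"se_{k}"], out[f"eaf_{k}"] = beta, se, eaf
            if ok:
                rows.append(out)
            continue
        ok = True
        for k in range(1, len(lookups)):
            ea, oa, beta, se, eaf = lookups[k][snp]
            action = _match_alleles(ea0, oa0, ea, oa)
            if action == "mismatch":
                dropped.append((snp, "allele-mismatch"))
                ok = False
                break
            if action == "swap":
                beta, eaf = swap_effect_allele(beta, eaf)
            out[f"beta_{k}"], out[f"se_{k}"], out[f"eaf_{k}"] = beta, se, eaf
        if ok:
            rows.append(out)

    cols = ["snp_id"]
    for k in range(len(studies)):
        cols += [f"beta_{k}", f"se_{k}", f"eaf_{k}"]
    wide = pd.DataFrame(rows, columns=cols)
    return wide, dropped


def harmonize(exposure: SumStats, outcome: SumStats, mediator: SumStats | None = None,
              palindrome_maf_limit: float = 0.30) -> HarmonizedPairs:
    """Harmonize an outcome (and optionally a mediator) study to the exposure.

    All effects in the result are expressed per copy of the exposure's effect
    allele.  ``|retained| + |dropped|`` equals the SNP intersection size.
    """
    studies = [exposure, outcome] + ([mediator] if mediator is not None else [])
    wide, dropped = harmonize_studies(studies, palindrome_maf_limit)
    ren = {"beta_0": "beta_exposure", "se_0": "se_exposure", "eaf_0": "eaf_exposure",
           "beta_1": "beta_outcome", "se_1": "se_outcome"}
    keep = ["snp_id", "beta_exposure", "se_exposure", "beta_outcome",
            "se_outcome", "eaf_exposure"]
    if mediator is not None:
        ren.update({"beta_2": "beta_mediator", "se_2": "se_mediator"})
        keep = keep[:5] + ["beta_mediator", "se_mediator", "eaf_exposure"]
    table = wide.rename(columns=ren)[keep]
    return HarmonizedPairs(table, dropped)


# ---------------------------------------------------------------------------
# clumping & instrument selection
# ---------------------------------------------------------------------------

def clump(stats: SumStats, ld: LDTable, r2_threshold: float = 0.001,
          window_bp: int = 10_000_000) -> list[str]:
    """Greedy p-value clumping: keep index SNPs, prune their LD neighbours.

    Repeatedly takes the unremoved SNP with the smallest p-value (ties broken
    by chrom, pos, snp_id) and removes every SNP on the same chromosome within
    ``window_bp`` basepairs (|delta pos| <= window_bp of the index SNP) whose
    r² with it is >= ``r2_threshold``.  Returns the index SNPs in p-value
    order; deterministic and invariant to input row order.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = stats.table
    if len(df) == 0:
        return []
    order = sorted(range(len(df)),
                   key=lambda i: (df["pval"].iat[i], df["chrom"].iat[i],
                                  df["pos"].iat[i], df["snp_id"].iat[i]))
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    ids = df["snp_id"].to_numpy()
    removed = np.zeros(len(df), bool)
    kept: list[str] = []
    for i in order:
        if removed[i]:
            continue
        kept.append(ids[i])
        removed[i] = True
        near = np.flatnonzero((chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= window_bp) & ~removed)
        for j in near:
            if ld.r2(ids[i], ids[j]) >= r2_threshold:
                removed[j] = True
    return kept


def select_instruments(stats: SumStats, ld: LDTable,
                       p_threshold: float = 5e-8, r2_threshold: float = 0.001,
                       window_bp: int = 10_000_000,
                       min_variants: int = 10) -> InstrumentSet:
    """Genome-wide-significant, independent, biallelic instruments.

    Filters to p < ``p_threshold`` and single-nucleotide biallelic alleles,
    then clumps.  Raises :class:`InsufficientInstrumentsError` (carrying the
    surviving count) when fewer than ``min_variants`` index SNPs survive.
    """
    df = stats.table
    biallelic = np.array([is_biallelic_snp(ea, oa) for ea, oa
                          in zip(df["effect_allele"], df["other_allele"])])
    mask = biallelic & (df["pval"].to_numpy() < p_threshold)
    filtered = SumStats(stats.trait_label, df[mask].copy(), dict(stats.meta))
    kept = clump(filtered, ld, r2_threshold, window_bp)
    if len(kept) < min_variants:
        raise InsufficientInstrumentsError(len(kept), min_variants)
    idx = filtered.indexed()
    fstat = {s: per_snp_f(idx.loc[s, "beta"], idx.loc[s, "se"]) for s in kept}
    return InstrumentSet(
        snp_ids=kept,
        selection_params={"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                          "window_bp": window_bp, "min_variants": min_variants},
        per_snp_f=fstat,
    )


def per_snp_f(beta: float, se: float) -> float:
    """Single-instrument strength F = (beta / se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float((beta / se) ** 2)
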