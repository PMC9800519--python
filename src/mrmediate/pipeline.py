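"""Full-study orchestration: config validation, run directory, manifest.

``run_full_study`` executes the complete two-step design — screen every
candidate trait against the mediator and outcome, then decompose the effect
of each eligible trait — writing a screen table, a mediation table, per-pair
univariable MR reports, and a JSON manifest recording parameters, seed and
input content hashes so a rerun with the same config is bit-identical.
A failure in one trait is logged and isolated; the run only fails when no
trait completes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .mediation import (
    ScreenStatus,
    mediation_table,
    screen_traits,
    two_step_mediation,
    venn_counts,
)
from .sumstats import LDTable, read_sumstats
from .uvmr import uvmr_report

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_full_study"]

log = logging.getLogger("mrmediate")


@dataclasses.dataclass
class RunConfig:
    trait_paths: list[str]
    mediator_path: str
    outcome_path: str
    out_dir: str
    ld_path: str | None = None
    column_map: dict = dataclasses.field(default_factory=dict)
    delimiter: str = "\t"
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_bp: int = 10_000_000
    min_variants: int = 10
    fdr_level: float = 0.05
    palindrome_maf_limit: float = 0.30
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0


class ConfigError(Exception):
    """All configuration violations, reported at once."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


def validate_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Every violation (missing file, out-of-range parameter, unknown key) is
    collected and reported together in a single :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    errors = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    for req in ("trait_paths", "mediator_path", "outcome_path", "out_dir"):
        if req not in raw:
            errors.append(f"missing required key: {req}")
    if errors:
        raise ConfigError(errors)

    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    for p in [*cfg.trait_paths, cfg.mediator_path, cfg.outcome_path,
              *( [cfg.ld_path] if cfg.ld_path else [] )]:
        if not Path(p).exists():
            errors.append(f"input path does not exist: {p}")
    if not 0 < cfg.p_threshold <= 1:
        errors.append("p_threshold must be in (0, 1]")
    if not 0 < cfg.r2_threshold <= 1:
        errors.append("r2_threshold must be in (0, 1]")
    if cfg.window_bp <= 0:
        errors.append("window_bp must be positive")
    if cfg.min_variants < 1:
        errors.append("min_variants must be >= 1")
    if not 0 < cfg.fdr_level < 1:
        errors.append("fdr_level must be in (0, 1)")
    if not 0 <= cfg.palindrome_maf_limit <= 0.5:
        errors.append("palindrome_maf_limit must be in [0, 0.5]")
    if cfg.n_boot < 2:
        errors.append("n_boot must be >= 2")
    if cfg.n_sim < 1:
        errors.append("n_sim must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_study(config: RunConfig) -> Path:
    """Execute the two-step study end to end; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ld = LDTable.from_file(config.ld_path) if config.ld_path else LDTable()
    colmap = config.column_map or None

    mediator = read_sumstats(config.mediator_path, colmap, config.delimiter)
    outcome = read_sumstats(config.outcome_path, colmap, config.delimiter)
    traits = []
    for p in config.trait_paths:
        try:
            traits.append(read_sumstats(p, colmap, config.delimiter))
        except (ValueError, FileNotFoundError) as exc:
            log.error("trait %s unreadable, skipped: %s", p, exc)
    if not traits:
        raise RuntimeError("no readable trait datasets; nothing to screen")

    sel = dict(p_threshold=config.p_threshold, r2_threshold=config.r2_threshold,
               window_bp=config.window_bp, min_variants=config.min_variants,
               palindrome_maf_limit=config.palindrome_maf_limit)
    log.info("screening %d traits (seed=%d)", len(traits), config.seed)
    screened = screen_traits(traits, mediator, outcome, ld,
                             fdr_level=config.fdr_level, **sel)
    screen_df = pd.DataFrame([r.to_row() for r in screened])
    screen_df.to_csv(out / "screen.tsv", sep="\t", index=False)
    counts = venn_counts(screened, config.fdr_level)
    log.info("screen counts: %s", counts)

    mediation_results, completed, reports = [], 0, {}
    by_label = {t.trait_label: t for t in traits}
    for res in screened:
        if res.status is not ScreenStatus.ELIGIBLE:
            log.info("trait %s: status=%s, skipped", res.trait_label,
                     res.status.value)
            continue
        trait = by_label[res.trait_label]
        try:
            med = two_step_mediation(trait, mediator, outcome, ld, **sel)
            mediation_results.append(med)
            reports[res.trait_label] = uvmr_report(
                trait, outcome, ld, **sel, n_boot=config.n_boot,
                n_sim=config.n_sim, seed=config.seed)
            completed += 1
            log.info("trait %s: total=%.4f indirect=%.4f", res.trait_label,
                     med.total.beta, med.indirect)
        except Exception as exc:  # per-trait isolation
            log.error("trait %s failed: %s", res.trait_label, exc)
    n_eligible = sum(r.status is ScreenStatus.ELIGIBLE for r in screened)
    if n_eligible and completed == 0:
        raise RuntimeError("all eligible traits failed")

    mediation_table(mediation_results).to_csv(out / "mediation.tsv",
                                              sep="\t", index=False)
    with open(out / "uvmr_reports.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    manifest = {
        "params": dataclasses.asdict(config),
        "seed": config.seed,
        "screen_counts": counts,
        "inputs": {str(p): _sha256(p) for p in
                   [*config.trait_paths, config.mediator_path,
                    config.outcome_path,
                    *([config.ld_path] if config.ld_path else [])]},
        "outputs": ["screen.tsv", "mediation.tsv", "uvmr_reports.json"],
        "n_traits_completed": completed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
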