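"""Forward and reverse two-sample MR pipelines with deterministic reporting.

``run_forward`` executes, per outcome: significance filtering, LD clumping,
harmonization, instrument-strength screening (reported, not auto-dropped),
then the estimator battery (IVW, weighted median, MR-Egger, MR-PRESSO),
leave-one-out and funnel-plot data.  ``run_reverse`` swaps the roles of the
two traits and runs the same battery, flagging whether the reverse estimate is
compatible with no reverse causation.  ``render_report`` serializes a report
to TSVs plus a Markdown summary; identical ``(config, seed)`` produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, EmptyAnalysisError
from .estimators import (egger, estimates_table, funnel_data, ivw,
                         leave_one_out, weighted_median)
from .instruments import (clump, harmonize, instrument_strength,
                          select_significant)
from .presso import presso_global
from .sumstats import SummaryStatsTable, read_ld, read_sumstats

log = logging.getLogger("summr")

_DISPLAY_NAMES = {
    "ivw": "IVW",
    "weighted_median": "Weighted median",
    "presso_corrected": "MR-PRESSO (outlier-corrected)",
    "egger": "MR-Egger",
}


@dataclass
class OutcomeSpec:
    """One outcome dataset: where it lives and how its effects are scaled."""

    name: str
    path: str | None = None
    trait_type: str = "binary"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.case_fraction is not None) != (self.trait_type == "binary"):
            raise ConfigError(f"outcome {self.name!r}: case_fraction must be given "
                              f"exactly when trait_type is binary")


@dataclass
class AnalysisConfig:
    """All settings of one analysis run; ``seed`` drives every stochastic step."""

    seed: int
    exposure_path: str | None = None
    exposure_name: str = "exposure"
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    ld_path: str | None = None
    # instrument thresholds
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    palindrome_eaf_window: float = 0.08
    f_min: float = 10.0
    drop_weak: bool = False
    # estimator settings
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    second_order: bool = False
    direction: str = "forward"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigError(f"direction must be forward|reverse|both, got {self.direction!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        outcomes = [OutcomeSpec(**o) if isinstance(o, dict) else o
                    for o in d.pop("outcomes", [])]
        return cls(outcomes=outcomes, **d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a flat key-value (YAML) config file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable digest of all settings (provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-component seed below 2^31, keyed by a text label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class OutcomeSection:
    """All results for one exposure/outcome pair in one direction.

    ``label`` is the outcome dataset's configured name (stable lookup key in
    both directions); ``exposure_name``/``outcome_name`` describe the pair as
    analyzed, so in the reverse direction they appear role-swapped.
    """

    direction: str
    label: str
    exposure_name: str
    outcome_name: str
    outcome_binary: bool
    nsnp: int
    estimates: pd.DataFrame
    heterogeneity: dict
    egger_intercept: dict
    presso: dict | None
    strength: dict
    loo: pd.DataFrame
    funnel: pd.DataFrame
    exclusions: pd.DataFrame
    stage_counts: dict
    reverse_null: bool | None = None  # reverse direction: IVW CI covers zero?


@dataclass
class MRReport:
    """Report of a full run: per-outcome sections plus provenance."""

    sections: list[OutcomeSection]
    provenance: dict

    def section(self, label: str, direction: str = "forward") -> OutcomeSection:
        for s in self.sections:
            if s.label == label and s.direction == direction:
                return s
        raise KeyError(f"no section for {label!r} ({direction})")


def _load_exposure(config: AnalysisConfig) -> SummaryStatsTable:
    if config.exposure_path is None:
        raise ConfigError("exposure_path is required when no table is passed")
    return read_sumstats(config.exposure_path, trait_name=config.exposure_name,
                         trait_type="continuous")


def _load_outcomes(config: AnalysisConfig) -> dict[str, SummaryStatsTable]:
    if not config.outcomes:
        raise ConfigError("at least one outcome is required")
    tables = {}
    for spec in config.outcomes:
        if spec.path is None:
            raise ConfigError(f"outcome {spec.name!r} has no path")
        tables[spec.name] = read_sumstats(spec.path, trait_name=spec.name,
                                          trait_type=spec.trait_type,
                                          case_fraction=spec.case_fraction)
    return tables


def _select_instruments(exposure, ld, config, stage_counts):
    selected = select_significant(exposure, config.p_threshold)
    stage_counts["significant"] = selected.n_variants
    log.info("significance filter: %d -> %d variants",
             exposure.n_variants, selected.n_variants)
    if selected.n_variants == 0:
        raise EmptyAnalysisError("significance_filter")
    clumped = clump(selected, ld, config.r2_threshold, config.window_kb)
    stage_counts["clumped"] = clumped.n_variants
    log.info("clumping: %d -> %d variants", selected.n_variants, clumped.n_variants)
    if clumped.n_variants == 0:
        raise EmptyAnalysisError("clumping")
    return clumped


def _analyze_pair(instruments_table, outcome_table, config: AnalysisConfig,
                  direction: str, label: str, stage_counts: dict) -> OutcomeSection:
    hset = harmonize(instruments_table, outcome_table, config.palindrome_eaf_window)
    stage_counts = dict(stage_counts,
                        harmonized=hset.nsnp, excluded=len(hset.excluded))
    log.info("harmonization (%s ~ %s): %d kept, %d excluded",
             hset.exposure_name, hset.outcome_name, hset.nsnp, len(hset.excluded))
    if hset.nsnp == 0:
        raise EmptyAnalysisError("harmonization")

    strength_df, total_r2 = instrument_strength(
        instruments_table.subset(hset.snp_ids))
    weak_ids = strength_df.loc[strength_df["weak"], "snp_id"].tolist()
    if config.drop_weak and weak_ids:
        hset = hset.drop(weak_ids)
        log.info("dropped %d weak instruments (F < %g)", len(weak_ids), config.f_min)
        if hset.nsnp == 0:
            raise EmptyAnalysisError("weak_instrument_screen")
    stage_counts["analyzed"] = hset.nsnp

    pair = f"{direction}:{hset.exposure_name}:{hset.outcome_name}"
    ests = []
    ivw_est, het = ivw(hset, model=config.ivw_model, second_order=config.second_order)
    ests.append(ivw_est)
    if hset.nsnp >= 3:
        ests.append(weighted_median(hset, n_boot=config.n_boot,
                                    seed=derive_seed(config.seed, pair + ":wm"),
                                    second_order=config.second_order))
    presso_res = None
    if hset.nsnp >= 4:
        presso_res = presso_global(hset, n_sim=config.presso_n_sim,
                                   seed=derive_seed(config.seed, pair + ":presso"),
                                   outlier_alpha=config.outlier_alpha,
                                   ivw_model=config.ivw_model)
        if presso_res.corrected is not None:
            ests.append(presso_res.corrected)
    egger_row = {"intercept": np.nan, "se": np.nan, "pvalue": np.nan,
                 "significant": False}
    if hset.nsnp >= 3:
        egger_est, intercept = egger(hset)
        ests.append(egger_est)
        egger_row = {"intercept": intercept.intercept, "se": intercept.se,
                     "pvalue": intercept.pvalue, "significant": intercept.significant}

    het_row = ({"q": het.q, "df": het.df, "pvalue": het.pvalue} if het is not None
               else {"q": np.nan, "df": 0, "pvalue": np.nan})
    loo = (leave_one_out(hset, model=config.ivw_model) if hset.nsnp >= 2
           else pd.DataFrame())
    ci_excludes_zero = ivw_est.ci_low > 0 or ivw_est.ci_high < 0

    return OutcomeSection(
        direction=direction,
        label=label,
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        outcome_binary=hset.outcome_binary,
        nsnp=hset.nsnp,
        estimates=estimates_table(ests),
        heterogeneity=het_row,
        egger_intercept=egger_row,
        presso=presso_res.as_row() if presso_res is not None else None,
        strength={"total_r2": total_r2, "n_weak": len(weak_ids),
                  "min_f": float(strength_df["f"].min()) if len(strength_df) else np.nan,
                  "weak_dropped": bool(config.drop_weak and weak_ids)},
        loo=loo,
        funnel=funnel_data(hset),
        exclusions=hset.exclusion_report(),
        stage_counts=stage_counts,
        reverse_null=(not ci_excludes_zero) if direction == "reverse" else None,
    )


def _provenance(config: AnalysisConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed,
            "summr_version": __version__, "settings": config.to_dict()}


def run_forward(config: AnalysisConfig, exposure: SummaryStatsTable | None = None,
                outcomes: dict[str, SummaryStatsTable] | None = None,
                ld=None) -> MRReport:
    """Full forward analysis: one instrument selection, one section per outcome."""
    exposure = exposure if exposure is not None else _load_exposure(config)
    outcomes = outcomes if outcomes is not None else _load_outcomes(config)
    if ld is None and config.ld_path:
        ld = read_ld(config.ld_path)
    stage_counts = {"input": exposure.n_variants}
    instruments_table = _select_instruments(exposure, ld, config, stage_counts)
    sections = [
        _analyze_pair(instruments_table, out_table, config, "forward", name,
                      stage_counts)
        for name, out_table in outcomes.items()
    ]
    return MRReport(sections=sections, provenance=_provenance(config))


def run_reverse(config: AnalysisConfig, exposure: SummaryStatsTable | None = None,
                outcomes: dict[str, SummaryStatsTable] | None = None,
                ld=None) -> MRReport:
    """Reverse-direction analysis: instruments selected from each outcome GWAS,
    effects estimated on the former exposure."""
    exposure = exposure if exposure is not None else _load_exposure(config)
    outcomes = outcomes if outcomes is not None else _load_outcomes(config)
    if ld is None and config.ld_path:
        ld = read_ld(config.ld_path)
    sections = []
    for name, out_table in outcomes.items():
        stage_counts = {"input": out_table.n_variants}
        instruments_table = _select_instruments(out_table, ld, config, stage_counts)
        sections.append(_analyze_pair(instruments_table, exposure, config,
                                      "reverse", name, stage_counts))
    return MRReport(sections=sections, provenance=_provenance(config))


def run(config: AnalysisConfig, exposure=None, outcomes=None, ld=None) -> MRReport:
    """Dispatch on ``config.direction`` (forward, reverse or both)."""
    sections: list[OutcomeSection] = []
    if config.direction in ("forward", "both"):
        sections += run_forward(config, exposure, outcomes, ld).sections
    if config.direction in ("reverse", "both"):
        sections += run_reverse(config, exposure, outcomes, ld).sections
    return MRReport(sections=sections, provenance=_provenance(config))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt_ci(lo: float, hi: float) -> str:
    return f"{lo:.2f}–{hi:.2f}"


def format_estimate_human(row: dict, binary: bool) -> str:
    """Human table cell: ``0.72 (0.62–0.83)`` (OR scale when binary)."""
    if binary:
        return f"{row['or']:.2f} ({_fmt_ci(row['or_ci_low'], row['or_ci_high'])})"
    return f"{row['beta']:.2f} ({_fmt_ci(row['ci_low'], row['ci_high'])})"


def _section_markdown(s: OutcomeSection) -> list[str]:
    scale = "OR" if s.outcome_binary else "Effect"
    lines = [f"## {s.direction.capitalize()}: {s.exposure_name} → {s.outcome_name}",
             "",
             f"| Method | SNPs | {scale} (95% CI) | p |",
             "|---|---|---|---|"]
    for _, row in s.estimates.iterrows():
        lines.append(f"| {_DISPLAY_NAMES.get(row['method'], row['method'])} "
                     f"| {int(row['nsnp'])} | {format_estimate_human(row, s.outcome_binary)} "
                     f"| {row['pvalue']:.3g} |")
    lines.append("")
    diag = [f"- Cochran's Q = {s.heterogeneity['q']:.2f} "
            f"(df = {s.heterogeneity['df']}, p = {s.heterogeneity['pvalue']:.3g})",
            f"- MR-Egger intercept = {s.egger_intercept['intercept']:.4g} "
            f"(p = {s.egger_intercept['pvalue']:.3g})"]
    if s.presso is not None:
        diag.append(f"- MR-PRESSO global test p = {s.presso['global_p']:.3g} "
                    f"({s.presso['n_outliers']} outlier(s))")
    diag.append(f"- Weak instruments (F < 10): {s.strength['n_weak']} "
                f"(min F = {s.strength['min_f']:.1f}; summed R² = "
                f"{s.strength['total_r2']:.4g})")
    if len(s.loo):
        n_flag = int(s.loo["sign_change"].sum() + s.loo["significance_change"].sum())
        diag.append(f"- Leave-one-out: {n_flag} influential drop(s) flagged")
    if s.reverse_null is not None:
        verdict = ("no evidence of reverse causation (CI covers 0)"
                   if s.reverse_null else "reverse estimate excludes 0")
        diag.append(f"- Reverse direction: {verdict}")
    lines.extend(diag)
    lines.append("")
    return lines


def render_report(report: MRReport, output_dir, formats=("tsv", "markdown")) -> list[Path]:
    """Write per-outcome TSVs and/or a Markdown summary; deterministic output.

    TSVs carry full float precision; the Markdown tables round ORs/CIs to two
    decimals and p-values to three significant digits.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "tsv" in formats:
        for s in report.sections:
            prefix = f"{s.direction}_{s.label}"
            pieces = {
                "estimates": s.estimates,
                "diagnostics": pd.DataFrame([{**s.heterogeneity,
                                              **{f"egger_{k}": v for k, v in
                                                 s.egger_intercept.items()},
                                              **(s.presso or {}),
                                              **s.strength}]),
                "exclusions": s.exclusions,
                "leave_one_out": s.loo,
                "funnel": s.funnel,
            }
            for piece, df in pieces.items():
                path = outdir / f"{prefix}_{piece}.tsv"
                df.to_csv(path, sep="\t", index=False)
                written.append(path)
        manifest = outdir / "run_manifest.json"
        manifest.write_text(json.dumps(report.provenance, indent=2, sort_keys=True,
                                       default=str) + "\n")
        written.append(manifest)

    if "markdown" in formats:
        lines = ["# Mendelian randomization report", "",
                 f"Seed {report.provenance['seed']}, "
                 f"config {report.provenance['config_hash']}, "
                 f"summr {report.provenance['summr_version']}", ""]
        for s in report.sections:
            lines.extend(_section_markdown(s))
        path = outdir / "summary.md"
        path.write_text("\n".join(lines))
        written.append(path)
    return written
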