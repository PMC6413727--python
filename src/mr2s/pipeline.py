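"""End-to-end pipeline: selection -> estimation -> sensitivity -> report.

``run_pipeline`` wires the stages together from a :class:`PipelineConfig`
(loadable from YAML) and writes a report bundle: tab-separated tables for
the selection log, the estimator comparison, heterogeneity, leave-one-out,
funnel and forest data, plus one machine-readable JSON holding every number
at full precision. Two runs with the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, instruments as instr_mod, io as io_mod, sensitivity
from .records import (
    ConfigError,
    HarmonizedInstrument,
    MREstimate,
    SelectionReport,
    WaldRatio,
)

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass(slots=True)
class PipelineConfig:
    """Everything one analysis run needs; all thresholds config-exposed."""

    # input: either a merged fixture-style table (None = bundled BMI/T2DM
    # table) or separate exposure/outcome tables with dialect mappings
    merged_fixture: str | None = None
    exposure_path: str | None = None
    outcome_path: str | None = None
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    # selection thresholds; clumping is opt-in because the default input is
    # an already-LD-pruned table, where the distance backstop (no reference
    # panel available) would spuriously drop independent nearby loci
    p_exposure: float = 5e-8
    clump: bool = False
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    p_outcome: float = 0.05
    ld_table: str | None = None
    known_loci_file: str | None = None
    extra_exclusions: list[str] = field(default_factory=list)
    skip_selection: bool = False
    # missing-beta policy
    missing_beta: str = "impute"  # impute | exclude
    impute_sign: int = -1
    strict: bool = False  # turn imputation fallbacks into hard errors
    # estimator settings
    model: str = "auto"
    se_method: str = "second_order"
    n_boot: int = 10_000
    seed: int = 1
    # output
    out_dir: str = "mr2s_report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(slots=True)
class ReportBundle:
    """In-memory results of one pipeline run plus where they were written."""

    instruments: list[HarmonizedInstrument]
    ratios: list[WaldRatio]
    selection: SelectionReport
    estimates: estimators.EstimateReport
    egger_slope: MREstimate
    egger_intercept: MREstimate
    leave_one_out: list
    funnel: list
    forest: pd.DataFrame
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)


def forest_data(ratios: list[WaldRatio], pooled: MREstimate) -> pd.DataFrame:
    """Per-SNP ratio rows with 95% CIs plus a pooled summary row."""
    rows = [
        {
            "snp": r.snp_id,
            "beta_xy": r.beta_xy,
            "ci_low": r.beta_xy - estimators.CI_Z * r.se_xy,
            "ci_high": r.beta_xy + estimators.CI_Z * r.se_xy,
            "is_summary": False,
        }
        for r in ratios
    ]
    rows.append(
        {
            "snp": f"Pooled ({pooled.method})",
            "beta_xy": pooled.beta,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "is_summary": True,
        }
    )
    return pd.DataFrame(rows)


def _apply_missing_beta_policy(cfg: PipelineConfig, exposure, outcome):
    missing = [v for v in outcome if v.beta_missing]
    if not missing:
        return exposure, outcome
    if cfg.missing_beta == "impute":
        if cfg.strict:
            raise ConfigError(
                "strict mode: unreported betas present "
                f"({', '.join(v.snp_id for v in missing)}), imputation disabled"
            )
        outcome = [
            io_mod.impute_missing_beta(v, cfg.impute_sign) if v.beta_missing else v
            for v in outcome
        ]
    elif cfg.missing_beta == "exclude":
        dropped = {v.snp_id for v in missing}
        exposure = [v for v in exposure if v.snp_id not in dropped]
        outcome = [v for v in outcome if not v.beta_missing]
    else:
        raise ConfigError(f"missing_beta must be impute|exclude, got {cfg.missing_beta!r}")
    return exposure, outcome


def _load_instruments(cfg: PipelineConfig) -> list[HarmonizedInstrument]:
    if cfg.exposure_path is not None or cfg.outcome_path is not None:
        if not (cfg.exposure_path and cfg.outcome_path):
            raise ConfigError("exposure_path and outcome_path must both be set")
        if not (cfg.exposure_columns and cfg.outcome_columns):
            raise ConfigError("column dialects required for external tables")
        exposure = io_mod.read_summary_table(
            cfg.exposure_path, io_mod.ColumnDialect.from_mapping(cfg.exposure_columns)
        )
        outcome = io_mod.read_summary_table(
            cfg.outcome_path, io_mod.ColumnDialect.from_mapping(cfg.outcome_columns)
        )
    else:
        # merged fixture-shaped table; None means the bundled BMI/T2DM table
        meta = io_mod.load_table1_metadata()
        src = cfg.merged_fixture
        if src is None:
            exposure, outcome = io_mod.load_table1()
        else:
            exposure = io_mod.read_summary_table(
                src, io_mod.ColumnDialect.from_mapping(meta["exposure_columns"])
            )
            outcome = io_mod.read_summary_table(
                src, io_mod.ColumnDialect.from_mapping(meta["outcome_columns"])
            )
    exposure, outcome = _apply_missing_beta_policy(cfg, exposure, outcome)
    return io_mod.harmonize_pair(exposure, outcome)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda x: f"{x:.10g}" if isinstance(x, float) else x)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute selection, estimation and sensitivity; write the report bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    harmonized = _load_instruments(cfg)
    log.info("loaded %d harmonized instruments", len(harmonized))

    if cfg.skip_selection:
        selected, selection = harmonized, SelectionReport(n_input=len(harmonized))
    else:
        ld = instr_mod.read_ld_table(cfg.ld_table) if cfg.ld_table else None
        if cfg.known_loci_file:
            with open(cfg.known_loci_file) as fh:
                known = [line.strip() for line in fh if line.strip()]
        else:
            known = io_mod.load_known_outcome_loci()
        selected, selection = instr_mod.select_instruments(
            harmonized,
            p_exposure=cfg.p_exposure,
            ld=ld,
            clump_r2=cfg.clump_r2,
            clump_kb=cfg.clump_kb,
            known_loci=known,
            p_outcome=cfg.p_outcome,
            extra_exclusions=cfg.extra_exclusions,
            clump=cfg.clump,
        )
    log.info("%d instruments after selection", len(selected))

    report = estimators.estimate_all(
        selected,
        model=cfg.model,
        se_method=cfg.se_method,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )
    ratios = estimators.wald_ratios(selected, cfg.se_method)
    ivw = report.estimates[0]
    if len(selected) >= 3:
        slope, intercept = estimators.egger_regression(selected)
        loo_model = "random" if ivw.method == "IVW-random" else "fixed"
        loo = sensitivity.leave_one_out(ratios, model=loo_model)
    else:
        raise ConfigError(
            "estimation stage: fewer than 3 instruments survived selection"
        )
    funnel, funnel_ref = sensitivity.funnel_data(ratios, ivw)
    forest = forest_data(ratios, ivw)

    bundle = ReportBundle(
        instruments=selected,
        ratios=ratios,
        selection=selection,
        estimates=report,
        egger_slope=slope,
        egger_intercept=intercept,
        leave_one_out=loo,
        funnel=funnel,
        forest=forest,
        out_dir=out_dir,
    )
    _write_bundle(bundle, cfg, funnel_ref)
    return bundle


def _write_bundle(bundle: ReportBundle, cfg: PipelineConfig, funnel_ref: float) -> None:
    out = bundle.out_dir
    files = bundle.files

    sel = bundle.selection
    sel_df = pd.DataFrame(sel.removed, columns=["snp", "reason"])
    files["selection"] = out / "selection_report.tsv"
    sel_df.to_csv(files["selection"], sep="\t", index=False)

    est_df = bundle.estimates.to_frame()
    egger_rows = pd.DataFrame(
        [bundle.egger_slope.to_dict(), bundle.egger_intercept.to_dict()]
    )
    est_df = pd.concat([est_df, egger_rows], ignore_index=True)
    files["estimates"] = out / "estimates.tsv"
    _fmt(est_df).to_csv(files["estimates"], sep="\t", index=False)

    het = bundle.estimates.heterogeneity
    het_df = pd.DataFrame([het.to_dict()] if het else [])
    files["heterogeneity"] = out / "heterogeneity.tsv"
    _fmt(het_df).to_csv(files["heterogeneity"], sep="\t", index=False)

    loo_df = pd.DataFrame(
        {
            "dropped_snp": row.dropped_snp,
            "or": row.estimate.odds_ratio,
            "or_ci_low": row.estimate.or_ci_low,
            "or_ci_high": row.estimate.or_ci_high,
            "pval": row.estimate.pval,
            "delta_rel": row.delta_rel,
        }
        for row in bundle.leave_one_out
    )
    files["leave_one_out"] = out / "leave_one_out.tsv"
    _fmt(loo_df).to_csv(files["leave_one_out"], sep="\t", index=False)

    funnel_df = pd.DataFrame(
        {"snp": p.snp_id, "beta_xy": p.beta_xy, "precision": p.precision}
        for p in bundle.funnel
    )
    files["funnel"] = out / "funnel.tsv"
    _fmt(funnel_df).to_csv(files["funnel"], sep="\t", index=False)

    files["forest"] = out / "forest.tsv"
    _fmt(bundle.forest).to_csv(files["forest"], sep="\t", index=False)

    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "p_exposure": cfg.p_exposure,
            "clump_r2": cfg.clump_r2,
            "clump_kb": cfg.clump_kb,
            "p_outcome": cfg.p_outcome,
            "missing_beta": cfg.missing_beta,
            "impute_sign": cfg.impute_sign,
            "model": cfg.model,
            "se_method": cfg.se_method,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
        },
        "selection": {
            "n_input": sel.n_input,
            "n_after_significance": sel.n_after_significance,
            "n_after_clump": sel.n_after_clump,
            "n_after_known_outcome_loci": sel.n_after_known_outcome_loci,
            "n_after_outcome_p": sel.n_after_outcome_p,
            "n_final": sel.n_final,
            "removed": [{"snp": s, "reason": r} for s, r in sel.removed],
        },
        "estimates": [e.to_dict() for e in bundle.estimates.estimates],
        "skipped_estimators": bundle.estimates.skipped,
        "egger": {
            "slope": bundle.egger_slope.to_dict(),
            "intercept": bundle.egger_intercept.to_dict(),
        },
        "heterogeneity": het.to_dict() if het else None,
        "leave_one_out": [
            {
                "dropped_snp": row.dropped_snp,
                "or": row.estimate.odds_ratio,
                "or_ci_low": row.estimate.or_ci_low,
                "or_ci_high": row.estimate.or_ci_high,
                "pval": row.estimate.pval,
                "delta_rel": row.delta_rel,
            }
            for row in bundle.leave_one_out
        ],
        "funnel": {
            "reference_log_or": funnel_ref,
            "points": [
                {"snp": p.snp_id, "beta_xy": p.beta_xy, "precision": p.precision}
                for p in bundle.funnel
            ],
        },
        "forest": bundle.forest.to_dict(orient="records"),
    }
    files["json"] = out / "report.json"
    with open(files["json"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def summarize(bundle: ReportBundle) -> str:
    """Three-decimal human-readable summary of the headline numbers."""
    ivw = bundle.estimates.estimates[0]
    het = bundle.estimates.heterogeneity
    lines = [
        f"Instruments: {len(bundle.instruments)}",
        f"{ivw.method}: OR {ivw.odds_ratio:.3f} "
        f"(95% CI {ivw.or_ci_low:.3f} to {ivw.or_ci_high:.3f}; P = {ivw.pval:.3f})",
    ]
    if het is not None:
        lines.append(
            f"Heterogeneity: Q = {het.Q:.2f} (df {het.df}), "
            f"P = {het.pval:.3f}, I2 = {het.i2:.1f}%"
        )
    lines.append(
        f"Egger intercept {bundle.egger_intercept.beta:.3f} "
        f"(P = {bundle.egger_intercept.pval:.3f}); "
        f"slope OR {bundle.egger_slope.odds_ratio:.3f}"
    )
    for est in bundle.estimates.estimates[1:]:
        lines.append(
            f"{est.method}: OR {est.odds_ratio:.3f} "
            f"({est.or_ci_low:.3f} to {est.or_ci_high:.3f}; P = {est.pval:.3f})"
        )
    ors = [row.estimate.odds_ratio for row in bundle.leave_one_out]
    lines.append(f"Leave-one-out OR range: {min(ors):.3f} to {max(ors):.3f}")
    return "\n".join(lines)
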