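"""End-to-end orchestration: simulate/load -> screen -> participation ->
latent fit -> post-stratify -> diagnostics -> optional sensitivity analyses.

A run writes a self-contained bundle directory: the echoed configuration
(seed included), the cohort actually analysed, every stage's results as
JSON/CSV and a Markdown summary.  All randomness flows from the single
recorded seed, so a bundle suffices to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from ._rng import child_seed
from .cohort import SimConfig, StratumSpec, read_cohort, write_cohort
from .descriptive import sex_ratio
from .diagnostics import diagnose
from .latent import (
    LatentModelSpec,
    MCMCSpec,
    fit_latent_model,
    pooled_crude_prevalence,
    post_stratify,
    sex_grade_breakdown,
)
from .participation import fit_participation
from .screening import ScreenConfig, summarize_flow
from .sensitivity import CapSpec, GridSpec, cap_scan, deterministic_grid, probabilistic_sensitivity

log = logging.getLogger("screenprev")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run.  Supply exactly one of ``cohort_path``/``sim_config``."""

    output_dir: str
    cohort_path: str | None = None
    sim_config: SimConfig | None = None
    stratum_specs: tuple[StratumSpec, ...] | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    model: LatentModelSpec = field(default_factory=LatentModelSpec)
    mcmc: MCMCSpec = field(default_factory=MCMCSpec)
    participation_covariates: tuple[str, ...] = ("scq_score", "sex", "grade")
    run_grid: bool = False
    grid: GridSpec = field(default_factory=GridSpec)
    run_caps: bool = False
    caps: CapSpec = field(default_factory=CapSpec)
    run_probabilistic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.sim_config is None):
            raise ValueError("supply exactly one of cohort_path / sim_config")
        if self.cohort_path is not None and self.stratum_specs is None:
            raise ValueError("stratum population sizes are required with a cohort file")

    def resolved_strata(self) -> tuple[StratumSpec, ...]:
        if self.stratum_specs is not None:
            return self.stratum_specs
        return self.sim_config.stratum_specs


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle as a dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "complete": False}
    stage = "configuration"
    try:
        echo = {
            "seed": config.seed,
            "screen": dataclasses.asdict(config.screen),
            "model": dataclasses.asdict(config.model),
            "mcmc": dataclasses.asdict(dataclasses.replace(config.mcmc, seed=config.seed)),
            "strata": [dataclasses.asdict(s) for s in config.resolved_strata()],
            "sim_config": (cohort_mod.config_to_dict(config.sim_config)
                           if config.sim_config else None),
            "cohort_path": config.cohort_path,
        }
        _dump(echo, out / "config_echo.json")

        stage = "cohort"
        if config.sim_config is not None:
            sim = dataclasses.replace(config.sim_config,
                                      seed=child_seed(config.seed, "pipeline", 0))
            records = cohort_mod.simulate_population(sim)
            write_cohort(records, out / "cohort.csv")
        else:
            records = read_cohort(config.cohort_path, cutoff=config.screen.cutoff)
        strata = config.resolved_strata()

        stage = "screening"
        flow = summarize_flow(records)
        (out / "flow.json").write_text(flow.to_json() + "\n")
        log.info("screening: %d screen-positive of %d screened",
                 flow.table.loc["overall", "screen_positive"],
                 flow.table.loc["overall", "screened"])

        stage = "participation"
        part_fit = fit_participation(records, covariates=config.participation_covariates)
        (out / "participation.json").write_text(part_fit.to_json() + "\n")

        stage = "latent model"
        mcmc = dataclasses.replace(config.mcmc, seed=child_seed(config.seed, "pipeline", 1))
        draws = fit_latent_model(records, config.model, mcmc)
        result = post_stratify(draws, records, strata, scale="per_1000")
        breakdown = sex_grade_breakdown(draws, records, strata)
        crude = pooled_crude_prevalence(records, strata)
        prevalence = {
            "overall": result.to_dict(),
            "by_subgroup": {f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k:
                            (v.to_dict() if hasattr(v, "to_dict") else v)
                            for k, v in breakdown.items()},
            "pooled_crude_per_1000": crude,
        }
        _dump(prevalence, out / "prevalence.json")

        stage = "diagnostics"
        report = diagnose(draws.chain_arrays())
        (out / "diagnostics.json").write_text(report.to_json() + "\n")

        grid_table = caps_table = prob = None
        if config.run_grid:
            stage = "deterministic sensitivity grid"
            grid_table = deterministic_grid(records, config.model, config.grid, mcmc, strata)
            grid_table.to_csv(out / "sensitivity_grid.csv", index=False)
        if config.run_caps:
            stage = "HR capping"
            caps_table = cap_scan(draws, config.caps, strata)
            caps_table.to_csv(out / "sensitivity_caps.csv", index=False)
        if config.run_probabilistic:
            stage = "probabilistic sensitivity"
            prob_mcmc = dataclasses.replace(config.mcmc,
                                            seed=child_seed(config.seed, "pipeline", 2))
            prob = probabilistic_sensitivity(
                records, config.model, config.model.misclass.se_prior,
                config.model.misclass.sp_prior, prob_mcmc, strata)
            _dump({"prevalence": prob["prevalence"].to_dict(),
                   "se": prob["se"], "sp": prob["sp"]}, out / "probabilistic.json")

        stage = "report"
        (out / "report.md").write_text(_render_report(flow, part_fit, result, breakdown,
                                                      crude, report, grid_table, caps_table))
        bundle.update(
            complete=True, diagnostics_passed=report.passed,
            prevalence=result, breakdown=breakdown, pooled_crude_per_1000=crude,
            flow=flow, participation=part_fit, draws=draws, diagnostics=report,
            grid=grid_table, caps=caps_table, probabilistic=prob, records=records,
        )
        return bundle
    except Exception as exc:
        _dump({"failed_stage": stage, "error": str(exc)}, out / "FAILED.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _render_report(flow, part_fit, result, breakdown, crude, diag_report,
                   grid_table, caps_table) -> str:
    lines = ["# Two-phase prevalence run", "", "## Case-identification flow", "",
             "```", flow.to_text(), "```", "",
             "## Participation model (screen-positives)", "",
             "```", part_fit.to_text(), "```", "",
             "## Post-stratified prevalence", "",
             f"Overall: **{result}**", ""]
    for lab, v in result.stratum.items():
        lines.append(f"- {lab}: {v['median']:.1f} ({v['lower']:.1f}-{v['upper']:.1f}) per 1,000")
    lines.append(f"- pooled participation-weighted crude: {crude:.1f} per 1,000")
    lines.append("")
    lines.append("| group | median | 95% CrI |")
    lines.append("|---|---|---|")
    for k, v in breakdown.items():
        if isinstance(k, tuple):
            lines.append(f"| {k[0]} {k[1]} | {v.median:.1f} | {v.lower:.1f}-{v.upper:.1f} |")
    if "adjusted_sex_ratio" in breakdown:
        r = breakdown["adjusted_sex_ratio"]
        lines.append("")
        lines.append(f"Adjusted sex ratio: {r['median']:.1f} "
                     f"(95% CrI {r['lower']:.1f}-{r['upper']:.1f})")
    lines += ["", "## MCMC diagnostics", "", "```", diag_report.to_json(), "```", ""]
    if grid_table is not None:
        lines += ["## Se x Sp sensitivity grid (per 1,000)", "",
                  grid_table.round(2).to_markdown(index=False), ""]
    if caps_table is not None:
        lines += ["## HR-cap sensitivity (per 1,000)", "",
                  caps_table.round(2).to_markdown(index=False), ""]
    return "\n".join(lines) + "\n"


def empirical_sex_ratio(records: pd.DataFrame) -> float:
    """Crude male:female ratio of positive diagnoses in a cohort."""
    pos = records.loc[records["diagnosis"] == "positive"]
    return sex_ratio(int((pos["sex"] == "M").sum()), int((pos["sex"] == "F").sum()))
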