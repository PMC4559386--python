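"""End-to-end orchestration: simulate or analyze a cohort and emit reports.

Stage order: design -> (choice simulation) -> catch-trial QC -> per-block
indifference points -> discount-model fits and NImp -> memory scoring ->
EM imputation of missing income -> gender group comparisons, memory/covariate
correlations, hierarchical moderation regressions, and median-split
summaries. All tables are written as CSV; regression objects as JSON; the
seed and configuration are echoed alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import CohortConfig, generate_cohort, simulate_trials
from .discounting import fit_cohort
from .indifference import indifference_profile
from .inference import (
    compare_groups,
    em_impute,
    fit_model_hierarchy,
    median_split_summary,
    memory_covariate_correlations,
)
from .memory import score_memory_table
from .qc import apply_exclusions, qc_cohort

logger = logging.getLogger("tempodisc")

OUTCOMES = ["ln_k", "beta", "delta", "n_imp"]
GROUP_VARIABLES = ["age", "iq", "income", "fnpa_pf", "igd_c1", "igd_c2",
                   "ln_k", "beta", "delta"]
MEDIAN_SPLITS = [("igd_c2", "ln_k"), ("igd_c2", "beta"), ("igd_c1", "delta")]

MEMORY_RAW_COLUMNS = (
    ["participant_id", "fnpa_hits", "fnpa_fa"]
    + [f"c1_events_e{i}" for i in range(1, 5)]
    + [f"c1_ratings_e{i}" for i in range(1, 5)]
    + ["c2_answered", "c2_yes", "c2_conf"]
)
COVARIATE_COLUMNS = ["participant_id", "gender", "age", "iq", "income"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    ``mode`` is "simulate" (generate a synthetic cohort) or "analyze" (read
    trial, memory-response and covariate CSVs).
    """

    mode: str = "simulate"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    trials_path: str | None = None
    memory_path: str | None = None
    covariates_path: str | None = None
    outdir: str | None = None
    verbosity: int = 1

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze":
            missing = [
                name
                for name, path in [
                    ("trials_path", self.trials_path),
                    ("memory_path", self.memory_path),
                    ("covariates_path", self.covariates_path),
                ]
                if path is None
            ]
            if missing:
                raise ValueError(f"analyze mode requires {', '.join(missing)}")


@dataclass
class PipelineResult:
    """All tables and fitted models produced by one run."""

    trials: pd.DataFrame
    qc: pd.DataFrame
    indifference: pd.DataFrame
    discount_fits: pd.DataFrame
    analysis_table: pd.DataFrame
    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    regressions: dict  # outcome -> list of RegressionResult
    median_splits: pd.DataFrame
    cohort: pd.DataFrame | None = None  # simulate mode: includes ground truth


def _read_csv(path, required, label):
    table = pd.read_csv(path)
    missing = set(required) - set(table.columns)
    if missing:
        raise ValueError(f"{label} table {path} missing columns: {sorted(missing)}")
    return table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)

    cohort = None
    if config.mode == "simulate":
        config.cohort.seed = config.seed
        cohort = generate_cohort(config.cohort)
        logger.info("generated cohort of %d participants", len(cohort))
        trials = simulate_trials(cohort, config.seed)
        memory = cohort[MEMORY_RAW_COLUMNS].copy()
        covariates = cohort[COVARIATE_COLUMNS].copy()
    else:
        trials = _read_csv(config.trials_path, ["participant_id", "block",
                                                "sooner_amount", "is_catch",
                                                "choice"], "trial")
        trials["is_catch"] = trials["is_catch"].astype(bool)
        memory = _read_csv(config.memory_path, MEMORY_RAW_COLUMNS, "memory")
        covariates = _read_csv(config.covariates_path, COVARIATE_COLUMNS,
                               "covariate")

    qc = qc_cohort(trials)
    kept_trials = apply_exclusions(trials, qc)
    n_kept = kept_trials["participant_id"].nunique()
    logger.info("QC: %d of %d participants retained", n_kept, len(qc))
    if n_kept == 0:
        raise RuntimeError("QC excluded every participant; nothing to analyze")

    profile = indifference_profile(kept_trials)
    fits = fit_cohort(profile, kept_trials)

    scored = score_memory_table(memory)
    analysis = (
        covariates.merge(
            scored[["participant_id", "fnpa_pf", "igd_c1", "igd_c2"]],
            on="participant_id",
        )
        .merge(
            fits[["participant_id", "k", "ln_k", "beta", "delta", "n_imp"]],
            on="participant_id",
        )
    )
    analysis = em_impute(analysis)

    comparisons = pd.DataFrame(
        [
            {
                "variable": comp.variable,
                "test": comp.test_name,
                "statistic": comp.statistic,
                "p": comp.p,
                **{
                    f"{g}_{stat}": val
                    for g, (mean, se, n) in comp.group_stats.items()
                    for stat, val in zip(("mean", "se", "n"), (mean, se, n))
                },
            }
            for comp in (
                compare_groups(analysis, v)
                for v in GROUP_VARIABLES
                if v in analysis.columns
            )
        ]
    )
    correlations = memory_covariate_correlations(analysis)
    regressions = {o: fit_model_hierarchy(analysis, o) for o in OUTCOMES}
    splits = pd.concat(
        [median_split_summary(analysis, s, o) for s, o in MEDIAN_SPLITS],
        ignore_index=True,
    )

    result = PipelineResult(
        trials=trials,
        qc=qc,
        indifference=profile,
        discount_fits=fits,
        analysis_table=analysis,
        group_comparisons=comparisons,
        correlations=correlations,
        regressions=regressions,
        median_splits=splits,
        cohort=cohort,
    )
    if config.outdir is not None:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(outdir / "trials.csv", index=False)
    if result.cohort is not None:
        result.cohort.to_csv(outdir / "cohort.csv", index=False)
        result.cohort[MEMORY_RAW_COLUMNS].to_csv(outdir / "memory.csv", index=False)
        result.cohort[COVARIATE_COLUMNS].to_csv(outdir / "covariates.csv", index=False)
    result.qc.to_csv(outdir / "qc.csv", index=False)
    result.indifference.to_csv(outdir / "indifference.csv", index=False)
    result.discount_fits.to_csv(outdir / "discount_fits.csv", index=False)
    result.analysis_table.to_csv(outdir / "analysis_table.csv", index=False)
    result.group_comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    result.correlations.to_csv(outdir / "correlations.csv", index=False)
    result.median_splits.to_csv(outdir / "median_splits.csv", index=False)
    with open(outdir / "regressions.json", "w") as fh:
        json.dump(
            {
                outcome: [r.to_dict() for r in results]
                for outcome, results in result.regressions.items()
            },
            fh,
            indent=2,
        )
    with open(outdir / "regressions.md", "w") as fh:
        fh.write(render_regressions_markdown(result.regressions))
    with open(outdir / "config.json", "w") as fh:
        json.dump(
            {
                "mode": config.mode,
                "seed": config.seed,
                "cohort": config.cohort.to_dict(),
            },
            fh,
            indent=2,
        )


def render_regressions_markdown(regressions: dict) -> str:
    """Markdown summary of the model hierarchy per outcome (standardized betas)."""
    lines = []
    for outcome, results in regressions.items():
        lines.append(f"## Outcome: {outcome}\n")
        lines.append("| term | " + " | ".join(f"model {r.model_id}" for r in results) + " |")
        lines.append("|---|" + "---|" * len(results))
        terms = results[-1].predictors
        for term in terms:
            cells = []
            for r in results:
                if term in r.coefficients:
                    beta, p = r.coefficients[term]
                    cells.append(f"{beta:.3f} ({p:.3f})")
                else:
                    cells.append("")
            lines.append(f"| {term} | " + " | ".join(cells) + " |")
        lines.append(
            "| F (df) | "
            + " | ".join(f"{r.fvalue:.3f} ({r.df[0]},{r.df[1]})" for r in results)
            + " |"
        )
        lines.append("| R2 | " + " | ".join(f"{r.r2:.3f}" for r in results) + " |")
        lines.append(
            "| adj. R2 | " + " | ".join(f"{r.adj_r2:.3f}" for r in results) + " |"
        )
        lines.append(
            "| p (model) | " + " | ".join(f"{r.p_model:.3f}" for r in results) + " |"
        )
        delta_cells = []
        for r in results:
            if r.delta_r2_test is None:
                delta_cells.append("")
            else:
                t = r.delta_r2_test
                delta_cells.append(
                    f"F({t['df'][0]},{t['df'][1]})={t['F']:.3f}, p={t['p']:.3f}"
                )
        lines.append("| dR2 F-test | " + " | ".join(delta_cells) + " |")
        lines.append("")
    return "\n".join(lines)
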