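"""Stage runners behind the CLI: each stage reads its upstream artifacts,
writes its outputs plus a machine-readable manifest (inputs, seed, versions,
checksums), and logs row counts so conservation can be audited."""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Callable

import pandas as pd

from . import analysis, design as design_mod, pseudowords, phonotactics, simulate
from .config import PipelineConfig, write_manifest
from .lexicon import bp_inventory, read_inventory, read_lexicon, lexicon_forms

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _load_lexicon(cfg: PipelineConfig):
    inv = read_inventory(cfg.inventory) if cfg.inventory else bp_inventory()
    if cfg.lexicon:
        entries, rejected = read_lexicon(cfg.lexicon, inv)
    else:
        ref = resources.files("cswlkit") / "data" / "toy_lexicon.tsv"
        with resources.as_file(ref) as p:
            entries, rejected = read_lexicon(p, inv)
    if rejected:
        logger.warning("lexicon: %d rows rejected", len(rejected))
    if not entries:
        raise PipelineError("no valid lexicon entries")
    return inv, entries


def stage_phonotactics(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, entries = _load_lexicon(cfg)
    table = phonotactics.compute_biphone_table(entries)
    path = out / "biphone_table.tsv"
    phonotactics.write_table(table, path)
    logger.info("phonotactics: %d lexicon rows -> %d biphone entries",
                len(entries), len(table.prob))
    return [path]


def stage_genwords(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inv, entries = _load_lexicon(cfg)
    table_path = out / "biphone_table.tsv"
    if not table_path.exists():
        raise PipelineError("missing upstream output biphone_table.tsv (run phonotactics)")
    table = phonotactics.read_table(table_path)
    template = pseudowords.WordTemplate(tuple(cfg.template))
    forms = lexicon_forms(entries)
    candidates = pseudowords.generate_candidates(
        table, template, inv, forms, cfg.aggregation
    )
    constraints = pseudowords.SelectionConstraints(
        max_shared_biphones=cfg.max_shared_biphones,
        max_onset_reuse=cfg.max_onset_reuse,
    )
    pp_plus = pseudowords.select_top_set(candidates, cfg.k, constraints)
    pp_minus = pseudowords.recombine_biphones(
        pp_plus, table, template, forms,
        floor=cfg.floor, mode=cfg.recombination_mode, aggregation=cfg.aggregation,
    )
    path = out / "stimuli.tsv"
    pseudowords.write_stimulus_sets([pp_plus, pp_minus], path)
    logger.info(
        "genwords: %d candidates -> PP+ mean %.4g, PP- mean %.4g",
        len(candidates), pp_plus.mean_pp, pp_minus.mean_pp,
    )
    return [path]


def _design_words(cfg: PipelineConfig) -> list[tuple[str, str]]:
    path = Path(cfg.out_dir) / "stimuli.tsv"
    if path.exists():
        sets = pseudowords.read_stimulus_sets(path)
        return [
            ("".join(phon), label)
            for label, rows in sorted(sets.items(), reverse=True)
            for _, phon, _ in rows
        ]
    words, _ = design_mod.default_words_objects(cfg.pairs_per_set)
    return words


def stage_design(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    words = _design_words(cfg)
    objects = [f"obj{i+1:02d}" for i in range(len(words))]
    spec = design_mod.DesignSpec(
        pairs_per_set=cfg.pairs_per_set,
        exposures_per_pair=cfg.exposures_per_pair,
        test_repetitions=cfg.test_repetitions,
        interleave_policy=cfg.interleave_policy,  # type: ignore[arg-type]
        counterbalance_version=cfg.counterbalance_version,  # type: ignore[arg-type]
        seed=cfg.stage_seed("design"),
    )
    design = design_mod.generate_design(words, objects, spec)
    design_mod.write_design(design, out)
    report = design_mod.validate_design(design)
    report_path = out / "design_report.json"
    report.to_json(report_path)
    if report.violations:
        raise PipelineError(f"design violations: {report.violations}")
    logger.info("design: %d training + %d test trials", report.n_training, report.n_test)
    return [out / "pairs.csv", out / "training_trials.csv", out / "test_trials.csv", report_path]


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    if not (out / "training_trials.csv").exists():
        raise PipelineError("missing upstream design outputs (run design)")
    design = design_mod.read_design(out)
    pconfig = simulate.ParticipantConfig(
        learner=cfg.learner,  # type: ignore[arg-type]
        beta0=cfg.beta0,
        delta_pp_plus=cfg.delta_pp_plus,
        tau_participant=cfg.tau_participant,
        tau_stimulus=cfg.tau_stimulus,
        contamination_rate=cfg.contamination_rate,
    )
    records = simulate.simulate_cohort(
        design, cfg.n_participants, pconfig, seed=cfg.stage_seed("simulate")
    )
    path = out / "responses.csv"
    records.to_csv(path, index=False)
    logger.info("simulate: %d participants -> %d rows", cfg.n_participants, len(records))
    return [path]


def stage_analyze(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.out_dir)
    resp_path = out / "responses.csv"
    if not resp_path.exists():
        raise PipelineError("missing upstream responses.csv (run simulate)")
    records = pd.read_csv(resp_path)
    full, halved = analysis.make_datasets(
        records, k=cfg.exclusion_k, scope=cfg.exclusion_scope  # type: ignore[arg-type]
    )
    logger.info(
        "analyze: conservation full %d = %d kept + %d excluded",
        len(records), len(full.rows), full.n_excluded,
    )
    results: dict = {"datasets": {}}
    coef_rows = []
    for ds in (full, halved):
        entry: dict = {
            "n_rows": len(ds.rows),
            "n_excluded": ds.n_excluded,
            "offset": ds.offset,
            "accuracy": analysis.accuracy_summary(
                ds, cfg.n_boot, cfg.stage_seed(f"boot_{ds.variant}")
            ).to_dict("records"),
        }
        try:
            freq = analysis.fit_glmm_frequentist(ds)
            entry["frequentist"] = freq.to_dict()
            entry["combined_odds_ppplus"] = analysis.combine_odds(
                freq.fixed["intercept_PPminus"].odds_ratio,
                freq.fixed["PPplus"].odds_ratio,
            )
            for name, fe in freq.fixed.items():
                coef_rows.append(
                    {"dataset": ds.variant, "method": "laplace", "term": name,
                     "estimate": fe.estimate, "odds_ratio": fe.odds_ratio,
                     "ci_low": fe.ci_low, "ci_high": fe.ci_high}
                )
        except analysis.AnalysisError as exc:
            entry["frequentist"] = {"error": str(exc)}
        if cfg.run_bayes:
            try:
                bay = analysis.fit_glmm_bayesian(
                    ds,
                    n_warmup=cfg.mcmc_warmup,
                    n_draws=cfg.mcmc_draws,
                    n_chains=cfg.mcmc_chains,
                    seed=cfg.stage_seed(f"mcmc_{ds.variant}"),
                )
                entry["bayesian"] = bay.to_dict()
                for name, fe in bay.fixed.items():
                    coef_rows.append(
                        {"dataset": ds.variant, "method": "mcmc", "term": name,
                         "estimate": fe.estimate, "odds_ratio": fe.odds_ratio,
                         "ci_low": fe.ci_low, "ci_high": fe.ci_high}
                    )
            except analysis.AnalysisError as exc:
                entry["bayesian"] = {"error": str(exc)}
        results["datasets"][ds.variant] = entry
    results_path = out / "analysis_results.json"
    results_path.write_text(json.dumps(results, indent=2), encoding="utf-8")
    coef_path = out / "coefficients.csv"
    pd.DataFrame(coef_rows).to_csv(coef_path, index=False)
    summary_path = out / "summary.txt"
    summary_path.write_text(_text_summary(results), encoding="utf-8")
    return [results_path, coef_path, summary_path]


def _text_summary(results: dict) -> str:
    lines = ["cswlkit analysis summary", "=" * 26]
    for variant, entry in results["datasets"].items():
        lines.append(f"\n[{variant} dataset] rows={entry['n_rows']} excluded={entry['n_excluded']}")
        for acc in entry["accuracy"]:
            lines.append(
                f"  accuracy {acc['set_label']}: {acc['mean_accuracy']:.3f} "
                f"[{acc['ci_low']:.3f}, {acc['ci_high']:.3f}]"
            )
        freq = entry.get("frequentist", {})
        if "fixed" in freq:
            ors = {k: v["odds_ratio"] for k, v in freq["fixed"].items()}
            lines.append(
                f"  OR intercept(PP-)={ors['intercept_PPminus']:.2f}, "
                f"PP+={ors['PPplus']:.2f}, combined={entry['combined_odds_ppplus']:.2f}"
            )
            lines.append(
                f"  ICC={freq['icc']:.2f}  R2m/R2c={freq['r2_marginal']:.3f}/"
                f"{freq['r2_conditional']:.3f}  converged={freq['converged']}"
            )
    return "\n".join(lines) + "\n"


STAGES: dict[str, Callable[[PipelineConfig], list[Path]]] = {
    "phonotactics": stage_phonotactics,
    "genwords": stage_genwords,
    "design": stage_design,
    "simulate": stage_simulate,
    "analyze": stage_analyze,
}


def run_stage(stage: str, cfg: PipelineConfig) -> list[Path]:
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    try:
        outputs = STAGES[stage](cfg)
    except (PipelineError, ValueError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    write_manifest(Path(cfg.out_dir), stage, cfg, outputs)
    return outputs


def run_all(cfg: PipelineConfig) -> dict:
    """Full synthetic replication: stimuli -> design -> cohort -> analysis."""
    for stage in ("phonotactics", "genwords", "design", "simulate", "analyze"):
        run_stage(stage, cfg)
    out = Path(cfg.out_dir)
    results = json.loads((out / "analysis_results.json").read_text(encoding="utf-8"))
    report = json.loads((out / "design_report.json").read_text(encoding="utf-8"))
    final = {
        "design": {
            "n_pairs": 2 * cfg.pairs_per_set,
            "exposures_per_pair": cfg.exposures_per_pair,
            "test_repetitions": cfg.test_repetitions,
            "n_training_trials": report["n_training"],
            "n_test_trials": report["n_test"],
        },
        "analysis": results["datasets"],
    }
    (out / "report.json").write_text(json.dumps(final, indent=2), encoding="utf-8")
    return final
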