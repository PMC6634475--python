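"""End-to-end orchestration: simulate or load, analyse, report.

The pipeline reproduces the full analysis chain on a trial table and
cursor log (synthetic or deposited): descriptive statistics, the PCA
speech-rate composite, AICc all-subsets selection of speech and gesture
cue models for speaker veracity and guesser response, and the
time-locked mouse-trajectory analyses for the two cues that drive
guesser responses (pauses, affect displays).

Every stage logs its trial counts and exclusion tallies so the data
funnel is auditable, and a machine-readable manifest (seed, config hash,
library versions) accompanies the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    GESTURE_CATEGORIES,
    SPEECH_CATEGORIES,
    apply_exclusions,
    collapse_categories,
    descriptives,
    exclusion_summary,
    read_trials,
    speech_rate_composite,
    validate_trials,
    write_trials,
)
from .glmm import ModelSpec, fit_glmm
from .mousetrace import assemble_tracks, read_cursor_logs, trajectory_analysis, write_cursor_logs
from .selection import best_model_report, enumerate_candidates, selection_table
from .simulate import GeneratorConfig, generate_dataset, ground_truth_summary

log = logging.getLogger("veracue")

SPEECH_PREDICTORS = list(SPEECH_CATEGORIES) + ["speech_rate"]
GESTURE_PREDICTORS = list(GESTURE_CATEGORIES)
OUTCOMES = ("speaker_veracity", "guesser_response")
RANDOM_INTERCEPTS = (("dyad_id", ("intercept",)), ("item_id", ("intercept",)))


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of generator / input paths."""

    generator: GeneratorConfig | None = None
    trials_path: str | None = None
    cursor_path: str | None = None
    analyses: tuple = ("speech", "gesture", "mouse")
    threshold: float = 2.0
    outdir: str | None = None
    seed: int | None = None
    denominator: str = "x"
    elogit_c: float = 0.5

    def validate(self):
        has_gen = self.generator is not None
        has_paths = self.trials_path is not None
        if has_gen == has_paths:
            raise ValueError("provide exactly one of a generator config or input paths")
        if "mouse" in self.analyses and not has_gen and self.cursor_path is None:
            raise ValueError("mouse analysis requires a cursor log path")
        return self


def _select_cues(df: pd.DataFrame, outcome: str, predictors, threshold: float):
    specs = enumerate_candidates(
        predictors, ModelSpec(outcome=outcome, random=RANDOM_INTERCEPTS, family="binomial")
    )
    fits = [fit_glmm(spec, df) for spec in specs]
    table = selection_table(fits, threshold=threshold, predictors=list(predictors))
    report = best_model_report(table, fits)
    return {"fits": fits, "table": table, "report": report}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the in-memory results bundle.

    Deterministic given the seed: rerunning with the same configuration
    produces identical numbers.
    """
    cfg = config.validate()
    results: dict = {}

    # --- stage: data -----------------------------------------------------
    if cfg.generator is not None:
        gen = cfg.generator
        if cfg.seed is not None:
            gen = dataclasses.replace(gen, seed=cfg.seed)
        log.info("simulate: %d dyads x %d trials (seed %d)", gen.n_dyads,
                 gen.trials_per_dyad, gen.seed)
        trials, cursor, gt = generate_dataset(gen)
        trials = validate_trials(trials)
        results["ground_truth"] = ground_truth_summary(gt)
    else:
        trials = read_trials(cfg.trials_path)
        cursor = read_cursor_logs(cfg.cursor_path) if cfg.cursor_path else None
        gt = None
    results["trials"] = trials
    results["cursor"] = cursor

    trials = collapse_categories(trials)
    included, excl_log = apply_exclusions(trials, "cue_models")
    logs = [excl_log]
    log.info("exclusions (cue_models): %d of %d trials dropped; %d retained",
             len(trials) - len(included), len(trials), len(included))

    # --- stage: descriptives and the speech-rate composite ---------------
    desc = descriptives(included)
    results["descriptives"] = desc
    log.info("descriptives: truth %.1f%%, perceived truth %.1f%%, accuracy %.1f%%",
             desc.truth_rate, desc.perceived_truth_rate, desc.accuracy_overall)

    comp = speech_rate_composite(
        included["utterance_duration_ms"],
        included["silent_pause_duration_ms"],
        included["syllable_rate"],
    )
    included = included.copy()
    scores = comp.scores
    included["speech_rate"] = (scores - scores.mean()) / scores.std(ddof=1)
    results["speech_rate_composite"] = comp
    log.info("speech-rate PCA: eigenvalue %.3f, %.1f%% of variance",
             comp.eigenvalue, 100 * comp.variance_share)

    # --- stage: cue model selection ---------------------------------------
    selections: dict = {}
    if "speech" in cfg.analyses:
        selections["speech"] = {
            outcome: _select_cues(included, outcome, SPEECH_PREDICTORS, cfg.threshold)
            for outcome in OUTCOMES
        }
        for outcome in OUTCOMES:
            rep = selections["speech"][outcome]["report"]
            log.info("speech/%s best model: %s (w=%.3f)", outcome,
                     rep["best_model"], rep["best_weight"])
    if "gesture" in cfg.analyses:
        gdf = included[included["gesture_data_present"] == 1]
        log.info("gesture analyses: %d trials with video", len(gdf))
        selections["gesture"] = {
            outcome: _select_cues(gdf, outcome, GESTURE_PREDICTORS, cfg.threshold)
            for outcome in OUTCOMES
        }
        for outcome in OUTCOMES:
            rep = selections["gesture"][outcome]["report"]
            log.info("gesture/%s best model: %s (w=%.3f)", outcome,
                     rep["best_model"], rep["best_weight"])
    results["selections"] = selections

    # --- stage: mouse trajectories ----------------------------------------
    if "mouse" in cfg.analyses and cursor is not None:
        tracks = assemble_tracks(cursor, trials)
        mouse = {}
        for cue in ("pause", "affect_display"):
            ana = trajectory_analysis(
                tracks, trials, cue=cue, denominator=cfg.denominator, c=cfg.elogit_c
            )
            mouse[cue] = ana
            logs.append(ana.exclusion_log)
            terms = dict(zip(ana.fit.terms, ana.fit.estimates))
            stats = dict(zip(ana.fit.terms, ana.fit.stat))
            log.info("mouse/%s: %d trials, time x cue beta=%.3f t=%.2f", cue,
                     ana.n_trials, terms["time:cue"], stats["time:cue"])
        results["mouse"] = mouse

    results["exclusion_log"] = pd.concat(logs, ignore_index=True)
    results["manifest"] = _manifest(cfg)

    if cfg.outdir is not None:
        write_results(results, cfg.outdir)
    return results


def _manifest(cfg: RunConfig) -> dict:
    plain = _plain(dataclasses.asdict(cfg))
    digest = hashlib.sha256(
        yaml.safe_dump(plain, sort_keys=True).encode()
    ).hexdigest()
    return {
        "veracue_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": plain,
        "config_sha256": digest,
        "seed": cfg.seed if cfg.seed is not None else (
            cfg.generator.seed if cfg.generator else None
        ),
    }


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.generic,)):
        return obj.item()
    return obj


def _selection_frame(table) -> pd.DataFrame:
    tab = table.entries.copy()
    tab["model"] = [" + ".join(t) if t else "(null)" for t in tab["terms"]]
    tab = tab.drop(columns="terms")
    return tab.sort_values("rank")[
        ["rank", "model", "k", "loglik", "aicc", "delta", "weight", "evidence_ratio"]
    ]


def write_results(results: dict, outdir) -> None:
    """Write the results bundle as delimited-text and JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if results.get("trials") is not None:
        write_trials(results["trials"], out / "trials.csv")
    if results.get("cursor") is not None:
        write_cursor_logs(results["cursor"], out / "cursor.csv")
    if results.get("ground_truth") is not None:
        results["ground_truth"].to_csv(out / "ground_truth.csv", index=False)

    desc = results.get("descriptives")
    if desc is not None:
        (out / "descriptives.json").write_text(json.dumps(_plain(desc.as_dict()), indent=2))

    comp = results.get("speech_rate_composite")
    if comp is not None:
        (out / "speech_rate_composite.json").write_text(json.dumps({
            "loadings": list(map(float, comp.loadings)),
            "eigenvalue": float(comp.eigenvalue),
            "variance_share": float(comp.variance_share),
            "orientation": "positive syllable-rate loading (higher = more fluent)",
        }, indent=2))

    for family, by_outcome in results.get("selections", {}).items():
        for outcome, sel in by_outcome.items():
            stem = f"{family}_{outcome}"
            _selection_frame(sel["table"]).to_csv(out / f"selection_{stem}.csv", index=False)
            sel["table"].parameter_weights.rename_axis("parameter").to_csv(
                out / f"parameter_weights_{stem}.csv"
            )
            (out / f"best_model_{stem}.json").write_text(
                json.dumps(_plain(sel["report"]), indent=2)
            )

    for cue, ana in results.get("mouse", {}).items():
        stem = f"mouse_{cue}"
        ana.fit.coef_table().to_csv(out / f"{stem}_coefficients.csv", index=False)
        (out / f"{stem}_meta.json").write_text(json.dumps(_plain({
            **ana.meta, "n_trials": ana.n_trials, "loglik": ana.fit.loglik,
            "k": ana.fit.k, "n_rows": ana.fit.n, "vc": ana.fit.vc,
            "converged": ana.fit.converged,
        }), indent=2))
        ana.curves.to_csv(out / f"{stem}_curves.csv", index=False)

    excl = results.get("exclusion_log")
    if excl is not None:
        excl.to_csv(out / "exclusions.csv", index=False)
        exclusion_summary(excl).to_csv(out / "exclusion_summary.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(results["manifest"], indent=2))
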