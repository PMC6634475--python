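"""Synthetic dyad-game generator with known ground truth.

Emulates a two-player treasure-hunting deception game: 24 dyads play 48
trials each; on every trial the speaker truthfully names the treasure's
location or lies, the guesser clicks the referent (truth judgement) or
the distractor, and the guesser's mouse is sampled at 50 Hz from screen
centre until the click.

Generative structure (cause -> cue -> judgement):

* veracity ~ Bernoulli(truth bias), with a per-speaker random effect;
* each of the 7 disfluency and 4 gesture-category cues ~ Bernoulli with a
  base log-odds and a veracity-dependent shift (the shift equals the
  cue/veracity log odds ratio a retrospective logistic model recovers);
* the guesser's referent click follows a logistic model on the cue
  categories with crossed guesser and item random intercepts (defaults:
  pauses -0.39, affect displays +0.29);
* continuous speech measures come from a latent trivariate Gaussian
  (log-duration, pause fraction, syllable rate) with a stated correlation
  matrix; silent-pause duration is 0 exactly when the silent-pause flag
  is 0 and never exceeds utterance duration;
* the cursor performs zero-mean jitter until a drift onset (a fixed
  reaction delay after disambiguation, lengthened additively when the
  utterance contains a pause or lacks an affect display), then drifts at
  constant speed toward the eventually clicked object and rests on it.

Default rates and moments are matched to the study conditions: truth
bias 53.9%, per-cue raw counts of the annotated corpus (e.g. filled
pauses 288/1149), utterance duration mean 3008.92 / SD 1329.35 ms.
All draws flow from a single integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

__all__ = [
    "CueParams",
    "ResponseModel",
    "ContinuousModel",
    "TrajectoryModel",
    "DisambiguationModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "ground_truth_summary",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass
class CueParams:
    """Per-cue logistic parameters.

    P(cue | veracity) = expit(base_logit +/- veracity_logit_shift / 2),
    '+' for truths.  The shift is therefore the truth-vs-lie log odds
    ratio of the cue.
    """

    base_logit: float
    veracity_logit_shift: float = 0.0


def _default_cue_model() -> dict:
    # Base rates chosen to match the annotated corpus raw counts
    # (speech n = 1149, gestures n = 1101); gesture-category rates are
    # plausible values since the corpus reports only raw gesture types.
    rates = {
        "filled_pause": 288 / 1149,
        "silent_pause": 588 / 1149,
        "repetition": 55 / 1149,
        "restart": 109 / 1149,
        "substitution": 36 / 1149,
        "addition": 12 / 1149,
        "prolongation": 334 / 1149,
        "adaptor": 0.35,
        "illustrator": 0.25,
        "affect_display": 0.29,
        "eye_contact": 130 / 1101,
    }
    shifts = {
        # Truth-tellers pause more; liars produce more adaptors.
        "filled_pause": 0.26,
        "silent_pause": 0.26,
        "adaptor": -0.29,
    }
    return {k: CueParams(float(logit(p)), shifts.get(k, 0.0)) for k, p in rates.items()}


@dataclass
class ResponseModel:
    """Guesser referent-click model: logit P = intercept + sum(coef * cue) + u_g + u_item."""

    intercept: float = 0.40
    coef: dict = field(default_factory=lambda: {"pauses": -0.39, "affect_display": 0.29})
    guesser_sd: float = 0.40
    item_sd: float = 0.20


@dataclass
class ContinuousModel:
    """Latent-Gaussian model of the three continuous speech measures.

    Log utterance duration is matched to mean 3008.92 / SD 1329.35 ms;
    syllable rate to mean 3.82 / SD 1.42 syll/s (floored at 0.3).  The
    silent-pause fraction of the utterance is a Beta(a, b) quantile
    transform of the second latent coordinate, applied only when the
    silent-pause flag is set.
    """

    log_duration_mean: float = 7.9202
    log_duration_sd: float = 0.4224
    syllable_rate_mean: float = 3.82
    syllable_rate_sd: float = 1.42
    syllable_rate_floor: float = 0.3
    pause_frac_a: float = 2.0
    pause_frac_b: float = 3.0
    latent_corr: tuple = (
        (1.00, 0.60, -0.55),
        (0.60, 1.00, -0.60),
        (-0.55, -0.60, 1.00),
    )


@dataclass
class TrajectoryModel:
    """Jitter-then-constant-drift cursor model sampled at 50 Hz."""

    sample_rate_hz: float = 50.0
    jitter_sd_px: float = 4.0
    drift_px_s: float = 350.0
    base_delay_ms: float = 200.0
    pause_lag_ms: float = 250.0
    affect_absent_lag_ms: float = 250.0
    target_x_px: float = 300.0
    click_dwell_ms: float = 200.0


@dataclass
class DisambiguationModel:
    """Disambiguation point uniform within a fraction window of the utterance."""

    frac_lo: float = 0.30
    frac_hi: float = 0.90
    missing_prob: float = 0.189  # additional-dialogue trials (point not codable)
    pause_onset_beta: tuple = (1.0, 4.0)
    affect_onset_beta: tuple = (1.0, 2.0)


@dataclass
class GeneratorConfig:
    n_dyads: int = 24
    trials_per_dyad: int = 48
    n_items: int = 96
    truth_prob: float = 0.539
    speaker_sd: float = 0.38
    cue_model: dict = field(default_factory=_default_cue_model)
    response_model: ResponseModel = field(default_factory=ResponseModel)
    continuous_model: ContinuousModel = field(default_factory=ContinuousModel)
    trajectory_model: TrajectoryModel = field(default_factory=TrajectoryModel)
    disambiguation_model: DisambiguationModel = field(default_factory=DisambiguationModel)
    inconsistent_prob: float = 0.003
    n_gesture_missing_dyads: int = 1  # video lost for one speaker
    generate_cursor: bool = True  # skip track simulation when only the trial table is needed
    seed: int = 0

    def validate(self):
        if self.trials_per_dyad > self.n_items:
            raise ValueError("infeasible config: trials_per_dyad exceeds n_items")
        for name, p in [
            ("truth_prob", self.truth_prob),
            ("inconsistent_prob", self.inconsistent_prob),
            ("disambiguation missing_prob", self.disambiguation_model.missing_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        C = np.asarray(self.continuous_model.latent_corr, dtype=float)
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("latent correlation matrix is not positive semi-definite")
        if self.trajectory_model.drift_px_s <= 0:
            raise ValueError("drift must be positive")
        return self


@dataclass
class GroundTruth:
    """Every generating parameter and drawn random effect, in the
    parameterisation the fitting module reports."""

    config: GeneratorConfig
    speaker_effects: dict
    guesser_effects: dict
    item_effects: dict
    response_coefficients: dict
    cue_veracity_log_odds: dict


_DISFLUENCIES = (
    "filled_pause", "silent_pause", "repetition", "restart",
    "substitution", "addition", "prolongation",
)
_GESTURE_CATS = ("adaptor", "illustrator", "affect_display", "eye_contact")
_RAW_GESTURE_RATES = {
    "gest_head": 651 / 1101,
    "gest_hand": 280 / 1101,
    "gest_body": 377 / 1101,
    "gest_shoulder": 26 / 1101,
    "gest_lip_mouth": 85 / 1101,
    "gest_eyebrow": 242 / 1101,
    "gest_smile_laugh": 156 / 1101,
}


def generate_dataset(config: GeneratorConfig | None = None):
    """Simulate one dyad-game dataset.

    Returns ``(trials, cursor, ground_truth)``: a trial table (one row
    per utterance), a long-format cursor log, and the ground-truth
    record.
    """
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_dyads * cfg.trials_per_dyad

    dyads = [f"d{i + 1:03d}" for i in range(cfg.n_dyads)]
    items_all = [f"item{i + 1:03d}" for i in range(cfg.n_items)]

    speaker_fx = dict(zip(dyads, rng.normal(0.0, cfg.speaker_sd, cfg.n_dyads)))
    guesser_fx = dict(zip(dyads, rng.normal(0.0, cfg.response_model.guesser_sd, cfg.n_dyads)))
    item_fx = dict(zip(items_all, rng.normal(0.0, cfg.response_model.item_sd, cfg.n_items)))
    missing_video = set(rng.choice(dyads, size=cfg.n_gesture_missing_dyads, replace=False))

    rows = []
    for d in dyads:
        items = rng.choice(items_all, size=cfg.trials_per_dyad, replace=False)
        sides = np.array(["left", "right"])[
            rng.permutation(np.arange(cfg.trials_per_dyad) % 2)
        ]
        treasure = np.array(["gold", "silver"])[
            rng.permutation(np.arange(cfg.trials_per_dyad) % 2)
        ]
        for t in range(cfg.trials_per_dyad):
            rows.append(
                {
                    "dyad_id": d,
                    "trial_index": t + 1,
                    "item_id": items[t],
                    "target_side": sides[t],
                    "treasure": treasure[t],
                }
            )
    df = pd.DataFrame(rows)

    # Veracity with per-speaker truth bias.
    base = logit(cfg.truth_prob)
    sp = df["dyad_id"].map(speaker_fx).to_numpy()
    truth = rng.random(n) < expit(base + sp)
    df["veracity"] = np.where(truth, "truth", "lie")
    vsign = np.where(truth, 0.5, -0.5)

    # Binary cues conditional on veracity.
    for cue, params in cfg.cue_model.items():
        p = expit(params.base_logit + params.veracity_logit_shift * vsign)
        df[cue] = (rng.random(n) < p).astype(int)
    for g, rate in _RAW_GESTURE_RATES.items():
        df[g] = (rng.random(n) < rate).astype(int)
    df["gest_eye_contact"] = df["eye_contact"]

    df["pauses"] = ((df["filled_pause"] == 1) | (df["silent_pause"] == 1)).astype(int)

    # Guesser response from the cue categories plus crossed random effects.
    rm = cfg.response_model
    eta = np.full(n, rm.intercept, dtype=float)
    cat_cols = {"pauses": df["pauses"], "repetitions": df["repetition"],
                "affect_display": df["affect_display"], "adaptor": df["adaptor"],
                "illustrator": df["illustrator"], "eye_contact": df["eye_contact"],
                "prolongations": df["prolongation"]}
    for term, b in rm.coef.items():
        if term not in cat_cols:
            raise ValueError(f"unknown response-model term {term!r}")
        eta += b * cat_cols[term].to_numpy(float)
    eta += df["dyad_id"].map(guesser_fx).to_numpy()
    eta += df["item_id"].map(item_fx).to_numpy()
    click_ref = rng.random(n) < expit(eta)
    df["response"] = np.where(click_ref, "truth", "lie")

    # Continuous speech measures from the latent trivariate Gaussian.
    cm = cfg.continuous_model
    C = np.asarray(cm.latent_corr, dtype=float)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ L.T
    dur = np.exp(cm.log_duration_mean + cm.log_duration_sd * z[:, 0])
    frac = beta_dist.ppf(
        np.clip(_phi(z[:, 1]), 1e-12, 1 - 1e-12), cm.pause_frac_a, cm.pause_frac_b
    )
    pause_dur = np.where(df["silent_pause"] == 1, dur * frac, 0.0)
    syll = np.maximum(
        cm.syllable_rate_floor, cm.syllable_rate_mean + cm.syllable_rate_sd * z[:, 2]
    )
    df["utterance_duration_ms"] = dur
    df["silent_pause_duration_ms"] = pause_dur
    df["syllable_rate"] = syll

    # Disambiguation point and cue onsets.
    dm = cfg.disambiguation_model
    disamb = dur * rng.uniform(dm.frac_lo, dm.frac_hi, n)
    has_disamb = rng.random(n) >= dm.missing_prob
    df["disambiguation_ms"] = np.where(has_disamb, disamb, np.nan)
    a, b = dm.pause_onset_beta
    df["pause_onset_ms"] = np.where(df["pauses"] == 1, dur * rng.beta(a, b, n), np.nan)
    a, b = dm.affect_onset_beta
    df["affect_onset_ms"] = np.where(
        df["affect_display"] == 1, dur * rng.beta(a, b, n), np.nan
    )

    df["consistent_commitment"] = (rng.random(n) >= cfg.inconsistent_prob).astype(int)
    df["gesture_data_present"] = (~df["dyad_id"].isin(missing_video)).astype(int)
    df = df.drop(columns="pauses")

    cursor = _simulate_cursor(df, cfg, rng, disamb) if cfg.generate_cursor else None

    gt = GroundTruth(
        config=cfg,
        speaker_effects=speaker_fx,
        guesser_effects=guesser_fx,
        item_effects=item_fx,
        response_coefficients={"(Intercept)": rm.intercept, **rm.coef},
        cue_veracity_log_odds={k: v.veracity_logit_shift for k, v in cfg.cue_model.items()},
    )
    return df, cursor, gt


def _phi(x):
    from scipy.special import ndtr

    return ndtr(x)


def _simulate_cursor(df: pd.DataFrame, cfg: GeneratorConfig, rng, disamb_all) -> pd.DataFrame:
    """Jitter-then-drift cursor tracks; the final sample rests on the
    clicked object, so it always lies in that object's half of the screen."""
    tm = cfg.trajectory_model
    dt_ms = 1000.0 / tm.sample_rate_hz
    veracity = df["veracity"].to_numpy()
    target_side = df["target_side"].to_numpy()
    response = df["response"].to_numpy()
    pauses = ((df["filled_pause"] == 1) | (df["silent_pause"] == 1)).to_numpy()
    affect = (df["affect_display"] == 1).to_numpy()
    dur = df["utterance_duration_ms"].to_numpy()
    disamb_obs = df["disambiguation_ms"].to_numpy()
    dyad_arr = df["dyad_id"].to_numpy()
    trial_arr = df["trial_index"].to_numpy()

    t_parts, x_parts, y_parts, dyad_parts, trial_parts = [], [], [], [], []
    for i in range(len(df)):
        ref_side = target_side[i] if veracity[i] == "truth" else (
            "left" if target_side[i] == "right" else "right"
        )
        clicked = ref_side if response[i] == "truth" else (
            "left" if ref_side == "right" else "right"
        )
        sign = 1.0 if clicked == "right" else -1.0
        t_dis = disamb_all[i] if not np.isnan(disamb_obs[i]) else 0.6 * dur[i]
        onset = (
            t_dis
            + tm.base_delay_ms
            + (tm.pause_lag_ms if pauses[i] else 0.0)
            + (tm.affect_absent_lag_ms if not affect[i] else 0.0)
        )
        reach = onset + tm.target_x_px / tm.drift_px_s * 1000.0
        click = reach + tm.click_dwell_ms
        t = np.arange(0.0, click + dt_ms, dt_ms)
        jitter = np.cumsum(rng.normal(0.0, tm.jitter_sd_px, len(t)))
        drift = np.clip((t - onset), 0.0, None) * tm.drift_px_s / 1000.0
        drift = np.minimum(drift, tm.target_x_px)
        x = sign * drift + jitter
        x[t >= reach] = sign * tm.target_x_px
        y = np.cumsum(rng.normal(0.0, tm.jitter_sd_px / 2.0, len(t)))
        t_parts.append(t)
        x_parts.append(x)
        y_parts.append(y)
        dyad_parts.append(np.full(len(t), dyad_arr[i], dtype=object))
        trial_parts.append(np.full(len(t), trial_arr[i]))
    return pd.DataFrame(
        {
            "dyad_id": np.concatenate(dyad_parts),
            "trial_index": np.concatenate(trial_parts).astype(int),
            "t_ms": np.concatenate(t_parts),
            "x_px": np.concatenate(x_parts),
            "y_px": np.concatenate(y_parts),
        }
    )


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """True parameters in the parameterisation the fitting module reports.

    Response-model coefficients are log odds of clicking the referent;
    cue shifts are truth-vs-lie log odds ratios (what a logistic model of
    veracity on the cue recovers, by odds-ratio symmetry).
    """
    rows = [
        {"outcome": "guesser_response", "term": t, "value": v}
        for t, v in gt.response_coefficients.items()
    ]
    rows += [
        {"outcome": "speaker_veracity", "term": t, "value": v}
        for t, v in gt.cue_veracity_log_odds.items()
    ]
    return pd.DataFrame(rows, columns=["outcome", "term", "value"])


# ---------------------------------------------------------------------------
# Config file round-trip (nested key/value text)
# ---------------------------------------------------------------------------

def config_to_yaml(cfg: GeneratorConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(dataclasses.asdict(cfg)), fh, sort_keys=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_from_yaml(path) -> GeneratorConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> GeneratorConfig:
    kwargs = dict(raw)
    if "cue_model" in kwargs:
        kwargs["cue_model"] = {
            k: CueParams(**v) if isinstance(v, dict) else v
            for k, v in kwargs["cue_model"].items()
        }
    for key, cls in [
        ("response_model", ResponseModel),
        ("continuous_model", ContinuousModel),
        ("trajectory_model", TrajectoryModel),
        ("disambiguation_model", DisambiguationModel),
    ]:
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return GeneratorConfig(**kwargs).validate()
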