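"""Time-locked analysis of guessers' mouse-cursor trajectories.

Cursor samples (nominally 50 Hz) are binned into 20 ms bins relative to
the utterance's disambiguation point (bin 0 starts at it).  For each bin
the x-axis pixels travelled toward the referent (the object the speaker
named) and toward the distractor are accumulated; the proportion-of-
movement measure for an object is the cumulative x distance moved toward
it divided by the total cumulative distance travelled so far.  The model
DV is the difference between the empirical logits of the two proportions,

    elogit(p) = ln((p N + c) / ((1 - p) N + c)),   N = cumulative px,

with smoothing constant c (default 0.5), so the difference reduces to
2 ln((d_ref + c) / (d_dist + c)).  The DV is modelled over the window
0-800 ms post-disambiguation as DV ~ time x cue with by-subject and
by-item random intercepts and slopes for both predictors; mean +/- SE
proportion curves per condition are produced out to 4000 ms for plotting.

Only x displacement enters numerator and denominator by default; a
configurable mode adds |dy| to the denominator.  Bins before any movement
(zero cumulative distance) carry DV = 0 and a zero-movement flag; a
drop-bin mode is available.  Time enters the model centred on the window
midpoint and scaled to seconds, which sets the scale of the time and
interaction coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import apply_exclusions, collapse_categories
from .glmm import FitResult, ModelSpec
from .lmm import fit_lmm

__all__ = [
    "CursorTrack",
    "BinnedTrajectory",
    "read_cursor_logs",
    "write_cursor_logs",
    "assemble_tracks",
    "bin_track",
    "elogit_difference",
    "trajectory_analysis",
    "TrajectoryAnalysis",
]

CURSOR_COLUMNS = ("dyad_id", "trial_index", "t_ms", "x_px", "y_px")


@dataclass
class CursorTrack:
    """Timestamped cursor samples for one trial."""

    trial_key: tuple  # (dyad_id, trial_index)
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    referent_side: str  # {"left", "right"}
    disambiguation_ms: float

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if len(self.t_ms) < 2:
            raise ValueError(f"track {self.trial_key}: need at least 2 samples")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError(f"track {self.trial_key}: timestamps must be strictly increasing")
        if self.referent_side not in ("left", "right"):
            raise ValueError("referent_side must be 'left' or 'right'")


@dataclass
class BinnedTrajectory:
    """Per-20 ms-bin directional distances and cumulative proportions."""

    trial_key: tuple
    time_rel: np.ndarray  # bin start, ms relative to disambiguation
    d_ref: np.ndarray
    d_dist: np.ndarray
    cum_total: np.ndarray
    p_ref: np.ndarray  # NaN where cum_total == 0
    p_dist: np.ndarray
    zero_movement: np.ndarray  # bool per bin
    bin_ms: float
    cum_ref: np.ndarray = field(default=None)
    cum_dist: np.ndarray = field(default=None)


def read_cursor_logs(path) -> pd.DataFrame:
    """Read a long-format cursor log (dyad_id, trial_index, t_ms, x_px, y_px)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"dyad_id": str})
    missing = [c for c in CURSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cursor log missing column(s): {', '.join(missing)}")
    return df


def write_cursor_logs(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def referent_side_of(row) -> str:
    """Side of the object the speaker named (target side if truthful)."""
    if row["veracity"] == "truth":
        return row["target_side"]
    return "left" if row["target_side"] == "right" else "right"


def assemble_tracks(cursor: pd.DataFrame, trials: pd.DataFrame) -> dict:
    """Join cursor samples with trial metadata into CursorTrack objects.

    Trials without a disambiguation point are skipped (they are excluded
    from the time-locked analysis anyway).
    """
    side = {}
    disamb = {}
    for row in trials[["dyad_id", "trial_index", "veracity", "target_side",
                       "disambiguation_ms"]].itertuples(index=False):
        key = (row.dyad_id, row.trial_index)
        if pd.isna(row.disambiguation_ms):
            continue
        flip = row.target_side if row.veracity == "truth" else (
            "left" if row.target_side == "right" else "right"
        )
        side[key] = flip
        disamb[key] = float(row.disambiguation_ms)

    tracks = {}
    for key, grp in cursor.groupby(["dyad_id", "trial_index"], sort=False):
        if key not in side:
            continue
        grp = grp.sort_values("t_ms")
        tracks[key] = CursorTrack(
            trial_key=key,
            t_ms=grp["t_ms"].to_numpy(float),
            x_px=grp["x_px"].to_numpy(float),
            y_px=grp["y_px"].to_numpy(float),
            referent_side=side[key],
            disambiguation_ms=disamb[key],
        )
    return tracks


def bin_track(track: CursorTrack, bin_ms: float = 20.0, denominator: str = "x") -> BinnedTrajectory:
    """Bin a cursor track into fixed-width bins relative to disambiguation.

    Each inter-sample displacement is assigned to the bin containing the
    later sample.  Positive x displacement toward the referent's side of
    the screen accrues to ``d_ref``, displacement toward the other side to
    ``d_dist``.  ``denominator="xy"`` additionally counts |dy| in the
    total (denominator only).
    """
    if denominator not in ("x", "xy"):
        raise ValueError("denominator must be 'x' or 'xy'")
    t0 = track.disambiguation_ms
    if not (track.t_ms[0] <= t0 <= track.t_ms[-1]):
        raise ValueError(
            f"track {track.trial_key}: disambiguation point {t0} outside sampled range"
        )
    dx = np.diff(track.x_px)
    dy = np.diff(track.y_px)
    t_later = track.t_ms[1:]
    sign = 1.0 if track.referent_side == "right" else -1.0
    toward_ref = np.where(sign * dx > 0, np.abs(dx), 0.0)
    toward_dist = np.where(sign * dx < 0, np.abs(dx), 0.0)

    bins = np.floor((t_later - t0) / bin_ms).astype(int)
    b_min, b_max = int(bins.min()), int(bins.max())
    nb = b_max - b_min + 1
    d_ref = np.bincount(bins - b_min, weights=toward_ref, minlength=nb)
    d_dist = np.bincount(bins - b_min, weights=toward_dist, minlength=nb)
    extra = np.bincount(bins - b_min, weights=np.abs(dy), minlength=nb) if denominator == "xy" else 0.0

    cum_ref = np.cumsum(d_ref)
    cum_dist = np.cumsum(d_dist)
    cum_total = cum_ref + cum_dist + (np.cumsum(extra) if denominator == "xy" else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(cum_total > 0, cum_ref / cum_total, np.nan)
        p_dist = np.where(cum_total > 0, cum_dist / cum_total, np.nan)
    return BinnedTrajectory(
        trial_key=track.trial_key,
        time_rel=(np.arange(b_min, b_max + 1) * bin_ms),
        d_ref=d_ref,
        d_dist=d_dist,
        cum_total=cum_total,
        p_ref=p_ref,
        p_dist=p_dist,
        zero_movement=cum_total == 0,
        bin_ms=bin_ms,
        cum_ref=cum_ref,
        cum_dist=cum_dist,
    )


def elogit_difference(traj: BinnedTrajectory, c: float = 0.5, zero_mode: str = "zero") -> np.ndarray:
    """Per-bin e-logit difference DV: elogit(p_ref) - elogit(p_dist).

    With N the cumulative distance and the p_ref + p_dist = 1 identity
    (x-only denominator) this equals 2 ln((cum_ref + c)/(cum_dist + c)).
    Zero-movement bins carry 0 (``zero_mode="zero"``) or NaN (``"drop"``).
    """
    if c <= 0:
        raise ValueError("smoothing constant c must be positive")
    if zero_mode not in ("zero", "drop"):
        raise ValueError("zero_mode must be 'zero' or 'drop'")
    N = traj.cum_total
    yr = traj.cum_ref
    yd = traj.cum_dist
    with np.errstate(invalid="ignore", divide="ignore"):
        dv = np.log((yr + c) / (N - yr + c)) - np.log((yd + c) / (N - yd + c))
    fill = 0.0 if zero_mode == "zero" else np.nan
    return np.where(traj.zero_movement, fill, dv)


_FOCAL = {"pause": ("pauses", "mouse_pause"), "affect_display": ("affect_display", "mouse_affect")}


@dataclass
class TrajectoryAnalysis:
    fit: FitResult
    curves: pd.DataFrame
    table: pd.DataFrame
    n_trials: int
    exclusion_log: pd.DataFrame
    meta: dict


def trajectory_analysis(
    tracks: dict,
    trials: pd.DataFrame,
    cue: str = "pause",
    window_ms: tuple = (0.0, 800.0),
    bin_ms: float = 20.0,
    c: float = 0.5,
    curve_max_ms: float = 4000.0,
    denominator: str = "x",
    zero_mode: str = "zero",
) -> TrajectoryAnalysis:
    """Time-locked trajectory analysis for a focal cue (pause / affect).

    Applies the mouse-analysis exclusions, bins every retained trial's
    track, fits DV ~ time x cue with by-subject and by-item random
    intercepts and slopes for both predictors over the analysis window,
    and returns per-condition mean +/- SE proportion curves to
    ``curve_max_ms``.
    """
    if cue not in _FOCAL:
        raise ValueError(f"cue must be one of {sorted(_FOCAL)}")
    cue_col, analysis = _FOCAL[cue]
    trials = collapse_categories(trials) if cue_col not in trials.columns else trials
    included, log = apply_exclusions(trials, analysis)

    rows, curve_rows = [], []
    n_per_level = {0: 0, 1: 0}
    t_lo, t_hi = window_ms
    mid = 0.5 * (t_lo + t_hi)
    cols = ["dyad_id", "trial_index", "item_id"]
    for dyad_id, trial_index, item_id, cue_val in included[cols + [cue_col]].itertuples(index=False):
        key = (dyad_id, trial_index)
        if key not in tracks:
            continue
        traj = bin_track(tracks[key], bin_ms=bin_ms, denominator=denominator)
        dv = elogit_difference(traj, c=c, zero_mode=zero_mode)
        level = int(cue_val)
        n_per_level[level] += 1
        in_win = (traj.time_rel >= t_lo) & (traj.time_rel < t_hi)
        nw = int(in_win.sum())
        rows.append(
            pd.DataFrame(
                {
                    "dyad_id": np.repeat(dyad_id, nw),
                    "item_id": np.repeat(item_id, nw),
                    "trial_index": np.repeat(trial_index, nw),
                    "time_ms": traj.time_rel[in_win],
                    "time": (traj.time_rel[in_win] - mid) / 1000.0,  # centred, seconds
                    "cue": np.repeat(level, nw),
                    "elogit_diff": dv[in_win],
                }
            )
        )
        in_curve = (traj.time_rel >= 0) & (traj.time_rel <= curve_max_ms)
        curve_rows.append(
            pd.DataFrame(
                {
                    "time_rel": traj.time_rel[in_curve],
                    "cue": level,
                    "p_ref": traj.p_ref[in_curve],
                    "p_dist": traj.p_dist[in_curve],
                }
            )
        )

    if min(n_per_level.values()) < 2:
        raise ValueError(
            f"need at least 2 trials per {cue} level, got {n_per_level}"
        )
    table = pd.concat(rows, ignore_index=True)
    spec = ModelSpec(
        outcome="trajectory_dv",
        fixed_effects=("time", "cue", "time:cue"),
        random=(
            ("dyad_id", ("intercept", "time", "cue")),
            ("item_id", ("intercept", "time", "cue")),
        ),
        family="gaussian",
    )
    fit = fit_lmm(spec, table)

    cdf = pd.concat(curve_rows, ignore_index=True)
    curves = (
        cdf.groupby(["cue", "time_rel"])
        .agg(
            p_ref=("p_ref", "mean"),
            p_dist=("p_dist", "mean"),
            se_ref=("p_ref", "sem"),
            se_dist=("p_dist", "sem"),
            n=("p_ref", "size"),
        )
        .reset_index()
    )
    return TrajectoryAnalysis(
        fit=fit,
        curves=curves,
        table=table,
        n_trials=sum(n_per_level.values()),
        exclusion_log=log,
        meta={
            "cue": cue,
            "window_ms": list(window_ms),
            "bin_ms": bin_ms,
            "elogit_c": c,
            "denominator": denominator,
            "zero_mode": zero_mode,
            "time_coding": f"centred on {mid} ms, scaled to seconds",
            "n_per_level": n_per_level,
        },
    )
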