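"""Trial-level data model for the dyadic deception game.

One row of a trial table describes a single utterance: the speaker's
veracity (truth or lie), the guesser's response (click on referent =
truth judgement), binary annotations for seven disfluency types and
eight raw gesture types, function-based gesture categories, three
continuous speech measures, and the disambiguation point used to
time-lock the mouse analysis.

This module owns reading/writing of trial tables, the collapsing of raw
disfluency flags into the four analysis categories, the exclusion rules
for the different analyses, descriptive statistics, two-rater Cohen's
kappa, and the PCA speech-rate composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DISFLUENCY_FLAGS",
    "RAW_GESTURE_FLAGS",
    "GESTURE_CATEGORIES",
    "SPEECH_CATEGORIES",
    "TrialRecord",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "collapse_categories",
    "apply_exclusions",
    "Descriptives",
    "descriptives",
    "KappaResult",
    "cohens_kappa",
    "SpeechRateComposite",
    "SpeechRateResult",
    "speech_rate_composite",
]

#: The seven raw disfluency annotations.
DISFLUENCY_FLAGS = (
    "filled_pause",
    "silent_pause",
    "repetition",
    "restart",
    "substitution",
    "addition",
    "prolongation",
)

#: The eight raw gesture annotations (prefixed to avoid clashing with the
#: function-based category of the same name, eye contact).
RAW_GESTURE_FLAGS = (
    "gest_head",
    "gest_hand",
    "gest_body",
    "gest_shoulder",
    "gest_lip_mouth",
    "gest_eyebrow",
    "gest_smile_laugh",
    "gest_eye_contact",
)

#: Function-based gesture categories.  These are annotation-level inputs:
#: whether e.g. a hand movement is an adaptor or an illustrator is a human
#: judgement about its communicative function, so categories are carried in
#: the data rather than derived mechanically from the raw type flags.
GESTURE_CATEGORIES = ("adaptor", "illustrator", "affect_display", "eye_contact")

#: Collapsed disfluency categories used as model predictors.
SPEECH_CATEGORIES = ("pauses", "repetitions", "repairs", "prolongations")

_CATEGORICAL_LEVELS = {
    "target_side": ("left", "right"),
    "treasure": ("gold", "silver"),
    "veracity": ("truth", "lie"),
    "response": ("truth", "lie"),
}

_BOOL_COLUMNS = (
    DISFLUENCY_FLAGS
    + RAW_GESTURE_FLAGS
    + GESTURE_CATEGORIES
    + ("consistent_commitment", "gesture_data_present")
)

_NUMERIC_COLUMNS = (
    "utterance_duration_ms",
    "silent_pause_duration_ms",
    "syllable_rate",
)

#: Columns that may be empty (cue absent / not determinable).
_OPTIONAL_NUMERIC_COLUMNS = ("disambiguation_ms", "pause_onset_ms", "affect_onset_ms")

REQUIRED_COLUMNS = (
    ("dyad_id", "trial_index", "item_id")
    + tuple(_CATEGORICAL_LEVELS)
    + _BOOL_COLUMNS
    + _NUMERIC_COLUMNS
    + _OPTIONAL_NUMERIC_COLUMNS
)


@dataclass
class TrialRecord:
    """Single-utterance view of one trial-table row."""

    dyad_id: str
    trial_index: int
    item_id: str
    target_side: str
    treasure: str
    veracity: str
    response: str
    filled_pause: int
    silent_pause: int
    repetition: int
    restart: int
    substitution: int
    addition: int
    prolongation: int
    gest_head: int
    gest_hand: int
    gest_body: int
    gest_shoulder: int
    gest_lip_mouth: int
    gest_eyebrow: int
    gest_smile_laugh: int
    gest_eye_contact: int
    adaptor: int
    illustrator: int
    affect_display: int
    eye_contact: int
    consistent_commitment: int
    gesture_data_present: int
    utterance_duration_ms: float
    silent_pause_duration_ms: float
    syllable_rate: float
    disambiguation_ms: float | None = None
    pause_onset_ms: float | None = None
    affect_onset_ms: float | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "TrialRecord":
        kwargs = {}
        for f in dc_fields(cls):
            v = row[f.name]
            if f.name in _OPTIONAL_NUMERIC_COLUMNS and pd.isna(v):
                v = None
            kwargs[f.name] = v
        return cls(**kwargs)


class TrialTableError(ValueError):
    """Malformed trial table: missing columns or unparseable rows.

    ``row_errors`` lists (1-based data row number, message) pairs.
    """

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        if self.row_errors:
            detail = "; ".join(f"row {i}: {m}" for i, m in self.row_errors[:20])
            message = f"{message}: {detail}"
        super().__init__(message)


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_trials(path) -> pd.DataFrame:
    """Read a trial table (comma- or tab-delimited UTF-8 text).

    Returns a validated DataFrame with one row per utterance.  Rows with
    unparseable required fields are rejected collectively with row-numbered
    diagnostics; a missing required column raises immediately.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"dyad_id": str, "item_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate levels, booleans and numeric fields; raise with diagnostics."""
    df = df.copy()
    errors: list[tuple[int, str]] = []

    for col, levels in _CATEGORICAL_LEVELS.items():
        df[col] = df[col].astype(str).str.strip()
        bad = ~df[col].isin(levels)
        for i in df.index[bad]:
            errors.append(
                (int(i) + 1, f"invalid {col} {df.at[i, col]!r}; allowed: {{{', '.join(levels)}}}")
            )

    for col in _BOOL_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = ~coerced.isin([0, 1])
        for i in df.index[bad]:
            errors.append((int(i) + 1, f"{col} must be 0/1, got {df.at[i, col]!r}"))
        df[col] = coerced.fillna(-1).astype(int)

    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[coerced.isna()]:
            errors.append((int(i) + 1, f"{col} is not numeric: {df.at[i, col]!r}"))
        df[col] = coerced

    for col in _OPTIONAL_NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    if errors:
        raise TrialTableError("trial table contains invalid rows", errors)

    # Internal-consistency checks that indicate a corrupted table.
    bad_pause = (df["silent_pause"] == 0) & (df["silent_pause_duration_ms"] != 0)
    bad_dur = df["silent_pause_duration_ms"] > df["utterance_duration_ms"]
    for i in df.index[bad_pause]:
        errors.append((int(i) + 1, "silent_pause flag is 0 but silent_pause_duration_ms != 0"))
    for i in df.index[bad_dur]:
        errors.append((int(i) + 1, "silent_pause_duration_ms exceeds utterance_duration_ms"))
    if errors:
        raise TrialTableError("trial table violates invariants", errors)
    return df


def write_trials(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a trial table as delimited UTF-8 text (round-trips read_trials)."""
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Cue-category collapsing
# ---------------------------------------------------------------------------

def collapse_categories(data):
    """Collapse raw disfluency flags into the four analysis categories.

    pauses = filled OR silent pause; repetitions = repetition;
    repairs = restart OR substitution OR addition; prolongations =
    prolongation.  Binary coding ignores multiplicity.  Gesture categories
    are annotation-level inputs and are copied through unchanged.

    Accepts a trial DataFrame (returns a copy with the category columns
    added) or a single :class:`TrialRecord` / Series (returns a dict).
    """
    if isinstance(data, TrialRecord):
        row = {f.name: getattr(data, f.name) for f in dc_fields(TrialRecord)}
        return _collapse_row(row)
    if isinstance(data, pd.Series):
        return _collapse_row(data)
    df = data.copy()
    df["pauses"] = ((df["filled_pause"] == 1) | (df["silent_pause"] == 1)).astype(int)
    df["repetitions"] = df["repetition"].astype(int)
    df["repairs"] = (
        (df["restart"] == 1) | (df["substitution"] == 1) | (df["addition"] == 1)
    ).astype(int)
    df["prolongations"] = df["prolongation"].astype(int)
    return df


def _collapse_row(row) -> dict:
    out = {
        "pauses": int(bool(row["filled_pause"]) or bool(row["silent_pause"])),
        "repetitions": int(bool(row["repetition"])),
        "repairs": int(
            bool(row["restart"]) or bool(row["substitution"]) or bool(row["addition"])
        ),
        "prolongations": int(bool(row["prolongation"])),
    }
    for g in GESTURE_CATEGORIES:
        out[g] = int(bool(row[g]))
    return out


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

ANALYSES = ("cue_models", "mouse_pause", "mouse_affect")


def apply_exclusions(df: pd.DataFrame, analysis: str):
    """Apply the exclusion rules for a given analysis.

    ``cue_models`` drops trials on which the speaker was inconsistent in
    their commitment to the treasure's location.  The mouse analyses
    additionally drop trials without a codable disambiguation point and
    trials on which the focal cue (a pause, or an affect display) occurred
    only after the disambiguation point; the affect analysis also requires
    gesture (video) data.

    Returns ``(included, log)`` where ``log`` has one row per excluded
    trial with columns (dyad_id, trial_index, rule, analysis).  Rules are
    evaluated independently, so the included set does not depend on rule
    order; a trial failing several rules is logged once per rule.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")

    df = df if "pauses" in df.columns else collapse_categories(df)
    rules: dict[str, pd.Series] = {
        "inconsistent_commitment": df["consistent_commitment"] == 0,
    }
    if analysis in ("mouse_pause", "mouse_affect"):
        rules["no_disambiguation_point"] = df["disambiguation_ms"].isna()
    if analysis == "mouse_pause":
        rules["cue_post_disambiguation"] = (
            (df["pauses"] == 1)
            & df["disambiguation_ms"].notna()
            & (df["pause_onset_ms"] > df["disambiguation_ms"])
        )
    if analysis == "mouse_affect":
        rules["no_gesture_data"] = df["gesture_data_present"] == 0
        rules["cue_post_disambiguation"] = (
            (df["affect_display"] == 1)
            & df["disambiguation_ms"].notna()
            & (df["affect_onset_ms"] > df["disambiguation_ms"])
        )

    log_rows = []
    drop = pd.Series(False, index=df.index)
    for rule, mask in rules.items():
        mask = mask.fillna(False).astype(bool)
        drop |= mask
        for i in df.index[mask]:
            log_rows.append(
                {
                    "dyad_id": df.at[i, "dyad_id"],
                    "trial_index": df.at[i, "trial_index"],
                    "rule": rule,
                    "analysis": analysis,
                }
            )
    log = pd.DataFrame(log_rows, columns=["dyad_id", "trial_index", "rule", "analysis"])
    return df.loc[~drop].copy(), log


def exclusion_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Count excluded trials per rule."""
    if log.empty:
        return pd.DataFrame(columns=["analysis", "rule", "n_excluded"])
    out = (
        log.groupby(["analysis", "rule"], as_index=False)
        .size()
        .rename(columns={"size": "n_excluded"})
    )
    return out


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

@dataclass
class Descriptives:
    """Dataset-level rates (percent) with per-speaker dispersion.

    ``accuracy_overall`` decomposes exactly on counts:
    P(correct) = P(truth)·P(correct|truth) + P(lie)·P(correct|lie).
    Per-speaker SE is the standard error of the speaker-level percentages
    (n = number of speakers).
    """

    n_trials: int
    n_speakers: int
    truth_rate: float
    perceived_truth_rate: float
    accuracy_overall: float
    accuracy_given_truth: float
    accuracy_given_lie: float
    per_speaker: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        return d


def _speaker_stats(values: pd.Series) -> dict:
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"se": se, "min": float(np.min(vals)), "max": float(np.max(vals))}


def descriptives(df: pd.DataFrame) -> Descriptives:
    """Truth bias, perceived-truth bias and discrimination accuracy.

    Rates are percentages over the supplied (already-filtered) trials.
    """
    if len(df) == 0:
        raise ValueError("descriptives requires at least one trial")
    truth = (df["veracity"] == "truth").astype(int)
    resp_truth = (df["response"] == "truth").astype(int)
    correct = (df["veracity"] == df["response"]).astype(int)

    by = df["dyad_id"]
    per_speaker = {
        "truth_rate": _speaker_stats(100.0 * truth.groupby(by).mean()),
        "perceived_truth_rate": _speaker_stats(100.0 * resp_truth.groupby(by).mean()),
        "accuracy": _speaker_stats(100.0 * correct.groupby(by).mean()),
    }

    n_truth = int(truth.sum())
    n_lie = len(df) - n_truth
    acc_truth = float(correct[truth == 1].mean()) if n_truth else float("nan")
    acc_lie = float(correct[truth == 0].mean()) if n_lie else float("nan")
    return Descriptives(
        n_trials=len(df),
        n_speakers=int(by.nunique()),
        truth_rate=100.0 * float(truth.mean()),
        perceived_truth_rate=100.0 * float(resp_truth.mean()),
        accuracy_overall=100.0 * float(correct.mean()),
        accuracy_given_truth=100.0 * acc_truth,
        accuracy_given_lie=100.0 * acc_lie,
        per_speaker=per_speaker,
    )


# ---------------------------------------------------------------------------
# Interrater agreement
# ---------------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    n_items: int
    observed_agreement: float
    expected_agreement: float


def cohens_kappa(coder_a, coder_b) -> KappaResult:
    """Two-rater Cohen's kappa with marginal-product expected agreement.

    kappa = (p_o - p_e) / (1 - p_e).  Undefined when both coders assign a
    single identical category to every item (p_e = 1).
    """
    a = np.asarray(coder_a)
    b = np.asarray(coder_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coder vectors must be 1-d and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement is 1 (constant identical codings)")
    return KappaResult(
        kappa=(p_o - p_e) / (1.0 - p_e),
        n_items=n,
        observed_agreement=p_o,
        expected_agreement=p_e,
    )


# ---------------------------------------------------------------------------
# PCA speech-rate composite
# ---------------------------------------------------------------------------

class SpeechRateComposite(TransformerMixin, BaseEstimator):
    """First principal component of the three continuous speech measures.

    The PCA is computed on the correlation matrix (i.e. on standardized
    utterance duration, silent-pause duration and syllable rate); the
    composite score for a trial is the projection of its standardized
    measures onto the unit-norm first eigenvector.  The component sign is
    fixed so that syllable rate loads positively: a higher score means
    faster, more fluent speech.

    Attributes
    ----------
    loadings_ : ndarray of shape (3,)
        Unit-norm first eigenvector of the correlation matrix.
    eigenvalue_ : float
        Leading eigenvalue λ1 of the correlation matrix.
    variance_share_ : float
        λ1 / 3, the fraction of total standardized variance explained.
    """

    def __init__(self, columns=("utterance_duration_ms", "silent_pause_duration_ms", "syllable_rate")):
        self.columns = columns

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.columns)]
        M = np.asarray(X, dtype=float)
        if M.ndim != 2 or M.shape[1] != len(self.columns):
            raise ValueError(f"expected {len(self.columns)} measure columns")
        return M

    def fit(self, X, y=None):
        M = self._matrix(X)
        if M.shape[0] < 3:
            raise ValueError("need at least 3 complete trials")
        sd = M.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if s == 0 or not np.isfinite(s):
                raise ValueError(f"measure {self.columns[j]!r} has zero variance")
        self.mean_ = M.mean(axis=0)
        self.scale_ = sd
        corr = np.corrcoef(M, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        self.eigenvalues_ = evals[::-1].copy()
        v = evecs[:, -1]
        if v[-1] < 0:  # orient: syllable rate loads positively
            v = -v
        self.loadings_ = v
        self.eigenvalue_ = float(evals[-1])
        self.variance_share_ = float(evals[-1] / corr.shape[0])
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        M = self._matrix(X)
        Z = (M - self.mean_) / self.scale_
        return Z @ self.loadings_


@dataclass
class SpeechRateResult:
    loadings: np.ndarray
    eigenvalue: float
    variance_share: float
    scores: np.ndarray


def speech_rate_composite(durations, pause_durations, syllable_rates) -> SpeechRateResult:
    """Functional wrapper over :class:`SpeechRateComposite`."""
    M = np.column_stack(
        [np.asarray(durations, float), np.asarray(pause_durations, float), np.asarray(syllable_rates, float)]
    )
    est = SpeechRateComposite(columns=("utterance_duration_ms", "silent_pause_duration_ms", "syllable_rate"))
    scores = est.fit(M).transform(M)
    return SpeechRateResult(
        loadings=est.loadings_,
        eigenvalue=est.eigenvalue_,
        variance_share=est.variance_share_,
        scores=scores,
    )
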