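import numpy as np
import pandas as pd
import pytest

from veracue.data import collapse_categories, validate_trials
from veracue.simulate import GeneratorConfig, generate_dataset


def make_trial_row(**over):
    """One well-formed trial-table row with all cues absent."""
    row = {
        "dyad_id": "d001",
        "trial_index": 1,
        "item_id": "item001",
        "target_side": "left",
        "treasure": "gold",
        "veracity": "truth",
        "response": "truth",
        "filled_pause": 0,
        "silent_pause": 0,
        "repetition": 0,
        "restart": 0,
        "substitution": 0,
        "addition": 0,
        "prolongation": 0,
        "gest_head": 0,
        "gest_hand": 0,
        "gest_body": 0,
        "gest_shoulder": 0,
        "gest_lip_mouth": 0,
        "gest_eyebrow": 0,
        "gest_smile_laugh": 0,
        "gest_eye_contact": 0,
        "adaptor": 0,
        "illustrator": 0,
        "affect_display": 0,
        "eye_contact": 0,
        "consistent_commitment": 1,
        "gesture_data_present": 1,
        "utterance_duration_ms": 3000.0,
        "silent_pause_duration_ms": 0.0,
        "syllable_rate": 3.8,
        "disambiguation_ms": 1500.0,
        "pause_onset_ms": np.nan,
        "affect_onset_ms": np.nan,
    }
    row.update(over)
    return row


def make_trials(rows):
    return validate_trials(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (24 dyads x 48 trials)."""
    trials, cursor, gt = generate_dataset(GeneratorConfig(seed=123))
    return collapse_categories(trials), cursor, gt


@pytest.fixture(scope="session")
def default_trials(default_dataset):
    return default_dataset[0]
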