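import numpy as np
import pandas as pd
import pytest

from cuelearn.models import ModelSpec, Params
from cuelearn.synthdata import DesignSpec, default_population, simulate_cohort
from cuelearn.trialdata import TrialTable, make_table, normalize_ratings


def toy_trials(
    cues, levels=None, E=None, O=None, session=None, participant="p1", task="pain",
    cue_display=None, scale=1.0,
):
    """Hand-built single-subject trial table (unit scale by default)."""
    n = len(cues)
    levels = levels or [2] * n
    df = pd.DataFrame(
        {
            "participant_id": [participant] * n,
            "task": [task] * n,
            "session": session or [1] * n,
            "run": [1] * n,
            "trial_index": np.arange(1, n + 1),
            "cue_type": cues,
            "cue_display_mean": cue_display or [0.65 * scale if c == "high" else 0.35 * scale for c in cues],
            "stimulus_level": levels,
            "expectation_rating": E if E is not None else [0.5 * scale] * n,
            "perceptual_rating": O if O is not None else [0.5 * scale] * n,
        }
    )
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x 72 trials generated from the dual-rate carryover model."""
    pop = default_population("M3c", n_subjects=8)
    table, truth = simulate_cohort(DesignSpec(), pop, n_tasks=1, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def small_cohort_unit(small_cohort):
    table, truth = small_cohort
    return normalize_ratings(table), truth


@pytest.fixture
def m2a():
    return ModelSpec("M2a")


@pytest.fixture
def m3c():
    return ModelSpec("M3c")
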