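import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mediboot import TrialDataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_dataset(records, roles=None, transforms=None):
    """records: iterable of (subject_id, arm, timepoint, variable, value)."""
    df = pd.DataFrame(
        records, columns=["subject_id", "arm", "timepoint", "variable", "value"]
    )
    return TrialDataset(df, roles or {}, transforms or {})


def complete_two_arm(values_by_subject, variable="y", roles=None):
    """values_by_subject: {subject_id: (arm, y_baseline, y_followup)}."""
    records = []
    for sid, (arm, y0, y1) in values_by_subject.items():
        records.append((sid, arm, 0, variable, y0))
        records.append((sid, arm, 1, variable, y1))
    return make_dataset(records, roles or {variable: "outcome"})


@pytest.fixture
def did_toy():
    """Balanced complete 2-subjects-per-arm toy with cell means
    control 10 -> 12 and exercise 10 -> 15, so the difference-in-differences
    of cell means is (15 - 10) - (12 - 10) = 3."""
    return complete_two_arm(
        {
            "c1": (0, 9.5, 11.5),
            "c2": (0, 10.5, 12.5),
            "e1": (1, 9.0, 14.0),
            "e2": (1, 11.0, 16.0),
        }
    )


@pytest.fixture
def flat_toy():
    """Both arms identical at both timepoints: every contrast is zero."""
    return complete_two_arm(
        {
            "c1": (0, 10.0, 12.0),
            "c2": (0, 11.0, 13.0),
            "e1": (1, 10.0, 12.0),
            "e2": (1, 11.0, 13.0),
        }
    )
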