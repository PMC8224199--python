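"""Shared fixtures and helpers for the cohortsig test suite.

All randomness is seeded; hypothesis runs derandomized so the suite is
deterministic across machines and runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cohortsig import FeatureTable, SampleMetadata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# Simulation helpers emit alignment / panel warnings that are asserted where
# relevant; silence them globally to keep test output readable.
logging.getLogger("cohortsig").setLevel(logging.ERROR)


def make_table(values, feature_ids=None, sample_ids=None, is_count=True):
    arr = np.asarray(values)
    feature_ids = feature_ids or [f"F{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[1])]
    return FeatureTable(
        pd.DataFrame(arr, index=feature_ids, columns=sample_ids), is_count=is_count
    )


def make_meta(rows):
    """rows: iterable of (sample_id, subject_id, study_id, timepoint_months)."""
    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "study_id",
                                    "timepoint_months"])
    )


def paired_meta(n_subjects, timepoints=(0, 1), study="A"):
    rows = []
    for i in range(n_subjects):
        for t in timepoints:
            rows.append((f"{study}_{i}_m{t}", f"{study}_{i}", study, float(t)))
    return make_meta(rows)


@pytest.fixture
def tiny_counts():
    return make_table([[5, 0, 3], [0, 2, 1], [10, 8, 6]])


@pytest.fixture
def tiny_meta():
    return make_meta([
        ("s0", "p0", "A", 0.0),
        ("s1", "p0", "A", 1.0),
        ("s2", "p1", "A", 0.0),
    ])
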