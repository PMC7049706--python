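"""Shared fixtures: simulated fields processed once per session."""

from __future__ import annotations

import dataclasses

import pytest

import speckquant as sq


@pytest.fixture(scope="session")
def default_params() -> sq.FieldParams:
    return sq.FieldParams()


@pytest.fixture(scope="session")
def field_17(default_params):
    """One default field at a fixed seed, with its truth."""
    return sq.generate_field(default_params, 17)


@pytest.fixture(scope="session")
def result_17(field_17):
    stack, truth = field_17
    return sq.process_field(stack), truth


@pytest.fixture(scope="session")
def batch(default_params):
    """Ten default fields (seeds 0..9), each fully processed.

    Returns a list of (FieldResult, GroundTruth) used by ground-truth
    recovery and invariant checks.
    """
    out = []
    for seed in range(10):
        stack, truth = sq.generate_field(default_params, seed)
        out.append((sq.process_field(stack), truth))
    return out


@pytest.fixture(scope="session")
def cohort_summaries(default_params):
    """WT-like vs elevated-cytoplasmic cohorts, ~200 cells per group.

    Cytoplasmic fractions 0.05 vs 0.30, 20 fields of 10 cells each per
    group; per-cell summaries concatenated per group.
    """
    import pandas as pd

    params_b = dataclasses.replace(
        default_params, cytoplasmic_fraction={"malat1": 0.30}
    )
    group_a, group_b = sq.generate_cohort(default_params, params_b, n_fields=20, seed=42)
    summaries = []
    for group in (group_a, group_b):
        frames = []
        for f in group:
            res = sq.process_field(f.stack)
            s = res.cell_summary.copy()
            s["field"] = f.field_index
            frames.append(s)
        summaries.append(pd.concat(frames, ignore_index=True))
    return summaries[0], summaries[1]
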