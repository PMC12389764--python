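"""Shared fixtures: profiles, a known-good synthetic layout, and the
(expensive) defective/clean fixture pair evaluated once per session."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from ergocab.core import default_profile
from ergocab.fusion import compare_layouts
from ergocab.pipeline import Participant, evaluate_layout
from ergocab.synthetic import (
    NEUTRAL_TEMPLATE,
    LayoutSpec,
    generate_layout,
    paperlike_fixture,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p50():
    return default_profile("P50")


@pytest.fixture(scope="session")
def allgood():
    """Layout in which every control is visible, recognizable, unoccluded,
    and reachable for its class (known ground truth)."""
    return generate_layout(LayoutSpec(), seed=5)


@pytest.fixture(scope="session")
def neutral_cohort():
    parts = [Participant(f"S{i}", default_profile("P50")) for i in range(3)]
    samples = [
        dataclasses.replace(NEUTRAL_TEMPLATE, participant_id=p.id) for p in parts
    ]
    return parts, samples


@pytest.fixture(scope="session")
def fixture_bundle():
    """Defective/clean layout pair evaluated over the shared cohort."""
    (bad, bad_truth), (clean, clean_truth), (parts, samples) = paperlike_fixture()
    res_bad = evaluate_layout(bad, samples, parts)
    res_clean = evaluate_layout(clean, samples, parts)
    report = compare_layouts(res_bad, res_clean)
    return {
        "bad": bad,
        "clean": clean,
        "bad_truth": bad_truth,
        "clean_truth": clean_truth,
        "participants": parts,
        "samples": samples,
        "res_bad": res_bad,
        "res_clean": res_clean,
        "report": report,
    }
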