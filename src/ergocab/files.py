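"""Structured text formats: layout and anthropometry files (JSON dialect),
participant rosters, and evaluation/comparison reports.

All on-disk artefacts are plain text; numeric payloads are serialised at
full precision (display rounding belongs to the CLI layer).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import (
    AnthropometricProfile,
    CockpitLayout,
    ControlPoint,
    Occluder,
    RigidTransform,
)
from .fusion import ComparisonReport, EvaluationResult
from .pipeline import Participant

__all__ = [
    "save_layout",
    "load_layout",
    "save_anthropometry",
    "load_anthropometry",
    "save_participants",
    "load_participants",
    "result_to_dict",
    "save_result",
    "save_comparison",
]

_FRAME_KEYS = ("eye_from_cab", "shoulder_from_cab", "hip_from_cab")

_PROFILE_FIELDS = (
    "upper_arm_len",
    "forearm_len",
    "trunk_len",
    "thigh_len",
    "shank_len",
    "body_weight_force",
    "upper_body_fraction",
    "extensor_lever",
    "percentile_label",
)


def _transform_to_dict(t: RigidTransform) -> dict:
    return {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()}


def _transform_from_dict(d: dict, where: str) -> RigidTransform:
    try:
        return RigidTransform(np.array(d["rotation"]), np.array(d["translation"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid rigid transform under {where!r}: {exc}") from exc


def save_layout(layout: CockpitLayout, path) -> None:
    doc = {
        "controls": [
            {
                "id": c.id,
                "position": c.position.tolist(),
                "limb": c.limb,
                "ops_per_minute": c.ops_per_minute,
                "color": c.color,
                "safety_critical": c.safety_critical,
            }
            for c in layout.controls
        ],
        "occluders": [
            {
                "id": o.id,
                "center": o.center.tolist(),
                "normal": o.normal.tolist(),
                "half_extents": o.half_extents.tolist(),
            }
            for o in layout.occluders
        ],
        "frames": {
            k: _transform_to_dict(getattr(layout, k)) for k in _FRAME_KEYS
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_layout(path) -> CockpitLayout:
    """Read and validate a layout document (keys: controls, occluders, frames)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"layout file not found: {path}")
    doc = json.loads(path.read_text())
    for key in ("controls", "occluders", "frames"):
        if key not in doc:
            raise ValueError(f"layout file {path} is missing top-level key {key!r}")
    controls = [
        ControlPoint(
            id=str(c["id"]),
            position=c["position"],
            limb=c.get("limb", "upper"),
            ops_per_minute=float(c.get("ops_per_minute", 1.0)),
            color=c.get("color", "none"),
            safety_critical=bool(c.get("safety_critical", False)),
        )
        for c in doc["controls"]
    ]
    occluders = [
        Occluder(
            id=str(o["id"]),
            center=o["center"],
            normal=o["normal"],
            half_extents=o["half_extents"],
        )
        for o in doc["occluders"]
    ]
    frames = {
        k: _transform_from_dict(doc["frames"][k], k)
        for k in _FRAME_KEYS
        if k in doc["frames"]
    }
    return CockpitLayout(controls=controls, occluders=occluders, **frames)


def save_anthropometry(profile: AnthropometricProfile, path) -> None:
    Path(path).write_text(
        json.dumps({f: getattr(profile, f) for f in _PROFILE_FIELDS}, indent=2)
    )


def load_anthropometry(path) -> AnthropometricProfile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"anthropometry file not found: {path}")
    doc = json.loads(path.read_text())
    unknown = set(doc) - set(_PROFILE_FIELDS)
    if unknown:
        raise ValueError(f"unknown anthropometry fields: {sorted(unknown)}")
    return AnthropometricProfile(**doc)


def save_participants(participants: list[Participant], path) -> None:
    doc = [
        {
            "id": p.id,
            "profile": {f: getattr(p.profile, f) for f in _PROFILE_FIELDS},
            "landmark_offset": list(p.landmark_offset),
        }
        for p in participants
    ]
    Path(path).write_text(json.dumps(doc, indent=2))


def load_participants(path) -> list[Participant]:
    doc = json.loads(Path(path).read_text())
    return [
        Participant(
            id=str(d["id"]),
            profile=AnthropometricProfile(**d["profile"]),
            landmark_offset=tuple(d.get("landmark_offset", (0.0, 0.0, 0.0))),
        )
        for d in doc
    ]


def result_to_dict(result: EvaluationResult) -> dict:
    return {
        "M": result.m_total,
        "M_sd": result.m_sd,
        "weights": result.weights,
        "domains": list(result.domains),
        "summary": result.summary(),
        "na_ledger": result.na_ledger,
    }


def save_result(result: EvaluationResult, out_dir) -> dict[str, Path]:
    """Write the JSON summary plus the flat per-sample and per-participant
    comma-separated tables.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "evaluation.json",
        "samples": out / "sample_scores.csv",
        "participants": out / "participant_scores.csv",
    }
    paths["summary"].write_text(json.dumps(result_to_dict(result), indent=2))
    result.sample_table.to_csv(paths["samples"], index=False)
    result.participant_table.to_csv(paths["participants"], index=False)
    return paths


def save_comparison(report: ComparisonReport, path) -> None:
    doc = {
        "alpha": report.alpha,
        "alpha_corrected": report.alpha_corrected,
        "n_indicators": report.n_indicators,
        "n_pairs": report.n_pairs,
        "rows": [vars(r) for r in report.rows],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
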