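"""End-to-end cohort evaluation: leaf scores -> domains -> CRITIC -> M.

A cohort is a set of participants (each with an anthropometric profile and
an optional landmark offset modelling stature/seat differences) and their
per-task posture samples.  For every sample the pipeline computes the
eleven leaf scores against the layout, fuses them into the eight domain
scores, derives CRITIC weights over the whole cohort, and reports the
comprehensive score M (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnthropometricProfile, CockpitLayout, PostureSample, default_profile
from .fusion import (
    DOMAINS,
    EvaluationResult,
    MethodScores,
    critic_weights,
    default_ranges,
    domain_means,
    normalize_score,
)
from .posture_scores import REGIONS, region_scores
from .reach import ReachOptions, score_reach
from .vision import VisionParams, score_vision

__all__ = ["Participant", "EvalConfig", "evaluate_layout"]


@dataclass(frozen=True)
class Participant:
    """One cohort member: identity, anthropometry, landmark placement."""

    id: str
    profile: AnthropometricProfile
    landmark_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class EvalConfig:
    """Options shared by every sample of one evaluation run."""

    vision: VisionParams = field(default_factory=VisionParams)
    reach: ReachOptions = field(default_factory=ReachOptions)
    owas_policy: str = "severity"
    vision_sweep: str = "comfort"

    def __post_init__(self) -> None:
        self.norm = default_ranges()


def _leaf_scores_for_participant(
    layout: CockpitLayout, participant: Participant, config: EvalConfig
) -> dict[str, float | None]:
    """Layout-geometry leaf scores P1-P7 (shared by a participant's samples)."""
    adj = layout.for_participant(np.asarray(participant.landmark_offset))
    vis = score_vision(adj, None, config.vision, sweep=config.vision_sweep)
    rea = score_reach(adj, participant.profile, config.reach)
    return {
        "p1": vis.p1,
        "p2": vis.p2,
        "p3": vis.p3,
        "p4": rea.p4,
        "p5": rea.p5,
        "p6": rea.p6,
        "p7": rea.p7,
    }


def _posture_leaf_scores(
    sample: PostureSample, profile: AnthropometricProfile, config: EvalConfig
) -> dict:
    """Normalised region-wise P8-P11 for one sample."""
    p8: dict[str, float | None] = {}
    p10: dict[str, float | None] = {}
    p11: dict[str, float | None] = {}
    p9: float | None = None
    for region in REGIONS:
        rs = region_scores(sample, profile, region, owas_policy=config.owas_policy)
        if rs.p8_rula is not None:
            p8[region] = normalize_score(rs.p8_rula, config.norm[f"rula_{region}"])
        if rs.p9_lba is not None:
            p9 = normalize_score(rs.p9_lba, config.norm["lba"])
        if rs.p10_ca is not None:
            p10[region] = normalize_score(rs.p10_ca, config.norm["ca"])
        if rs.p11_owas is not None:
            p11[region] = normalize_score(rs.p11_owas, config.norm["owas"])
    return {"p8": p8, "p9": p9, "p10": p10, "p11": p11}


def evaluate_layout(
    layout: CockpitLayout,
    samples: list[PostureSample],
    participants: list[Participant] | None = None,
    config: EvalConfig | None = None,
) -> EvaluationResult:
    """Evaluate one layout over a cohort of posture samples.

    ``participants`` supplies per-person anthropometry and landmark
    offsets; when omitted, every sample is scored with the P50 profile at
    the nominal landmarks.  Domains that are not applicable for any sample
    (e.g. no coloured controls anywhere) are dropped from the CRITIC
    matrix and from M, with a ledger entry.
    """
    if not samples:
        raise ValueError("no posture samples to evaluate")
    config = config or EvalConfig()
    if participants is None:
        ids = {s.participant_id for s in samples}
        participants = [Participant(i, default_profile("P50")) for i in sorted(ids)]
    by_id = {p.id: p for p in participants}
    missing = {s.participant_id for s in samples} - set(by_id)
    if missing:
        raise ValueError(f"samples reference unknown participants: {sorted(missing)}")

    geo_cache: dict[str, dict] = {}
    rows = []
    ledger: list[str] = []
    for s in samples:
        part = by_id[s.participant_id]
        if part.id not in geo_cache:
            geo_cache[part.id] = _leaf_scores_for_participant(layout, part, config)
        ms = MethodScores(
            **geo_cache[part.id], **_posture_leaf_scores(s, part.profile, config)
        )
        dm = domain_means(ms)
        for entry in dm.na_ledger:
            if entry not in ledger:
                ledger.append(entry)
        rows.append(
            {"participant_id": s.participant_id, "task_label": s.task_label}
            | dm.values
        )
    table = pd.DataFrame(rows)

    applicable = tuple(d for d in DOMAINS if table[d].notna().all())
    dropped = [d for d in DOMAINS if d not in applicable]
    for d in dropped:
        ledger.append(f"domain {d} not applicable for the cohort; excluded from M")

    matrix = table[list(applicable)].to_numpy(dtype=float)
    weights = critic_weights(matrix)
    table["M"] = matrix @ weights

    part_table = (
        table.groupby("participant_id")[list(applicable) + ["M"]]
        .mean()
        .reset_index()
    )
    m_total = float(matrix.mean(axis=0) @ weights)
    m_sd = float(part_table["M"].std(ddof=1)) if len(part_table) > 1 else 0.0

    return EvaluationResult(
        sample_table=table,
        participant_table=part_table,
        weights={d: float(w) for d, w in zip(applicable, weights)},
        domains=applicable,
        m_total=m_total,
        m_sd=m_sd,
        na_ledger=ledger,
    )
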