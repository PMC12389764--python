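"""Score quantification, normalisation, domain fusion, CRITIC weighting,
and statistical layout comparison.

The assessment model has three indicator groups mapped onto eight domains
(field-of-view MA1, view obstruction MA2, upper/lower reach MB1/MB2, and
upper/lower/trunk/whole posture rationality MC1-MC4) fed by eleven leaf
methods P1-P11.  Ratio scores P1-P7 are already in [0, 1]; raw scores
P8-P11 are min-max normalised.  Domain scores are means of their leaf
components (Table-style fixed groupings), CRITIC turns the cohort's domain
matrix into objective weights (contrast x conflict), and the comprehensive
score is the weighted mean of domain means - lower is better.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .posture_scores import rula_range

__all__ = [
    "MethodScores",
    "DomainScores",
    "NormalizationRange",
    "EvaluationResult",
    "ComparisonRow",
    "ComparisonReport",
    "DOMAINS",
    "LEAF_METHODS",
    "model_structure",
    "quantify_ratio",
    "normalize_score",
    "default_ranges",
    "domain_means",
    "critic_weights",
    "total_score",
    "relative_reduction",
    "compare_layouts",
]

DOMAINS = ("MA1", "MA2", "MB1", "MB2", "MC1", "MC2", "MC3", "MC4")
LEAF_METHODS = tuple(f"P{i}" for i in range(1, 12))

#: leaf methods feeding each domain, with the analysis region used by the
#: region-dependent posture scorers P8/P10/P11
DOMAIN_COMPOSITION: dict[str, tuple[tuple[str, str | None], ...]] = {
    "MA1": (("P1", None), ("P2", None)),
    "MA2": (("P3", None),),
    "MB1": (("P4", None), ("P5", None)),
    "MB2": (("P6", None), ("P7", None)),
    "MC1": (("P8", "upper"), ("P10", "upper"), ("P11", "upper")),
    "MC2": (("P9", "lower"), ("P11", "lower")),
    "MC3": (("P8", "trunk"), ("P10", "trunk"), ("P11", "trunk")),
    "MC4": (("P8", "whole"), ("P10", "whole"), ("P11", "whole")),
}


def model_structure() -> dict[str, list[str]]:
    """Domain -> leaf-method map of the default assessment model.

    The default model registers 11 leaf methods across 8 evaluation
    domains; region-dependent methods appear in several domains.
    """
    return {d: [leaf for leaf, _ in comps] for d, comps in DOMAIN_COMPOSITION.items()}


# ---------------------------------------------------------------------------
# quantification and normalisation
# ---------------------------------------------------------------------------

def quantify_ratio(total: int, in_scope: int) -> float | None:
    """Ratio score ``(x_t - x_a) / x_t``; ``None`` when the class is empty."""
    if total == 0:
        return None
    if not 0 <= in_scope <= total:
        raise ValueError("need 0 <= in_scope <= total")
    return (total - in_scope) / total


@dataclass(frozen=True)
class NormalizationRange:
    method: str
    xmin: float
    xmax: float

    def __post_init__(self) -> None:
        if not self.xmin < self.xmax:
            raise ValueError(f"invalid normalisation range for {self.method}: "
                             f"xmin {self.xmin} >= xmax {self.xmax}")


def normalize_score(xb: float, rng: NormalizationRange) -> float:
    """Min-max normalisation of a raw score, clipped to [0, 1] with a warning."""
    v = (xb - rng.xmin) / (rng.xmax - rng.xmin)
    if v < 0 or v > 1:
        warnings.warn(
            f"{rng.method} value {xb} outside [{rng.xmin}, {rng.xmax}]; clipped",
            stacklevel=2,
        )
    return float(min(1.0, max(0.0, v)))


def default_ranges() -> dict[str, NormalizationRange]:
    """Normalisation ranges: LBA 0-6000 N, comfort 0-80, OWAS levels 1-4,
    additive RULA the enumerated attainable range per region."""
    out = {
        "lba": NormalizationRange("lba", 0.0, 6000.0),
        "ca": NormalizationRange("ca", 0.0, 80.0),
        "owas": NormalizationRange("owas", 1.0, 4.0),
    }
    for region in ("upper", "trunk", "whole"):
        lo, hi = rula_range(region)
        out[f"rula_{region}"] = NormalizationRange(f"rula_{region}", float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# leaf-score container and domain means
# ---------------------------------------------------------------------------

@dataclass
class MethodScores:
    """Normalised leaf scores of one (layout, posture-sample) evaluation.

    P1-P7 are scalars; the region-dependent P8/P10/P11 are per-region
    mappings, P9 a scalar (lumbar loading is whole-body).  ``None`` marks a
    not-applicable score (e.g. an empty control class).
    """

    p1: float | None = None
    p2: float | None = None
    p3: float | None = None
    p4: float | None = None
    p5: float | None = None
    p6: float | None = None
    p7: float | None = None
    p8: dict[str, float | None] = field(default_factory=dict)
    p9: float | None = None
    p10: dict[str, float | None] = field(default_factory=dict)
    p11: dict[str, float | None] = field(default_factory=dict)

    def leaf(self, name: str, region: str | None = None) -> float | None:
        attr = getattr(self, name.lower())
        if isinstance(attr, dict):
            return attr.get(region)
        return attr


@dataclass(frozen=True)
class DomainScores:
    values: dict[str, float | None]
    na_ledger: list[str] = field(default_factory=list)

    def __getitem__(self, domain: str) -> float | None:
        return self.values[domain]

    def as_array(self, domains=DOMAINS) -> np.ndarray:
        return np.array(
            [math.nan if self.values[d] is None else self.values[d] for d in domains]
        )


def domain_means(scores: MethodScores) -> DomainScores:
    """Eight domain scores as means of their applicable leaf components.

    A not-applicable component is excluded and the mean renormalised over
    the rest (recorded in the ledger); a domain whose components are all
    missing is itself marked not applicable.
    """
    values: dict[str, float | None] = {}
    ledger: list[str] = []
    for domain, comps in DOMAIN_COMPOSITION.items():
        present = []
        for leaf, region in comps:
            v = scores.leaf(leaf, region)
            if v is None:
                ledger.append(f"{domain}: {leaf} not applicable, excluded from mean")
            else:
                present.append(v)
        if present:
            values[domain] = float(np.mean(present))
        else:
            values[domain] = None
            ledger.append(f"{domain}: all components not applicable")
    return DomainScores(values=values, na_ledger=ledger)


# ---------------------------------------------------------------------------
# CRITIC weighting and the comprehensive score
# ---------------------------------------------------------------------------

def critic_weights(matrix: np.ndarray) -> np.ndarray:
    """Objective weights from a (samples x domains) score matrix.

    Contrast is the population (1/n) standard deviation per column;
    conflict is ``R_j = sum_k (1 - r_jk)`` over Pearson correlations (a
    pair involving a zero-variance column contributes ``r = 0``, i.e.
    maximal conflict; the self term contributes 0).  Information
    ``C_j = sigma_j R_j`` is normalised to weights summing to 1.  If every
    ``C_j`` is zero the weights fall back to uniform with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples and >= 2 domains")
    n, k = x.shape
    mean = x.mean(axis=0)
    centred = x - mean
    sigma = np.sqrt((centred**2).mean(axis=0))  # population form

    norms = np.sqrt((centred**2).sum(axis=0))
    r = np.zeros((k, k))
    for j in range(k):
        for l in range(k):
            if j == l:
                r[j, l] = 1.0
            elif norms[j] > 0 and norms[l] > 0:
                r[j, l] = float(centred[:, j] @ centred[:, l] / (norms[j] * norms[l]))
            else:
                r[j, l] = 0.0
    conflict = (1.0 - r).sum(axis=1)
    info = sigma * conflict
    total = info.sum()
    if total <= 0:
        warnings.warn("all CRITIC information measures are zero; using uniform weights")
        return np.full(k, 1.0 / k)
    return info / total


def total_score(domain_mean_values: np.ndarray, weights: np.ndarray) -> float:
    """Comprehensive score ``M = sum_j mean_j * w_j`` (lower is better)."""
    m = np.asarray(domain_mean_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("domain means and weights must have equal length")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    return float(m @ w)


def relative_reduction(before: float, after: float) -> float:
    """Percent reduction of a score, ``100 (before - after) / before``."""
    if before == 0:
        raise ValueError("before must be non-zero")
    return 100.0 * (before - after) / before


# ---------------------------------------------------------------------------
# cohort result container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Cohort evaluation of one layout.

    ``sample_table`` has one row per (participant, task) with the eight
    domain scores and the per-sample comprehensive score ``M``;
    ``participant_table`` aggregates to one row per participant (the unit
    of the statistical comparison).
    """

    sample_table: pd.DataFrame
    participant_table: pd.DataFrame
    weights: dict[str, float]
    domains: tuple[str, ...]
    m_total: float
    m_sd: float
    na_ledger: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out: dict = {"M": {"mean": self.m_total, "sd": self.m_sd}}
        for d in self.domains:
            col = self.participant_table[d]
            out[d] = {"mean": float(col.mean()), "sd": float(col.std(ddof=1))}
        out["weights"] = dict(self.weights)
        return out


# ---------------------------------------------------------------------------
# paired comparison of two layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonRow:
    indicator: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    shapiro_p: float
    significant: bool


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    alpha: float
    alpha_corrected: float
    n_indicators: int
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def compare_layouts(
    results_a: EvaluationResult,
    results_b: EvaluationResult,
    n_indicators: int | None = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Paired per-participant comparison of two layout evaluations.

    For each indicator (the eight domains plus M): Shapiro-Wilk normality
    check on the paired differences, a paired t-test with df = n - 1, and a
    significance flag at the Bonferroni-corrected level
    ``alpha' = alpha / n_indicators``.  Identical pairs (zero-variance,
    zero-mean differences) are reported as no difference.
    """
    ta = results_a.participant_table.set_index("participant_id")
    tb = results_b.participant_table.set_index("participant_id")
    if set(ta.index) != set(tb.index):
        raise ValueError("the two evaluations cover different participants")
    tb = tb.loc[ta.index]
    n = len(ta)
    if n < 3:
        raise ValueError("need at least 3 paired participants")

    indicators = list(results_a.domains) + ["M"]
    if n_indicators is None:
        n_indicators = len(indicators)
    alpha_c = alpha / n_indicators

    rows = []
    for ind in indicators:
        a = ta[ind].to_numpy(dtype=float)
        b = tb[ind].to_numpy(dtype=float)
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t_stat, p_val = 0.0, 1.0
            else:  # constant non-zero shift: unbounded evidence
                t_stat, p_val = math.inf * np.sign(diff.mean()), 0.0
            shapiro_p = math.nan
        else:
            shapiro_p = float(stats.shapiro(diff).pvalue)
            t_res = stats.ttest_rel(a, b)
            t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
        rows.append(
            ComparisonRow(
                indicator=ind,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                t=t_stat,
                df=n - 1,
                p=p_val,
                shapiro_p=shapiro_p,
                significant=bool(p_val < alpha_c),
            )
        )
    return ComparisonReport(
        rows=rows,
        alpha=alpha,
        alpha_corrected=alpha_c,
        n_indicators=n_indicators,
        n_pairs=n,
    )
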