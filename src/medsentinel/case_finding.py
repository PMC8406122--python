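"""Risk-indexed case finding.

Pipeline: compute indicators for one stream → map them to risk points →
sum into a total index of risk per product → select the top-budget products →
build a sample frame over their stocked (product, outlet) pairs, weighted by
geographic risk → draw samples → simulate two-tier testing (visual/device
screening for the falsified stream, assay and dissolution for the substandard
stream) → report yield.

The aim of case finding is individual-level action (recall, enhanced
oversight), not prevalence estimation: the draws are purposive, so the yield
is a measure of how well the risk index concentrates testing, not an
estimate of market prevalence.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .indicators import (
    FALSIFIED_INDICATOR_IDS,
    SUBSTANDARD_INDICATOR_IDS,
    DecileAssignment,
    IndicatorValue,
    assign_deciles,
    falsified_indicators,
    substandard_indicators,
)
from .quality import realize_statuses
from .scoring import RiskIndex, ScoringRule, default_scoring_rules, risk_index, score_indicator, select_for_sampling
from .types import MarketSnapshot, QualityTruth, ValidationError

__all__ = [
    "TestProtocol",
    "SampleFrame",
    "TestResultSet",
    "compute_risk_indices",
    "build_sample_frame",
    "draw_from_frame",
    "simulate_testing",
    "case_finding_yield",
    "run_case_finding",
    "tune_weights",
]


@dataclass(frozen=True)
class TestProtocol:
    """Sensitivity/specificity of the two testing tiers.

    Screening (visual inspection, hand-held spectrometry, field TLC) detects
    falsified products; quantitative assay and dissolution detect substandard
    ones.
    """

    screen_sensitivity: float = 0.90
    screen_specificity: float = 0.98
    assay_sensitivity: float = 0.95
    assay_specificity: float = 0.98

    def __post_init__(self) -> None:
        for name in (
            "screen_sensitivity",
            "screen_specificity",
            "assay_sensitivity",
            "assay_specificity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")

    def for_stream(self, stream: str) -> tuple[float, float]:
        if stream == "falsified":
            return self.screen_sensitivity, self.screen_specificity
        if stream == "substandard":
            return self.assay_sensitivity, self.assay_specificity
        raise ValidationError(f"unknown stream {stream!r}")


@dataclass
class SampleFrame:
    """Weighted frame of stocked (product, outlet) pairs."""

    entries: list[tuple[str, str, float]]  # (product_id, outlet_id, weight > 0)

    def __post_init__(self) -> None:
        if any(w <= 0 for _, _, w in self.entries):
            raise ValidationError("sample frame weights must be > 0")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.array([w for _, _, w in self.entries], dtype=float)
        return w / w.sum()


@dataclass
class TestResultSet:
    """One record per drawn and tested sample."""

    records: pd.DataFrame  # product_id, outlet_id, stream, true_status, test_positive

    def __len__(self) -> int:
        return len(self.records)


def compute_risk_indices(
    market: MarketSnapshot,
    stream: str,
    rules: Mapping[str, ScoringRule] | None = None,
    weights: Mapping[str, float] | None = None,
) -> list[RiskIndex]:
    """Score every product on one stream's indicator panel.

    Streams are scored separately: the substandard panel uses the 7 market
    indicators of production risk, the falsified panel the 4 indicators of
    falsifier incentive.
    """
    rules = dict(rules or default_scoring_rules())
    if stream == "substandard":
        ivs = substandard_indicators(market)
        panel = SUBSTANDARD_INDICATOR_IDS
    elif stream == "falsified":
        ivs = falsified_indicators(market)
        panel = FALSIFIED_INDICATOR_IDS
    else:
        raise ValidationError(f"unknown stream {stream!r}")

    by_ind: dict[str, list[IndicatorValue]] = {ind: [] for ind in panel}
    for iv in ivs:
        by_ind[iv.indicator_id].append(iv)
    lookup = {ind: {iv.product_id: iv for iv in vals} for ind, vals in by_ind.items()}

    # decile assignments for decile-kind rules
    deciles: dict[str, DecileAssignment] = {}
    for ind in panel:
        if rules[ind].kind == "decile":
            if ind == "price_ratio":
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    deciles[ind] = assign_deciles(
                        by_ind[ind],
                        eligibility=lambda iv: float(iv.raw_value) < 1.0,
                        eligibility_rule="price ratio < 1 (below the market median)",
                    )
            else:
                deciles[ind] = assign_deciles(by_ind[ind])

    out: list[RiskIndex] = []
    for pid in sorted(market.products):
        points: dict[str, int] = {}
        for ind in panel:
            iv = lookup[ind][pid]
            if rules[ind].kind == "decile":
                points[ind] = score_indicator(deciles[ind].decile.get(pid), rules[ind])
            else:
                points[ind] = score_indicator(iv.raw_value, rules[ind])
        out.append(risk_index(pid, stream, points, weights))
    return out


def build_sample_frame(
    selected: Sequence[str],
    market: MarketSnapshot,
    geography_weights: Mapping[str, float] | None = None,
) -> SampleFrame:
    """One weighted entry per stocked (product, outlet) pair among the
    selected products; weight ∝ the geography weight of the outlet's
    accessibility class."""
    gw = dict(geography_weights or {"accessible": 1.0, "remote": 1.0})
    if any(w <= 0 for w in gw.values()):
        raise ValidationError("geography weights must be positive")
    entries = []
    stocked_products = set()
    for pid, oid, _units in market.stocked_pairs(product_ids=set(selected)):
        acc = market.outlets[oid].district_accessibility
        entries.append((pid, oid, float(gw[acc])))
        stocked_products.add(pid)
    for pid in selected:
        if pid not in stocked_products:
            _warnings.warn(
                f"selected product {pid} is stocked nowhere; excluded from frame",
                stacklevel=2,
            )
    return SampleFrame(entries=entries)


def draw_from_frame(
    frame: SampleFrame, n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Draw ``n`` units (one per pair) without replacement, with probability
    proportional to frame weight; a tested unit is physically consumed."""
    if n < 1:
        raise ValidationError("number of draws must be >= 1")
    if not frame.entries:
        return []
    n = min(n, len(frame.entries))
    idx = rng.choice(
        len(frame.entries), size=n, replace=False, p=frame.normalized_weights
    )
    return [(frame.entries[i][0], frame.entries[i][1]) for i in idx]


def simulate_testing(
    draws: Sequence[tuple[str, str]],
    market: MarketSnapshot,
    truth: QualityTruth,
    protocol: TestProtocol,
    stream: str,
    seed: int = 0,
) -> TestResultSet:
    """Realize true statuses for drawn units and apply the stream's test tier.

    A truly positive unit (its status equals the stream) tests positive with
    the tier's sensitivity; any other unit with 1 − specificity.
    """
    sens, spec = protocol.for_stream(stream)
    rng = child_rng(seed, f"testing-{stream}")
    statuses = realize_statuses(list(draws), market, truth, rng)
    rows = []
    for (pid, oid), status in zip(draws, statuses):
        truly_positive = status == stream
        p_pos = sens if truly_positive else (1.0 - spec)
        rows.append(
            {
                "product_id": pid,
                "outlet_id": oid,
                "stream": stream,
                "true_status": status,
                "test_positive": bool(rng.random() < p_pos),
            }
        )
    return TestResultSet(records=pd.DataFrame(rows, columns=[
        "product_id", "outlet_id", "stream", "true_status", "test_positive"
    ]))


def case_finding_yield(results: TestResultSet) -> dict[str, float]:
    """Yield metrics of a testing campaign.

    yield = positives / tests; sensitivity = detected truly-positive units /
    truly-positive units; PPV = true positives / all positives.
    """
    df = results.records
    if len(df) == 0:
        raise ValidationError("no tests performed")
    stream = df["stream"].iloc[0]
    truly_pos = df["true_status"] == stream
    tested_pos = df["test_positive"]
    tp = int((truly_pos & tested_pos).sum())
    pos = int(tested_pos.sum())
    metrics = {
        "tests": float(len(df)),
        "positives": float(pos),
        "yield": pos / len(df),
        "sensitivity": tp / int(truly_pos.sum()) if truly_pos.any() else float("nan"),
        "ppv": tp / pos if pos > 0 else float("nan"),
    }
    return metrics


def tune_weights(
    market: MarketSnapshot,
    truth: QualityTruth,
    stream: str,
    candidate_weights: Sequence[Mapping[str, float]],
    budget: int,
    protocol: TestProtocol | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Grid search over candidate indicator weightings by retrospective yield.

    Runs a full case-finding round per candidate against known (retrospective)
    quality data and returns the weighting with the highest yield, ties broken
    by candidate order. A deliberately simple utility — picking among a few
    expert-proposed weightings — not a learning framework.
    """
    if not candidate_weights:
        raise ValidationError("no candidate weightings supplied")
    best: tuple[dict[str, float], float] | None = None
    for i, weights in enumerate(candidate_weights):
        _, metrics = run_case_finding(
            market, truth, stream, budget,
            protocol=protocol, weights=weights, seed=seed,
        )
        if best is None or metrics["yield"] > best[1]:
            best = (dict(weights), metrics["yield"])
    return best


def run_case_finding(
    market: MarketSnapshot,
    truth: QualityTruth,
    stream: str,
    budget: int,
    protocol: TestProtocol | None = None,
    rules: Mapping[str, ScoringRule] | None = None,
    weights: Mapping[str, float] | None = None,
    geography_weights: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[TestResultSet, dict[str, float]]:
    """Full case-finding round: score → prioritize → frame → draw → test."""
    protocol = protocol or TestProtocol()
    indices = compute_risk_indices(market, stream, rules=rules, weights=weights)
    selected = select_for_sampling(indices, budget)
    frame = build_sample_frame(selected, market, geography_weights)
    draws = draw_from_frame(frame, budget, child_rng(seed, f"case-draws-{stream}"))
    results = simulate_testing(draws, market, truth, protocol, stream, seed=seed)
    return results, case_finding_yield(results)
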