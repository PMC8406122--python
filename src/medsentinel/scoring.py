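"""Risk-point scoring: indicators → points → total index of risk.

Each numeric indicator is mapped to 0–3 risk points (none / minimal / some /
high) through a :class:`ScoringRule`. The canonical example is the price-ratio
rule: products priced above the volume-weighted market median score 0 (not
irrationally cheap); among products below the median, deciles 7–10 score 0,
deciles 5–6 score 1 (minimal risk of cost cutting), deciles 2–4 score 2
(some risk), and decile 1 — the deepest discounts — scores 3 (high risk).

Points are summed, optionally with per-indicator weights (brand-specific
indicators are more specific than molecule-wide ones and may be upweighted),
into a total index of risk per product and stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .types import ValidationError

__all__ = [
    "Band",
    "ScoringRule",
    "RiskIndex",
    "score_indicator",
    "risk_index",
    "select_for_sampling",
    "default_scoring_rules",
    "POINT_LABELS",
]

POINT_LABELS: Mapping[int, str] = {0: "none", 1: "minimal", 2: "some", 3: "high"}


def scoring_rules_from_config(config: Mapping[str, dict]) -> dict[str, "ScoringRule"]:
    """Build scoring rules from a configuration mapping (e.g. parsed YAML).

    Each entry: ``{kind: decile|threshold|flag, ineligible_points: int,
    bands: [{points, lo, hi, flag}, ...]}``. Unlisted indicators keep their
    defaults.
    """
    rules = default_scoring_rules()
    for indicator_id, spec in config.items():
        bands = tuple(
            Band(
                points=int(b["points"]),
                lo=b.get("lo"),
                hi=b.get("hi"),
                flag=b.get("flag"),
            )
            for b in spec["bands"]
        )
        rules[indicator_id] = ScoringRule(
            indicator_id=indicator_id,
            kind=spec["kind"],
            bands=bands,
            ineligible_points=int(spec.get("ineligible_points", 0)),
        )
    return rules


@dataclass(frozen=True)
class Band:
    """One scoring band. Matching semantics depend on the rule kind:

    - kind="decile": lo/hi are inclusive decile bounds (1..10)
    - kind="threshold": lo <= value < hi (hi may be inf)
    - kind="flag": value equals ``flag``
    """

    points: int
    lo: float | None = None
    hi: float | None = None
    flag: bool | str | None = None

    def __post_init__(self) -> None:
        if self.points not in POINT_LABELS:
            raise ValidationError(f"points must be 0..3, got {self.points}")

    @property
    def label(self) -> str:
        return POINT_LABELS[self.points]


@dataclass(frozen=True)
class ScoringRule:
    """Bands partitioning an indicator's domain into risk points."""

    indicator_id: str
    kind: str  # "decile" | "threshold" | "flag"
    bands: Sequence[Band]
    ineligible_points: int = 0  # e.g. price ratio above the median

    def __post_init__(self) -> None:
        if self.kind not in ("decile", "threshold", "flag"):
            raise ValidationError(f"unknown rule kind {self.kind!r}")
        if not self.bands:
            raise ValidationError("rule needs at least one band")
        if self.kind == "decile":
            covered = sorted(
                d for b in self.bands for d in range(int(b.lo), int(b.hi) + 1)
            )
            if covered != list(range(1, 11)):
                raise ValidationError(
                    f"{self.indicator_id}: decile bands must partition 1..10, got {covered}"
                )


def score_indicator(value, rule: ScoringRule) -> int:
    """Map a raw value / decile / flag to its band's points.

    For decile rules, ``value=None`` means the product was ineligible for
    decile ranking (e.g. priced above the median) and scores
    ``rule.ineligible_points``.
    """
    if rule.kind == "decile":
        if value is None:
            return rule.ineligible_points
        d = int(value)
        if not 1 <= d <= 10:
            raise ValidationError(f"{rule.indicator_id}: decile {d} outside 1..10")
        for b in rule.bands:
            if b.lo <= d <= b.hi:
                return b.points
    elif rule.kind == "threshold":
        v = float(value)
        for b in rule.bands:
            lo = -float("inf") if b.lo is None else b.lo
            hi = float("inf") if b.hi is None else b.hi
            if lo <= v < hi:
                return b.points
    else:  # flag
        for b in rule.bands:
            if value == b.flag:
                return b.points
    raise ValidationError(
        f"{rule.indicator_id}: value {value!r} outside all bands (bands must partition)"
    )


@dataclass
class RiskIndex:
    """Per-product summed risk points for one stream."""

    product_id: str
    stream: str
    points: dict[str, int]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"negative weight for indicator {k}")

    @property
    def total(self) -> float:
        return sum(self.weights.get(k, 1.0) * p for k, p in self.points.items())


def risk_index(
    product_id: str,
    stream: str,
    points: Mapping[str, int],
    weights: Mapping[str, float] | None = None,
) -> RiskIndex:
    """Sum per-indicator risk points into the total index of risk.

    Unit weights by default; a weighted sum if weights are supplied.
    """
    return RiskIndex(
        product_id=product_id,
        stream=stream,
        points=dict(points),
        weights=dict(weights or {}),
    )


def select_for_sampling(indices: Sequence[RiskIndex], budget: int) -> list[str]:
    """Top-``budget`` product ids by total index of risk, highest first; ties
    broken by product_id for reproducibility."""
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    ranked = sorted(indices, key=lambda ri: (-ri.total, ri.product_id))
    return [ri.product_id for ri in ranked[: min(budget, len(ranked))]]


def default_scoring_rules() -> dict[str, ScoringRule]:
    """Documented default rules for both streams.

    The price-ratio and profitability rules are decile-based. Threshold bands
    for the remaining numeric indicators are starting points a national expert
    committee would adapt to the local market; they can be overridden through
    configuration.
    """
    decile_1_to_3 = (
        Band(points=3, lo=1, hi=1),
        Band(points=2, lo=2, hi=4),
        Band(points=1, lo=5, hi=6),
        Band(points=0, lo=7, hi=10),
    )
    return {
        # --- substandard stream ---
        "price_ratio": ScoringRule(
            "price_ratio", "decile", decile_1_to_3, ineligible_points=0
        ),
        "producer_years_on_molecule": ScoringRule(
            "producer_years_on_molecule",
            "threshold",
            (
                Band(points=3, lo=None, hi=1.0),
                Band(points=2, lo=1.0, hi=3.0),
                Band(points=1, lo=3.0, hi=7.0),
                Band(points=0, lo=7.0, hi=None),
            ),
        ),
        "months_since_inspection": ScoringRule(
            "months_since_inspection",
            "threshold",
            (
                Band(points=0, lo=None, hi=12.0),
                Band(points=1, lo=12.0, hi=24.0),
                Band(points=2, lo=24.0, hi=48.0),
                Band(points=3, lo=48.0, hi=None),
            ),
        ),
        "warnings_count": ScoringRule(
            "warnings_count",
            "threshold",
            (
                Band(points=0, lo=None, hi=1.0),
                Band(points=1, lo=1.0, hi=2.0),
                Band(points=2, lo=2.0, hi=3.0),
                Band(points=3, lo=3.0, hi=None),
            ),
        ),
        "ma_holder_years": ScoringRule(
            "ma_holder_years",
            "threshold",
            (
                Band(points=3, lo=None, hi=2.0),
                Band(points=2, lo=2.0, hi=5.0),
                Band(points=1, lo=5.0, hi=10.0),
                Band(points=0, lo=10.0, hi=None),
            ),
        ),
        "stability_class": ScoringRule(
            "stability_class",
            "flag",
            (
                Band(points=0, flag="stable"),
                Band(points=1, flag="moderate"),
                Band(points=3, flag="unstable"),
            ),
        ),
        "accessibility_class": ScoringRule(
            "accessibility_class",
            "flag",
            (Band(points=0, flag="accessible"), Band(points=2, flag="remote")),
        ),
        # --- falsified stream ---
        "patent_not_in_formulary": ScoringRule(
            "patent_not_in_formulary",
            "flag",
            (Band(points=0, flag=False), Band(points=3, flag=True)),
        ),
        "offlabel_flag": ScoringRule(
            "offlabel_flag",
            "flag",
            (Band(points=0, flag=False), Band(points=3, flag=True)),
        ),
        "profitability_ratio": ScoringRule(
            # higher revenue relative to the market = riskier, so decile 1
            # (assigned in the risk direction) again scores 3
            "profitability_ratio",
            "decile",
            decile_1_to_3,
            ineligible_points=0,
        ),
        "internet_listings": ScoringRule(
            "internet_listings",
            "threshold",
            (
                Band(points=0, lo=None, hi=1.0),
                Band(points=1, lo=1.0, hi=3.0),
                Band(points=2, lo=3.0, hi=10.0),
                Band(points=3, lo=10.0, hi=None),
            ),
        ),
    }
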