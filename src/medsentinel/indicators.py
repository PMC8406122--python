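"""Objective risk indicators computed from routine market data.

Two indicator panels are computed per product:

* substandard stream (7 indicators): price-to-weighted-median ratio, producer
  experience on the molecule, GMP inspection lag, regulatory warnings, MA
  holder age, molecule stability, and distribution-district accessibility;
* falsified stream (4 indicators): on-patent-but-not-in-formulary,
  recreational/off-label use, profitability ratio (price x retail volume
  relative to the market median for the dosage form), and internet listings.

Relative measures are taken against volume-weighted market medians, since
absolute prices are meaningless across a heterogeneous market. Deciles of
risk are then assigned within an eligible subset (for the price ratio, only
products priced below the market median), decile 1 being the riskiest
extreme.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import MarketSnapshot, Product, STABILITY_LEVELS, ValidationError

__all__ = [
    "IndicatorValue",
    "DecileAssignment",
    "weighted_median",
    "price_ratio",
    "profitability_ratio",
    "substandard_indicators",
    "falsified_indicators",
    "assign_deciles",
    "indicators_table",
    "SUBSTANDARD_INDICATOR_IDS",
    "FALSIFIED_INDICATOR_IDS",
]

# indicator_id -> (level at which it applies, risk direction)
_INDICATOR_META: dict[str, tuple[str, str]] = {
    "price_ratio": ("brand", "lower_riskier"),
    "producer_years_on_molecule": ("manufacturer", "lower_riskier"),
    "months_since_inspection": ("manufacturer", "higher_riskier"),
    "warnings_count": ("manufacturer", "higher_riskier"),
    "ma_holder_years": ("ma_holder", "lower_riskier"),
    "stability_class": ("molecule", "higher_riskier"),
    "accessibility_class": ("geography", "higher_riskier"),
    "patent_not_in_formulary": ("brand", "higher_riskier"),
    "offlabel_flag": ("molecule", "higher_riskier"),
    "profitability_ratio": ("brand", "higher_riskier"),
    "internet_listings": ("brand", "higher_riskier"),
}

SUBSTANDARD_INDICATOR_IDS: tuple[str, ...] = (
    "price_ratio",
    "producer_years_on_molecule",
    "months_since_inspection",
    "warnings_count",
    "ma_holder_years",
    "stability_class",
    "accessibility_class",
)
FALSIFIED_INDICATOR_IDS: tuple[str, ...] = (
    "patent_not_in_formulary",
    "offlabel_flag",
    "profitability_ratio",
    "internet_listings",
)


@dataclass(frozen=True)
class IndicatorValue:
    product_id: str
    indicator_id: str
    raw_value: float | bool | str
    level: str = ""
    direction: str = ""

    def __post_init__(self) -> None:
        if self.indicator_id not in _INDICATOR_META:
            raise ValidationError(f"unknown indicator_id {self.indicator_id!r}")
        level, direction = _INDICATOR_META[self.indicator_id]
        object.__setattr__(self, "level", level)
        object.__setattr__(self, "direction", direction)


@dataclass
class DecileAssignment:
    """Risk deciles over an eligible product subset; decile 1 = riskiest."""

    eligible: set[str]
    decile: dict[str, int]
    eligibility_rule: str = ""

    def __post_init__(self) -> None:
        extra = set(self.decile) - self.eligible
        if extra:
            raise ValidationError(f"deciles assigned to ineligible products: {sorted(extra)[:3]}")


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Smallest value v such that the cumulative weight of items <= v reaches
    half of the total weight."""
    if len(values) == 0:
        raise ValidationError("weighted_median: empty input")
    if len(values) != len(weights):
        raise ValidationError("weighted_median: values and weights differ in length")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weighted_median: negative weight")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weighted_median: all weights zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(v[order][idx])


def _group_key(product: Product) -> tuple[str, str]:
    return (product.molecule_id, product.dosage_form)


def _reference_price(product: Product, channel: str) -> float | None:
    return product.price_by_channel.get(channel)


def price_ratio(
    product: Product, market: MarketSnapshot, channel: str = "retail"
) -> float:
    """Ratio of a product's price to the volume-weighted median price among
    products of the same molecule and dosage form.

    A product that is the sole member of its comparator group has no market
    to undercut and gets ratio 1.0 by convention.
    """
    own = _reference_price(product, channel)
    if own is None:
        raise ValidationError(
            f"product {product.product_id} has no price in channel {channel!r}"
        )
    peers = [
        p
        for p in market.products.values()
        if _group_key(p) == _group_key(product) and channel in p.price_by_channel
    ]
    if len(peers) <= 1:
        return 1.0
    vals = [p.price_by_channel[channel] for p in peers]
    wts = [p.retail_sales_volume.get(channel if channel != "public" else "public", 0.0)
           for p in peers]
    if sum(wts) <= 0:
        wts = [1.0] * len(peers)
    med = weighted_median(vals, wts)
    return float(own / med)


def profitability_ratio(product: Product, market: MarketSnapshot) -> float:
    """(retail price x retail sales volume) relative to the volume-weighted
    market median of that revenue within the same dosage form."""
    own_price = product.price_by_channel.get("retail")
    if own_price is None:
        return 1.0
    own_rev = own_price * product.retail_sales_volume.get("retail", 0.0)
    peers = [
        p
        for p in market.products.values()
        if p.dosage_form == product.dosage_form and "retail" in p.price_by_channel
    ]
    if len(peers) <= 1:
        return 1.0
    revs = [p.price_by_channel["retail"] * p.retail_sales_volume.get("retail", 0.0)
            for p in peers]
    wts = [p.retail_sales_volume.get("retail", 0.0) for p in peers]
    if sum(wts) <= 0:
        wts = [1.0] * len(peers)
    med = weighted_median(revs, wts)
    if med <= 0:
        return 1.0
    return float(own_rev / med)


def _producer_years(product: Product, market: MarketSnapshot) -> float:
    mfr = market.manufacturers.get(product.producing_manufacturer_id)
    if mfr is None:
        raise ValidationError(
            f"product {product.product_id}: missing manufacturer "
            f"{product.producing_manufacturer_id}"
        )
    return float(mfr.years_producing.get(product.molecule_id, 0.0))


def _accessibility_class(product: Product, market: MarketSnapshot) -> str:
    """A product distributed through any remote-district outlet is classed remote."""
    for (pid, oid), units in market.stock.items():
        if pid == product.product_id and units > 0:
            if market.outlets[oid].district_accessibility == "remote":
                return "remote"
    return "accessible"


def substandard_indicators(market: MarketSnapshot) -> list[IndicatorValue]:
    """All seven substandard-stream indicators for every product."""
    out: list[IndicatorValue] = []
    # precompute remote exposure once
    remote_products = {
        pid
        for (pid, oid), units in market.stock.items()
        if units > 0 and market.outlets[oid].district_accessibility == "remote"
    }
    for pid in sorted(market.products):
        prod = market.products[pid]
        mfr = market.manufacturers.get(prod.producing_manufacturer_id)
        holder = market.manufacturers.get(prod.ma_holder_id)
        if mfr is None or holder is None:
            raise ValidationError(f"product {pid}: missing manufacturer link")
        try:
            ratio = price_ratio(prod, market)
        except ValidationError:
            # no retail price: fall back to whichever channel exists
            ch = next(iter(prod.price_by_channel))
            ratio = price_ratio(prod, market, channel=ch)
        mol = market.molecules[prod.molecule_id]
        out += [
            IndicatorValue(pid, "price_ratio", ratio),
            IndicatorValue(pid, "producer_years_on_molecule", _producer_years(prod, market)),
            IndicatorValue(pid, "months_since_inspection", mfr.months_since_gmp_inspection),
            IndicatorValue(pid, "warnings_count", float(mfr.warnings_count)),
            IndicatorValue(pid, "ma_holder_years", holder.ma_holder_years_in_market),
            IndicatorValue(pid, "stability_class", mol.stability_class),
            IndicatorValue(
                pid,
                "accessibility_class",
                "remote" if pid in remote_products else "accessible",
            ),
        ]
    return out


def falsified_indicators(market: MarketSnapshot) -> list[IndicatorValue]:
    """All four falsified-stream indicators for every product."""
    out: list[IndicatorValue] = []
    for pid in sorted(market.products):
        prod = market.products[pid]
        mol = market.molecules[prod.molecule_id]
        out += [
            IndicatorValue(
                pid, "patent_not_in_formulary", bool(mol.on_patent and not mol.in_national_formulary)
            ),
            IndicatorValue(pid, "offlabel_flag", bool(mol.recreational_or_offlabel)),
            IndicatorValue(pid, "profitability_ratio", profitability_ratio(prod, market)),
            IndicatorValue(pid, "internet_listings", float(prod.internet_listings_count)),
        ]
    return out


def assign_deciles(
    values: Iterable[IndicatorValue],
    eligibility: Callable[[IndicatorValue], bool] = lambda iv: True,
    eligibility_rule: str = "",
) -> DecileAssignment:
    """Rank eligible products by raw value in the risk direction and bin into
    deciles; decile 1 holds the riskiest ~10%.

    For n eligible products, product at risk-rank r (1 = riskiest) gets decile
    ceil(10 r / n), which reduces to equal-count deciles when 10 | n and keeps
    "decile 1 = riskiest extreme" at any n. Ties are broken by product_id for
    reproducibility.
    """
    ivs = [iv for iv in values if eligibility(iv)]
    if not ivs:
        _warnings.warn("assign_deciles: empty eligible set", stacklevel=2)
        return DecileAssignment(eligible=set(), decile={}, eligibility_rule=eligibility_rule)
    ids = {iv.indicator_id for iv in ivs}
    if len(ids) > 1:
        raise ValidationError(f"assign_deciles: mixed indicators {sorted(ids)}")
    direction = ivs[0].direction
    sign = 1.0 if direction == "lower_riskier" else -1.0
    ranked = sorted(ivs, key=lambda iv: (sign * float(iv.raw_value), iv.product_id))
    n = len(ranked)
    decile = {
        iv.product_id: math.ceil(10 * (r + 1) / n) for r, iv in enumerate(ranked)
    }
    return DecileAssignment(
        eligible={iv.product_id for iv in ivs},
        decile=decile,
        eligibility_rule=eligibility_rule,
    )


def indicators_table(
    market: MarketSnapshot, deciles: dict[str, DecileAssignment] | None = None
) -> pd.DataFrame:
    """Long-format indicator table (the ``indicators.csv`` export schema)."""
    rows = []
    dec = deciles or {}
    for iv in substandard_indicators(market) + falsified_indicators(market):
        d = dec.get(iv.indicator_id)
        rows.append(
            {
                "product_id": iv.product_id,
                "indicator_id": iv.indicator_id,
                "raw_value": iv.raw_value,
                "level": iv.level,
                "direction": iv.direction,
                "decile": d.decile.get(iv.product_id) if d else None,
            }
        )
    return pd.DataFrame(rows)


def stability_ordinal(stability: str) -> int:
    """stable=0 < moderate=1 < unstable=2."""
    return STABILITY_LEVELS.index(stability)
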