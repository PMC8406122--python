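"""Domain types for a national medicine market.

The market is modelled at product granularity: a *molecule* (active
ingredient) is sold as one or more *products* (brand + dosage form), each
registered to a market-authorization (MA) holder and physically produced by a
manufacturer that may differ from the MA holder (contract manufacture).
Products are stocked at *outlets* belonging to the public, private, nonprofit,
or internet sector.

Monetary values are in an unspecified local currency per unit; volumes are
units per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

Stability = Literal["stable", "moderate", "unstable"]
TherapeuticIndex = Literal["wide", "narrow"]
Sector = Literal["public", "private", "nonprofit", "internet"]
Accessibility = Literal["accessible", "remote"]
Channel = Literal["public", "retail", "internet"]
Stream = Literal["substandard", "falsified"]

STABILITY_LEVELS: tuple[str, ...] = ("stable", "moderate", "unstable")
SECTORS: tuple[str, ...] = ("public", "private", "nonprofit", "internet")
CHANNELS: tuple[str, ...] = ("public", "retail", "internet")
STREAMS: tuple[str, ...] = ("substandard", "falsified")

#: Sector → the price/supply channel its outlets buy from.
SECTOR_CHANNEL: Mapping[str, str] = {
    "public": "public",
    "private": "retail",
    "nonprofit": "retail",
    "internet": "internet",
}


class ValidationError(ValueError):
    """A domain invariant was violated."""


@dataclass(frozen=True)
class Molecule:
    molecule_id: str
    name: str
    stability_class: str
    therapeutic_index: str
    sterile_form: bool
    recreational_or_offlabel: bool
    on_patent: bool
    in_national_formulary: bool
    life_saving: bool
    international_reference_price: float

    def __post_init__(self) -> None:
        if self.stability_class not in STABILITY_LEVELS:
            raise ValidationError(
                f"molecule {self.molecule_id}: unknown stability_class "
                f"{self.stability_class!r}"
            )
        if self.therapeutic_index not in ("wide", "narrow"):
            raise ValidationError(
                f"molecule {self.molecule_id}: unknown therapeutic_index "
                f"{self.therapeutic_index!r}"
            )
        if not self.international_reference_price > 0:
            raise ValidationError(
                f"molecule {self.molecule_id}: international_reference_price "
                "must be strictly positive"
            )


@dataclass(frozen=True)
class Manufacturer:
    manufacturer_id: str
    ma_holder_years_in_market: float
    months_since_gmp_inspection: float
    warnings_count: int
    had_involuntary_recall: bool
    years_producing: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ma_holder_years_in_market < 0 or self.months_since_gmp_inspection < 0:
            raise ValidationError(
                f"manufacturer {self.manufacturer_id}: durations must be non-negative"
            )
        if self.warnings_count < 0:
            raise ValidationError(
                f"manufacturer {self.manufacturer_id}: warnings_count must be >= 0"
            )
        if any(v < 0 for v in self.years_producing.values()):
            raise ValidationError(
                f"manufacturer {self.manufacturer_id}: years_producing must be >= 0"
            )


@dataclass(frozen=True)
class Product:
    product_id: str
    molecule_id: str
    dosage_form: str
    brand: str
    ma_holder_id: str
    producing_manufacturer_id: str
    price_by_channel: Mapping[str, float]
    retail_sales_volume: Mapping[str, float]
    internet_listings_count: int
    insurer_covered: bool

    def __post_init__(self) -> None:
        if not self.price_by_channel:
            raise ValidationError(
                f"product {self.product_id}: at least one channel price required"
            )
        for ch, p in self.price_by_channel.items():
            if ch not in CHANNELS:
                raise ValidationError(
                    f"product {self.product_id}: unknown channel {ch!r}"
                )
            if not p > 0:
                raise ValidationError(
                    f"product {self.product_id}: price in channel {ch} must be > 0"
                )
        if any(v < 0 for v in self.retail_sales_volume.values()):
            raise ValidationError(
                f"product {self.product_id}: sales volumes must be >= 0"
            )
        if self.internet_listings_count < 0:
            raise ValidationError(
                f"product {self.product_id}: internet_listings_count must be >= 0"
            )

    @property
    def contract_manufactured(self) -> bool:
        return self.producing_manufacturer_id != self.ma_holder_id


@dataclass(frozen=True)
class Outlet:
    outlet_id: str
    sector: str
    licensed: bool
    district_accessibility: str

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValidationError(f"outlet {self.outlet_id}: unknown sector {self.sector!r}")
        if self.district_accessibility not in ("accessible", "remote"):
            raise ValidationError(
                f"outlet {self.outlet_id}: unknown accessibility "
                f"{self.district_accessibility!r}"
            )
        if self.sector == "public" and not self.licensed:
            raise ValidationError(
                f"outlet {self.outlet_id}: public outlets are always licensed"
            )

    @property
    def channel(self) -> str:
        return SECTOR_CHANNEL[self.sector]


@dataclass
class MarketSnapshot:
    """Full state of a medicine market at one point in time."""

    molecules: dict[str, Molecule]
    manufacturers: dict[str, Manufacturer]
    products: dict[str, Product]
    outlets: dict[str, Outlet]
    stock: dict[tuple[str, str], int]
    per_capita_household_spending: float
    reference_period_years: float = 5.0

    def validate(self) -> None:
        for pid, prod in self.products.items():
            if prod.molecule_id not in self.molecules:
                raise ValidationError(
                    f"product {pid} references unknown molecule {prod.molecule_id}"
                )
            for mid in (prod.ma_holder_id, prod.producing_manufacturer_id):
                if mid not in self.manufacturers:
                    raise ValidationError(
                        f"product {pid} references unknown manufacturer {mid}"
                    )
        for (pid, oid), units in self.stock.items():
            if pid not in self.products:
                raise ValidationError(f"stock references unknown product {pid}")
            if oid not in self.outlets:
                raise ValidationError(f"stock references unknown outlet {oid}")
            if units < 0:
                raise ValidationError(f"stock ({pid}, {oid}) negative")
        if not self.per_capita_household_spending > 0:
            raise ValidationError("per_capita_household_spending must be > 0")
        if self.total_volume <= 0:
            raise ValidationError("total market volume must be > 0")

    @property
    def total_volume(self) -> int:
        return sum(self.stock.values())

    def stocked_pairs(self, product_ids=None, sectors=None) -> list[tuple[str, str, int]]:
        """Stocked ``(product_id, outlet_id, units)`` triples, optionally filtered,
        in deterministic sorted order."""
        out = []
        for (pid, oid), units in self.stock.items():
            if units <= 0:
                continue
            if product_ids is not None and pid not in product_ids:
                continue
            if sectors is not None and self.outlets[oid].sector not in sectors:
                continue
            out.append((pid, oid, units))
        out.sort()
        return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic market generator.

    Defaults describe a mid-sized national market segment: ~30 molecules sold
    as ~150 products through ~40 outlets across all four sectors.
    """

    n_molecules: int = 30
    n_manufacturers: int = 20
    n_products: int = 150
    n_outlets: int = 40
    price_sigma: float = 0.35          # lognormal dispersion of brand prices
    channel_markup: Mapping[str, float] = field(
        default_factory=lambda: {"public": 0.8, "retail": 1.0, "internet": 1.15}
    )
    contract_share: float = 0.25       # share of products made under contract
    internet_outlet_share: float = 0.10
    unlicensed_internet_share: float = 0.6  # of internet outlets
    remote_share: float = 0.25         # of outlets in remote districts
    mean_stock: float = 40.0           # mean units per stocked (product, outlet)
    stocking_prob: float = 0.25        # P(outlet carries a given eligible product)
    per_capita_household_spending: float = 1500.0
    reference_period_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_molecules", "n_manufacturers", "n_products"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_outlets < 1:
            raise ValidationError("n_outlets must be >= 1")
        for name in ("contract_share", "internet_outlet_share",
                     "unlicensed_internet_share", "remote_share", "stocking_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.price_sigma < 0 or self.mean_stock <= 0:
            raise ValidationError("price_sigma must be >= 0 and mean_stock > 0")


#: Risk-factor ids accepted by EffectConfig, by stream.
SUBSTANDARD_FACTORS: tuple[str, ...] = (
    "cost_cutting_discount",   # depth of discount below the market median price
    "producer_inexperience",   # few years producing the molecule
    "inspection_lag",          # months since last GMP inspection
    "warnings_history",        # regulatory warnings in the reference period
    "ma_holder_youth",         # few years of the MA holder in the market
    "molecule_instability",    # stable < moderate < unstable
    "remote_distribution",     # share of stock in remote districts
)
FALSIFIED_FACTORS: tuple[str, ...] = (
    "shortage_affordability",  # desirable product with restricted/unaffordable access
    "profitability_ratio",     # (price x retail volume) relative to market median
    "unregulated_exposure",    # sold through the internet channel
)


@dataclass(frozen=True)
class EffectConfig:
    """Log-odds model coefficients for the ground-truth quality process.

    ``beta`` maps risk-factor ids (see :data:`SUBSTANDARD_FACTORS` and
    :data:`FALSIFIED_FACTORS`) to log-odds coefficients on z-scored covariates;
    unlisted factors get coefficient 0.
    """

    beta0_substandard: float = -2.944438979166441  # logit(0.05)
    beta0_falsified: float = -3.8918202981106265   # logit(0.02)
    beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(SUBSTANDARD_FACTORS) | set(FALSIFIED_FACTORS)
        for k, v in self.beta.items():
            if k not in known:
                raise ValidationError(f"unknown risk factor in EffectConfig.beta: {k!r}")
            if not np_isfinite(v):
                raise ValidationError(f"coefficient for {k!r} must be finite")
        for name in ("beta0_substandard", "beta0_falsified"):
            if not np_isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def coef(self, factor: str) -> float:
        return float(self.beta.get(factor, 0.0))


def np_isfinite(x: float) -> bool:
    import math

    return math.isfinite(x)


@dataclass
class QualityTruth:
    """Simulated ground truth: per-product / per-channel poor-quality probabilities.

    A sampled unit is falsified with ``p_falsified[(product, channel)]``;
    otherwise substandard with ``p_substandard[product]``; otherwise compliant.
    Falsification takes precedence because a falsified product's actual
    contents are unknowable.
    """

    p_substandard: dict[str, float]
    p_falsified: dict[tuple[str, str], float]

    def validate(self) -> None:
        for p in self.p_substandard.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("p_substandard out of [0, 1]")
        for p in self.p_falsified.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("p_falsified out of [0, 1]")

    def status_probs(self, product_id: str, channel: str) -> tuple[float, float, float]:
        """Return (P(falsified), P(substandard), P(compliant)) for one unit."""
        pf = self.p_falsified.get((product_id, channel), 0.0)
        ps = self.p_substandard[product_id] * (1.0 - pf)
        return pf, ps, 1.0 - pf - ps
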