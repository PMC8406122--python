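"""Hand-constructible worked-example markets.

Small deterministic markets used in the documentation, the test suite, and
the reproduction script: a 20-product price ladder for decile scoring, and
single-predicate probe markets for the sentinel threshold boundaries.
"""

from __future__ import annotations

from .types import Manufacturer, MarketSnapshot, Molecule, Outlet, Product

__all__ = [
    "price_ladder_market",
    "public_price_probe_market",
    "affordability_probe_market",
    "internet_price_probe_market",
]


def _molecule(mid: str = "MOL0", **overrides) -> Molecule:
    defaults = dict(
        molecule_id=mid,
        name=mid.lower(),
        stability_class="stable",
        therapeutic_index="wide",
        sterile_form=False,
        recreational_or_offlabel=False,
        on_patent=False,
        in_national_formulary=True,
        life_saving=False,
        international_reference_price=100.0,
    )
    defaults.update(overrides)
    return Molecule(**defaults)


def _manufacturer(mid: str = "MFR0") -> Manufacturer:
    return Manufacturer(
        manufacturer_id=mid,
        ma_holder_years_in_market=10.0,
        months_since_gmp_inspection=6.0,
        warnings_count=0,
        had_involuntary_recall=False,
        years_producing={"MOL0": 10.0},
    )


def price_ladder_market() -> MarketSnapshot:
    """Twenty products of one molecule and dosage form.

    One high-volume anchor brand at price 100 carries more than half of the
    retail sales volume, pinning the volume-weighted median price at 100; the
    other 19 brands have distinct prices 5, 10, ..., 95, all below the
    median, so exactly those 19 are eligible for deciles of cost-cutting risk.
    """
    mol = _molecule()
    mfr = _manufacturer()
    outlet = Outlet(outlet_id="OUT0", sector="private", licensed=True,
                    district_accessibility="accessible")
    products = {}
    stock = {}
    # anchor: price 100, dominant volume
    products["P_anchor"] = Product(
        product_id="P_anchor",
        molecule_id="MOL0",
        dosage_form="tablet",
        brand="anchor",
        ma_holder_id="MFR0",
        producing_manufacturer_id="MFR0",
        price_by_channel={"retail": 100.0},
        retail_sales_volume={"retail": 1_000_000.0},
        internet_listings_count=0,
        insurer_covered=True,
    )
    stock[("P_anchor", "OUT0")] = 10
    for i in range(1, 20):
        pid = f"P{i:02d}"
        products[pid] = Product(
            product_id=pid,
            molecule_id="MOL0",
            dosage_form="tablet",
            brand=f"brand-{i}",
            ma_holder_id="MFR0",
            producing_manufacturer_id="MFR0",
            price_by_channel={"retail": 5.0 * i},
            retail_sales_volume={"retail": 1.0},
            internet_listings_count=0,
            insurer_covered=True,
        )
        stock[(pid, "OUT0")] = 10
    market = MarketSnapshot(
        molecules={"MOL0": mol},
        manufacturers={"MFR0": mfr},
        products=products,
        outlets={"OUT0": outlet},
        stock=stock,
        per_capita_household_spending=1500.0,
    )
    market.validate()
    return market


def public_price_probe_market(reference_price: float = 100.0) -> MarketSnapshot:
    """100 public-sector products priced at 1%, 2%, ..., 100% of the
    international reference price — a grid probe of the irrationally-low-price
    predicate."""
    mol = _molecule(international_reference_price=reference_price)
    mfr = _manufacturer()
    outlet = Outlet(outlet_id="OUT0", sector="public", licensed=True,
                    district_accessibility="accessible")
    products = {}
    stock = {}
    for pct in range(1, 101):
        pid = f"P{pct:03d}"
        products[pid] = Product(
            product_id=pid,
            molecule_id="MOL0",
            dosage_form="tablet",
            brand=f"b{pct}",
            ma_holder_id="MFR0",
            producing_manufacturer_id="MFR0",
            price_by_channel={"public": reference_price * pct / 100.0},
            retail_sales_volume={"public": 1.0},
            internet_listings_count=0,
            insurer_covered=True,
        )
        stock[(pid, "OUT0")] = 1
    market = MarketSnapshot(
        molecules={"MOL0": mol},
        manufacturers={"MFR0": mfr},
        products=products,
        outlets={"OUT0": outlet},
        stock=stock,
        per_capita_household_spending=1500.0,
    )
    market.validate()
    return market


def affordability_probe_market(spending: float = 1000.0) -> MarketSnapshot:
    """Life-saving, non-insurer-covered products priced at 1%, ..., 50% of
    per-capita household spending — a grid probe of the
    life-saving-but-unaffordable predicate."""
    mol = _molecule(life_saving=True, in_national_formulary=False)
    mfr = _manufacturer()
    outlet = Outlet(outlet_id="OUT0", sector="private", licensed=True,
                    district_accessibility="accessible")
    products = {}
    stock = {}
    for pct in range(1, 51):
        pid = f"P{pct:03d}"
        products[pid] = Product(
            product_id=pid,
            molecule_id="MOL0",
            dosage_form="tablet",
            brand=f"b{pct}",
            ma_holder_id="MFR0",
            producing_manufacturer_id="MFR0",
            price_by_channel={"retail": spending * pct / 100.0},
            retail_sales_volume={"retail": 1.0},
            internet_listings_count=0,
            insurer_covered=False,
        )
        stock[(pid, "OUT0")] = 1
    market = MarketSnapshot(
        molecules={"MOL0": mol},
        manufacturers={"MFR0": mfr},
        products=products,
        outlets={"OUT0": outlet},
        stock=stock,
        per_capita_household_spending=spending,
    )
    market.validate()
    return market


def internet_price_probe_market(median_price: float = 100.0) -> MarketSnapshot:
    """Products on an unlicensed internet outlet priced at 100%, ..., 300% of
    the dosage-form market median retail price — a grid probe of the
    purposive price predicate within the unregulated-internet group.

    An anchor brand with dominant retail volume pins the volume-weighted
    dosage-form median at ``median_price``.
    """
    mol = _molecule()
    mfr = _manufacturer()
    retail_outlet = Outlet(outlet_id="OUT_R", sector="private", licensed=True,
                           district_accessibility="accessible")
    net_outlet = Outlet(outlet_id="OUT_I", sector="internet", licensed=False,
                        district_accessibility="accessible")
    products = {
        "P_anchor": Product(
            product_id="P_anchor",
            molecule_id="MOL0",
            dosage_form="tablet",
            brand="anchor",
            ma_holder_id="MFR0",
            producing_manufacturer_id="MFR0",
            price_by_channel={"retail": median_price},
            retail_sales_volume={"retail": 1_000_000.0},
            internet_listings_count=0,
            insurer_covered=True,
        )
    }
    stock = {("P_anchor", "OUT_R"): 10}
    for pct in range(100, 301):
        pid = f"P{pct:03d}"
        products[pid] = Product(
            product_id=pid,
            molecule_id="MOL0",
            dosage_form="tablet",
            brand=f"b{pct}",
            ma_holder_id="MFR0",
            producing_manufacturer_id="MFR0",
            price_by_channel={
                "retail": median_price * pct / 100.0,
                "internet": median_price * pct / 100.0,
            },
            retail_sales_volume={"retail": 0.0, "internet": 1.0},
            internet_listings_count=1,
            insurer_covered=False,
        )
        stock[(pid, "OUT_I")] = 1
    market = MarketSnapshot(
        molecules={"MOL0": mol},
        manufacturers={"MFR0": mfr},
        products=products,
        outlets={"OUT_R": retail_outlet, "OUT_I": net_outlet},
        stock=stock,
        per_capita_household_spending=1500.0,
    )
    market.validate()
    return market
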