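import pytest

from medsentinel import GeneratorConfig, generate_market
from medsentinel.types import Manufacturer, MarketSnapshot, Molecule, Outlet, Product


@pytest.fixture(scope="session")
def market():
    """Mid-size generated market shared across read-only tests."""
    return generate_market(GeneratorConfig(seed=7))


def make_product(pid, molecule_id="MOL0", dosage_form="tablet", ma="MFR0",
                 producer="MFR0", prices=None, volumes=None, listings=0,
                 covered=True):
    return Product(
        product_id=pid,
        molecule_id=molecule_id,
        dosage_form=dosage_form,
        brand=f"brand-{pid}",
        ma_holder_id=ma,
        producing_manufacturer_id=producer,
        price_by_channel=prices or {"retail": 10.0},
        retail_sales_volume=volumes or {"retail": 100.0},
        internet_listings_count=listings,
        insurer_covered=covered,
    )


@pytest.fixture
def toy_market():
    """Three-product market with hand-printed stock for tally tests.

    Stock: (A, O1)=100, (B, O1)=50, (B, O2)=30, (C, O2)=20.
    """
    mol = Molecule(
        molecule_id="MOL0", name="m", stability_class="stable",
        therapeutic_index="wide", sterile_form=False,
        recreational_or_offlabel=False, on_patent=False,
        in_national_formulary=True, life_saving=False,
        international_reference_price=100.0,
    )
    mfr = Manufacturer(
        manufacturer_id="MFR0", ma_holder_years_in_market=10.0,
        months_since_gmp_inspection=6.0, warnings_count=0,
        had_involuntary_recall=False, years_producing={"MOL0": 10.0},
    )
    outlets = {
        "O1": Outlet(outlet_id="O1", sector="public", licensed=True,
                     district_accessibility="accessible"),
        "O2": Outlet(outlet_id="O2", sector="private", licensed=True,
                     district_accessibility="remote"),
    }
    products = {
        "A": make_product("A", prices={"public": 8.0, "retail": 10.0}),
        "B": make_product("B", prices={"public": 9.0, "retail": 12.0}),
        "C": make_product("C", prices={"retail": 11.0}),
    }
    m = MarketSnapshot(
        molecules={"MOL0": mol},
        manufacturers={"MFR0": mfr},
        products=products,
        outlets=outlets,
        stock={("A", "O1"): 100, ("B", "O1"): 50, ("B", "O2"): 30, ("C", "O2"): 20},
        per_capita_household_spending=1500.0,
    )
    m.validate()
    return m
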