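"""Seeded synthetic-market generator.

Emulates the structural heterogeneity of a real pharmaceutical market:
right-skewed prices dispersed around molecule base prices with multiplicative
channel markups, multi-sector supply (public / private / nonprofit /
unlicensed-internet), contract manufacture, and manufacturer regulatory
histories. Everything is a deterministic function of the config's seed.
"""

from __future__ import annotations

import numpy as np

from ._rng import child_rng
from .types import (
    GeneratorConfig,
    Manufacturer,
    MarketSnapshot,
    Molecule,
    Outlet,
    Product,
)

__all__ = ["generate_market"]

_DOSAGE_FORMS = ("tablet", "capsule", "syrup", "injection")


def generate_market(config: GeneratorConfig) -> MarketSnapshot:
    """Generate a :class:`MarketSnapshot` fully determined by ``config.seed``."""
    seed = config.seed

    molecules = _gen_molecules(config, child_rng(seed, "molecules"))
    manufacturers = _gen_manufacturers(config, molecules, child_rng(seed, "manufacturers"))
    products = _gen_products(config, molecules, manufacturers, child_rng(seed, "products"))
    outlets = _gen_outlets(config, child_rng(seed, "outlets"))
    stock = _gen_stock(config, products, outlets, child_rng(seed, "stock"))

    market = MarketSnapshot(
        molecules=molecules,
        manufacturers=manufacturers,
        products=products,
        outlets=outlets,
        stock=stock,
        per_capita_household_spending=config.per_capita_household_spending,
        reference_period_years=config.reference_period_years,
    )
    market.validate()
    return market


def _gen_molecules(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, Molecule]:
    out: dict[str, Molecule] = {}
    for i in range(cfg.n_molecules):
        mid = f"MOL{i:04d}"
        # base reference prices lognormal: cheap generics to expensive specialty
        ref_price = float(np.exp(rng.normal(1.5, 1.0)))
        out[mid] = Molecule(
            molecule_id=mid,
            name=f"molecule-{i}",
            stability_class=str(rng.choice(["stable", "moderate", "unstable"], p=[0.5, 0.3, 0.2])),
            therapeutic_index=str(rng.choice(["wide", "narrow"], p=[0.8, 0.2])),
            sterile_form=bool(rng.random() < 0.15),
            recreational_or_offlabel=bool(rng.random() < 0.10),
            on_patent=bool(rng.random() < 0.20),
            in_national_formulary=bool(rng.random() < 0.75),
            life_saving=bool(rng.random() < 0.25),
            international_reference_price=ref_price,
        )
    return out


def _gen_manufacturers(
    cfg: GeneratorConfig, molecules: dict[str, Molecule], rng: np.random.Generator
) -> dict[str, Manufacturer]:
    mol_ids = list(molecules)
    out: dict[str, Manufacturer] = {}
    for i in range(cfg.n_manufacturers):
        mid = f"MFR{i:03d}"
        # each firm produces a subset of molecules with its own experience
        k = int(rng.integers(1, max(2, len(mol_ids) // 2)))
        produced = rng.choice(mol_ids, size=min(k, len(mol_ids)), replace=False)
        years_in_market = float(rng.gamma(shape=2.0, scale=6.0))
        years_producing = {
            str(m): float(min(years_in_market, rng.gamma(shape=1.5, scale=4.0)))
            for m in sorted(produced)
        }
        out[mid] = Manufacturer(
            manufacturer_id=mid,
            ma_holder_years_in_market=years_in_market,
            months_since_gmp_inspection=float(rng.exponential(scale=18.0)),
            warnings_count=int(rng.poisson(0.6)),
            had_involuntary_recall=bool(rng.random() < 0.10),
            years_producing=years_producing,
        )
    return out


def _gen_products(
    cfg: GeneratorConfig,
    molecules: dict[str, Molecule],
    manufacturers: dict[str, Manufacturer],
    rng: np.random.Generator,
) -> dict[str, Product]:
    mol_ids = list(molecules)
    mfr_ids = list(manufacturers)
    out: dict[str, Product] = {}
    for i in range(cfg.n_products):
        pid = f"PRD{i:05d}"
        mol = molecules[str(rng.choice(mol_ids))]
        ma_holder = str(rng.choice(mfr_ids))
        if rng.random() < cfg.contract_share and len(mfr_ids) > 1:
            producer = str(rng.choice([m for m in mfr_ids if m != ma_holder]))
        else:
            producer = ma_holder
        form = str(rng.choice(_DOSAGE_FORMS, p=[0.5, 0.25, 0.15, 0.10]))
        # brand retail price: lognormal around the molecule reference price
        retail = float(
            mol.international_reference_price * np.exp(rng.normal(0.0, cfg.price_sigma))
        )
        prices = {}
        for ch, markup in cfg.channel_markup.items():
            # small idiosyncratic channel noise on top of the markup
            prices[ch] = float(retail * markup * np.exp(rng.normal(0.0, 0.05)))
        # drop the internet channel for most products (only some are listed online)
        listings = int(rng.poisson(1.0)) if rng.random() < 0.4 else 0
        if listings == 0 and rng.random() < 0.7:
            prices.pop("internet", None)
        volumes = {
            "public": float(rng.gamma(2.0, 4000.0)),
            "retail": float(rng.gamma(2.0, 6000.0)),
            "internet": float(rng.gamma(1.2, 500.0)) if "internet" in prices else 0.0,
        }
        out[pid] = Product(
            product_id=pid,
            molecule_id=mol.molecule_id,
            dosage_form=form,
            brand=f"brand-{i}",
            ma_holder_id=ma_holder,
            producing_manufacturer_id=producer,
            price_by_channel=prices,
            retail_sales_volume=volumes,
            internet_listings_count=listings,
            insurer_covered=bool(mol.in_national_formulary and rng.random() < 0.85),
        )
        # make sure the producer has an experience record for this molecule
        prod_mfr = manufacturers[producer]
        if mol.molecule_id not in prod_mfr.years_producing:
            years = float(
                min(prod_mfr.ma_holder_years_in_market, rng.gamma(shape=1.5, scale=4.0))
            )
            yp = dict(prod_mfr.years_producing)
            yp[mol.molecule_id] = years
            manufacturers[producer] = Manufacturer(
                manufacturer_id=prod_mfr.manufacturer_id,
                ma_holder_years_in_market=prod_mfr.ma_holder_years_in_market,
                months_since_gmp_inspection=prod_mfr.months_since_gmp_inspection,
                warnings_count=prod_mfr.warnings_count,
                had_involuntary_recall=prod_mfr.had_involuntary_recall,
                years_producing=yp,
            )
    return out


def _gen_outlets(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, Outlet]:
    out: dict[str, Outlet] = {}
    n_internet = int(round(cfg.n_outlets * cfg.internet_outlet_share))
    n_rest = cfg.n_outlets - n_internet
    sectors = ["internet"] * n_internet + [
        str(s) for s in rng.choice(["public", "private", "nonprofit"], size=n_rest, p=[0.35, 0.55, 0.10])
    ]
    for i, sector in enumerate(sectors):
        oid = f"OUT{i:04d}"
        if sector == "internet":
            licensed = bool(rng.random() >= cfg.unlicensed_internet_share)
        elif sector == "public":
            licensed = True
        else:
            licensed = bool(rng.random() < 0.95)
        out[oid] = Outlet(
            outlet_id=oid,
            sector=sector,
            licensed=licensed,
            district_accessibility=(
                "remote" if (sector != "internet" and rng.random() < cfg.remote_share) else "accessible"
            ),
        )
    return out


def _gen_stock(
    cfg: GeneratorConfig,
    products: dict[str, Product],
    outlets: dict[str, Outlet],
    rng: np.random.Generator,
) -> dict[tuple[str, str], int]:
    stock: dict[tuple[str, str], int] = {}
    for pid in sorted(products):
        prod = products[pid]
        carried_anywhere = False
        for oid in sorted(outlets):
            outlet = outlets[oid]
            # an outlet only carries products priced in its channel
            if outlet.channel not in prod.price_by_channel:
                continue
            # internet outlets only carry products with internet listings
            if outlet.sector == "internet" and prod.internet_listings_count == 0:
                continue
            if rng.random() < cfg.stocking_prob:
                units = 1 + int(rng.poisson(cfg.mean_stock - 1))
                stock[(pid, oid)] = units
                carried_anywhere = True
        if not carried_anywhere:
            # every product exists somewhere in the market: force one placement
            eligible = [
                oid
                for oid in sorted(outlets)
                if outlets[oid].channel in prod.price_by_channel
                and not (outlets[oid].sector == "internet" and prod.internet_listings_count == 0)
            ]
            if eligible:
                oid = str(rng.choice(eligible))
                stock[(pid, oid)] = 1 + int(rng.poisson(cfg.mean_stock - 1))
    return stock
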