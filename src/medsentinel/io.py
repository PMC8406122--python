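"""CSV / YAML interchange.

A market directory holds six UTF-8, RFC-4180 CSV files: ``molecules.csv``,
``manufacturers.csv``, ``products.csv``, ``outlets.csv``, ``stock.csv`` and
``market.csv`` (the two market-level scalars). Writing then loading
reproduces the snapshot exactly. Maps inside a row (per-molecule producer
experience, per-channel prices/volumes) are stored as JSON-encoded cells or
wide columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .types import (
    CHANNELS,
    EffectConfig,
    GeneratorConfig,
    Manufacturer,
    MarketSnapshot,
    Molecule,
    Outlet,
    Product,
    ValidationError,
)

__all__ = ["write_market", "load_market", "load_yaml_config", "MARKET_FILES"]

MARKET_FILES = (
    "molecules.csv",
    "manufacturers.csv",
    "products.csv",
    "outlets.csv",
    "stock.csv",
    "market.csv",
)

_REQUIRED_COLUMNS = {
    "molecules.csv": [
        "molecule_id", "name", "stability_class", "therapeutic_index",
        "sterile_form", "recreational_or_offlabel", "on_patent",
        "in_national_formulary", "life_saving", "international_reference_price",
    ],
    "manufacturers.csv": [
        "manufacturer_id", "ma_holder_years_in_market",
        "months_since_gmp_inspection", "warnings_count",
        "had_involuntary_recall", "years_producing",
    ],
    "products.csv": [
        "product_id", "molecule_id", "dosage_form", "brand", "ma_holder_id",
        "producing_manufacturer_id", "price_public", "price_retail",
        "price_internet", "volume_public", "volume_retail", "volume_internet",
        "internet_listings_count", "insurer_covered",
    ],
    "outlets.csv": ["outlet_id", "sector", "licensed", "district_accessibility"],
    "stock.csv": ["product_id", "outlet_id", "units"],
    "market.csv": ["per_capita_household_spending", "reference_period_years"],
}


def write_market(market: MarketSnapshot, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "molecule_id": m.molecule_id,
                "name": m.name,
                "stability_class": m.stability_class,
                "therapeutic_index": m.therapeutic_index,
                "sterile_form": int(m.sterile_form),
                "recreational_or_offlabel": int(m.recreational_or_offlabel),
                "on_patent": int(m.on_patent),
                "in_national_formulary": int(m.in_national_formulary),
                "life_saving": int(m.life_saving),
                "international_reference_price": repr(m.international_reference_price),
            }
            for m in (market.molecules[k] for k in sorted(market.molecules))
        ]
    ).to_csv(d / "molecules.csv", index=False)

    pd.DataFrame(
        [
            {
                "manufacturer_id": m.manufacturer_id,
                "ma_holder_years_in_market": repr(m.ma_holder_years_in_market),
                "months_since_gmp_inspection": repr(m.months_since_gmp_inspection),
                "warnings_count": m.warnings_count,
                "had_involuntary_recall": int(m.had_involuntary_recall),
                "years_producing": json.dumps(
                    {k: m.years_producing[k] for k in sorted(m.years_producing)}
                ),
            }
            for m in (market.manufacturers[k] for k in sorted(market.manufacturers))
        ]
    ).to_csv(d / "manufacturers.csv", index=False)

    pd.DataFrame(
        [
            {
                "product_id": p.product_id,
                "molecule_id": p.molecule_id,
                "dosage_form": p.dosage_form,
                "brand": p.brand,
                "ma_holder_id": p.ma_holder_id,
                "producing_manufacturer_id": p.producing_manufacturer_id,
                **{
                    f"price_{ch}": (
                        repr(p.price_by_channel[ch]) if ch in p.price_by_channel else ""
                    )
                    for ch in CHANNELS
                },
                **{
                    f"volume_{ch}": repr(p.retail_sales_volume.get(ch, 0.0))
                    for ch in CHANNELS
                },
                "internet_listings_count": p.internet_listings_count,
                "insurer_covered": int(p.insurer_covered),
            }
            for p in (market.products[k] for k in sorted(market.products))
        ]
    ).to_csv(d / "products.csv", index=False)

    pd.DataFrame(
        [
            {
                "outlet_id": o.outlet_id,
                "sector": o.sector,
                "licensed": int(o.licensed),
                "district_accessibility": o.district_accessibility,
            }
            for o in (market.outlets[k] for k in sorted(market.outlets))
        ]
    ).to_csv(d / "outlets.csv", index=False)

    pd.DataFrame(
        [
            {"product_id": pid, "outlet_id": oid, "units": units}
            for (pid, oid), units in sorted(market.stock.items())
        ]
    ).to_csv(d / "stock.csv", index=False)

    pd.DataFrame(
        [
            {
                "per_capita_household_spending": repr(market.per_capita_household_spending),
                "reference_period_years": repr(market.reference_period_years),
            }
        ]
    ).to_csv(d / "market.csv", index=False)


def _read_checked(d: Path, name: str) -> pd.DataFrame:
    f = d / name
    if not f.exists():
        raise ValidationError(f"missing market file: {name}")
    df = pd.read_csv(f, keep_default_na=False, na_values=[""], float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")
    return df


def load_market(directory: str | Path) -> MarketSnapshot:
    d = Path(directory)
    mols_df = _read_checked(d, "molecules.csv")
    mfrs_df = _read_checked(d, "manufacturers.csv")
    prods_df = _read_checked(d, "products.csv")
    outs_df = _read_checked(d, "outlets.csv")
    stock_df = _read_checked(d, "stock.csv")
    meta_df = _read_checked(d, "market.csv")

    molecules = {
        r.molecule_id: Molecule(
            molecule_id=str(r.molecule_id),
            name=str(r.name),
            stability_class=str(r.stability_class),
            therapeutic_index=str(r.therapeutic_index),
            sterile_form=bool(int(r.sterile_form)),
            recreational_or_offlabel=bool(int(r.recreational_or_offlabel)),
            on_patent=bool(int(r.on_patent)),
            in_national_formulary=bool(int(r.in_national_formulary)),
            life_saving=bool(int(r.life_saving)),
            international_reference_price=float(r.international_reference_price),
        )
        for r in mols_df.itertuples()
    }
    manufacturers = {
        r.manufacturer_id: Manufacturer(
            manufacturer_id=str(r.manufacturer_id),
            ma_holder_years_in_market=float(r.ma_holder_years_in_market),
            months_since_gmp_inspection=float(r.months_since_gmp_inspection),
            warnings_count=int(r.warnings_count),
            had_involuntary_recall=bool(int(r.had_involuntary_recall)),
            years_producing={
                k: float(v) for k, v in json.loads(r.years_producing).items()
            },
        )
        for r in mfrs_df.itertuples()
    }
    products = {}
    for r in prods_df.itertuples():
        prices = {}
        volumes = {}
        for ch in CHANNELS:
            pv = getattr(r, f"price_{ch}")
            if pd.notna(pv) and str(pv) != "":
                prices[ch] = float(pv)
            volumes[ch] = float(getattr(r, f"volume_{ch}"))
        products[r.product_id] = Product(
            product_id=str(r.product_id),
            molecule_id=str(r.molecule_id),
            dosage_form=str(r.dosage_form),
            brand=str(r.brand),
            ma_holder_id=str(r.ma_holder_id),
            producing_manufacturer_id=str(r.producing_manufacturer_id),
            price_by_channel=prices,
            retail_sales_volume=volumes,
            internet_listings_count=int(r.internet_listings_count),
            insurer_covered=bool(int(r.insurer_covered)),
        )
    outlets = {
        r.outlet_id: Outlet(
            outlet_id=str(r.outlet_id),
            sector=str(r.sector),
            licensed=bool(int(r.licensed)),
            district_accessibility=str(r.district_accessibility),
        )
        for r in outs_df.itertuples()
    }
    stock = {
        (str(r.product_id), str(r.outlet_id)): int(r.units)
        for r in stock_df.itertuples()
    }
    meta = meta_df.iloc[0]
    market = MarketSnapshot(
        molecules=molecules,
        manufacturers=manufacturers,
        products=products,
        outlets=outlets,
        stock=stock,
        per_capita_household_spending=float(meta["per_capita_household_spending"]),
        reference_period_years=float(meta["reference_period_years"]),
    )
    market.validate()
    return market


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration; returns the raw mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return data


def generator_config_from_dict(d: dict[str, Any]) -> GeneratorConfig:
    return GeneratorConfig(**d)


def effect_config_from_dict(d: dict[str, Any]) -> EffectConfig:
    return EffectConfig(**d)
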