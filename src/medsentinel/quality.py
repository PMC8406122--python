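"""Ground-truth quality model for simulated markets.

Each product's probability of being substandard, and each (product, channel)
pair's probability of being falsified, follows a logistic model on z-scored
risk-factor covariates:

    logit p_substandard = beta0_s + sum_j beta_j * z(x_j)   (7 market factors)
    logit p_falsified   = beta0_f + sum_k beta_k * z(x_k)   (3 market factors)

The factor covariates mirror the surveillance indicators: discount depth below
the volume-weighted median price, producer inexperience, GMP inspection lag,
warnings history, MA-holder youth, molecule instability, and remote
distribution for the substandard stream; affordability/shortage gap,
profitability, and unregulated-channel exposure for the falsified stream.
Coefficients are on the log-odds scale per 1 SD of the covariate, so an
``EffectConfig`` is scale-free across markets.

A sampled unit is realized falsified with p_falsified, else substandard with
p_substandard, else compliant — falsification takes precedence because a
falsified product's actual contents are unknowable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_rng
from .indicators import price_ratio, profitability_ratio, stability_ordinal
from .types import (
    CHANNELS,
    EffectConfig,
    FALSIFIED_FACTORS,
    MarketSnapshot,
    QualityTruth,
    SUBSTANDARD_FACTORS,
    ValidationError,
)

__all__ = [
    "assign_true_quality",
    "substandard_covariates",
    "falsified_covariates",
    "realize_statuses",
    "true_prevalence",
]


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return col * 0.0
    return (col - col.mean()) / sd


def substandard_covariates(market: MarketSnapshot) -> pd.DataFrame:
    """Raw (pre-standardization) substandard-stream covariates, one row per
    product, oriented so larger = riskier."""
    remote_volume: dict[str, float] = {}
    total_volume: dict[str, float] = {}
    for (pid, oid), units in market.stock.items():
        total_volume[pid] = total_volume.get(pid, 0.0) + units
        if market.outlets[oid].district_accessibility == "remote":
            remote_volume[pid] = remote_volume.get(pid, 0.0) + units
    rows = {}
    for pid in sorted(market.products):
        prod = market.products[pid]
        mfr = market.manufacturers.get(prod.producing_manufacturer_id)
        holder = market.manufacturers.get(prod.ma_holder_id)
        if mfr is None:
            raise ValidationError(
                f"cannot compute producer_inexperience: product {pid} has no "
                f"manufacturer {prod.producing_manufacturer_id}"
            )
        if holder is None:
            raise ValidationError(
                f"cannot compute ma_holder_youth: product {pid} has no "
                f"MA holder {prod.ma_holder_id}"
            )
        try:
            ratio = price_ratio(prod, market)
        except ValidationError:
            ch = next(iter(prod.price_by_channel))
            ratio = price_ratio(prod, market, channel=ch)
        mol = market.molecules[prod.molecule_id]
        tv = total_volume.get(pid, 0.0)
        rows[pid] = {
            "cost_cutting_discount": -ratio,
            "producer_inexperience": -mfr.years_producing.get(prod.molecule_id, 0.0),
            "inspection_lag": mfr.months_since_gmp_inspection,
            "warnings_history": float(mfr.warnings_count),
            "ma_holder_youth": -holder.ma_holder_years_in_market,
            "molecule_instability": float(stability_ordinal(mol.stability_class)),
            "remote_distribution": (remote_volume.get(pid, 0.0) / tv) if tv > 0 else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, list(SUBSTANDARD_FACTORS)]


def falsified_covariates(market: MarketSnapshot) -> pd.DataFrame:
    """Product-level falsified-stream covariates (the channel-level
    unregulated-exposure term is added separately), larger = riskier."""
    rows = {}
    for pid in sorted(market.products):
        prod = market.products[pid]
        mol = market.molecules[prod.molecule_id]
        retail_price = prod.price_by_channel.get("retail", 0.0)
        unaffordable = (
            mol.life_saving
            and not prod.insurer_covered
            and retail_price > 0.10 * market.per_capita_household_spending
        )
        gap = float(
            (mol.on_patent and not mol.in_national_formulary)
            or mol.recreational_or_offlabel
            or unaffordable
        )
        rows[pid] = {
            "shortage_affordability": gap,
            "profitability_ratio": np.log(max(profitability_ratio(prod, market), 1e-12)),
            "unregulated_exposure": 0.0,  # channel-level; filled per channel below
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, list(FALSIFIED_FACTORS)]


def assign_true_quality(
    market: MarketSnapshot, effects: EffectConfig, seed: int = 0
) -> QualityTruth:
    """Compute per-product p_substandard and per-(product, channel) p_falsified
    under the logistic risk model.

    The probabilities themselves are deterministic functions of the market and
    the effects; ``seed`` is retained for downstream unit realization streams.
    """
    xs = substandard_covariates(market)
    zs = xs.apply(_zscore)
    eta_s = effects.beta0_substandard + sum(
        effects.coef(f) * zs[f] for f in SUBSTANDARD_FACTORS
    )
    p_sub = 1.0 / (1.0 + np.exp(-eta_s))

    xf = falsified_covariates(market)
    zf = xf.apply(_zscore)
    eta_f_base = effects.beta0_falsified + sum(
        effects.coef(f) * zf[f] for f in FALSIFIED_FACTORS if f != "unregulated_exposure"
    )
    # unregulated exposure is a channel attribute: 1 on the internet channel.
    # It is left unstandardized (a plain 0/1 shift) so the internet channel is
    # riskier by exactly its coefficient in log-odds.
    b_unreg = effects.coef("unregulated_exposure")

    p_falsified: dict[tuple[str, str], float] = {}
    for pid in xs.index:
        for ch in CHANNELS:
            eta = float(eta_f_base.loc[pid]) + (b_unreg if ch == "internet" else 0.0)
            p_falsified[(pid, ch)] = float(1.0 / (1.0 + np.exp(-eta)))

    truth = QualityTruth(
        p_substandard={pid: float(p_sub.loc[pid]) for pid in xs.index},
        p_falsified=p_falsified,
    )
    truth.validate()
    return truth


def realize_statuses(
    draws: list[tuple[str, str]],
    market: MarketSnapshot,
    truth: QualityTruth,
    rng: np.random.Generator,
) -> list[str]:
    """Realize a quality status for each drawn (product_id, outlet_id) unit.

    Statuses are mutually exclusive per unit: falsified takes precedence,
    then substandard, else compliant.
    """
    statuses = []
    for pid, oid in draws:
        channel = market.outlets[oid].channel
        pf, ps, _ = truth.status_probs(pid, channel)
        u = rng.random()
        if u < pf:
            statuses.append("falsified")
        elif u < pf + ps:
            statuses.append("substandard")
        else:
            statuses.append("compliant")
    return statuses


def true_prevalence(
    market: MarketSnapshot,
    truth: QualityTruth,
    stream: str,
    product_ids=None,
    sectors=None,
) -> float:
    """Expected stock-weighted prevalence of ``stream`` over (a subset of) the
    market: the probability that a unit drawn uniformly from stock is
    substandard (resp. falsified)."""
    num = 0.0
    den = 0.0
    for pid, oid, units in market.stocked_pairs(product_ids=product_ids, sectors=sectors):
        channel = market.outlets[oid].channel
        pf, ps, _ = truth.status_probs(pid, channel)
        p = pf if stream == "falsified" else ps
        num += units * p
        den += units
    if den == 0:
        raise ValidationError("true_prevalence: no stocked units in scope")
    return num / den


def realization_rng(seed: int) -> np.random.Generator:
    return child_rng(seed, "realize")
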