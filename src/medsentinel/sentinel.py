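"""Risk-based sentinel surveillance.

Products are classified into sentinel groups — market segments expected to
concentrate poor-quality medicines, the analogue of risk-defined populations
in HIV sentinel surveillance:

substandard stream
  - irrationally_low_price: public-system price strictly below 75% of the
    international reference price, or (retail arm) the cheapest available
    version of a target molecule;
  - contract_manufactured: producer differs from the MA holder;
  - poor_regulatory_history: manufacturer with warnings or an involuntary
    recall within the reference period;
  - technically_vulnerable: unstable molecule, narrow therapeutic index, or
    sterile form.

falsified stream
  - high_irrational_demand: recreational / off-label molecules;
  - lifesaving_unaffordable: life-saving, retailing strictly above 10% of
    per-capita household spending, not covered by national insurers;
  - unregulated_internet: sold through unlicensed internet outlets; an
    optional purposive sub-frame adds brands priced strictly above 200% of
    the dosage-form market median.

Because a product can satisfy several predicates, the membership flags are
resolved into a hard partition by a configurable priority order (the overlap
matrix is always reported for audit), keeping stratum volumes additive for
national estimation. Per-group prevalence uses the Wilson score interval,
which behaves well at small counts including k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._rng import child_rng
from .indicators import weighted_median
from .types import MarketSnapshot, ValidationError

__all__ = [
    "SentinelThresholds",
    "SurveyDesign",
    "MembershipPartition",
    "PrevalenceEstimate",
    "SUBSTANDARD_GROUPS",
    "FALSIFIED_GROUPS",
    "GROUP_SECTORS",
    "classify_substandard_groups",
    "classify_falsified_groups",
    "internet_purposive_subframe",
    "resolve_overlaps",
    "draw_sentinel_sample",
    "group_prevalence",
]

SUBSTANDARD_GROUPS: tuple[str, ...] = (
    "irrationally_low_price",
    "contract_manufactured",
    "poor_regulatory_history",
    "technically_vulnerable",
)
FALSIFIED_GROUPS: tuple[str, ...] = (
    "high_irrational_demand",
    "lifesaving_unaffordable",
    "unregulated_internet",
)

#: Sectors in which each group is sampled. Unregulated-channel groups cannot
#: exist in the public sector.
GROUP_SECTORS: Mapping[str, tuple[str, ...]] = {
    "irrationally_low_price": ("public", "private", "nonprofit"),
    "contract_manufactured": ("public", "private", "nonprofit"),
    "poor_regulatory_history": ("public", "private", "nonprofit"),
    "technically_vulnerable": ("public", "private", "nonprofit"),
    "high_irrational_demand": ("private", "nonprofit", "internet"),
    "lifesaving_unaffordable": ("private", "nonprofit", "internet"),
    "unregulated_internet": ("internet",),
}


@dataclass(frozen=True)
class SentinelThresholds:
    """Threshold parameters of the group predicates (strict inequalities)."""

    low_price_fraction: float = 0.75       # public price < 75% of reference price
    spending_fraction: float = 0.10        # retail price > 10% of household spending
    internet_price_multiple: float = 2.0   # retail price > 200% of dosage-form median
    warnings_threshold: int = 1            # >= 1 warning flags poor history
    target_molecules: tuple[str, ...] = () # retail arm of irrationally_low_price

    def __post_init__(self) -> None:
        if self.low_price_fraction <= 0 or self.spending_fraction <= 0 or self.internet_price_multiple <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass(frozen=True)
class SurveyDesign:
    """Per-group sample sizes (units to draw and test) and seed."""

    n_per_group: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValidationError(f"sample size for group {g} must be >= 1")


@dataclass
class MembershipPartition:
    """Sentinel-group membership flags resolved into a hard partition."""

    membership: pd.DataFrame          # index product_id, bool column per group
    assigned_group: dict[str, str]    # product_id -> group_id or "residual"
    overlap_matrix: pd.DataFrame      # group x group joint member counts
    priority_order: list[str]

    def members(self, group_id: str) -> set[str]:
        return {p for p, g in self.assigned_group.items() if g == group_id}

    @property
    def residual(self) -> set[str]:
        return self.members("residual")


@dataclass(frozen=True)
class PrevalenceEstimate:
    group_id: str
    k: int
    n: int
    ci_low: float
    ci_high: float
    ci_method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValidationError("need 0 <= k <= n")
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValidationError("CI must bracket the point estimate in [0, 1]")

    @property
    def point(self) -> float:
        return self.k / self.n


def _cheapest_retail_versions(market: MarketSnapshot, target_molecules) -> set[str]:
    """Cheapest retail-priced product of each target molecule."""
    cheapest: set[str] = set()
    for mol in target_molecules:
        candidates = [
            (p.price_by_channel["retail"], pid)
            for pid, p in market.products.items()
            if p.molecule_id == mol and "retail" in p.price_by_channel
        ]
        if candidates:
            cheapest.add(min(candidates)[1])
    return cheapest


def classify_substandard_groups(
    market: MarketSnapshot, thresholds: SentinelThresholds | None = None
) -> pd.DataFrame:
    """Membership flags for the four substandard-stream sentinel groups."""
    t = thresholds or SentinelThresholds()
    cheapest = _cheapest_retail_versions(market, t.target_molecules)
    rows = {}
    for pid in sorted(market.products):
        prod = market.products[pid]
        mol = market.molecules[prod.molecule_id]
        mfr = market.manufacturers[prod.producing_manufacturer_id]
        public_price = prod.price_by_channel.get("public")
        low_price = False
        if public_price is not None:  # no public price: skip the public predicate
            low_price = public_price < t.low_price_fraction * mol.international_reference_price
        low_price = low_price or (pid in cheapest)
        rows[pid] = {
            "irrationally_low_price": low_price,
            "contract_manufactured": prod.contract_manufactured,
            "poor_regulatory_history": (
                mfr.warnings_count >= t.warnings_threshold or mfr.had_involuntary_recall
            ),
            "technically_vulnerable": (
                mol.stability_class == "unstable"
                or mol.therapeutic_index == "narrow"
                or mol.sterile_form
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, list(SUBSTANDARD_GROUPS)]


def _dosage_form_median_retail(market: MarketSnapshot) -> dict[str, float]:
    med = {}
    by_form: dict[str, list[tuple[float, float]]] = {}
    for p in market.products.values():
        if "retail" in p.price_by_channel:
            by_form.setdefault(p.dosage_form, []).append(
                (p.price_by_channel["retail"], p.retail_sales_volume.get("retail", 0.0))
            )
    for form, pairs in by_form.items():
        vals = [v for v, _ in pairs]
        wts = [w for _, w in pairs]
        if sum(wts) <= 0:
            wts = [1.0] * len(vals)
        med[form] = weighted_median(vals, wts)
    return med


def classify_falsified_groups(
    market: MarketSnapshot, thresholds: SentinelThresholds | None = None
) -> pd.DataFrame:
    """Membership flags for the three falsified-stream sentinel groups."""
    t = thresholds or SentinelThresholds()
    unlicensed_internet_outlets = {
        oid
        for oid, o in market.outlets.items()
        if o.sector == "internet" and not o.licensed
    }
    on_unlicensed_internet = {
        pid
        for (pid, oid), units in market.stock.items()
        if units > 0 and oid in unlicensed_internet_outlets
    }
    rows = {}
    for pid in sorted(market.products):
        prod = market.products[pid]
        mol = market.molecules[prod.molecule_id]
        retail_price = prod.price_by_channel.get("retail")
        unaffordable = (
            mol.life_saving
            and retail_price is not None
            and retail_price > t.spending_fraction * market.per_capita_household_spending
            and not prod.insurer_covered
        )
        rows[pid] = {
            "high_irrational_demand": mol.recreational_or_offlabel,
            "lifesaving_unaffordable": bool(unaffordable),
            "unregulated_internet": pid in on_unlicensed_internet,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, list(FALSIFIED_GROUPS)]


def internet_purposive_subframe(
    market: MarketSnapshot, thresholds: SentinelThresholds | None = None
) -> set[str]:
    """Optional purposive sub-frame within the unregulated-internet group:
    brands retailing strictly above ``internet_price_multiple`` times the
    volume-weighted market median for the dosage form."""
    t = thresholds or SentinelThresholds()
    membership = classify_falsified_groups(market, t)
    med = _dosage_form_median_retail(market)
    out = set()
    for pid in membership.index[membership["unregulated_internet"]]:
        prod = market.products[pid]
        retail_price = prod.price_by_channel.get("retail")
        m = med.get(prod.dosage_form)
        if retail_price is not None and m is not None and m > 0:
            if retail_price > t.internet_price_multiple * m:
                out.add(pid)
    return out


def resolve_overlaps(
    membership: pd.DataFrame, priority_order: Sequence[str]
) -> MembershipPartition:
    """Assign each member product to its highest-priority group; report the
    group x group joint-membership counts for audit."""
    groups = list(membership.columns)
    order = list(priority_order)
    if len(set(order)) != len(order):
        raise ValidationError("duplicate group in priority order")
    if set(order) != set(groups):
        raise ValidationError(
            f"priority order {order} must cover exactly the groups {groups}"
        )
    assigned: dict[str, str] = {}
    for pid, flags in membership.iterrows():
        assigned[pid] = next((g for g in order if flags[g]), "residual")
    m = membership.astype(int)
    overlap = m.T @ m
    return MembershipPartition(
        membership=membership.astype(bool),
        assigned_group=assigned,
        overlap_matrix=overlap,
        priority_order=order,
    )


def draw_sentinel_sample(
    partition: MembershipPartition,
    design: SurveyDesign,
    market: MarketSnapshot,
    sectors_by_group: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Draw ``n_g`` units per group, uniformly without replacement over the
    units stocked at (assigned member product, applicable-sector outlet)
    pairs. Deterministic given the design seed."""
    sectors_by_group = sectors_by_group or GROUP_SECTORS
    draws: dict[str, list[tuple[str, str]]] = {}
    for group, n_g in sorted(design.n_per_group.items()):
        members = partition.members(group)
        sectors = set(sectors_by_group.get(group, ("public", "private", "nonprofit", "internet")))
        pairs = market.stocked_pairs(product_ids=members, sectors=sectors)
        total_units = sum(u for _, _, u in pairs)
        if n_g > total_units:
            raise ValidationError(
                f"group {group}: requested {n_g} units but only {total_units} stocked"
            )
        rng = child_rng(design.seed, f"sentinel-{group}")
        # uniform over units: a pair is drawn with probability ∝ its stock
        unit_pair = np.repeat(np.arange(len(pairs)), [u for _, _, u in pairs])
        chosen = rng.choice(len(unit_pair), size=n_g, replace=False)
        draws[group] = [(pairs[unit_pair[i]][0], pairs[unit_pair[i]][1]) for i in chosen]
    return draws


def group_prevalence(k: int, n: int, group_id: str = "", alpha: float = 0.05) -> PrevalenceEstimate:
    """Point estimate k/n with a Wilson score interval."""
    if n < 1:
        raise ValidationError("group_prevalence: n must be >= 1")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return PrevalenceEstimate(
        group_id=group_id, k=int(k), n=int(n), ci_low=float(lo), ci_high=float(hi)
    )
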