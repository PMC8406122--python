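"""Sentinel-group classification, overlap resolution, sampling, prevalence."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, norm

from medsentinel import (
    GeneratorConfig,
    ValidationError,
    assign_true_quality,
    classify_falsified_groups,
    classify_substandard_groups,
    generate_market,
    group_prevalence,
    internet_purposive_subframe,
    resolve_overlaps,
    true_prevalence,
)
from medsentinel.evaluation import strong_effects
from medsentinel.examples import (
    affordability_probe_market,
    internet_price_probe_market,
    public_price_probe_market,
)
from medsentinel.sentinel import (
    FALSIFIED_GROUPS,
    GROUP_SECTORS,
    SUBSTANDARD_GROUPS,
    SurveyDesign,
    draw_sentinel_sample,
)


class TestSubstandardClassifier:
    def test_public_price_just_below_threshold_is_member(self):
        m = public_price_probe_market()
        mem = classify_substandard_groups(m)
        assert mem.loc["P074", "irrationally_low_price"]

    def test_public_price_at_threshold_is_not_member(self):
        """The predicate is strictly below 75% of the reference price."""
        m = public_price_probe_market()
        mem = classify_substandard_groups(m)
        assert not mem.loc["P075", "irrationally_low_price"]

    def test_contract_manufactured_iff_producer_differs(self, market):
        mem = classify_substandard_groups(market)
        for pid, p in market.products.items():
            assert mem.loc[pid, "contract_manufactured"] == (
                p.producing_manufacturer_id != p.ma_holder_id
            )

    def test_sterile_form_is_technically_vulnerable(self, market):
        mem = classify_substandard_groups(market)
        for pid, p in market.products.items():
            mol = market.molecules[p.molecule_id]
            if mol.sterile_form:
                assert mem.loc[pid, "technically_vulnerable"]

    def test_poor_history_from_warnings_or_recall(self, market):
        mem = classify_substandard_groups(market)
        for pid, p in market.products.items():
            mfr = market.manufacturers[p.producing_manufacturer_id]
            assert mem.loc[pid, "poor_regulatory_history"] == (
                mfr.warnings_count >= 1 or mfr.had_involuntary_recall
            )


class TestFalsifiedClassifier:
    def test_price_just_above_spending_threshold_is_member(self):
        m = affordability_probe_market()
        mem = classify_falsified_groups(m)
        assert mem.loc["P011", "lifesaving_unaffordable"]

    def test_price_at_spending_threshold_is_not_member(self):
        """Strictly above 10% of per-capita household spending."""
        m = affordability_probe_market()
        mem = classify_falsified_groups(m)
        assert not mem.loc["P010", "lifesaving_unaffordable"]

    def test_purposive_subframe_boundary_is_strict(self):
        """Strictly above 200% of the dosage-form market median."""
        m = internet_price_probe_market()
        sub = internet_purposive_subframe(m)
        assert "P201" in sub and "P200" not in sub

    def test_unlicensed_internet_stocking_defines_group(self, market):
        mem = classify_falsified_groups(market)
        unlicensed = {
            oid for oid, o in market.outlets.items()
            if o.sector == "internet" and not o.licensed
        }
        expected = {
            pid for (pid, oid), u in market.stock.items()
            if u > 0 and oid in unlicensed
        }
        assert set(mem.index[mem["unregulated_internet"]]) == expected


class TestResolveOverlaps:
    def test_disjoint_membership_assigns_directly(self):
        mem = pd.DataFrame(
            {"g1": [True, False], "g2": [False, True]}, index=["A", "B"]
        )
        part = resolve_overlaps(mem, ["g1", "g2"])
        assert part.assigned_group == {"A": "g1", "B": "g2"}

    def test_priority_order_wins_on_overlap(self):
        mem = pd.DataFrame(
            {"contract_manufactured": [True], "technically_vulnerable": [True]},
            index=["A"],
        )
        part = resolve_overlaps(mem, ["technically_vulnerable", "contract_manufactured"])
        assert part.assigned_group["A"] == "technically_vulnerable"

    def test_partition_conserves_products(self, market):
        mem = classify_substandard_groups(market)
        part = resolve_overlaps(mem, list(SUBSTANDARD_GROUPS))
        counts = Counter(part.assigned_group.values())
        assert sum(counts.values()) == len(market.products)
        for pid, g in part.assigned_group.items():
            if g != "residual":
                assert part.membership.loc[pid, g]

    def test_overlap_matrix_counts_joint_membership(self):
        mem = pd.DataFrame(
            {"g1": [True, True, False], "g2": [True, False, True]},
            index=["A", "B", "C"],
        )
        part = resolve_overlaps(mem, ["g1", "g2"])
        assert part.overlap_matrix.loc["g1", "g2"] == 1
        assert part.overlap_matrix.loc["g1", "g1"] == 2

    def test_duplicate_priority_rejected(self):
        mem = pd.DataFrame({"g1": [True]}, index=["A"])
        with pytest.raises(ValidationError):
            resolve_overlaps(mem, ["g1", "g1"])


class TestSentinelSampling:
    @pytest.fixture
    def setup(self, market):
        mem = classify_substandard_groups(market)
        part = resolve_overlaps(mem, list(SUBSTANDARD_GROUPS))
        return market, part

    def test_census_draw_returns_all_units(self, setup):
        market, part = setup
        g = "contract_manufactured"
        pairs = market.stocked_pairs(
            product_ids=part.members(g), sectors=set(GROUP_SECTORS[g])
        )
        total = sum(u for _, _, u in pairs)
        draws = draw_sentinel_sample(
            part, SurveyDesign(n_per_group={g: total}, seed=0), market
        )
        assert len(draws[g]) == total

    def test_same_seed_identical_draw(self, setup):
        market, part = setup
        design = SurveyDesign(n_per_group={"technically_vulnerable": 20}, seed=5)
        d1 = draw_sentinel_sample(part, design, market)
        d2 = draw_sentinel_sample(part, design, market)
        assert d1 == d2

    def test_oversized_request_errors_with_count(self, setup):
        market, part = setup
        with pytest.raises(ValidationError, match="stocked"):
            draw_sentinel_sample(
                part,
                SurveyDesign(n_per_group={"contract_manufactured": 10**9}, seed=0),
                market,
            )

    def test_public_sector_never_in_unregulated_internet_frame(self, market):
        mem = classify_falsified_groups(market)
        part = resolve_overlaps(mem, list(FALSIFIED_GROUPS))
        n_avail = sum(
            u
            for _, _, u in market.stocked_pairs(
                product_ids=part.members("unregulated_internet"),
                sectors={"internet"},
            )
        )
        if n_avail == 0:
            pytest.skip("no unregulated-internet stock in this market")
        draws = draw_sentinel_sample(
            part,
            SurveyDesign(n_per_group={"unregulated_internet": min(5, n_avail)}, seed=1),
            market,
        )
        for _, oid in draws["unregulated_internet"]:
            assert market.outlets[oid].sector == "internet"

    def test_unit_draw_frequency_is_uniform(self, toy_market):
        """Over 2,000 replicate single-unit draws, each unit's selection
        frequency stays within binomial 99% bounds of uniform."""
        mem = classify_substandard_groups(toy_market)
        # force every toy product into a single sentinel group
        mem.loc[:, :] = False
        mem["technically_vulnerable"] = True
        part = resolve_overlaps(mem, list(SUBSTANDARD_GROUPS))
        n_units = toy_market.total_volume  # 200 units
        counts = Counter()
        reps = 2000
        for s in range(reps):
            design = SurveyDesign(n_per_group={"technically_vulnerable": 1}, seed=s)
            sectors = {"technically_vulnerable": ("public", "private", "nonprofit")}
            d = draw_sentinel_sample(part, design, toy_market, sectors_by_group=sectors)
            counts[d["technically_vulnerable"][0]] += 1
        # pair-level frequency should be proportional to its stock
        for pid, oid, units in toy_market.stocked_pairs():
            p = units / n_units
            lo, hi = binom.ppf([0.005, 0.995], reps, p)
            assert lo <= counts[(pid, oid)] <= hi


class TestGroupPrevalence:
    def test_zero_positives_boundary(self):
        est = group_prevalence(0, 50)
        assert est.point == 0.0 and est.ci_low == 0.0

    def test_point_estimate(self):
        assert group_prevalence(10, 100).point == pytest.approx(0.10)

    def test_wilson_interval_closed_form(self):
        """k=10, n=100 against the Wilson closed form."""
        est = group_prevalence(10, 100)
        z = norm.ppf(0.975)
        p, n = 0.10, 100
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert est.ci_low == pytest.approx(centre - half, abs=1e-9)
        assert est.ci_high == pytest.approx(centre + half, abs=1e-9)
        assert est.ci_low == pytest.approx(0.0552, abs=2e-4)
        assert est.ci_high == pytest.approx(0.1744, abs=2e-4)

    def test_zero_n_is_an_error(self):
        with pytest.raises(ValidationError):
            group_prevalence(0, 0)


class TestSentinelConcentration:
    def test_member_prevalence_exceeds_residual_under_clustering(self):
        """With strongly clustered truth, sentinel-group members have higher
        true prevalence than the residual in nearly all simulated markets."""
        effects = strong_effects()
        wins = 0
        reps = 60
        usable = 0
        for r in range(reps):
            m = generate_market(GeneratorConfig(seed=10_000 + r))
            truth = assign_true_quality(m, effects)
            mem = classify_substandard_groups(m)
            part = resolve_overlaps(mem, list(SUBSTANDARD_GROUPS))
            members = {p for p, g in part.assigned_group.items() if g != "residual"}
            residual = part.residual
            if not members or not residual:
                continue
            usable += 1
            p_m = true_prevalence(m, truth, "substandard", product_ids=members)
            p_r = true_prevalence(m, truth, "substandard", product_ids=residual)
            wins += p_m > p_r
        assert usable > 0
        assert wins / usable >= 0.95
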