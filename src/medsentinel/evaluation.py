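"""Evaluation experiments tying the pipeline together.

Two experiments validate the simulator–surveillance–estimator chain:

* :func:`evaluate_yield` — the core argument for risk-based surveillance:
  for the same testing budget, risk-indexed and sentinel sampling find more
  poor-quality units per test than simple random sampling whenever quality
  problems cluster on the risk factors. Run over paired replicate markets so
  strategies face identical markets and budgets.
* :func:`recovery_experiment` — parameter recovery: on simulated markets the
  national estimator, fed sentinel surveys and a truthful residual ledger,
  recovers the known true prevalence without systematic bias, and its
  sensitivity bounds cover the truth.

Yields here are computed against realized true statuses (a perfect-test
reading), isolating the sampling strategy from test-device noise; test
sensitivity/specificity are exercised separately in the case-finding module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_rng
from .case_finding import build_sample_frame, compute_risk_indices, draw_from_frame
from .estimator import Assumption, national_prevalence, stratum_volumes
from .generate import generate_market
from .quality import assign_true_quality, realize_statuses, true_prevalence
from .scoring import select_for_sampling
from .sentinel import (
    FALSIFIED_GROUPS,
    SUBSTANDARD_GROUPS,
    SurveyDesign,
    classify_falsified_groups,
    classify_substandard_groups,
    draw_sentinel_sample,
    group_prevalence,
    resolve_overlaps,
)
from .types import (
    EffectConfig,
    FALSIFIED_FACTORS,
    GeneratorConfig,
    MarketSnapshot,
    QualityTruth,
    SUBSTANDARD_FACTORS,
    ValidationError,
)

__all__ = [
    "YieldReport",
    "RecoveryReport",
    "strong_effects",
    "null_effects",
    "evaluate_yield",
    "recovery_experiment",
]

_LOGIT_05 = math.log(0.05 / 0.95)
_LOGIT_02 = math.log(0.02 / 0.98)


def strong_effects(log_or: float = math.log(4.0)) -> EffectConfig:
    """Effects with an odds ratio of 4 per SD on every risk factor: strongly
    clustered poor quality."""
    beta = {f: log_or for f in SUBSTANDARD_FACTORS + FALSIFIED_FACTORS}
    return EffectConfig(beta0_substandard=_LOGIT_05, beta0_falsified=_LOGIT_02, beta=beta)


def null_effects(base_rate: float = 0.05) -> EffectConfig:
    """No clustering: every product equally likely to be poor quality."""
    b0 = math.log(base_rate / (1 - base_rate))
    return EffectConfig(beta0_substandard=b0, beta0_falsified=_LOGIT_02, beta={})


@dataclass
class YieldReport:
    """Paired-replicate yield comparison across sampling strategies."""

    stream: str
    budget: int
    n_replicates: int
    mean_yield: dict[str, float]
    # paired differences vs. the random baseline: mean and Monte-Carlo SE
    paired_diff_mean: dict[str, float]
    paired_diff_se: dict[str, float]
    yields: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _random_draws(
    market: MarketSnapshot, budget: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Simple random sample of units: uniform over all stocked units."""
    pairs = market.stocked_pairs()
    unit_pair = np.repeat(np.arange(len(pairs)), [u for _, _, u in pairs])
    n = min(budget, len(unit_pair))
    chosen = rng.choice(len(unit_pair), size=n, replace=False)
    return [(pairs[unit_pair[i]][0], pairs[unit_pair[i]][1]) for i in chosen]


def _sentinel_draws(
    market: MarketSnapshot, stream: str, budget: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Uniform draw over units of sentinel-group member products (any group
    of the stream)."""
    if stream == "substandard":
        membership = classify_substandard_groups(market)
        order = list(SUBSTANDARD_GROUPS)
    else:
        membership = classify_falsified_groups(market)
        order = list(FALSIFIED_GROUPS)
    partition = resolve_overlaps(membership, order)
    members = {p for p, g in partition.assigned_group.items() if g != "residual"}
    pairs = market.stocked_pairs(product_ids=members)
    if not pairs:
        return []
    unit_pair = np.repeat(np.arange(len(pairs)), [u for _, _, u in pairs])
    n = min(budget, len(unit_pair))
    chosen = rng.choice(len(unit_pair), size=n, replace=False)
    return [(pairs[unit_pair[i]][0], pairs[unit_pair[i]][1]) for i in chosen]


def _risk_index_draws(
    market: MarketSnapshot, stream: str, budget: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    indices = compute_risk_indices(market, stream)
    selected = select_for_sampling(indices, max(budget // 2, 1))
    frame = build_sample_frame(selected, market)
    if not frame.entries:
        return []
    return draw_from_frame(frame, budget, rng)


def evaluate_yield(
    generator: GeneratorConfig,
    effects: EffectConfig,
    stream: str = "substandard",
    budget: int = 50,
    n_replicates: int = 200,
    seed: int = 0,
) -> YieldReport:
    """Compare random, risk-indexed, and sentinel sampling at equal budget
    over paired replicate markets.

    Yield = realized poor-quality units (of the stream) per unit drawn.
    """
    if budget < 1 or n_replicates < 1:
        raise ValidationError("budget and n_replicates must be >= 1")
    strategies = ("random", "risk_index", "sentinel")
    yields: dict[str, list[float]] = {s: [] for s in strategies}
    for r in range(n_replicates):
        gcfg = replace(generator, seed=seed * 1_000_003 % (2**31) + r)
        market = generate_market(gcfg)
        truth = assign_true_quality(market, effects, seed=gcfg.seed)
        for strat in strategies:
            rng = child_rng(gcfg.seed, f"yield-{strat}")
            if strat == "random":
                draws = _random_draws(market, budget, rng)
            elif strat == "risk_index":
                draws = _risk_index_draws(market, stream, budget, rng)
            else:
                draws = _sentinel_draws(market, stream, budget, rng)
            if not draws:
                yields[strat].append(float("nan"))
                continue
            statuses = realize_statuses(draws, market, truth, rng)
            positives = sum(s == stream for s in statuses)
            yields[strat].append(positives / len(draws))

    arr = {s: np.asarray(v, dtype=float) for s, v in yields.items()}
    diff_mean, diff_se = {}, {}
    for s in ("risk_index", "sentinel"):
        d = arr[s] - arr["random"]
        d = d[~np.isnan(d)]
        diff_mean[s] = float(d.mean())
        diff_se[s] = float(d.std(ddof=1) / np.sqrt(len(d)))
    return YieldReport(
        stream=stream,
        budget=budget,
        n_replicates=n_replicates,
        mean_yield={s: float(np.nanmean(v)) for s, v in arr.items()},
        paired_diff_mean=diff_mean,
        paired_diff_se=diff_se,
        yields=arr,
    )


@dataclass
class RecoveryReport:
    """National-estimator parameter recovery over replicate surveys."""

    n_replicates: int
    estimates: np.ndarray
    truths: np.ndarray
    covered: np.ndarray

    @property
    def bias(self) -> float:
        return float(np.mean(self.estimates - self.truths))

    @property
    def bias_se(self) -> float:
        d = self.estimates - self.truths
        return float(d.std(ddof=1) / np.sqrt(len(d)))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.covered))


def _truthful_ledger(
    market: MarketSnapshot,
    truth: QualityTruth,
    stream: str,
    partition,
    volumes,
    band: float = 0.5,
) -> list[Assumption]:
    """Residual assumptions equal to the simulator's true residual prevalence
    (the idealized, fully-informed ledger), with a relative low/high band."""
    residual_products = partition.residual
    ledger = []
    for stratum in volumes.volumes:
        if not stratum.startswith("residual:"):
            continue
        sector = stratum.split(":", 1)[1]
        p = true_prevalence(
            market, truth, stream, product_ids=residual_products, sectors={sector}
        )
        ledger.append(
            Assumption(
                assumption_id=f"a-{stratum}",
                stratum_id=stratum,
                assumed_prevalence=p,
                low=max(0.0, p * (1 - band)),
                high=min(1.0, p * (1 + band)),
                source_note="simulator ground truth (validation ledger)",
            )
        )
    return ledger


def recovery_experiment(
    generator: GeneratorConfig,
    effects: EffectConfig | None = None,
    stream: str = "substandard",
    n_per_group: int = 200,
    n_replicates: int = 50,
    seed: int = 0,
) -> RecoveryReport:
    """Estimate national prevalence on replicate simulated markets with known
    truth, a sentinel survey of ``n_per_group`` units per group, and a
    truthful residual ledger; report bias and sensitivity-bound coverage.

    The default effects keep the falsified stream off (its probability near
    zero) so the substandard stream's true prevalence is channel-independent
    and the survey design is exactly aligned with the stratum volumes.
    """
    if effects is None:
        effects = EffectConfig(
            beta0_substandard=_LOGIT_05,
            beta0_falsified=-30.0,
            beta={f: math.log(2.0) for f in SUBSTANDARD_FACTORS},
        )
    estimates, truths, covered = [], [], []
    all_sectors = {g: ("public", "private", "nonprofit", "internet")
                   for g in (SUBSTANDARD_GROUPS if stream == "substandard" else FALSIFIED_GROUPS)}
    for r in range(n_replicates):
        gcfg = replace(generator, seed=seed * 999_983 % (2**31) + r)
        market = generate_market(gcfg)
        truth = assign_true_quality(market, effects, seed=gcfg.seed)
        if stream == "substandard":
            membership = classify_substandard_groups(market)
            order = list(SUBSTANDARD_GROUPS)
        else:
            membership = classify_falsified_groups(market)
            order = list(FALSIFIED_GROUPS)
        partition = resolve_overlaps(membership, order)
        volumes = stratum_volumes(market, partition)

        design_sizes = {}
        for g in order:
            pairs = market.stocked_pairs(product_ids=partition.members(g))
            avail = sum(u for _, _, u in pairs)
            if avail >= 1:
                design_sizes[g] = min(n_per_group, avail)
        design = SurveyDesign(n_per_group=design_sizes, seed=gcfg.seed)
        draws = draw_sentinel_sample(partition, design, market, sectors_by_group=all_sectors)

        rng = child_rng(gcfg.seed, "recovery-statuses")
        group_estimates = {}
        for g, dr in draws.items():
            statuses = realize_statuses(dr, market, truth, rng)
            k = sum(s == stream for s in statuses)
            group_estimates[g] = group_prevalence(k, len(dr), group_id=g)
        # surveyed strata with zero members still appear in volumes only if
        # they hold stock; strata without an estimate fall to the ledger
        ledger = _truthful_ledger(market, truth, stream, partition, volumes)
        # groups present in volumes but unsampled (no stock): treat via ledger
        for stratum in volumes.volumes:
            if stratum not in group_estimates and not stratum.startswith("residual:"):
                p = true_prevalence(
                    market, truth, stream, product_ids=partition.members(stratum)
                )
                ledger.append(
                    Assumption(
                        assumption_id=f"a-{stratum}",
                        stratum_id=stratum,
                        assumed_prevalence=p,
                        low=max(0.0, p * 0.5),
                        high=min(1.0, p * 1.5),
                        source_note="simulator ground truth (unsampled stratum)",
                    )
                )
        est = national_prevalence(stream, group_estimates, volumes, ledger)
        t = true_prevalence(market, truth, stream)
        estimates.append(est.prevalence)
        truths.append(t)
        covered.append(est.sensitivity_low <= t <= est.sensitivity_high)
    return RecoveryReport(
        n_replicates=n_replicates,
        estimates=np.asarray(estimates),
        truths=np.asarray(truths),
        covered=np.asarray(covered, dtype=bool),
    )
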