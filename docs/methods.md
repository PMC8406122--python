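# Methods

## The market model

A market snapshot holds molecules, manufacturers, products, outlets, and a
stock table mapping (product, outlet) pairs to unit counts. Sectors map to
supply channels — public outlets buy at public prices, private and nonprofit
outlets at retail prices, internet outlets at internet prices — and a
product exists in a channel only if it carries a price there. Two
market-level scalars complete the snapshot: per-capita household spending
(the affordability yardstick) and the reference period for regulatory
histories.

The generator produces snapshots that are deterministic functions of one
seed. All randomness flows through labelled child generators
(`child_rng(seed, label)`), so any stage can be re-run independently and two
runs of the same configuration export byte-identical CSVs.

Default generator conditions (one mid-sized national market segment):
30 molecules, 20 manufacturers, 150 products, 40 outlets (10% internet, of
which 60% unlicensed; 25% of bricks-and-mortar outlets in remote
districts), 25% contract-manufactured products. Prices are lognormal around
each molecule's international reference price (σ = 0.35 on the log scale)
with multiplicative channel markups (public 0.8, retail 1.0, internet
1.15) — strictly positive and right-skewed, like real price distributions.
Stocking is Bernoulli per eligible (product, outlet) pair (p = 0.25) with
Poisson unit counts (mean 40); every product is forced into at least one
outlet so the market has no phantom registrations. Manufacturer regulatory
histories use gamma-distributed ages, exponential inspection lags (mean 18
months), and Poisson warning counts (mean 0.6).

## Ground-truth quality process

The probability that a product is substandard, and that a (product,
channel) unit is falsified, follows a logistic model on z-scored risk-factor
covariates:

    logit p_sub  = β0_s + Σ_j β_j z(x_j)      (7 substandard factors)
    logit p_fals = β0_f + Σ_k β_k z(x_k)      (3 falsified factors)

The covariates deliberately mirror the surveillance indicators: discount
depth below the volume-weighted median price, producer inexperience on the
molecule, GMP inspection lag, warnings history, MA-holder youth, molecule
instability (stable < moderate < unstable), and the remote share of the
product's stock; for falsification, an affordability/shortage gap flag, log
profitability ratio, and unregulated-channel exposure. The exposure term is
an unstandardized 0/1 channel shift so the internet channel is riskier by
exactly its coefficient in log-odds. Standardizing the remaining covariates
within the snapshot makes coefficients scale-free (log odds per SD), which
is what makes parameter-recovery experiments portable across market sizes.

A logistic link was chosen because the risk factors are qualitative claims
about direction, not magnitudes; the simplest monotone model supports the
monotonicity and recovery tests without asserting more than is known.

Statuses per unit are mutually exclusive: a sampled unit is falsified with
p_fals, else substandard with p_sub, else compliant. Falsification takes
precedence because a falsified product's actual contents are unknowable.
Consequently P(substandard unit) = p_sub·(1 − p_fals): when both streams
are active, substandard prevalence is very slightly channel-dependent.
Statuses are realized at sampling time (a unit has no identity until it is
drawn), so census-style identities hold in expectation rather than exactly;
the recovery experiment therefore checks bias statistically.

## Indicators and deciles

The weighted median is the smallest value whose cumulative weight reaches
half the total. Weights are retail sales volumes — the comparison that
matters is against what patients actually buy. A product that is the sole
member of its molecule + dosage-form comparator group gets price ratio 1.0
by convention (no market to undercut) and is never flagged.

Deciles of risk are assigned within an eligible subset only (for the price
ratio: products priced strictly below the market median). Rank r of n in
the risk direction maps to decile ⌈10r/n⌉, which preserves "decile 1 = the
riskiest extreme" at any n and reduces to equal-count deciles when 10 | n.
Ties break on (value, product_id) for reproducibility.

## Scoring defaults

The price-ratio rule is fixed by its worked example: above-median → 0
points; deciles 7–10 → 0; 5–6 → 1; 2–4 → 2; decile 1 → 3. Threshold bands
for the other numeric indicators (inspection lag 12/24/48 months, warnings
1/2/3, producer experience 1/3/7 years, MA-holder age 2/5/10 years,
internet listings 1/3/10) are documented defaults meant to be overridden by
a national expert committee; they are configuration, not science. Weights
default to 1 (a simple additive index); brand-level indicators can be
upweighted via the `weights` argument.

## Sentinel groups and surveys

Threshold predicates follow their printed inequalities strictly: public
price **< 75%** of the international reference price, retail price **> 10%**
of per-capita household spending, purposive internet price **> 200%** of the
dosage-form median. Grid probes at integer percentages recover exactly
these boundaries (the acceptance script recomputes them).

Overlapping memberships are resolved into a hard partition by a
configurable priority order (default: table order per stream) so stratum
volumes stay additive for national estimation; the full group × group
overlap matrix is always reported for audit. `poor_regulatory_history`
defaults to ≥ 1 warning or any involuntary recall in the reference period.
The retail arm of `irrationally_low_price` (cheapest version of each target
molecule) acts on a configured target-molecule list, empty by default,
since molecule selection is a public-health-priority decision, not a market
computation.

Survey draws are uniform over *units* (a pair is drawn with probability
proportional to its stock), without replacement, within each group's
applicable sectors — unregulated-channel groups never touch the public
sector. Wilson score intervals are used throughout because they behave well
at small k, including k = 0.

## National estimation

The estimate is a volume-weighted mixture of surveyed and assumed stratum
prevalences: numerator = estimated poor-quality unit counts (surveyed count
Σ p̂_g V_g plus assumed count Σ p_r V_r), denominator = total volume. The
count-based numerator is the dimensionally consistent reading of
"prevalences applied to volumes"; it makes the estimate a proper mixture,
always bracketed by the stratum prevalences. Residual volume is subdivided
by outlet sector by default (configurable), since the sectors face
different supply chains and deserve separate assumptions. Assumptions
without a source note are rejected outright — transparency is a hard
invariant, not a convention. Sensitivity bounds substitute all CI limits
and ledger bands simultaneously: a deliberately conservative envelope, not
a probabilistic interval.

## Evaluation experiments

`evaluate_yield` compares random, risk-indexed, and sentinel sampling at an
identical budget on paired replicate markets (same market, same budget,
independent draw streams), reporting mean paired yield differences with
Monte-Carlo standard errors. Yields are computed against realized true
statuses (a perfect-test reading) to isolate the sampling strategy from
device noise; test sensitivity/specificity are exercised separately in the
case-finding tier simulation. The default experiment uses 200 replicates of
the default 150-product market at budget 50 — large enough that the
clustered-effects difference is many standard errors from zero while the
null-effects difference is statistically indistinguishable from it.

`recovery_experiment` (default 50 replicates, 200 units per group) surveys
each replicate market, pairs the survey with a ledger set to the
simulator's true residual prevalences (the idealized fully-informed
ledger, ±50% bands), and compares the estimate to the known true
prevalence. Its default effects activate only the substandard stream
(β0_fals → −∞), making substandard prevalence channel-independent, and the
validation survey frames cover all sectors so the design is exactly aligned
with the stratum volumes; both choices remove known small aliasing biases
so the experiment tests the estimator, not the design mismatches. Expected
results: |mean bias| within 2 MC SE of zero, sensitivity-bound coverage
well above 90%.

## What the simulator does and does not emulate

It emulates heterogeneous right-skewed prices around volume-weighted
medians, multi-sector supply including unlicensed internet outlets,
contract manufacture, regulatory histories, and quality probabilities that
rise with the documented risk factors. It does not emulate: temporal
dynamics (a snapshot, not a time series), correlated falsifier behavior
(falsification events are independent across units given p), supply-chain
topology beyond the outlet sector, country-specific accessibility schemes
(binary accessible/remote), or strategic adaptation of falsifiers to known
sentinel sites. Passing tests therefore demonstrate internal validity of
the methods under the stated market model, not field performance.

## Numerical choices

- Strict inequalities exactly as printed for all sentinel thresholds.
- Weighted median: ≤-cumulative rule, stable sort; errors on empty input or
  zero total weight.
- Decile ties: stable (value, product_id) sort. Top-k selection ties break
  by product_id.
- Zero-variance covariates z-score to 0 (no information, no effect).
- CSV round-trips use `repr` for floats on write and round-trip float
  parsing on read, so write → load is exact.
- Seeds: one master seed per run; child streams derived from
  (seed, CRC32(label)); master seeds are kept below 2³¹.

## Known limitations

- The sentinel-group survey estimates per-group prevalence in the group's
  applicable sectors; when quality differs by channel (active falsified
  stream), applying it to the group's all-sector volume introduces a small
  aliasing error, visible only when both streams are strong.
- The sensitivity envelope has no coverage calibration; it is an audit
  bracket driven by the ledger's honesty.
- Threshold scoring defaults are placeholders for expert judgment; the
  grid-search weight-tuning utility is deliberately simple (no learning
  framework).
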