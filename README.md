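# medsentinel

Risk-based post-market surveillance for substandard and falsified medicines.

No country currently measures the market-wide prevalence of poor-quality
medicines: markets contain thousands of products, pharmacopeial testing is
expensive, and random sampling wastes most tests on compliant products.
`medsentinel` implements, on top of a fully synthetic but structurally
realistic pharmaceutical-market simulator, the three surveillance methods a
medicine regulator can combine instead:

1. **Risk-indexed case finding** — score every product on objective market
   indicators (price discounts, producer experience, GMP inspection lag,
   regulatory warnings, MA-holder age, molecule stability, distribution
   geography for the substandard stream; patent/formulary gaps, off-label
   demand, profitability, internet listings for the falsified stream), sum
   the risk points into a *total index of risk*, and concentrate testing on
   the top-ranked products for immediate action (recall, enhanced
   oversight).
2. **Risk-based sentinel surveillance** — classify the market into sentinel
   groups (irrationally low-priced, contract-manufactured, poor regulatory
   history, technically vulnerable; high irrational demand, life-saving but
   unaffordable, unregulated internet), then repeatedly survey each group
   with a fixed design to track prevalence over time. Per-group prevalence
   gets a Wilson 95% confidence interval.
3. **National prevalence estimation** — a transparent, spreadsheet-exportable
   mixture model: surveyed sentinel strata contribute measured prevalences,
   residual subsectors contribute documented assumptions from an
   *assumption ledger* (every assumption carries a source note and a
   low/high band), and

   ```
   national prevalence = ( Σ_g p̂_g·V_g + Σ_r p_r·V_r ) / Σ V
   ```

   with sensitivity bounds from the CIs and ledger bands. The exported CSVs
   alone are sufficient to reproduce the estimate.

Because no real market dataset exists for this problem, the package includes
a seeded market generator (`generate_market`) and a logistic ground-truth
quality model (`assign_true_quality`) whose risk factors mirror the
surveillance indicators, so every stage — and the claim that risk-based
sampling out-yields random sampling — is testable end to end.

## Worked example

```python
from medsentinel import *
from medsentinel.evaluation import strong_effects

cfg = GeneratorConfig(seed=42)            # 150 products, 40 outlets
market = generate_market(cfg)
truth = assign_true_quality(market, strong_effects(), seed=42)
print(true_prevalence(market, truth, "substandard"))   # 0.2314

results, metrics = run_case_finding(market, truth, "substandard",
                                    budget=50, seed=42)
print(metrics)
# {'tests': 50.0, 'positives': 22.0, 'yield': 0.44,
#  'sensitivity': 0.913, 'ppv': 0.955}
```

With a true market prevalence of 23%, testing the 50 samples prioritized by
the risk index yields 44% positives — the concentration that makes
risk-based surveillance cheaper per detected case than random sampling
(compare `evaluate_yield`, which reports a paired random-vs-risk-based
comparison over replicate markets).

A sentinel survey of the same market (200 units per group, seed 42) and a
residual ledger produce the national estimate:

```
contract_manufactured   k=42 n=200 point=0.210 CI=(0.159, 0.272)
irrationally_low_price  k=56 n=200 point=0.280 CI=(0.222, 0.346)
poor_regulatory_history k=34 n=200 point=0.170 CI=(0.124, 0.228)
technically_vulnerable  k=40 n=200 point=0.200 CI=(0.150, 0.261)
national prevalence 0.2278  bounds (0.1702, 0.2942)   # truth: 0.2314
```

The same pipeline is available from the shell:

```bash
medsentinel generate-market --seed 42 --out market/
medsentinel find-cases --market market/ --stream substandard \
    --budget 50 --seed 42 --out cases.csv
medsentinel sentinel-classify --market market/ --stream substandard --out mem.csv
medsentinel sentinel-survey --market market/ --stream substandard \
    --n-per-group 200 --seed 42 --out prevalence.csv
medsentinel estimate --market market/ --stream substandard \
    --prevalence prevalence.csv --ledger ledger.csv --out model/
```

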