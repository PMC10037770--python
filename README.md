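# adexpose

Estimation of children's (2–11) and adolescents' (12–17) per-capita exposure
to televised food and beverage advertising. The pipeline ingests an
ad-occurrence log and a people-meter viewing panel, post-stratifies panel
weights to population cells, counts product-weighted impressions, converts
them to gross rating points (GRP = impressions / population × 100) and
per-capita exposure (GRP / 100), and reports results by station, food
category, marketing technique and nutrient-profile healthfulness, with
absolute and relative child-vs-adolescent differences.

Because the real advertising/viewership data are licensed and unavailable,
the package includes a synthetic-market simulator whose exact ground-truth
exposure is computed by exhaustive enumeration over the full synthetic
population, so the panel-based estimator can be validated end to end.

## Modules

| module | role |
| --- | --- |
| `adexpose.simulate` | synthetic market + panel generator, brute-force ground truth |
| `adexpose.ingest` | ad data model, unique-ad dedup, weighted frequency (3-product cap), category tables |
| `adexpose.exposure` | post-stratification weights, impression ledger, GRP / exposure estimates by slice |
| `adexpose.npm` | provenance-tiered nutrition lookup, threshold-based healthy/unhealthy classification |
| `adexpose.coding` | 22-technique codebook, coder assignment, inter-rater reliability, consensus |
| `adexpose.report` | difference statistics, daily rates, tables 2–5 style reports |

## CLI

```sh
adexpose simulate --config cfg.yaml --seed 1 --out market/   # synthetic market
adexpose ingest   --airings market/airings.csv --ads market/ads.json \
                  --catmap market/category_map.csv            # frequency table
adexpose expose   --market market/ --by station --out exp.csv # exposure estimates
adexpose classify --nutrition market/products.csv --thresholds npm.yaml \
                  --ads market/ads.json --out labels.json     # healthfulness
adexpose code reliability --codings market/codings.csv --metric cohen_kappa
adexpose report   --market market/ --out reports/             # tables 2-5
```

All interchange formats are plain text (CSV/JSON/YAML). A market directory
written by `simulate` contains everything the downstream commands read.

## Conventions worth knowing

- Weighted frequency = airings × unique products, capped at 3 products;
  brand ads (no identifiable product) count one unit per airing and are
  excluded from category and healthfulness tables.
- Ads spanning several coarse categories contribute fully to each category
  row but once to the grand total, so category rows can sum above the total.
- Viewing intervals are half-open `[start, end)`; an impression requires
  being tuned at the airing's start instant.
- Relative differences use children as denominator:
  (adolescent − child) / child × 100, rounded half-up to one decimal after
  all aggregation.
- Nutrient exceedance is strict (`> limit`) and only counts nutrients
  flagged as added ingredients; one unhealthy product makes the whole ad
  unhealthy.
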