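# lvikit

A toolkit for Livelihood Vulnerability Index (LVI / LVI-IPCC) analysis on
stratified household surveys, built around a five-unit agroecosystem (AES)
study of the Choke Mountain region.

The pipeline goes from per-household survey records to:

1. a unit × indicator raw-value table (survey aggregation + precomputed
   unit-level cells),
2. min–max standardized, orientation-corrected indicators,
3. profile scores (8 themed profiles) and the composite LVI
   (balanced weighted average: profiles weighted by indicator counts),
4. the three IPCC contributing factors — exposure (E), sensitivity (S),
   adaptive capacity (A) — and the LVI-IPCC score `(E − A) · S`,
5. vulnerability classes (low / moderate / high) and land-area shares per
   class,
6. pairwise inter-unit significance tests (pooled two-proportion z,
   Welch t, Pearson correlation) and climate-series trend tests (OLS slope,
   Student's t, df = n − 2).

Because the study's raw survey is not deposited, a seeded synthetic
generator (`lvikit.synthetic`) emulates the survey structure: 5 units with
sample sizes 87/183/148/284/91 (793 households) and per-unit category
probabilities / means taken from the published summary tables; within-unit
dispersions are synthetic conventions and are flagged as such in the
packaged spec.

## Layout

| module | purpose |
|---|---|
| `lvikit.framework` | indicator → profile → factor framework; packaged default (8 profiles, 39 indicators) |
| `lvikit.aggregate` | household records, TLU conversion, unit × indicator tables, cross-unit summaries |
| `lvikit.engine` | standardization, profile/factor scores, LVI, LVI-IPCC, classification, area shares |
| `lvikit.compare` | pairwise proportion/mean tests, correlations |
| `lvikit.trends` | annual aggregation, anomalies, linear-trend t-tests, grid masking |
| `lvikit.synthetic` | seeded survey + climate-series generators |
| `lvikit.report`, `lvikit.cli` | table formatting, CLI, end-to-end pipeline with manifest |
| `lvikit.datasets` | packaged data: default framework/spec, areas, published index rows |

## CLI

```bash
lvikit generate --seed 1 --out survey.csv          # synthetic survey
lvikit aggregate --survey survey.csv --out table.csv
lvikit lvi --seed 1 --out outdir                   # full pipeline bundle
lvikit compare --survey survey.csv --field temperature_perception \
    --category increasing --out cmp.csv
lvikit trends --climate stations.csv --out trends.csv
lvikit report --indices indices.csv                # formatted table + Average row
```

`lvikit lvi` writes `survey.csv`, `indicators.csv`, `standardized.csv`,
`profiles.csv`, `factors.csv`, `lvi.csv` (per-unit E/S/A/LVI/LVI-IPCC/class
plus an Average row), `area_shares.csv` and a `manifest.json` with output
hashes; runs are byte-identical for a fixed seed.

Note: published index tables can contain score columns that do not satisfy
`(E − A) · S` of their own printed factors; the report layer surfaces this
as a footnote rather than reconciling it.

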