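# Methods

## The estimation problem

National fisheries management intensity (the FMI, a 0–1 expert-survey
score) is a production-side sustainability measure.  The consumption-side
score is a weighted blend of the scores of every country whose product a
country ultimately eats.  Trade reporting breaks the weighting in one
specific way: when imported product is processed and exported again it is
recorded as a new product of the processing country, so the true origin
mix of imports is unobservable.  The estimator regularizes that gap rather
than pretending to resolve it.

## Pipeline

1. **Ingestion.**  Balance rows (country × ISSCAAP group × year;
   production/imports/exports, tonnes live weight), bilateral customs
   records (tonnes product weight), and a harmonization table mapping
   every raw reporter/partner name to a canonical id or a group of ids.
   Filtering removes non-food records, intra-national flows, and aggregate
   reporters, and sums duplicate keys (summation preserves totals; the
   alternative—keeping the first—silently drops volume).  Unmapped names
   are a hard error because a silently dropped partner biases import
   shares.  The year window (default 2012–2017, the overlap of
   high-resolution bilateral records and balance sheets) is applied at
   load.
2. **Product processing.**  Product→live weight via a conversion-factor
   table.  Match precedence is: longest exact code-prefix, then longest
   keyword hit on the normalized description, then a mandatory default of
   1 (for confidential/undescribed products the product weight itself is
   the only defensible estimate).  The precedence order is this package's
   operationalization of "use the closest taxonomic relative"; the chosen
   rule is logged per record.  ISSCAAP classification is an exact code
   mapping, total by construction (unmapped codes raise).  The
   aquaculture exclusion removes records hitting a farmed keyword (or
   structured farmed flag), a species list, or a generalized listing —
   unless an exemption phrase ("not farmed", "excluding farmed") appears;
   exemptions are checked first.  Matching is case-insensitive substring
   on whitespace-normalized text; the exclusion is a parallel analysis
   mode, never a destructive transform.
3. **Score assembly.**  Every canonical id referenced by any table needs
   exactly one score.  Missing countries with covariates are gap-filled by
   OLS `fmi ~ spi + C(geo_region)` (treatment-coded regions); predictions
   are clamped to [0, 1] because the score is defined on that interval
   (out-of-range predictions are a model artifact, and the clamp is
   logged).  Group partners get the unweighted arithmetic mean of member
   scores — unweighted because the group structures being proxied are
   political aggregates, not production-share constructs.  Provenance
   (surveyed / modeled / gapfilled / group_mean) is recorded per estimate.
   Gap-filling is deterministic.
4. **Propagation.**  Per product group, pooled over the year window:

   * consumption `C = P + I − E` per row, floored at 0 (balance sheets can
     report `E > P + I`; flooring keeps aggregation weights non-negative);
   * global regularizer `FMI_glbl = Σ_k pP_glbl,k FMI_P,k` with production
     shares from the pooled balance table;
   * import side `FMI_I,r = Σ_j pI_rj (pPE_j FMI_P,j + pIE_j FMI_glbl)`,
     with `pI_rj` from live-weight customs records and
     `pPE_j = P_j/(P_j+I_j)` from the balance table.  Balance quantities
     (not customs magnitudes) drive `pPE` because the two sources disagree
     substantially in magnitude; only *relative* partner shares are taken
     from customs records;
   * consumption side `FMI_C,r = pPC·FMI_P,r + (1−pPC)·FMI_I,r` under
     three derivations of the domestic share: proportional `P/(P+I)`, and
     fixed 0.365 / 0.74.  Zero-import countries get `pPC` forced to 1
     (the fixed constants presuppose imports exist); the override is
     logged.  Countries with `P + I = 0` in a group are omitted for that
     group.  A reporter with balance imports but no usable customs shares
     falls back to `FMI_glbl` for its import side (logged) — consistent
     with treating unattributable supply as globally sourced;
   * aggregation over groups by consumption share, then the unweighted
     mean and min/max of the three derivation aggregates per country.

   Every weight vector is a convex combination, so all outputs stay inside
   the hull of the production scores feeding them, and are monotone in any
   partner's score.
5. **Disparity analysis.**  `percent_change = (FMI_P − mean FMI_C)/FMI_P ×
   100` (positive = consumption less sustainably managed than production;
   undefined at `FMI_P = 0`), OLS of each derivation's aggregate on
   `FMI_P`, global import/export shares with lexicographic tie-breaks, and
   top-k partner breakdowns (defaults k = 25).  Report tables are written
   with fixed ordering and float formatting so re-runs at a fixed seed are
   byte-identical.

## Synthetic worlds and what they do (not) show

The generator emulates the statistical structure the estimator assumes or
must survive: eight skewed product groups, heavy-tailed lognormal volumes,
sparse bilateral links, processing hubs re-exporting a fraction of inflow
under their own flag, magnitude disagreement between balance-style and
customs-style totals, and countries with missing scores.  Key defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `n_countries` | 30 | enough mass for stable shares at desk scale |
| `years` | 2012–2017 | the standard pooled analysis window |
| `fmi_spec` | 0.10 + 0.007·SPI + region offsets + N(0, 0.05) | scores spread ≈0.3–0.9; noise sd 0.05 matches the scale used for recovery checks |
| `production_dist` | LogNormal(10.5, 1.4) | median ≈36 kt, long right tail |
| `trade_density` | 0.35 | sparse but connected partner sets |
| `reexport_fraction` | 0.75 | the reported scale of processing re-exports for major hub nations |
| `n_hubs` | 3 | a few dominant processors |
| `source_disagreement` | LogNormal(median 1.6, σ 0.35) per reporter | customs totals exceed balance totals, sometimes substantially |
| `missing_fmi_fraction` | 0.14 | roughly the gap-filled share of real partner lists |

Countries take fixed roles — pure producer-exporters, pure
importer-consumers, hubs (import, consume, re-export; hubs do not export
own production).  This makes re-export chains depth exactly 2 and, at
`reexport_fraction = 0`, makes every estimator assumption true, so the
proportional derivation is *exact* against the provenance ledger.  That
exactness is the calibration anchor; the bias study then measures how the
error grows with the re-export fraction.  Real economies violate the role
partition (every country does all three things at once), so passing these
tests shows internal consistency and correct regularization behaviour, not
real-world accuracy.  The generator also does not model prices, "other
uses" sinks (the world is closed so mass balance is exact), IUU fishing,
or per-year score dynamics (the score is static).

## Numerical design

* All synthetic tonnages live on an integer grid of 2⁻¹⁰ t and conversion
  factors are powers of two, so balance sums, ledger marginals and the
  product↔live weight round trip are exact in IEEE doubles; integer
  largest-remainder apportionment conserves every split exactly.  Mass
  balance and ledger-consistency tests therefore assert equality, not
  tolerances.
* Exactness claims are verified in rational arithmetic
  (`fractions.Fraction`): the estimator expanded symbolically over a
  zero-re-export world equals ledger truth with literally zero error;
  the floating-point pipeline is then held to 1e-12 of truth.
* Pipeline-vs-oracle equivalence (pandas pipeline vs an independent
  pure-Python triple-loop expansion of the equations) is held to 1e-12;
  analytic regression identities to 1e-9; weight-sum conservation to
  1e-9.
* Production-share vectors are validated to sum to 1 within 1e-9 and
  renormalized; worse deviations are an error, not a warning.
* Ties: conversion-factor matches of equal length resolve by table order;
  trader rankings resolve by lexicographic country id; apportionment
  remainders resolve by index.  All logged or documented so reruns are
  reproducible bit-for-bit.
* Test and validation runs use scaled-down worlds (≤40 countries, 1–3
  product groups for oracle sweeps); these sizes are a package choice that
  keeps the exhaustive oracles cheap while exercising every code path.

## Open choices made here

* Duplicate customs rows are summed (reporting practice is ambiguous;
  summation preserves totals).
* Negative computed consumption is floored at zero rather than allowed as
  a negative aggregation weight.
* Import shares are pooled over the whole year window rather than averaged
  per year (pooling weights years by volume, which matches how the pooled
  balance quantities enter everywhere else).
* Gap-fill predictions are clamped to [0, 1]; whether the upstream
  modelling tradition clamped or transformed is unstated, and the clamp is
  the minimal intervention consistent with the score's definition.
* The fixed-share derivations force `pPC = 1` for zero-import countries
  instead of producing an undefined import blend.

## Known limitations

* The re-export regularizer (`FMI_glbl`) is a first-moment correction: it
  fixes the mean attribution of untraceable product but not its
  distribution, so country-level errors under heavy re-exporting are
  bounded but not removed (the bias study quantifies this).
* The fixed domestic-share derivations apply one constant to every
  country; they bracket, rather than estimate, the true heterogeneity.
* Group partners use unweighted member means for both score and export
  composition; production-weighted alternatives would differ for
  heterogeneous groups.
* The gap-fill model is a two-covariate OLS; it inherits all the caveats
  of score extrapolation to countries outside the surveyed set.
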