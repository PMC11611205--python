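# seatrace

Country-level **seafood consumption sustainability** estimated from the
sustainability of **production** and bilateral trade flows.

A country's seafood sustainability is usually judged by how it manages its
own fisheries — a production-side view.  But most seafood is traded: what a
country *eats* is a blend of domestic product and imports harvested under
other countries' management regimes, routed through processing hubs that
re-export imports under their own flag and erase the origin trail.
`seatrace` is for fisheries and food-systems analysts who want to quantify
that production/consumption gap: it propagates a production-side
management-intensity score (the Fisheries Management Index, FMI ∈ [0, 1])
through a bilateral trade network to a consumption-side score per country,
and measures the disparity between the two.

## The model

For reporter *r* and one product group, with live-weight production *P*,
imports *I* and exports *E* from a food balance sheet:

```
C      = P + I − E                                 consumption
FMI_C,r = pPC_r · FMI_P,r + (1 − pPC_r) · FMI_I,r  consumption score
FMI_I,r = Σ_j pI_rj · (pPE_j · FMI_P,j + pIE_j · FMI_glbl)
FMI_glbl = Σ_k pP_glbl,k · FMI_P,k                 global regularizer
```

* `pI_rj` — partner *j*'s live-weight share of *r*'s imports (from
  bilateral customs records, converted from product to live weight);
* `pPE_j = P_j / (P_j + I_j)` — the share of partner *j*'s exports assumed
  to come from its own production, with the complement `pIE_j` treated as
  untraceable re-export and regularized to the production-weighted global
  score `FMI_glbl`;
* `pPC_r` — the domestic share of consumption, the key unknown, computed
  under three **derivations**: balance-proportional `P/(P+I)`, or the
  fixed literature values 0.365 and 0.74 (sensitivity analysis);
* per-group scores are aggregated by consumption share, and the headline
  disparity per country is
  `percent_change = (FMI_P − mean FMI_C) / FMI_P × 100`.

Missing production scores are gap-filled by OLS on the Social Progress
Index with geo-region offsets; aggregate trade partners get member-mean
scores.  An aquaculture-exclusion mode re-runs everything without records
plausibly tied to farming.

Because the licensed bilateral trade data cannot be redistributed, the
package ships a **synthetic world generator** with a provenance ledger: a
closed economy of producer-exporters, importer-consumers and re-exporting
processing hubs in which the true origin of every consumed tonne is known.
The ledger provides ground truth for validating the estimator — including
the exactness of the proportional derivation when no re-exports occur, and
the growth of its error as re-exporting increases.

## Worked example

```python
import seatrace as st

cfg = st.WorldConfig(seed=1, n_countries=12, n_groups=3, n_hubs=2,
                     trade_density=0.5)
world = st.generate_world(cfg)
results = st.SeafoodSustainabilityModel.from_world(world).fit()
print(results.summary(k=5))
```

prints

```
Seafood consumption-sustainability results
==========================================================
countries: 12   derivations: proportional, gephart, guillen

Top 5 producers, production vs consumption score:
country_id fmi_p mean_fmi_c min_fmi_c max_fmi_c percent_change  production_rank
       C09 0.582      0.597     0.584     0.613          -2.70                1
       C08 0.566      0.566     0.566     0.566          +0.00                2
       C02 0.699      0.667     0.644     0.680          +4.61                3
       C03 0.461      0.517     0.491     0.559         -12.06                4
       C01 0.607      0.607     0.607     0.607          +0.00                5

OLS fit of consumption on production score (per derivation):
  derivation  intercept  intercept_se  slope  slope_se  slope_t  p_value     r2  nobs
proportional     0.0632        0.0262 0.8923    0.0427  20.8847   0.0000 0.9776    12
     gephart     0.1733        0.0654 0.7174    0.1065   6.7333   0.0001 0.8193    12
     guillen     0.0709        0.0268 0.8843    0.0436  20.2710   0.0000 0.9762    12
```

Reading it: country `C09` is a processing hub — it imports heavily, so its
consumption score (0.597) drifts away from its production score (0.582)
toward its suppliers'; a negative `percent_change` means it *consumes*
better-managed seafood than it produces.  Autarkic countries (`C08`,
`C01`) keep `FMI_C = FMI_P` exactly.  The min/max columns span the three
derivations — the sensitivity range for the unknown domestic share.  The
regression rows summarize how tightly consumption scores track production
scores under each derivation.

Ground truth from the provenance ledger is one call away:

```python
truth = st.true_consumption_fmi(world.ledger, world.fmi_true)
```

The same pipeline runs from CSV inputs (`SeafoodSustainabilityModel.
from_directory`) or the command line:

```sh
seatrace simulate --seed 3 --countries 20 --out fixtures/
seatrace run --inputs fixtures/ --out report/
```

writing `disparity.csv`, `regression.csv`, `trade_summary.csv`,
`partner_breakdown.csv` and a reproducibility manifest per analysis mode.

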