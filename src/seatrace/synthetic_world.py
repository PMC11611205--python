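"""Provenance-tracked synthetic seafood-trade worlds.

The generator emits the same table schemas the ingestion layer reads
(food-balance rows, bilateral trade records in product weight, management
scores with covariates, a harmonization table, conversion factors) together
with a :class:`ProvenanceLedger` recording the true origin of every consumed
tonne.  The ledger is the ground truth against which the consumption-score
estimator is validated.

Structure of the economy
------------------------
Countries take one of three roles:

* **exporters** produce, consume, and export part of their own production;
  they import nothing, so every tonne they ship is genuinely theirs;
* **importers** produce and import for consumption; they export nothing;
* **hubs** produce (for their own consumption) and import, then re-export a
  configurable fraction of their *imports* labelled as their own exports —
  the processing-hub behaviour that makes origin tracing impossible in real
  customs data.  Re-exported tonnes are drawn proportionally from the hub's
  import origin mix, so provenance chains have depth exactly two
  (producer -> hub -> consumer).

With ``reexport_fraction = 0`` hubs degenerate into pure importers and the
world satisfies every assumption of the proportional consumption estimator,
which is then exact (zero error against the ledger).  Raising the fraction
injects exactly the origin ambiguity the estimator has to regularize via the
global production-weighted score.

Numerical design
----------------
All tonnages are generated on an integer grid of 2**-10 t (about 1 kg) and
conversion factors are powers of two.  Every sum appearing in the balance
tables, the ledger, and the product-weight round trip is therefore exact in
IEEE double arithmetic, which keeps the mass-balance and exactness
invariants sharp instead of tolerance-laden.  The sampling order is fixed
(years, then product groups, then countries in id order), so a seed pins
the world byte-for-byte across platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import AGGREGATE, GEO_REGIONS, ISSCAAP_GROUPS
from .errors import ConfigError

#: tonnage grid: all synthetic quantities are integer multiples of 1/Q tonnes
Q = 1024

#: conversion factors used for synthetic product codes (powers of two, so
#: product-weight -> live-weight round trips are exact in floats)
_CODE_CFS = (1.0, 2.0, 0.5, 4.0)


@dataclass(frozen=True)
class FmiRule:
    """Generating rule for true management scores:
    ``fmi = intercept + spi_coef * SPI + region_offset + N(0, noise_sd)``,
    clamped to [0, 1].  Defaults give scores spread over roughly 0.3-0.9
    for SPI drawn uniformly on [45, 95]."""

    intercept: float = 0.10
    spi_coef: float = 0.007
    region_offsets: tuple[float, ...] = (0.05, -0.04, 0.02, -0.06, 0.03)
    noise_sd: float = 0.05


@dataclass(frozen=True)
class LogNormalVolumes:
    """Heavy-tailed production volumes, tonnes ~ LogNormal(mu, sigma) per
    (country, group, year).  mu=10.5, sigma=1.4 gives a median around
    36 kt with a long right tail into the millions, mimicking the skew of
    real national production statistics."""

    mu: float = 10.5
    sigma: float = 1.4


@dataclass(frozen=True)
class WorldConfig:
    """Full specification of a synthetic world.  ``seed`` is mandatory."""

    seed: int
    n_countries: int = 30
    n_groups: int = 8
    years: tuple[int, int] = (2012, 2017)
    fmi_spec: FmiRule = field(default_factory=FmiRule)
    production_dist: LogNormalVolumes = field(default_factory=LogNormalVolumes)
    trade_density: float = 0.35
    #: fraction of a hub's imports that it re-exports under its own flag.
    #: Default 0.75 reflects the scale of processing re-exports reported for
    #: the largest seafood processing nations.
    reexport_fraction: float = 0.75
    n_hubs: int = 3
    #: (median, sigma) of the lognormal multiplier applied to trade-table
    #: quantities relative to balance-table truth (customs data report larger
    #: totals than balance sheets; only relative shares survive downstream).
    #: ``None`` disables the disagreement.
    source_disagreement: tuple[float, float] | None = (1.6, 0.35)
    #: fraction of countries whose score is withheld from the score table
    #: (they keep covariates and must be gap-filled downstream).
    missing_fmi_fraction: float = 0.14
    #: fraction of flows labelled as farmed product (exercises the
    #: aquaculture-exclusion mode).
    farmed_fraction: float = 0.10
    #: number of non-food records (ornamentals/feed) per food record,
    #: exercising the non-food filter; these never enter balance or ledger.
    nonfood_fraction: float = 0.05

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if self.n_countries < 2:
            raise ConfigError("n_countries must be >= 2")
        if not 1 <= self.n_groups <= len(ISSCAAP_GROUPS):
            raise ConfigError(f"n_groups must be in 1..{len(ISSCAAP_GROUPS)}")
        for name in ("trade_density", "reexport_fraction",
                     "missing_fmi_fraction", "farmed_fraction",
                     "nonfood_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.reexport_fraction > 0 and self.n_hubs == 0:
            raise ConfigError(
                "reexport_fraction > 0 requires at least one hub country"
            )
        if self.n_hubs > max(self.n_countries - 2, 0):
            raise ConfigError(
                "n_hubs must leave at least one exporter and one importer"
            )
        if self.years[0] > self.years[1]:
            raise ConfigError("years must be an increasing (first, last) pair")


@dataclass
class SyntheticWorld:
    """Generated tables plus ground truth and generation audit."""

    config: WorldConfig
    balance: pd.DataFrame
    trade: pd.DataFrame
    fmi: pd.DataFrame           # observed (possibly masked) scores
    fmi_true: pd.DataFrame      # all countries, generating values
    covariates: pd.DataFrame
    harmonization: pd.DataFrame
    conversion_factors: pd.DataFrame
    product_groups: pd.DataFrame   # product_code -> ISSCAAP group
    ledger: pd.DataFrame           # the ProvenanceLedger (tidy form)
    audit: dict

    @property
    def product_group_mapping(self) -> dict:
        return dict(zip(self.product_groups["product_code"],
                        self.product_groups["product_group"]))

    def write(self, outdir) -> None:
        """Emit all tables as the CSV schemas the ingestion layer reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("balance", "trade", "fmi", "covariates",
                     "harmonization", "conversion_factors",
                     "product_groups", "ledger"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       float_format="%.12g")


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Split integer ``total`` proportionally to ``weights`` into integers
    summing exactly to ``total`` (largest-remainder method, ties broken by
    index).  Guarantees ``out[i] <= ceil(total * w_i / sum(w))``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or total <= 0:
        return np.zeros(len(w), dtype=np.int64)
    exact = total * (w / w.sum())
    base = np.floor(exact).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        # stable argsort on negated fractional part -> ties go to lower index
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a closed synthetic seafood economy.

    Deterministic given ``config.seed``; repeated calls return byte-identical
    tables.  Mass balance holds exactly per (country, group, year):
    consumption + exports = production + imports.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_countries
    countries = [f"C{i:02d}" for i in range(1, n + 1)]
    groups = list(ISSCAAP_GROUPS[: cfg.n_groups])
    years = list(range(cfg.years[0], cfg.years[1] + 1))

    # --- country attributes -------------------------------------------------
    regions = [GEO_REGIONS[i % len(GEO_REGIONS)] for i in range(n)]
    spi = np.round(rng.uniform(45.0, 95.0, n), 1)
    offsets = np.array([cfg.fmi_spec.region_offsets[
        GEO_REGIONS.index(r) % len(cfg.fmi_spec.region_offsets)]
        for r in regions])
    noise = rng.normal(0.0, cfg.fmi_spec.noise_sd, n)
    fmi_true = np.clip(
        cfg.fmi_spec.intercept + cfg.fmi_spec.spi_coef * spi + offsets + noise,
        0.0, 1.0,
    )

    # --- roles --------------------------------------------------------------
    idx = np.arange(n)
    hub_idx = np.sort(rng.choice(idx, size=cfg.n_hubs, replace=False))
    rest = np.array([i for i in idx if i not in set(hub_idx.tolist())])
    perm = rng.permutation(rest)
    n_exp = max(1, len(perm) // 2)
    exporter_idx = np.sort(perm[:n_exp])
    importer_idx = np.sort(perm[n_exp:])
    if len(importer_idx) == 0:  # pragma: no cover - guarded by config check
        raise ConfigError("world needs at least one importer")
    roles = {}
    for i in idx:
        roles[countries[i]] = (
            "hub" if i in set(hub_idx.tolist())
            else "exporter" if i in set(exporter_idx.tolist())
            else "importer"
        )

    # --- production (integer units of 1/Q t) --------------------------------
    mu_g = cfg.production_dist.mu + np.linspace(-0.5, 0.5, len(groups))
    prod_units = {}  # (country, group, year) -> int
    for y in years:
        for gi, g in enumerate(groups):
            draws = rng.lognormal(mu_g[gi], cfg.production_dist.sigma, n)
            for ci, c in enumerate(countries):
                prod_units[(c, g, y)] = int(round(draws[ci] * Q))

    # --- product codes & conversion factors ---------------------------------
    code_rows, cf_rows, codes_by_group = [], [], {}
    for gi, g in enumerate(groups):
        codes = [f"03{gi + 1:02d}0", f"03{gi + 1:02d}5"]
        codes_by_group[g] = codes
        for k, code in enumerate(codes):
            cf = _CODE_CFS[(gi + k) % len(_CODE_CFS)]
            code_rows.append({"product_code": code, "product_group": g})
            cf_rows.append({"match_key": code, "cf": cf, "source": "fao",
                            "note": f"synthetic factor for {g}"})
    cf_rows.append({"match_key": "*", "cf": 1.0, "source": "default",
                    "note": "fallback for unmatched products"})
    cf_by_code = {r["match_key"]: r["cf"] for r in cf_rows[:-1]}

    # --- trade flows ---------------------------------------------------------
    # flows: list of (year, group, origin_breakdown{origin: units}, exp, imp)
    flows = []
    inflow = {}   # (country, group, year) -> {origin: units}
    outflow_units = {}  # (country, group, year) -> int
    shipped_origins = {}  # (country, group, year) -> {origin: units shipped}

    hub_names = [countries[i] for i in hub_idx]
    imp_names = [countries[i] for i in importer_idx]
    exp_names = [countries[i] for i in exporter_idx]
    direct_dests = sorted(imp_names + hub_names)

    def _add_flow(y, g, exp, imp, origins):
        units = sum(origins.values())
        if units <= 0:
            return
        flows.append((y, g, exp, imp, dict(origins)))
        d = inflow.setdefault((imp, g, y), {})
        s = shipped_origins.setdefault((exp, g, y), {})
        for o, u in origins.items():
            d[o] = d.get(o, 0) + u
            s[o] = s.get(o, 0) + u
        outflow_units[(exp, g, y)] = outflow_units.get((exp, g, y), 0) + units

    for y in years:
        for g in groups:
            # direct exports from producers
            for e in exp_names:
                mask = rng.random(len(direct_dests)) < cfg.trade_density
                dests = [d for d, m in zip(direct_dests, mask) if m]
                frac = rng.uniform(0.2, 0.6)
                if not dests:
                    continue
                total = int(round(frac * prod_units[(e, g, y)]))
                if total <= 0:
                    continue
                alloc = _apportion(total, rng.dirichlet(np.ones(len(dests))))
                for d, u in zip(dests, alloc):
                    if u > 0:
                        _add_flow(y, g, e, d, {e: int(u)})
            # hub re-exports, drawn proportionally from import origin mix
            for h in hub_names:
                mix = inflow.get((h, g, y), {})
                total_in = sum(mix.values())
                reexp = int(round(cfg.reexport_fraction * total_in))
                if reexp <= 0:
                    continue
                mask = rng.random(len(imp_names)) < cfg.trade_density
                dests = [d for d, m in zip(sorted(imp_names), mask) if m]
                if not dests:
                    dests = [sorted(imp_names)[
                        int(rng.integers(0, len(imp_names)))]]
                alloc = _apportion(reexp, rng.dirichlet(np.ones(len(dests))))
                remaining = dict(mix)
                origins_sorted = sorted(remaining)
                for d, u in zip(dests, alloc):
                    if u <= 0:
                        continue
                    w = np.array([remaining[o] for o in origins_sorted],
                                 dtype=float)
                    draw = _apportion(int(u), w)
                    origins = {}
                    for o, du in zip(origins_sorted, draw):
                        if du > 0:
                            if du > remaining[o]:  # pragma: no cover
                                raise AssertionError(
                                    "re-export draw exceeded inflow")
                            remaining[o] -= int(du)
                            origins[o] = int(du)
                    _add_flow(y, g, h, d, origins)

    # --- balance table and provenance ledger ---------------------------------
    bal_rows, ledger_rows = [], []
    for y in years:
        for g in groups:
            for c in countries:
                p = prod_units[(c, g, y)]
                i_units = sum(inflow.get((c, g, y), {}).values())
                e_units = outflow_units.get((c, g, y), 0)
                cons = p + i_units - e_units
                if cons < 0:  # pragma: no cover - impossible by construction
                    raise AssertionError("closed world produced negative C")
                bal_rows.append({
                    "country_id": c, "product_group": g, "year": y,
                    "production_t": p / Q, "imports_t": i_units / Q,
                    "exports_t": e_units / Q, "food_supply_t": cons / Q,
                })
                # consumption origins: pool = own production + import origin
                # mix, minus what was shipped out of that pool (exporters
                # ship own production; hubs ship from their import mix)
                pool = {c: p}
                for o, u in inflow.get((c, g, y), {}).items():
                    pool[o] = pool.get(o, 0) + u
                for o, u in shipped_origins.get((c, g, y), {}).items():
                    pool[o] = pool.get(o, 0) - u
                origin_units = {o: u for o, u in pool.items() if u > 0}
                if any(u < 0 for u in pool.values()):  # pragma: no cover
                    raise AssertionError("shipped more than available")
                assert sum(origin_units.values()) == cons
                for o, u in sorted(origin_units.items()):
                    ledger_rows.append({
                        "consumer_id": c, "product_group": g, "year": y,
                        "origin_id": o, "tonnes": u / Q,
                    })

    balance = pd.DataFrame(bal_rows)
    ledger = pd.DataFrame(ledger_rows)

    # --- trade records (product weight, two reporting legs) ------------------
    if cfg.source_disagreement is None:
        factors = np.ones(n)
    else:
        med, sig = cfg.source_disagreement
        factors = rng.lognormal(np.log(med), sig, n)
    factor = dict(zip(countries, factors))

    trade_rows = []
    n_farmed = 0
    for (y, g, exp, imp, origins) in flows:
        units = sum(origins.values())
        codes = codes_by_group[g]
        code = codes[int(rng.integers(0, len(codes)))]
        cf = cf_by_code[code]
        pw = (units / Q) / cf  # exact: cf is a power of two
        farmed = rng.random() < cfg.farmed_fraction
        n_farmed += int(farmed)
        desc = f"{g.lower()}, frozen" + (", farmed" if farmed else "")
        flag = "farmed" if farmed else "unknown"
        for reporter, partner, direction in (
            (imp, exp, "import"), (exp, imp, "export"),
        ):
            trade_rows.append({
                "reporter_id": reporter, "partner_id": partner,
                "direction": direction, "product_code": code,
                "product_desc": desc, "year": y,
                "product_weight_t": pw * factor[reporter],
                "is_food": True, "farmed_flag": flag,
            })
    n_food_records = len(trade_rows)

    n_nonfood = int(round(cfg.nonfood_fraction * n_food_records))
    for _ in range(n_nonfood):
        a, b = rng.choice(idx, size=2, replace=False)
        trade_rows.append({
            "reporter_id": countries[a], "partner_id": countries[b],
            "direction": "import", "product_code": "0511",
            "product_desc": "ornamental fish, live", "year":
                years[int(rng.integers(0, len(years)))],
            "product_weight_t": round(float(rng.lognormal(2.0, 1.0)), 3),
            "is_food": False, "farmed_flag": "unknown",
        })
    from .definitions import TRADE_COLUMNS
    trade = pd.DataFrame(trade_rows, columns=list(TRADE_COLUMNS))
    trade["is_food"] = trade["is_food"].astype(bool)

    # --- scores, covariates, harmonization -----------------------------------
    covariates = pd.DataFrame({
        "country_id": countries, "spi": spi, "geo_region": regions,
    })
    fmi_true_df = pd.DataFrame({
        "country_id": countries, "fmi": fmi_true,
        "provenance": "surveyed", "se": np.nan,
    })
    mask = rng.random(n) < cfg.missing_fmi_fraction
    # keep at least one observed score per region so the gap-fill design
    # matrix stays full rank
    for r in set(regions):
        members = [i for i in range(n) if regions[i] == r]
        if members and all(mask[i] for i in members):
            mask[members[0]] = False
    if mask.all():  # pragma: no cover
        mask[0] = False
    fmi_obs = fmi_true_df.loc[~mask].reset_index(drop=True)

    harmonization = pd.DataFrame({
        "raw_name": countries, "canonical_id": countries,
        "kind": "country", "members": "",
    })
    conversion_factors = pd.DataFrame(cf_rows)
    product_groups = pd.DataFrame(code_rows)

    group_totals: dict[str, float] = {}
    for (_y, g, _e, _i, origins) in flows:
        group_totals[g] = group_totals.get(g, 0.0) + sum(origins.values()) / Q
    audit = {
        "roles": roles,
        "n_flows": len(flows),
        "n_food_records": n_food_records,
        "n_trade_records": len(trade),
        "n_nonfood_records": n_nonfood,
        "n_farmed_flows": n_farmed,
        "masked_fmi": [countries[i] for i in range(n) if mask[i]],
        "disagreement_ratio": {c: 1.0 / factor[c] for c in countries},
        "group_live_totals": group_totals,
    }

    return SyntheticWorld(
        config=cfg, balance=balance, trade=trade, fmi=fmi_obs,
        fmi_true=fmi_true_df, covariates=covariates,
        harmonization=harmonization, conversion_factors=conversion_factors,
        product_groups=product_groups, ledger=ledger, audit=audit,
    )


def true_consumption_fmi(ledger: pd.DataFrame, fmi: pd.DataFrame,
                         include_aggregate: bool = True) -> pd.DataFrame:
    """Ground-truth consumption-weighted score from the provenance ledger.

    For each consumer (per product group, pooled over years, plus an
    ``AGGREGATE`` row over all groups) returns
    ``sum_origins(tonnes_share * fmi_origin)``.
    """
    lf = ledger.merge(
        fmi[["country_id", "fmi"]].rename(
            columns={"country_id": "origin_id", "fmi": "fmi_origin"}),
        on="origin_id", how="left", validate="many_to_one",
    )
    if lf["fmi_origin"].isna().any():
        missing = sorted(lf.loc[lf.fmi_origin.isna(), "origin_id"].unique())
        raise ValueError(f"score table missing origins: {missing}")
    lf["wfmi"] = lf["tonnes"] * lf["fmi_origin"]

    def _collapse(df, keys):
        g = df.groupby(keys, as_index=False)[["tonnes", "wfmi"]].sum()
        g = g[g["tonnes"] > 0]
        g["true_fmi_c"] = g["wfmi"] / g["tonnes"]
        return g.drop(columns="wfmi")

    per_group = _collapse(lf, ["consumer_id", "product_group"])
    if not include_aggregate:
        return per_group.reset_index(drop=True)
    agg = _collapse(lf, ["consumer_id"])
    agg.insert(1, "product_group", AGGREGATE)
    return (
        pd.concat([per_group, agg], ignore_index=True)
        .sort_values(["consumer_id", "product_group"])
        .reset_index(drop=True)
    )


def true_consumption_fmi_exact(ledger: pd.DataFrame,
                               fmi: pd.DataFrame) -> dict:
    """Aggregate ledger truth per consumer in exact rational arithmetic.

    Returns ``{consumer_id: Fraction}``.  Used to state exactness claims
    without floating-point slack; the float variant is
    :func:`true_consumption_fmi`.
    """
    score = {c: Fraction(v) for c, v in
             zip(fmi["country_id"], fmi["fmi"])}
    num, den = {}, {}
    for row in ledger.itertuples(index=False):
        t = Fraction(row.tonnes)
        num[row.consumer_id] = (
            num.get(row.consumer_id, Fraction(0)) + t * score[row.origin_id])
        den[row.consumer_id] = den.get(row.consumer_id, Fraction(0)) + t
    return {c: num[c] / den[c] for c in num if den[c] > 0}


def constant_import_mix_world(n_importers: int = 20, seed: int = 0,
                              exporter_fmi: float | None = None):
    """World in which every importer buys only from one exporter.

    All importers then share the same import-side score (the exporter's own
    score ``g``), so under a fixed domestic-share derivation with weight
    ``p`` the consumption score is exactly ``p * FMI_P + (1 - p) * g`` — a
    straight line whose OLS fit recovers the mixing weight analytically.
    The exporter's own autarky point ``(g, g)`` also lies on that line.

    Returns ``(balance, trade, fmi, g)`` with trade already in live weight
    and classified (no conversion step needed).
    """
    rng = np.random.default_rng(seed)
    exporter = "X00"
    importers = [f"I{i:02d}" for i in range(1, n_importers + 1)]
    groups = list(ISSCAAP_GROUPS[:2])
    g_val = float(exporter_fmi) if exporter_fmi is not None \
        else float(np.round(rng.uniform(0.3, 0.9), 3))

    bal_rows, trade_rows = [], []
    year = 2015
    for g in groups:
        flows = np.round(rng.uniform(10.0, 500.0, n_importers), 3)
        for imp, f in zip(importers, flows):
            p = float(np.round(rng.uniform(50.0, 2000.0), 3))
            bal_rows.append({"country_id": imp, "product_group": g,
                             "year": year, "production_t": p,
                             "imports_t": float(f), "exports_t": 0.0,
                             "food_supply_t": p + float(f)})
            trade_rows.append({
                "reporter_id": imp, "partner_id": exporter,
                "direction": "import", "product_code": "0300",
                "product_desc": f"{g.lower()}, whole", "year": year,
                "product_weight_t": float(f), "live_weight_t": float(f),
                "product_group": g, "is_food": True,
                "farmed_flag": "unknown",
            })
        total_exp = float(flows.sum())
        bal_rows.append({"country_id": exporter, "product_group": g,
                         "year": year, "production_t": total_exp + 100.0,
                         "imports_t": 0.0, "exports_t": total_exp,
                         "food_supply_t": 100.0})
    fmi = pd.DataFrame({
        "country_id": [exporter] + importers,
        "fmi": [g_val] + list(np.round(rng.uniform(0.15, 0.95,
                                                   n_importers), 3)),
        "provenance": "surveyed", "se": np.nan,
    })
    return pd.DataFrame(bal_rows), pd.DataFrame(trade_rows), fmi, g_val


def estimator_bias_study(reexport_fractions=(0.0, 0.3, 0.6),
                         derivations=("proportional", "gephart", "guillen"),
                         n_seeds: int = 5, seed: int = 0,
                         base_config: WorldConfig | None = None
                         ) -> pd.DataFrame:
    """Mean absolute error of the estimated consumption score against ledger
    truth, by re-export fraction and derivation.

    The default base world isolates re-export bias: no score masking, no
    source disagreement, no non-food noise.  At ``reexport_fraction = 0``
    the proportional derivation is exact, so its error row is zero up to
    float round-off.
    """
    from .model import SeafoodSustainabilityModel  # local: avoid cycle

    if base_config is None:
        base_config = WorldConfig(
            seed=0, n_countries=12, n_groups=3, n_hubs=2,
            trade_density=0.5, missing_fmi_fraction=0.0,
            source_disagreement=None, farmed_fraction=0.0,
            nonfood_fraction=0.0,
        )
    rows = []
    for rf in reexport_fractions:
        for k in range(n_seeds):
            cfg = dataclasses.replace(
                base_config, reexport_fraction=float(rf),
                seed=(seed + 7919 * k + 104729 * int(round(100 * rf)))
                % (2 ** 31),
            )
            world = generate_world(cfg)
            res = SeafoodSustainabilityModel.from_world(world).fit(
                derivations=derivations)
            truth = true_consumption_fmi(world.ledger, world.fmi_true)
            truth_agg = truth[truth.product_group == AGGREGATE].set_index(
                "consumer_id")["true_fmi_c"]
            agg = res.results[res.results.product_group == AGGREGATE]
            for der in derivations:
                sub = agg[agg.derivation == der].set_index("country_id")
                common = sub.index.intersection(truth_agg.index)
                err = (sub.loc[common, "fmi_c"]
                       - truth_agg.loc[common]).abs()
                rows.append({"reexport_fraction": float(rf),
                             "derivation": der, "seed": cfg.seed,
                             "mae": float(err.mean()),
                             "n_countries": int(len(common))})
    out = pd.DataFrame(rows)
    return (
        out.groupby(["reexport_fraction", "derivation"], as_index=False)
        .agg(mae=("mae", "mean"), n_countries=("n_countries", "sum"))
        .sort_values(["derivation", "reexport_fraction"])
        .reset_index(drop=True)
    )
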