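"""Propagating production-sustainability scores through the trade network.

Per product group and country the chain is:

1. **consumption** from the balance identity ``C = P + I - E`` (negative
   results, which real balance sheets can produce, are floored at zero so
   aggregation weights stay non-negative);
2. a **global score** per product group: the production-share-weighted
   mean of country scores, ``FMI_glbl = sum_k pP_glbl,k * FMI_P,k`` — the
   regularizer standing in for untraceable re-exported product;
3. an **import-side score** per reporter:
   ``FMI_I,r = sum_j pI_rj * (pPE_j * FMI_P,j + pIE_j * FMI_glbl)`` where
   ``pI_rj`` are live-weight partner shares of the reporter's imports and
   ``pPE_j = P_j / (P_j + I_j)`` is the balance-proportional share of
   partner j's exports assumed to come from its own production;
4. a **consumption-side score**
   ``FMI_C,r = pPC_r * FMI_P,r + (1 - pPC_r) * FMI_I,r`` under three
   derivations of the domestic share ``pPC``: balance-proportional
   ``P / (P + I)``, or the fixed literature values 0.365 and 0.74;
5. **aggregation** over product groups, weighted by each group's share of
   total consumption, and the across-derivation mean/min/max per country.

Every weight vector in the chain is a convex combination, so every output
score stays inside the convex hull of the production scores feeding it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .definitions import AGGREGATE
from .errors import ConfigError, MissingCompositionError, SeatraceError
from .ingestion import Harmonization

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DerivationSpec:
    """A rule for the domestic share of consumption ``pPC``.

    ``fixed_ppc is None`` means balance-proportional ``P / (P + I)``;
    otherwise the constant applies to every country with imports.
    """

    name: str
    fixed_ppc: float | None = None

    def __post_init__(self):
        if self.fixed_ppc is not None and not 0 <= self.fixed_ppc <= 1:
            raise ConfigError(
                f"fixed_ppc must be in [0, 1], got {self.fixed_ppc}")


#: The three standard sensitivity derivations: the naive proportional
#: assumption and two fixed domestic-share estimates from the literature
#: (0.365 from a re-export-aware US consumption study; 0.74 from a global
#: multi-region input-output model).
DERIVATIONS: dict[str, DerivationSpec] = {
    "proportional": DerivationSpec("proportional", None),
    "gephart": DerivationSpec("gephart", 0.365),
    "guillen": DerivationSpec("guillen", 0.74),
}
DEFAULT_DERIVATIONS = tuple(DERIVATIONS)


def resolve_derivations(derivations) -> list[DerivationSpec]:
    specs = []
    for d in derivations:
        if isinstance(d, DerivationSpec):
            specs.append(d)
        elif isinstance(d, str):
            if d not in DERIVATIONS:
                raise ConfigError(
                    f"unknown derivation {d!r}; expected one of "
                    f"{sorted(DERIVATIONS)}")
            specs.append(DERIVATIONS[d])
        else:
            raise ConfigError(f"cannot interpret derivation {d!r}")
    if len({s.name for s in specs}) != len(specs):
        raise ConfigError("derivation names must be unique")
    return specs


def compute_consumption(balance: pd.DataFrame) -> pd.DataFrame:
    """Apply the balance identity per row: ``consumption_t = P + I - E``.

    Negative values are floored at zero with a logged warning (balance
    sheets occasionally report exports exceeding supply).
    """
    out = balance.copy()
    raw = (out["production_t"] + out["imports_t"] - out["exports_t"])
    neg = raw < 0
    if neg.any():
        logger.warning(
            "floored %d negative consumption value(s) at 0", int(neg.sum()))
    out["consumption_t"] = raw.clip(lower=0.0)
    return out


def pool_balance(balance: pd.DataFrame) -> pd.DataFrame:
    """Sum balance quantities over the year window per (country, group)."""
    b = balance if "consumption_t" in balance.columns \
        else compute_consumption(balance)
    return (b.groupby(["country_id", "product_group"], as_index=False)
            [["production_t", "imports_t", "exports_t", "consumption_t"]]
            .sum())


def import_shares(trade: pd.DataFrame) -> pd.DataFrame:
    """Live-weight partner shares of each reporter's imports (pooled years).

    Returns tidy rows (reporter_id, product_group, partner_id,
    live_weight_t, share); shares sum to 1 per (reporter, group).
    """
    if "live_weight_t" not in trade.columns:
        raise SeatraceError(
            "trade records need live_weight_t; run conversion first")
    if "product_group" not in trade.columns:
        raise SeatraceError(
            "trade records need product_group; run classification first")
    imp = trade[trade["direction"] == "import"]
    g = (imp.groupby(["reporter_id", "product_group", "partner_id"],
                     as_index=False)["live_weight_t"].sum())
    g = g[g["live_weight_t"] > 0].copy()
    tot = g.groupby(["reporter_id", "product_group"])["live_weight_t"] \
        .transform("sum")
    g["share"] = g["live_weight_t"] / tot
    return g.reset_index(drop=True)


def partner_composition(pooled: pd.DataFrame,
                        harmonization: Harmonization | None = None,
                        partner_ids=None) -> pd.DataFrame:
    """Production/import composition of each potential partner's exports.

    ``p_pe = P / (P + I)`` from pooled balance quantities (the
    proportionality assumption); ``p_ie = 1 - p_pe``.  Group partners get
    the unweighted mean of their members' compositions.  Countries with
    ``P + I = 0`` get NaN (no export basis).
    """
    denom = pooled["production_t"] + pooled["imports_t"]
    base = pd.DataFrame({
        "country_id": pooled["country_id"],
        "product_group": pooled["product_group"],
        "p_pe": np.where(denom > 0, pooled["production_t"] / denom, np.nan),
    })
    frames = [base]
    if harmonization is not None and partner_ids is not None:
        group_ids = [p for p in set(partner_ids)
                     if p in harmonization.group_ids()]
        for gid in sorted(group_ids):
            members = harmonization.members(gid)
            sub = base[base["country_id"].isin(members)]
            if len(sub):
                rows = (sub.groupby("product_group", as_index=False)
                        ["p_pe"].mean())
                rows.insert(0, "country_id", gid)
                frames.append(rows)
    out = pd.concat(frames, ignore_index=True)
    out["p_ie"] = 1.0 - out["p_pe"]
    return out


def production_shares(pooled: pd.DataFrame) -> pd.DataFrame:
    """Global production share ``pP_glbl`` per (product_group, country)."""
    tot = pooled.groupby("product_group")["production_t"].transform("sum")
    out = pd.DataFrame({
        "product_group": pooled["product_group"],
        "country_id": pooled["country_id"],
        "p_pglbl": np.where(tot > 0, pooled["production_t"] / tot, np.nan),
    })
    return out[out["p_pglbl"].notna()].reset_index(drop=True)


def compute_global_fmi(shares: pd.DataFrame, fmi: pd.DataFrame
                       ) -> pd.DataFrame:
    """Production-share-weighted global score per product group.

    ``shares`` rows are (product_group, country_id, p_pglbl); per group the
    weights must sum to 1 within 1e-9 (renormalized) else an error is
    raised.  The result is a convex combination, so it is bounded by the
    min/max country score in each group.
    """
    s = shares.copy()
    sums = s.groupby("product_group")["p_pglbl"].transform("sum")
    bad = (sums - 1.0).abs() > 1e-9
    if bad.any():
        groups = sorted(s.loc[bad, "product_group"].unique())
        raise SeatraceError(
            f"production shares do not sum to 1 for group(s): {groups}")
    s["p_pglbl"] = s["p_pglbl"] / sums
    s = s.merge(fmi[["country_id", "fmi"]], on="country_id", how="left",
                validate="many_to_one")
    if s["fmi"].isna().any():
        missing = sorted(s.loc[s["fmi"].isna(), "country_id"].unique())
        raise SeatraceError(f"no score for producing countries: {missing}")
    s["w"] = s["p_pglbl"] * s["fmi"]
    out = (s.groupby("product_group", as_index=False)["w"].sum()
           .rename(columns={"w": "fmi_glbl"}))
    return out


def compute_fmi_imports(shares: pd.DataFrame, composition: pd.DataFrame,
                        fmi: pd.DataFrame, global_fmi: pd.DataFrame,
                        strict: bool = True) -> pd.DataFrame:
    """Import-side score per (reporter, product_group).

    ``FMI_I,r = sum_j pI_rj * (pPE_j * FMI_P,j + pIE_j * FMI_glbl)`` — a
    convex combination of partner scores and the global regularizer, hence
    in [0, 1].  Partners with positive share but no composition raise
    :class:`~seatrace.errors.MissingCompositionError` unless
    ``strict=False``, in which case their exports are treated as fully
    re-exported (``pPE = 0``, logged).
    """
    df = shares.merge(
        composition.rename(columns={"country_id": "partner_id"}),
        on=["partner_id", "product_group"], how="left",
        validate="many_to_one")
    missing = df["p_pe"].isna()
    if missing.any():
        partners = sorted(df.loc[missing, "partner_id"].unique())
        if strict:
            raise MissingCompositionError(partners)
        logger.info(
            "treating exports of %d partner(s) without composition as "
            "re-exports: %s", len(partners), ", ".join(partners))
        df.loc[missing, "p_pe"] = 0.0
    df = df.merge(
        fmi[["country_id", "fmi"]].rename(
            columns={"country_id": "partner_id", "fmi": "fmi_partner"}),
        on="partner_id", how="left", validate="many_to_one")
    if df["fmi_partner"].isna().any():
        bad = sorted(df.loc[df["fmi_partner"].isna(),
                            "partner_id"].unique())
        raise SeatraceError(f"no score for trade partner(s): {bad}")
    df = df.merge(global_fmi, on="product_group", how="left",
                  validate="many_to_one")
    df["contrib"] = df["share"] * (
        df["p_pe"] * df["fmi_partner"]
        + (1.0 - df["p_pe"]) * df["fmi_glbl"])
    return (df.groupby(["reporter_id", "product_group"], as_index=False)
            ["contrib"].sum()
            .rename(columns={"contrib": "fmi_i"}))


@dataclass
class PropagationResult:
    """Everything the propagation computed, for results objects and audits.

    ``results`` is tidy: one row per (country, product group, derivation)
    plus AGGREGATE rows per (country, derivation); ``summary`` is one row
    per country with the production score, each derivation's aggregate
    consumption score, and their mean/min/max.
    """

    results: pd.DataFrame
    summary: pd.DataFrame
    global_fmi: pd.DataFrame
    production_shares: pd.DataFrame
    import_shares: pd.DataFrame
    composition: pd.DataFrame
    fmi_imports: pd.DataFrame
    logs: dict = field(default_factory=dict)


def derive_consumption(pooled: pd.DataFrame, fmi: pd.DataFrame,
                       fmi_imports_df: pd.DataFrame,
                       global_fmi: pd.DataFrame,
                       spec: DerivationSpec,
                       logs: dict | None = None) -> pd.DataFrame:
    """Per-group consumption score for one derivation.

    Countries with ``P + I = 0`` in a group are omitted (no consumption
    basis).  Zero-import countries get ``pPC`` forced to 1 — the fixed
    literature shares presuppose imports exist — with the override counted.
    Reporters with balance imports but no usable trade shares fall back to
    the global score for their import side (counted).
    """
    logs = logs if logs is not None else {}
    d = pooled.merge(
        fmi[["country_id", "fmi"]].rename(columns={"fmi": "fmi_p"}),
        on="country_id", how="left", validate="many_to_one")
    if d["fmi_p"].isna().any():
        bad = sorted(d.loc[d["fmi_p"].isna(), "country_id"].unique())
        raise SeatraceError(f"no production score for: {bad}")
    basis = d["production_t"] + d["imports_t"]
    omitted = d.loc[basis <= 0, ["country_id", "product_group"]]
    if len(omitted):
        logs.setdefault("omitted_no_basis", 0)
        logs["omitted_no_basis"] += len(omitted)
    d = d[basis > 0].copy()

    d = d.merge(
        fmi_imports_df.rename(columns={"reporter_id": "country_id"}),
        on=["country_id", "product_group"], how="left",
        validate="one_to_one")
    d = d.merge(global_fmi, on="product_group", how="left",
                validate="many_to_one")

    has_imports = (d["imports_t"] > 0).to_numpy()
    if spec.fixed_ppc is None:
        ppc = (d["production_t"]
               / (d["production_t"] + d["imports_t"])).to_numpy()
    else:
        ppc = np.full(len(d), float(spec.fixed_ppc))
        overridden = int((~has_imports).sum())
        if overridden:
            logs["ppc_override"] = logs.get("ppc_override", 0) + overridden
    ppc = np.where(has_imports, ppc, 1.0)

    fmi_i = d["fmi_i"].to_numpy(dtype=float)
    fallback = has_imports & np.isnan(fmi_i)
    if fallback.any():
        logs["fmi_i_global_fallback"] = (
            logs.get("fmi_i_global_fallback", 0) + int(fallback.sum()))
        fmi_i = np.where(fallback, d["fmi_glbl"].to_numpy(), fmi_i)

    fmi_p = d["fmi_p"].to_numpy()
    import_term = np.where(ppc < 1.0, (1.0 - ppc) * fmi_i, 0.0)
    fmi_c = ppc * fmi_p + import_term
    return pd.DataFrame({
        "country_id": d["country_id"].to_numpy(),
        "product_group": d["product_group"].to_numpy(),
        "derivation": spec.name,
        "ppc_used": ppc,
        "fmi_i": np.where(has_imports, fmi_i, np.nan),
        "fmi_c": fmi_c,
        "consumption_t": d["consumption_t"].to_numpy(),
    })


def aggregate_fmi_c(group_results: pd.DataFrame) -> pd.DataFrame:
    """Consumption-weighted aggregate score per (country, derivation).

    Weights are each group's share of the country's total consumption;
    countries whose total consumption is zero are omitted.
    """
    df = group_results[group_results["product_group"] != AGGREGATE].copy()
    tot = df.groupby(["country_id", "derivation"])["consumption_t"] \
        .transform("sum")
    df = df[tot > 0].copy()
    tot = tot[tot > 0]
    df["w"] = df["consumption_t"] / tot
    df["wf"] = df["w"] * df["fmi_c"]
    agg = (df.groupby(["country_id", "derivation"], as_index=False)
           .agg(fmi_c=("wf", "sum"), consumption_t=("consumption_t", "sum")))
    agg.insert(1, "product_group", AGGREGATE)
    agg["ppc_used"] = np.nan
    agg["fmi_i"] = np.nan
    return agg[["country_id", "product_group", "derivation", "ppc_used",
                "fmi_i", "fmi_c", "consumption_t"]]


def run_derivations(balance: pd.DataFrame, trade: pd.DataFrame,
                    fmi: pd.DataFrame,
                    derivations=DEFAULT_DERIVATIONS,
                    harmonization: Harmonization | None = None,
                    strict_composition: bool = True) -> PropagationResult:
    """Full propagation: per-group scores, aggregates, and the
    across-derivation summary (mean and min/max range per country)."""
    specs = resolve_derivations(derivations)
    logs: dict = {}
    pooled = pool_balance(balance)
    shares = import_shares(trade)
    comp = partner_composition(pooled, harmonization,
                               partner_ids=shares["partner_id"].unique())
    pshares = production_shares(pooled)
    glbl = compute_global_fmi(pshares, fmi)
    fmi_i = compute_fmi_imports(shares, comp, fmi, glbl,
                                strict=strict_composition)

    frames = []
    for spec in specs:
        per_group = derive_consumption(pooled, fmi, fmi_i, glbl, spec, logs)
        frames.append(per_group)
        frames.append(aggregate_fmi_c(per_group))
    results = (pd.concat(frames, ignore_index=True)
               .sort_values(["country_id", "product_group", "derivation"])
               .reset_index(drop=True))

    agg = results[results["product_group"] == AGGREGATE]
    wide = agg.pivot(index="country_id", columns="derivation",
                     values="fmi_c")
    der_cols = [s.name for s in specs]
    summary = wide.reindex(columns=der_cols)
    summary["mean_fmi_c"] = summary[der_cols].mean(axis=1)
    summary["min_fmi_c"] = summary[der_cols].min(axis=1)
    summary["max_fmi_c"] = summary[der_cols].max(axis=1)
    summary = summary.reset_index().merge(
        fmi[["country_id", "fmi"]].rename(columns={"fmi": "fmi_p"}),
        on="country_id", how="left")
    summary = summary[["country_id", "fmi_p"] + der_cols
                      + ["mean_fmi_c", "min_fmi_c", "max_fmi_c"]]

    return PropagationResult(
        results=results, summary=summary, global_fmi=glbl,
        production_shares=pshares, import_shares=shares, composition=comp,
        fmi_imports=fmi_i, logs=logs,
    )
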