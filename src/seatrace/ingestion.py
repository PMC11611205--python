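"""Reading, validating, filtering, and harmonizing the input tables.

Three CSV inputs feed the analysis:

* **balance** — food-balance-sheet rows per country x product group x year
  with production, imports, exports (and optionally reported food supply),
  all in tonnes live weight;
* **trade** — bilateral customs records (reporter, partner, direction,
  product code/description, year, tonnes product weight, food and farmed
  flags);
* **harmonization** — mapping from every raw reporter/partner name to a
  canonical country/territory id, or to a group of canonical ids.

Filtering mirrors the cleaning a trade analyst applies to customs data:
drop non-food products, drop flows a country reports between its own
regions, drop aggregate reporters that duplicate their member countries,
and re-key everything to canonical ids.  Any raw name absent from the
harmonization table is a hard error — silent drops would bias the import
shares that drive the downstream propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import (
    BALANCE_COLUMNS,
    BALANCE_OPTIONAL,
    DIRECTIONS,
    FARMED_FLAGS,
    HARMONIZATION_COLUMNS,
    ISSCAAP_GROUPS,
    TRADE_COLUMNS,
)
from .errors import SchemaError, UnmappedNameError, ValidationError

logger = logging.getLogger(__name__)

#: default analysis window (inclusive): the years over which high-resolution
#: bilateral records and balance sheets overlap.
DEFAULT_YEARS = (2012, 2017)


@dataclass(frozen=True)
class HarmonizationEntry:
    raw_name: str
    canonical_id: str
    kind: str  # country | territory | group
    members: tuple[str, ...] = ()


class Harmonization:
    """Total mapping from raw reporter/partner names to canonical ids."""

    def __init__(self, entries):
        self._by_raw: dict[str, HarmonizationEntry] = {}
        self._by_canonical: dict[str, HarmonizationEntry] = {}
        for e in entries:
            if e.kind not in ("country", "territory", "group"):
                raise ValidationError(
                    f"harmonization kind must be country|territory|group, "
                    f"got {e.kind!r} for {e.raw_name!r}")
            if e.kind == "group" and not e.members:
                raise ValidationError(
                    f"group entry {e.raw_name!r} has no members")
            if e.kind != "group" and e.members:
                raise ValidationError(
                    f"non-group entry {e.raw_name!r} lists members")
            if e.raw_name in self._by_raw:
                raise ValidationError(
                    f"duplicate raw name {e.raw_name!r}")
            self._by_raw[e.raw_name] = e
            self._by_canonical.setdefault(e.canonical_id, e)
        # group membership must be acyclic: members may not be groups
        for e in entries:
            for m in e.members:
                me = self._by_canonical.get(m)
                if me is not None and me.kind == "group":
                    raise ValidationError(
                        f"group {e.raw_name!r} contains group member {m!r}")

    @classmethod
    def from_csv(cls, path) -> "Harmonization":
        df = _read_csv(path, HARMONIZATION_COLUMNS, optional=("members",))
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Harmonization":
        entries = []
        members_col = df["members"] if "members" in df else [""] * len(df)
        for raw, canon, kind, members in zip(
                df["raw_name"], df["canonical_id"], df["kind"], members_col):
            mem = tuple(m.strip() for m in str(members).split(";")
                        if m.strip()) if pd.notna(members) else ()
            entries.append(HarmonizationEntry(str(raw), str(canon),
                                              str(kind), mem))
        return cls(entries)

    @classmethod
    def identity(cls, ids, kind: str = "country") -> "Harmonization":
        return cls([HarmonizationEntry(i, i, kind) for i in ids])

    def __contains__(self, raw_name) -> bool:
        return raw_name in self._by_raw or raw_name in self._by_canonical

    def entry(self, raw_name) -> HarmonizationEntry:
        e = self._by_raw.get(raw_name)
        if e is None:
            # canonical ids are implicitly mapped to themselves, which makes
            # filtering idempotent even if only raw aliases are listed
            e = self._by_canonical.get(raw_name)
        if e is None:
            raise UnmappedNameError([raw_name])
        return e

    def canonical(self, raw_name) -> str:
        return self.entry(raw_name).canonical_id

    def kind(self, raw_name) -> str:
        return self.entry(raw_name).kind

    def members(self, canonical_id) -> tuple[str, ...]:
        e = self._by_canonical.get(canonical_id)
        return e.members if e is not None else ()

    def group_ids(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, e in self._by_canonical.items()
                            if e.kind == "group"))


def _read_csv(path, required, optional=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], skipinitialspace=True)
    missing = [c for c in required if c not in df.columns
               and c not in optional]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s): {', '.join(missing)}")
    return df


def _numeric(df, col, source, allow_na=False):
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:5]]  # +2: header + 1-base
        vals = ", ".join(repr(v) for v in raw[bad].head(3))
        raise ValidationError(
            f"{source}: cannot parse {col} at line(s) {', '.join(lines)}"
            f" (values {vals})")
    if not allow_na and out.isna().any():
        lines = [str(i + 2) for i in df.index[out.isna()][:5]]
        raise ValidationError(
            f"{source}: missing {col} at line(s) {', '.join(lines)}")
    return out


def _check_non_negative(df, cols, source):
    for c in cols:
        neg = df[c] < 0
        if neg.any():
            rows = ", ".join(str(i) for i in df.index[neg][:5])
            raise ValidationError(
                f"{source}: negative {c} at row index {rows}")


def load_balance_table(path, years: tuple[int, int] | None = DEFAULT_YEARS
                       ) -> pd.DataFrame:
    """Load and validate a food-balance table.

    Quantities are tonnes live weight (the ``_t`` suffix is part of the
    schema; files in other units fail the header check).  Rows outside the
    ``years`` window (inclusive) are dropped at load; pass ``None`` to keep
    all years.
    """
    df = _read_csv(path, BALANCE_COLUMNS)
    name = Path(path).name
    df["year"] = _numeric(df, "year", name).astype(int)
    for c in ("production_t", "imports_t", "exports_t"):
        df[c] = _numeric(df, c, name).astype(float)
    if "food_supply_t" in df.columns:
        df["food_supply_t"] = _numeric(df, "food_supply_t", name,
                                       allow_na=True).astype(float)
    _check_non_negative(
        df, ("production_t", "imports_t", "exports_t"), name)
    bad_groups = sorted(set(df["product_group"]) - set(ISSCAAP_GROUPS))
    if bad_groups:
        raise ValidationError(
            f"{name}: unknown product group(s): {', '.join(bad_groups)}")
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    dup = df.duplicated(["country_id", "product_group", "year"])
    if dup.any():
        keys = df.loc[dup, ["country_id", "product_group", "year"]].iloc[0]
        raise ValidationError(
            f"{name}: duplicate (country, group, year) key: "
            f"{tuple(keys)}")
    keep = list(BALANCE_COLUMNS) + [c for c in BALANCE_OPTIONAL
                                    if c in df.columns]
    return df[keep].reset_index(drop=True)


def load_trade_table(path, years: tuple[int, int] | None = DEFAULT_YEARS
                     ) -> pd.DataFrame:
    """Load and validate bilateral trade records (tonnes product weight).

    Direction tags and flags are checked; no partner validation or
    filtering happens here (see :func:`filter_trade`).
    """
    df = _read_csv(path, TRADE_COLUMNS)
    name = Path(path).name
    if len(df) == 0:
        df = df.astype({"product_weight_t": float})
        df["year"] = df.get("year", pd.Series(dtype=int))
        return df.reset_index(drop=True)
    df["year"] = _numeric(df, "year", name).astype(int)
    df["product_weight_t"] = _numeric(df, "product_weight_t", name
                                      ).astype(float)
    _check_non_negative(df, ("product_weight_t",), name)
    bad_dir = sorted(set(df["direction"]) - set(DIRECTIONS))
    if bad_dir:
        raise ValidationError(
            f"{name}: direction must be one of {DIRECTIONS}, "
            f"got {bad_dir}")
    df["is_food"] = df["is_food"].astype(str).str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False})
    if df["is_food"].isna().any():
        raise ValidationError(f"{name}: is_food must be true/false")
    df["farmed_flag"] = df["farmed_flag"].fillna("unknown")
    bad_flag = sorted(set(df["farmed_flag"]) - set(FARMED_FLAGS))
    if bad_flag:
        raise ValidationError(
            f"{name}: farmed_flag must be one of {FARMED_FLAGS}, "
            f"got {bad_flag}")
    df["product_desc"] = df["product_desc"].fillna("")
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    return df[list(TRADE_COLUMNS)].reset_index(drop=True)


def filter_trade(trade: pd.DataFrame, harmonization: Harmonization
                 ) -> tuple[pd.DataFrame, dict]:
    """Clean bilateral records and re-key them to canonical ids.

    Removal rules, each counted in the returned audit dict:

    * ``non_food`` — records with ``is_food`` false (ornamentals, oils,
      feed, capsules);
    * ``group_reporter`` — reporters that are aggregates of member
      countries (kind ``group``) and would double-count their members;
    * ``intra_national`` — reporter and partner mapping to the same
      canonical id (trade between regions of one country);
    * ``duplicates_summed`` — duplicate (reporter, partner, product, year,
      direction) rows are summed, preserving totals.

    Raw names absent from the harmonization table raise
    :class:`~seatrace.errors.UnmappedNameError`.  The operation is
    idempotent: filtering an already-filtered table removes nothing.
    """
    audit = {"non_food": 0, "group_reporter": 0, "intra_national": 0,
             "duplicates_summed": 0}
    df = trade.copy()

    food = df["is_food"].astype(bool)
    audit["non_food"] = int((~food).sum())
    df = df[food]

    unmapped = [x for x in
                set(df["reporter_id"]).union(df["partner_id"])
                if x not in harmonization]
    if unmapped:
        raise UnmappedNameError(unmapped)

    rep_kind = df["reporter_id"].map(lambda r: harmonization.kind(r))
    keep = rep_kind != "group"
    audit["group_reporter"] = int((~keep).sum())
    df = df[keep]

    df = df.assign(
        reporter_id=df["reporter_id"].map(harmonization.canonical),
        partner_id=df["partner_id"].map(harmonization.canonical),
    )
    intra = df["reporter_id"] == df["partner_id"]
    audit["intra_national"] = int(intra.sum())
    df = df[~intra]

    key = ["reporter_id", "partner_id", "product_code", "year", "direction"]
    n_before = len(df)
    agg = {"product_weight_t": "sum", "product_desc": "first",
           "is_food": "first", "farmed_flag": "first"}
    for extra in ("live_weight_t",):
        if extra in df.columns:
            agg[extra] = "sum"
    for extra in ("product_group", "cf", "cf_rule"):
        if extra in df.columns:
            agg[extra] = "first"
    df = df.groupby(key, as_index=False).agg(agg)
    audit["duplicates_summed"] = n_before - len(df)
    for rule, count in audit.items():
        if count:
            logger.info("filter_trade removed %d records (%s)", count, rule)
    cols = [c for c in list(TRADE_COLUMNS) + ["live_weight_t",
                                              "product_group", "cf",
                                              "cf_rule"]
            if c in df.columns]
    return df[cols].sort_values(key).reset_index(drop=True), audit


def compare_source_magnitudes(balance: pd.DataFrame, trade: pd.DataFrame
                              ) -> pd.DataFrame:
    """Total live-weight imports per country from each source, with ratio.

    ``ratio = balance_imports_t / trade_imports_t`` (NaN when the trade
    total is zero).  The downstream propagation uses only *relative*
    partner shares from trade records, so magnitude disagreement between
    the sources — common between balance sheets and customs data — does
    not bias it; this diagnostic quantifies the disagreement.
    """
    if "live_weight_t" not in trade.columns:
        raise ValidationError(
            "trade records need live_weight_t; run conversion first")
    b = (balance.groupby("country_id", as_index=False)["imports_t"].sum()
         .rename(columns={"imports_t": "balance_imports_t"}))
    t = (trade[trade["direction"] == "import"]
         .groupby("reporter_id", as_index=False)["live_weight_t"].sum()
         .rename(columns={"reporter_id": "country_id",
                          "live_weight_t": "trade_imports_t"}))
    out = b.merge(t, on="country_id", how="outer").fillna(
        {"balance_imports_t": 0.0, "trade_imports_t": 0.0})
    out["ratio"] = np.where(out["trade_imports_t"] > 0,
                            out["balance_imports_t"]
                            / out["trade_imports_t"], np.nan)
    return out.sort_values("country_id").reset_index(drop=True)
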