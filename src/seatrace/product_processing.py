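"""Product-weight conversion, ISSCAAP classification, aquaculture exclusion.

Customs records are in tonnes of *product* (fillets, canned, dried...);
balance sheets are in live-weight equivalents.  A conversion-factor table
maps each product back to live weight.  Matching precedence encodes
"closest taxonomic relative first": the longest exact code-prefix match
wins over any keyword match, which wins over the mandatory default factor
of 1 (used for confidential or otherwise undescribed products, where the
product weight itself is the only defensible estimate).

The aquaculture exclusion is a pipeline *mode*, not a destructive
transform: management-intensity scores describe wild-capture governance,
so a parallel analysis removes records plausibly tied to farming
(explicit farmed/cultured/cultivated labels, species common in
aquaculture, and generalized listings such as "oysters" whose mode of
capture cannot be told) unless the description explicitly exempts them
("not farmed", "excluding farmed").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import UnmappedProductError, ValidationError

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    """Lowercase and collapse whitespace for keyword matching."""
    return _WS.sub(" ", str(text).strip().lower())


@dataclass(frozen=True)
class ConversionFactor:
    match_key: str   # code prefix or keyword pattern; "*" for the default
    cf: float        # live weight = product weight * cf
    source: str      # fao | proxy | default
    note: str = ""


class ConversionFactorTable:
    """Ordered conversion-factor entries with documented match precedence."""

    def __init__(self, factors):
        factors = list(factors)
        defaults = [f for f in factors if f.source == "default"]
        if len(defaults) != 1:
            raise ValidationError(
                f"conversion table needs exactly one default entry, "
                f"found {len(defaults)}")
        if defaults[0].cf != 1.0:
            raise ValidationError("the default conversion factor must be 1")
        for f in factors:
            if not f.cf > 0:
                raise ValidationError(
                    f"conversion factor must be > 0: {f.match_key!r}")
        self._factors = factors
        self._default = defaults[0]

    @property
    def default(self) -> ConversionFactor:
        return self._default

    def __iter__(self):
        return iter(self._factors)

    @classmethod
    def from_csv(cls, path) -> "ConversionFactorTable":
        df = pd.read_csv(path, dtype={"match_key": str}, keep_default_na=False)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConversionFactorTable":
        return cls(ConversionFactor(str(r.match_key), float(r.cf),
                                    str(r.source), str(getattr(r, "note", "")))
                   for r in df.itertuples(index=False))

    def match(self, product_code: str, product_desc: str = ""
              ) -> tuple[ConversionFactor, str]:
        """Pick the factor for a product.

        Precedence: longest exact code-prefix match, then longest keyword
        (case-insensitive substring of the description), then the default.
        Returns ``(factor, rule)`` with rule in {prefix, keyword, default}.
        """
        code = str(product_code)
        prefix_hits = [f for f in self._factors
                       if f.source != "default" and f.match_key
                       and code.startswith(f.match_key)]
        if prefix_hits:
            best = max(prefix_hits, key=lambda f: len(f.match_key))
            return best, "prefix"
        desc = _norm(product_desc)
        kw_hits = [f for f in self._factors
                   if f.source != "default" and f.match_key
                   and _norm(f.match_key) in desc]
        if kw_hits:
            best = max(kw_hits, key=lambda f: len(_norm(f.match_key)))
            return best, "keyword"
        return self._default, "default"


def assign_conversion(trade: pd.DataFrame, table: ConversionFactorTable
                      ) -> pd.DataFrame:
    """Attach ``live_weight_t = product_weight_t * cf`` to every record.

    No record is lost or duplicated; the chosen factor and match rule are
    kept per record (``cf``, ``cf_rule``) for audit.
    """
    pairs = trade[["product_code", "product_desc"]].drop_duplicates()
    resolved = {
        (r.product_code, r.product_desc): table.match(r.product_code,
                                                      r.product_desc)
        for r in pairs.itertuples(index=False)
    }
    keys = list(zip(trade["product_code"], trade["product_desc"]))
    out = trade.copy()
    out["cf"] = [resolved[k][0].cf for k in keys]
    out["cf_rule"] = [resolved[k][1] for k in keys]
    out["live_weight_t"] = out["product_weight_t"] * out["cf"]
    return out


def classify_group(trade: pd.DataFrame, mapping: dict[str, str]
                   ) -> pd.DataFrame:
    """Assign the ISSCAAP product group from an exact product-code mapping.

    The mapping must be total over observed codes; unmapped codes raise
    :class:`~seatrace.errors.UnmappedProductError` listing them.
    """
    out = trade.copy()
    out["product_group"] = out["product_code"].map(mapping)
    if out["product_group"].isna().any():
        raise UnmappedProductError(
            out.loc[out["product_group"].isna(), "product_code"].unique())
    return out


@dataclass(frozen=True)
class AquacultureRuleSet:
    """String rules flagging products plausibly derived from aquaculture.

    Exemption keywords are checked first: an explicitly wild-labelled
    product is retained even if its species is common in farming.
    """

    farmed_keywords: tuple[str, ...] = ("farmed", "cultured", "cultivated")
    exemption_keywords: tuple[str, ...] = ("not farmed", "excluding farmed")
    species_list: tuple[str, ...] = ()
    generalized_listings: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "AquacultureRuleSet":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {k: tuple(v) for k, v in data.items()}
        return cls(**kwargs)


def exclude_aquaculture(trade: pd.DataFrame, rules: AquacultureRuleSet
                        ) -> tuple[pd.DataFrame, dict]:
    """Remove records matching the aquaculture rules; return (kept, audit).

    A record is removed iff it hits a farmed keyword, a species-list entry,
    or a generalized listing — and carries no exemption keyword.  Matching
    is case-insensitive substring on whitespace-normalized descriptions.
    The audit counts removals by first matching rule; the operation is
    idempotent and removes nothing when all rule lists are empty.
    """
    audit = {"farmed_keyword": 0, "species": 0, "generalized": 0,
             "exempted": 0}
    descs = trade["product_desc"].map(_norm)
    farmed_flags = trade.get("farmed_flag")

    def _verdict(i, desc):
        if any(_norm(k) in desc for k in rules.exemption_keywords):
            return "exempt"
        if any(_norm(k) in desc for k in rules.farmed_keywords):
            return "farmed_keyword"
        # structured flag counts as an explicit farmed label, but only when
        # the keyword rule is active (empty rule lists remove nothing)
        if (rules.farmed_keywords and farmed_flags is not None
                and farmed_flags.iloc[i] == "farmed"):
            return "farmed_keyword"
        if any(_norm(s) in desc for s in rules.species_list):
            return "species"
        if any(_norm(s) in desc for s in rules.generalized_listings):
            return "generalized"
        return "keep"

    verdicts = [_verdict(i, d) for i, d in enumerate(descs)]
    keep_mask = []
    for v in verdicts:
        if v in ("keep", "exempt"):
            keep_mask.append(True)
            if v == "exempt":
                audit["exempted"] += 1
        else:
            keep_mask.append(False)
            audit[v] += 1
    kept = trade[pd.Series(keep_mask, index=trade.index)]
    removed = len(trade) - len(kept)
    if removed:
        logger.info("aquaculture exclusion removed %d records", removed)
    return kept.reset_index(drop=True), audit
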