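"""Model/Results interface over the full analysis pipeline.

:class:`SeafoodSustainabilityModel` bundles the input tables (balance,
trade, scores, covariates, harmonization, conversion factors) and
``fit()`` executes filter -> convert -> classify -> (optional aquaculture
exclusion) -> score assembly -> propagation, returning a
:class:`SeafoodSustainabilityResults` that carries the per-country
estimates, the disparity and regression tables, trade rankings, and a
printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .definitions import AGGREGATE
from .disparity import (
    disparity_table,
    partner_breakdown,
    rank_traders,
    regression_table,
)
from .errors import SeatraceError
from .fmi_sources import assemble_fmi
from .ingestion import (
    Harmonization,
    compare_source_magnitudes,
    filter_trade,
    load_balance_table,
    load_trade_table,
)
from .product_processing import (
    AquacultureRuleSet,
    ConversionFactorTable,
    assign_conversion,
    classify_group,
    exclude_aquaculture,
)
from .propagation import (
    DEFAULT_DERIVATIONS,
    PropagationResult,
    pool_balance,
    resolve_derivations,
    run_derivations,
)

_CSV_KW = dict(index=False, float_format="%.12g")


@dataclass
class SeafoodSustainabilityModel:
    """Consumption-sustainability propagation model for one seafood economy.

    Parameters
    ----------
    balance : DataFrame
        Food-balance rows (country x product group x year, live weight).
    trade : DataFrame
        Bilateral trade records in product weight.  If ``live_weight_t``
        and ``product_group`` are already present, conversion and
        classification are skipped.
    fmi : DataFrame
        Known production scores (country_id, fmi[, provenance, se]).
    covariates : DataFrame, optional
        SPI and geo-region per country, for gap-filling missing scores.
    harmonization : Harmonization, optional
        Raw-name mapping; enables trade filtering and group partners.
    conversion_factors : ConversionFactorTable, optional
    product_groups : dict, optional
        product_code -> ISSCAAP group mapping.
    aquaculture_rules : AquacultureRuleSet, optional
    exclude_aquaculture : bool
        Run in aquaculture-exclusion mode (parallel analysis).
    """

    balance: pd.DataFrame
    trade: pd.DataFrame
    fmi: pd.DataFrame
    covariates: pd.DataFrame | None = None
    harmonization: Harmonization | None = None
    conversion_factors: ConversionFactorTable | None = None
    product_groups: dict | None = None
    aquaculture_rules: AquacultureRuleSet | None = None
    exclude_aquaculture: bool = False
    strict_composition: bool = True

    @classmethod
    def from_world(cls, world, exclude_aquaculture: bool = False,
                   use_true_fmi: bool = False) -> "SeafoodSustainabilityModel":
        """Build from a :class:`~seatrace.synthetic_world.SyntheticWorld`."""
        return cls(
            balance=world.balance.copy(),
            trade=world.trade.copy(),
            fmi=(world.fmi_true if use_true_fmi else world.fmi).copy(),
            covariates=world.covariates.copy(),
            harmonization=Harmonization.from_frame(world.harmonization),
            conversion_factors=ConversionFactorTable.from_frame(
                world.conversion_factors),
            product_groups=world.product_group_mapping,
            aquaculture_rules=AquacultureRuleSet(),
            exclude_aquaculture=exclude_aquaculture,
        )

    @classmethod
    def from_directory(cls, path, years=(2012, 2017),
                       exclude_aquaculture: bool = False
                       ) -> "SeafoodSustainabilityModel":
        """Build from a directory of CSVs in the documented schemas
        (balance.csv, trade.csv, fmi.csv, covariates.csv,
        harmonization.csv, conversion_factors.csv, product_groups.csv)."""
        p = Path(path)
        pg = pd.read_csv(p / "product_groups.csv", dtype=str)
        cov = p / "covariates.csv"
        return cls(
            balance=load_balance_table(p / "balance.csv", years=years),
            trade=load_trade_table(p / "trade.csv", years=years),
            fmi=pd.read_csv(p / "fmi.csv"),
            covariates=pd.read_csv(cov) if cov.exists() else None,
            harmonization=Harmonization.from_csv(p / "harmonization.csv"),
            conversion_factors=ConversionFactorTable.from_csv(
                p / "conversion_factors.csv"),
            product_groups=dict(zip(pg["product_code"],
                                    pg["product_group"])),
            aquaculture_rules=AquacultureRuleSet(),
            exclude_aquaculture=exclude_aquaculture,
        )

    def fit(self, derivations=DEFAULT_DERIVATIONS
            ) -> "SeafoodSustainabilityResults":
        """Run the full pipeline and return a results object."""
        specs = resolve_derivations(derivations)
        audits: dict = {}
        trade = self.trade

        if self.harmonization is not None:
            trade, audits["filter"] = filter_trade(trade, self.harmonization)
        if ("live_weight_t" not in trade.columns
                and self.conversion_factors is not None):
            trade = assign_conversion(trade, self.conversion_factors)
        if ("product_group" not in trade.columns
                or trade["product_group"].isna().any()):
            if self.product_groups is None:
                raise SeatraceError(
                    "trade records lack product groups and no mapping "
                    "was provided")
            trade = classify_group(trade, self.product_groups)
        if self.exclude_aquaculture:
            rules = self.aquaculture_rules or AquacultureRuleSet()
            trade, audits["aquaculture"] = exclude_aquaculture(trade, rules)

        required = set(self.balance["country_id"])
        required |= set(trade["reporter_id"]) | set(trade["partner_id"])
        fmi = assemble_fmi(self.fmi, self.covariates, self.harmonization,
                           required_ids=required)

        prop = run_derivations(
            self.balance, trade, fmi, derivations=specs,
            harmonization=self.harmonization,
            strict_composition=self.strict_composition)
        return SeafoodSustainabilityResults(
            model=self, propagation=prop, fmi=fmi, trade=trade,
            derivations=tuple(s.name for s in specs), audits=audits)


@dataclass
class SeafoodSustainabilityResults:
    """Fitted estimates plus the derived analysis tables."""

    model: SeafoodSustainabilityModel
    propagation: PropagationResult
    fmi: pd.DataFrame
    trade: pd.DataFrame
    derivations: tuple[str, ...]
    audits: dict = field(default_factory=dict)

    # -- primary outputs ----------------------------------------------------
    @property
    def results(self) -> pd.DataFrame:
        """Tidy per (country, group, derivation) consumption scores."""
        return self.propagation.results

    @property
    def summary_frame(self) -> pd.DataFrame:
        """Per-country production score, per-derivation aggregates,
        mean/min/max."""
        return self.propagation.summary

    @property
    def disparity(self) -> pd.DataFrame:
        """Per-country disparity table (adds percent_change)."""
        return disparity_table(self.summary_frame)

    def top_disparity(self, k: int = 25) -> pd.DataFrame:
        """Disparity for the top-k producers by pooled volume."""
        return disparity_table(self.summary_frame,
                               production=pool_balance(self.model.balance),
                               top=k)

    def regressions(self) -> pd.DataFrame:
        """OLS of each derivation's FMI_C on FMI_P across countries."""
        return regression_table(self.summary_frame, self.derivations)

    def trade_summary(self) -> pd.DataFrame:
        return rank_traders(self.trade)

    def partner_breakdown(self, country_id: str, direction: str = "import",
                          k: int = 25):
        return partner_breakdown(self.trade, country_id, direction, k,
                                 fmi=self.fmi)

    def compare_sources(self) -> pd.DataFrame:
        return compare_source_magnitudes(self.model.balance, self.trade)

    # -- presentation -------------------------------------------------------
    def summary(self, k: int = 10) -> str:
        """Printable overview: headline disparities and regression fits."""
        disp = self.top_disparity(k=min(k, len(self.summary_frame)))
        reg = self.regressions()
        lines = [
            "Seafood consumption-sustainability results",
            "=" * 58,
            f"countries: {len(self.summary_frame)}   "
            f"derivations: {', '.join(self.derivations)}",
            "",
            f"Top {len(disp)} producers, production vs consumption score:",
            disp.to_string(
                index=False,
                formatters={c: "{:.3f}".format for c in
                            ("fmi_p", "mean_fmi_c", "min_fmi_c",
                             "max_fmi_c")}
                | {"percent_change": "{:+.2f}".format},
            ),
            "",
            "OLS fit of consumption on production score (per derivation):",
            reg.to_string(index=False,
                          float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def save(self, out_dir, top_k: int = 25) -> None:
        """Write the report bundle (disparity, regression, trade summary,
        partner breakdowns) as deterministic CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.csv", **_CSV_KW)
        self.disparity.to_csv(out / "disparity.csv", **_CSV_KW)
        self.regressions().to_csv(out / "regression.csv", **_CSV_KW)
        self.trade_summary().to_csv(out / "trade_summary.csv", **_CSV_KW)
        ts = self.trade_summary()
        frames = []
        for direction, col in (("import", "share_of_global_imports"),
                               ("export", "share_of_global_exports")):
            top = ts.sort_values([col, "country_id"],
                                 ascending=[False, True]).head(1)
            if len(top):
                rows, _cov = self.partner_breakdown(
                    top["country_id"].iloc[0], direction, k=top_k)
                rows = rows.assign(country_id=top["country_id"].iloc[0],
                                   direction=direction)
                frames.append(rows)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "partner_breakdown.csv", **_CSV_KW)
        self.fmi.to_csv(out / "fmi_assembled.csv", **_CSV_KW)
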