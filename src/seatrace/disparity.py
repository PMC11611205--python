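"""Production-vs-consumption disparity scoring, regressions, trade ranks.

The headline statistic is the signed percent change

    percent_change = (FMI_P - mean(FMI_C)) / FMI_P * 100,

positive when a country consumes seafood managed less intensively than
what it produces.  The mean is taken over the three consumption-score
derivations, with the min/max retained as a sensitivity range.

Simple OLS of FMI_C on FMI_P per derivation summarizes how strongly
consumption scores track production scores (a fixed domestic share p
with a constant import-side score g gives the analytic line
``FMI_C = p * FMI_P + (1 - p) * g``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .definitions import AGGREGATE
from .errors import ConfigError, ValidationError

_CSV_KW = dict(index=False, float_format="%.12g")


def percent_change(fmi_p, mean_fmi_c):
    """Signed percent change from production to consumption score.

    ``(fmi_p - mean_fmi_c) / fmi_p * 100``; positive means consumption is
    less sustainably managed than production.  Undefined (NaN) when
    ``fmi_p`` is zero.  Accepts scalars or arrays.
    """
    p = np.asarray(fmi_p, dtype=float)
    c = np.asarray(mean_fmi_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p > 0, (p - c) / p * 100.0, np.nan)
    if np.isscalar(fmi_p) and np.isscalar(mean_fmi_c):
        return float(out)
    return out


def disparity_table(summary: pd.DataFrame,
                    production: pd.DataFrame | None = None,
                    top: int | None = None) -> pd.DataFrame:
    """Per-country disparity records from a propagation summary.

    Optionally restrict to the ``top`` producers by pooled production
    volume (``production``: pooled balance frame).
    """
    df = summary.copy()
    df["percent_change"] = percent_change(df["fmi_p"], df["mean_fmi_c"])
    if top is not None:
        if production is None:
            raise ConfigError("top-k selection needs the production frame")
        vol = (production.groupby("country_id")["production_t"].sum()
               .sort_values(ascending=False))
        order = [c for c in vol.index if c in set(df["country_id"])][:top]
        df = df.set_index("country_id").loc[order].reset_index()
        df["production_rank"] = np.arange(1, len(df) + 1)
    cols = ["country_id", "fmi_p", "mean_fmi_c", "min_fmi_c", "max_fmi_c",
            "percent_change"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + [c for c in extra if c == "production_rank"]]


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary for one consumption-score derivation vs FMI_P."""

    derivation: str
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    slope_t: float
    p_value: float
    r2: float
    nobs: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def fit_fmi_relationship(summary: pd.DataFrame, derivation: str
                         ) -> RegressionSummary:
    """OLS of one derivation's aggregate FMI_C on FMI_P across countries."""
    if derivation not in summary.columns:
        raise ConfigError(
            f"summary has no column for derivation {derivation!r}")
    sub = summary[["fmi_p", derivation]].dropna()
    if len(sub) < 3:
        raise ValidationError(
            "need at least 3 countries for the FMI_C ~ FMI_P regression")
    X = sm.add_constant(sub["fmi_p"].to_numpy())
    res = sm.OLS(sub[derivation].to_numpy(), X).fit()
    return RegressionSummary(
        derivation=derivation,
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        slope_t=float(res.tvalues[1]), p_value=float(res.pvalues[1]),
        r2=float(res.rsquared), nobs=int(res.nobs),
    )


def regression_table(summary: pd.DataFrame, derivations) -> pd.DataFrame:
    rows = [fit_fmi_relationship(summary, d).frame() for d in derivations]
    return pd.concat(rows, ignore_index=True)


def rank_traders(trade: pd.DataFrame) -> pd.DataFrame:
    """Global export/import shares and partner counts per country.

    Rankings use pooled live-weight volume over the window; ties are broken
    by lexicographic country id.  ``n_partners`` counts distinct partners
    with nonzero flow in either direction.
    """
    if "live_weight_t" not in trade.columns:
        raise ValidationError(
            "trade records need live_weight_t; run conversion first")
    t = trade[trade["live_weight_t"] > 0]
    totals = {}
    for direction in ("export", "import"):
        sub = t[t["direction"] == direction]
        tot = sub.groupby("reporter_id")["live_weight_t"].sum()
        totals[direction] = tot / tot.sum() if tot.sum() > 0 else tot
    partners = (t.groupby("reporter_id")["partner_id"].nunique())
    countries = sorted(set(t["reporter_id"]))
    out = pd.DataFrame({"country_id": countries})
    out["share_of_global_exports"] = out["country_id"].map(
        totals["export"]).fillna(0.0)
    out["share_of_global_imports"] = out["country_id"].map(
        totals["import"]).fillna(0.0)
    out["n_partners"] = out["country_id"].map(partners).fillna(0).astype(int)
    out = out.sort_values(
        ["share_of_global_exports", "country_id"],
        ascending=[False, True]).reset_index(drop=True)
    out["export_rank"] = (
        out["share_of_global_exports"].rank(method="first", ascending=False)
        .astype(int))
    out["import_rank"] = (
        out.sort_values(["share_of_global_imports", "country_id"],
                        ascending=[False, True])
        ["share_of_global_imports"]
        .rank(method="first", ascending=False)
        .reindex(out.index).astype(int))
    return out


def partner_breakdown(trade: pd.DataFrame, country_id: str,
                      direction: str = "import", k: int = 25,
                      fmi: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, float]:
    """Top-k partner shares of one country's imports or exports.

    Returns ``(rows, coverage)`` where coverage is the summed share of the
    top-k partners (<= 1).  Partner production scores are attached when a
    score table is given.
    """
    sub = trade[(trade["reporter_id"] == country_id)
                & (trade["direction"] == direction)]
    g = (sub.groupby("partner_id", as_index=False)["live_weight_t"].sum())
    total = g["live_weight_t"].sum()
    if total <= 0:
        return g.assign(share=np.nan, rank=np.nan), 0.0
    g["share"] = g["live_weight_t"] / total
    g = g.sort_values(["share", "partner_id"],
                      ascending=[False, True]).head(k).reset_index(drop=True)
    g["rank"] = np.arange(1, len(g) + 1)
    if fmi is not None:
        g = g.merge(fmi[["country_id", "fmi"]].rename(
            columns={"country_id": "partner_id", "fmi": "partner_fmi_p"}),
            on="partner_id", how="left")
    return g, float(g["share"].sum())


def config_hash(obj) -> str:
    """Stable short hash of a (nested dataclass / dict) configuration."""

    def _plain(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: _plain(getattr(x, f.name))
                    for f in dataclasses.fields(x)}
        if isinstance(x, dict):
            return {str(k): _plain(v) for k, v in sorted(x.items())}
        if isinstance(x, (list, tuple)):
            return [_plain(v) for v in x]
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, Path):
            return str(x)
        return x

    payload = json.dumps(_plain(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for a full end-to-end run.

    Either a synthetic ``world`` or a directory of input CSVs
    (``input_dir`` with the schemas the generator writes).  ``modes`` picks
    the parallel analyses: ``core`` keeps all food records, whereas
    ``no_aquaculture`` removes records matching the aquaculture rules.
    """

    world: object | None = None           # WorldConfig
    input_dir: str | None = None
    derivations: tuple[str, ...] = ("proportional", "gephart", "guillen")
    modes: tuple[str, ...] = ("core", "no_aquaculture")
    top_k: int = 25
    years: tuple[int, int] = (2012, 2017)

    def __post_init__(self):
        from .propagation import resolve_derivations
        resolve_derivations(self.derivations)
        bad = set(self.modes) - {"core", "no_aquaculture"}
        if bad:
            raise ConfigError(f"unknown analysis mode(s): {sorted(bad)}")
        if (self.world is None) == (self.input_dir is None):
            raise ConfigError(
                "exactly one of world / input_dir must be given")


def run_full_analysis(config: AnalysisConfig,
                      out_dir: str | None = None) -> dict:
    """Execute ingest -> process -> score assembly -> propagate -> analyze
    for every requested mode; optionally write the report bundle.

    Returns ``{mode: SeafoodSustainabilityResults, "manifest": dict}``.
    Written tables are byte-identical across re-runs at a fixed seed.
    """
    from . import __version__
    from .model import SeafoodSustainabilityModel
    from .synthetic_world import generate_world

    if config.world is not None:
        world = generate_world(config.world)
        seed = config.world.seed

        def _build(mode):
            return SeafoodSustainabilityModel.from_world(
                world, exclude_aquaculture=(mode == "no_aquaculture"))
    else:
        seed = None

        def _build(mode):
            return SeafoodSustainabilityModel.from_directory(
                config.input_dir, years=config.years,
                exclude_aquaculture=(mode == "no_aquaculture"))

    bundle: dict = {}
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "versions": {
            "seatrace": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "modes": {},
    }
    for mode in config.modes:
        res = _build(mode).fit(derivations=config.derivations)
        bundle[mode] = res
        manifest["modes"][mode] = {
            "n_countries": int(res.disparity["country_id"].nunique()),
            "n_result_rows": int(len(res.results)),
            "filter_audit": res.audits.get("filter", {}),
            "aquaculture_audit": res.audits.get("aquaculture", {}),
        }
        if out_dir is not None:
            mode_dir = Path(out_dir) / mode
            mode_dir.mkdir(parents=True, exist_ok=True)
            res.save(mode_dir, top_k=config.top_k)
    bundle["manifest"] = manifest
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return bundle
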