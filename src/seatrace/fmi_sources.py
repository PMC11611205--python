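"""Assembling a complete production-sustainability score table.

The propagation needs a management-intensity score (FMI, in [0, 1]) for
every canonical country, territory, or partner group appearing anywhere in
the balance or trade tables.  Scores come from four provenances, recorded
per estimate:

* ``surveyed`` / ``modeled`` — taken as given from the input table;
* ``gapfilled`` — predicted by an OLS regression of score on the Social
  Progress Index (SPI, 0-100) with geo-region offsets, the standard
  gap-filling model for this score family; predictions are clamped to
  [0, 1] since the score is defined on that interval;
* ``group_mean`` — unweighted arithmetic mean over a group's members
  (e.g. an aggregate trade partner covering several countries); single
  "most closely related country" proxies are groups of size one.

Gap-filling is deterministic: no randomness enters the fit or the
predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import GapfillError, ValidationError
from .ingestion import Harmonization

logger = logging.getLogger(__name__)

PROVENANCES = ("surveyed", "modeled", "gapfilled", "group_mean")


@dataclass
class GapfillModel:
    """Fitted OLS gap-filling model ``fmi ~ spi + C(geo_region)``."""

    params: pd.Series
    bse: pd.Series
    r2: float
    regions: tuple[str, ...]
    _result: object = None

    @property
    def spi_coef(self) -> float:
        return float(self.params["spi"])

    @property
    def spi_se(self) -> float:
        return float(self.bse["spi"])

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Unclamped predictions for rows with ``spi`` and ``geo_region``."""
        unseen = sorted(set(covariates["geo_region"]) - set(self.regions))
        if unseen:
            raise GapfillError(
                "no training observations for region(s): "
                + ", ".join(unseen))
        return np.asarray(self._result.predict(covariates), dtype=float)


def fit_gapfill_model(train: pd.DataFrame) -> GapfillModel:
    """Fit the score-on-SPI-and-region OLS model.

    ``train`` needs columns ``fmi``, ``spi``, ``geo_region`` with no
    missing values.  Requires at least two distinct SPI values and more
    observations than parameters; a region without observations surfaces
    later, at prediction time, as an error naming the region.
    """
    for col in ("fmi", "spi", "geo_region"):
        if col not in train.columns:
            raise ValidationError(f"training data missing column {col!r}")
        if train[col].isna().any():
            raise ValidationError(f"training data has missing {col}")
    if train["spi"].nunique() < 2:
        raise GapfillError(
            "gap-fill design is rank deficient: need >= 2 distinct SPI "
            "values")
    n_params = 1 + 1 + (train["geo_region"].nunique() - 1)
    if len(train) < n_params:
        raise GapfillError(
            f"gap-fill design is rank deficient: {len(train)} observations "
            f"for {n_params} parameters")
    res = smf.ols("fmi ~ spi + C(geo_region)", data=train).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise GapfillError("gap-fill design matrix is rank deficient")
    return GapfillModel(
        params=res.params, bse=res.bse, r2=float(res.rsquared),
        regions=tuple(sorted(train["geo_region"].unique())),
        _result=res,
    )


def gapfill(model: GapfillModel, missing: pd.DataFrame) -> pd.DataFrame:
    """Predict scores for countries without one.

    ``missing`` carries ``country_id``, ``spi``, ``geo_region``.  A missing
    SPI is an error (resolution must be explicit, never silently imputed).
    Predictions are clamped to [0, 1] with a logged count.
    """
    if len(missing) == 0:
        return pd.DataFrame(
            columns=["country_id", "fmi", "provenance", "se"])
    no_spi = missing["spi"].isna()
    if no_spi.any():
        raise GapfillError(
            "missing SPI for countries needing gap-fill: "
            + ", ".join(sorted(missing.loc[no_spi, "country_id"])))
    pred = model.predict(missing)
    clamped = int(((pred < 0) | (pred > 1)).sum())
    if clamped:
        logger.info("gapfill clamped %d prediction(s) to [0, 1]", clamped)
    return pd.DataFrame({
        "country_id": missing["country_id"].to_numpy(),
        "fmi": np.clip(pred, 0.0, 1.0),
        "provenance": "gapfilled",
        "se": np.nan,
    })


def group_fmi(members, estimates) -> float:
    """Unweighted mean score over a group's member countries.

    ``estimates`` maps country_id -> score.  All members must be present.
    """
    members = list(members)
    if not members:
        raise GapfillError("group has no members")
    missing = [m for m in members if m not in estimates]
    if missing:
        raise GapfillError(
            "group members without a score: " + ", ".join(sorted(missing)))
    return float(np.mean([estimates[m] for m in members]))


def assemble_fmi(known: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 harmonization: Harmonization | None = None,
                 required_ids=None) -> pd.DataFrame:
    """Build the complete score table for every required canonical id.

    Steps: validate the known scores, gap-fill countries that have
    covariates but no score, then resolve group ids as member means.
    Ids still unresolved raise :class:`~seatrace.errors.GapfillError`.
    """
    df = known.copy()
    if "provenance" not in df.columns:
        df["provenance"] = "surveyed"
    if "se" not in df.columns:
        df["se"] = np.nan
    bad = ~df["fmi"].between(0.0, 1.0)
    if bad.any():
        raise ValidationError(
            "scores outside [0, 1] for: "
            + ", ".join(sorted(df.loc[bad, "country_id"])))
    dup = df.duplicated("country_id")
    if dup.any():
        raise ValidationError(
            "duplicate score rows for: "
            + ", ".join(sorted(df.loc[dup, "country_id"].unique())))
    bad_prov = sorted(set(df["provenance"]) - set(PROVENANCES))
    if bad_prov:
        raise ValidationError(f"unknown provenance value(s): {bad_prov}")

    required = (set(required_ids) if required_ids is not None
                else set(df["country_id"]))
    have = set(df["country_id"])
    group_ids = set(harmonization.group_ids()) if harmonization else set()
    todo = sorted(required - have)

    fillable = [c for c in todo if c not in group_ids]
    if fillable and covariates is not None:
        cov = covariates.set_index("country_id")
        rows = cov.reindex([c for c in fillable if c in cov.index])
        if len(rows):
            train = df.merge(covariates, on="country_id")
            model = fit_gapfill_model(train)
            filled = gapfill(model, rows.reset_index())
            df = pd.concat([df, filled], ignore_index=True)
            have |= set(filled["country_id"])

    scores = dict(zip(df["country_id"], df["fmi"]))
    group_rows = []
    for gid in sorted(required & group_ids - have):
        members = harmonization.members(gid)
        group_rows.append({"country_id": gid,
                           "fmi": group_fmi(members, scores),
                           "provenance": "group_mean", "se": np.nan})
    if group_rows:
        df = pd.concat([df, pd.DataFrame(group_rows)], ignore_index=True)
        have |= {r["country_id"] for r in group_rows}

    unresolved = sorted(required - have)
    if unresolved:
        raise GapfillError(
            "no score, covariates, or group membership for: "
            + ", ".join(unresolved))
    return (df[["country_id", "fmi", "provenance", "se"]]
            .sort_values("country_id").reset_index(drop=True))
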