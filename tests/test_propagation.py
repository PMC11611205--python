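from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hyp_st

import seatrace as st
from seatrace.definitions import AGGREGATE

from _oracles import brute_force_fmi_c, cf_map_from_world
from conftest import CLEAN_KW, make_world


def _balance_row(country, group="Pelagic Fish", year=2014, p=0.0, i=0.0,
                 e=0.0):
    return {"country_id": country, "product_group": group, "year": year,
            "production_t": p, "imports_t": i, "exports_t": e}


class TestConsumption:
    @pytest.mark.parametrize("p,i,e,want", [
        (50.0, 10.0, 20.0, 40.0),
        (0.0, 0.0, 0.0, 0.0),
        (5.0, 1.0, 10.0, 0.0),  # floored: balance identity went negative
    ])
    def test_balance_identity_with_floor(self, p, i, e, want):
        balance = pd.DataFrame([_balance_row("A", p=p, i=i, e=e)])
        out = st.compute_consumption(balance)
        assert out["consumption_t"].iloc[0] == want
        # sign oracle: flooring applies exactly when P + I - E < 0
        assert (out["consumption_t"].iloc[0] != p + i - e) == (p + i - e < 0)


class TestGlobalFmi:
    def test_weighted_mean(self):
        shares = pd.DataFrame({
            "product_group": ["Pelagic Fish"] * 2,
            "country_id": ["A", "B"], "p_pglbl": [0.5, 0.5]})
        fmi = pd.DataFrame({"country_id": ["A", "B"], "fmi": [0.4, 0.8]})
        out = st.compute_global_fmi(shares, fmi)
        assert out["fmi_glbl"].iloc[0] == pytest.approx(0.6)

    def test_single_producer(self):
        shares = pd.DataFrame({"product_group": ["Crustaceans"],
                               "country_id": ["A"], "p_pglbl": [1.0]})
        fmi = pd.DataFrame({"country_id": ["A"], "fmi": [0.37]})
        assert st.compute_global_fmi(shares, fmi)["fmi_glbl"].iloc[0] \
            == pytest.approx(0.37)

    def test_bad_share_sum_is_error(self):
        shares = pd.DataFrame({"product_group": ["Crustaceans"] * 2,
                               "country_id": ["A", "B"],
                               "p_pglbl": [0.6, 0.6]})
        fmi = pd.DataFrame({"country_id": ["A", "B"], "fmi": [0.4, 0.8]})
        with pytest.raises(st.SeatraceError, match="sum to 1"):
            st.compute_global_fmi(shares, fmi)

    def test_seed1_group_matches_ledger_brute_force(self, world1,
                                                    world1_results):
        prop = world1_results.propagation
        pooled = st.pool_balance(world1.balance)
        fmi = world1_results.fmi.set_index("country_id")["fmi"]
        for g in pooled["product_group"].unique():
            sub = pooled[pooled.product_group == g]
            want = sum(r.production_t * fmi[r.country_id]
                       for r in sub.itertuples()) / sub.production_t.sum()
            got = prop.global_fmi.set_index("product_group").loc[g,
                                                                 "fmi_glbl"]
            assert got == pytest.approx(want, abs=1e-12)


class TestFmiImports:
    @staticmethod
    def _run(shares_rows, comp_rows, fmi_rows, glbl):
        shares = pd.DataFrame(shares_rows)
        comp = pd.DataFrame(comp_rows)
        comp["p_ie"] = 1.0 - comp["p_pe"]
        fmi = pd.DataFrame(fmi_rows)
        glbl_df = pd.DataFrame({"product_group": ["Pelagic Fish"],
                                "fmi_glbl": [glbl]})
        out = st.compute_fmi_imports(shares, comp, fmi, glbl_df)
        return out["fmi_i"].iloc[0]

    def test_single_partner_full_production(self):
        got = self._run(
            [{"reporter_id": "R", "product_group": "Pelagic Fish",
              "partner_id": "J", "live_weight_t": 5.0, "share": 1.0}],
            [{"country_id": "J", "product_group": "Pelagic Fish",
              "p_pe": 1.0}],
            [{"country_id": "J", "fmi": 0.9}], glbl=0.1)
        assert got == pytest.approx(0.9)

    def test_full_reexport_collapses_to_global(self):
        got = self._run(
            [{"reporter_id": "R", "product_group": "Pelagic Fish",
              "partner_id": "J", "live_weight_t": 5.0, "share": 1.0}],
            [{"country_id": "J", "product_group": "Pelagic Fish",
              "p_pe": 0.0}],
            [{"country_id": "J", "fmi": 0.9}], glbl=0.42)
        assert got == pytest.approx(0.42)

    def test_two_partner_hand_expansion(self):
        # .6(.5*.8+.5*.5) + .4(.5*.2+.5*.5) = .53
        got = self._run(
            [{"reporter_id": "R", "product_group": "Pelagic Fish",
              "partner_id": "J1", "live_weight_t": 6.0, "share": 0.6},
             {"reporter_id": "R", "product_group": "Pelagic Fish",
              "partner_id": "J2", "live_weight_t": 4.0, "share": 0.4}],
            [{"country_id": "J1", "product_group": "Pelagic Fish",
              "p_pe": 0.5},
             {"country_id": "J2", "product_group": "Pelagic Fish",
              "p_pe": 0.5}],
            [{"country_id": "J1", "fmi": 0.8},
             {"country_id": "J2", "fmi": 0.2}], glbl=0.5)
        assert got == pytest.approx(0.53, abs=1e-12)

    def test_missing_composition_strict_error(self):
        with pytest.raises(st.MissingCompositionError, match="J"):
            self._run(
                [{"reporter_id": "R", "product_group": "Pelagic Fish",
                  "partner_id": "J", "live_weight_t": 1.0, "share": 1.0}],
                [{"country_id": "K", "product_group": "Pelagic Fish",
                  "p_pe": 1.0}],
                [{"country_id": "J", "fmi": 0.9}], glbl=0.5)


class TestDeriveConsumption:
    @staticmethod
    def _fit(balance, trade, fmi, derivations):
        return st.run_derivations(balance, trade, fmi,
                                  derivations=derivations)

    def _autarky_world(self):
        balance = pd.DataFrame([
            _balance_row("A", p=100.0), _balance_row("B", p=50.0)])
        trade = pd.DataFrame(columns=[
            "reporter_id", "partner_id", "direction", "product_code",
            "product_desc", "year", "product_weight_t", "live_weight_t",
            "product_group", "is_food", "farmed_flag"])
        fmi = pd.DataFrame({"country_id": ["A", "B"], "fmi": [0.9, 0.3]})
        return balance, trade, fmi

    def test_autarky_returns_production_score(self):
        res = self._fit(*self._autarky_world(),
                        derivations=("proportional", "gephart", "guillen"))
        # no trade: every derivation collapses to FMI_P (ppc forced to 1)
        for _, row in res.summary.iterrows():
            for c in ("proportional", "gephart", "guillen", "mean_fmi_c"):
                assert row[c] == pytest.approx(row["fmi_p"], abs=1e-15)

    def test_proportional_ppc_five_to_one(self):
        # a country producing 50 t and importing 10 t sources domestic vs
        # imported consumption 5:1
        balance = pd.DataFrame([
            _balance_row("R", p=50.0, i=10.0),
            _balance_row("J", p=30.0, e=10.0)])
        trade = pd.DataFrame([{
            "reporter_id": "R", "partner_id": "J", "direction": "import",
            "product_code": "x", "product_desc": "", "year": 2014,
            "product_weight_t": 10.0, "live_weight_t": 10.0,
            "product_group": "Pelagic Fish", "is_food": True,
            "farmed_flag": "unknown"}])
        fmi = pd.DataFrame({"country_id": ["R", "J"], "fmi": [0.9, 0.3]})
        res = self._fit(balance, trade, fmi, ("proportional",))
        row = res.results[(res.results.country_id == "R")
                          & (res.results.product_group != AGGREGATE)]
        assert row["ppc_used"].iloc[0] == pytest.approx(5 / 6)
        # J exports only own production -> fmi_i = fmi_J
        assert row["fmi_i"].iloc[0] == pytest.approx(0.3)
        assert row["fmi_c"].iloc[0] == pytest.approx(
            5 / 6 * 0.9 + 1 / 6 * 0.3, abs=1e-12)

    def test_guillen_fixed_mixture_arithmetic(self):
        balance = pd.DataFrame([
            _balance_row("R", p=50.0, i=10.0),
            _balance_row("J", p=30.0, e=10.0)])
        trade = pd.DataFrame([{
            "reporter_id": "R", "partner_id": "J", "direction": "import",
            "product_code": "x", "product_desc": "", "year": 2014,
            "product_weight_t": 10.0, "live_weight_t": 10.0,
            "product_group": "Pelagic Fish", "is_food": True,
            "farmed_flag": "unknown"}])
        # choose scores so FMI_I = 0.5 exactly (single partner, p_pe = 1)
        fmi = pd.DataFrame({"country_id": ["R", "J"], "fmi": [0.9, 0.5]})
        res = self._fit(balance, trade, fmi, ("guillen",))
        row = res.results[(res.results.country_id == "R")
                          & (res.results.product_group != AGGREGATE)]
        assert row["fmi_c"].iloc[0] == pytest.approx(
            0.74 * 0.9 + 0.26 * 0.5, abs=1e-12)   # = .796

    def test_zero_import_override_logged_for_fixed_ppc(self):
        balance, trade, fmi = self._autarky_world()
        res = self._fit(balance, trade, fmi, ("guillen",))
        assert res.logs.get("ppc_override", 0) == 2

    def test_no_basis_group_omitted(self):
        balance = pd.DataFrame([
            _balance_row("A", p=100.0),
            _balance_row("A", group="Crustaceans", p=0.0, i=0.0, e=0.0)])
        _, trade, _ = self._autarky_world()
        fmi = pd.DataFrame({"country_id": ["A"], "fmi": [0.9]})
        res = self._fit(balance, trade, fmi, ("proportional",))
        groups = res.results[res.results.product_group != AGGREGATE]
        assert groups["product_group"].tolist() == ["Pelagic Fish"]
        assert res.logs["omitted_no_basis"] == 1

    def test_unknown_derivation_name(self):
        balance, trade, fmi = self._autarky_world()
        with pytest.raises(st.ConfigError, match="unknown derivation"):
            self._fit(balance, trade, fmi, ("bogus",))


class TestAggregate:
    def test_two_equal_groups_average(self):
        rows = pd.DataFrame([
            {"country_id": "A", "product_group": "Pelagic Fish",
             "derivation": "proportional", "ppc_used": 1.0,
             "fmi_i": np.nan, "fmi_c": 0.6, "consumption_t": 10.0},
            {"country_id": "A", "product_group": "Crustaceans",
             "derivation": "proportional", "ppc_used": 1.0,
             "fmi_i": np.nan, "fmi_c": 0.8, "consumption_t": 10.0},
        ])
        agg = st.aggregate_fmi_c(rows)
        assert agg["fmi_c"].iloc[0] == pytest.approx(0.7)

    def test_single_group_passthrough(self):
        rows = pd.DataFrame([
            {"country_id": "A", "product_group": "Pelagic Fish",
             "derivation": "proportional", "ppc_used": 1.0,
             "fmi_i": np.nan, "fmi_c": 0.6, "consumption_t": 5.0}])
        assert st.aggregate_fmi_c(rows)["fmi_c"].iloc[0] == 0.6

    def test_seed1_matches_brute_force_weighted_sum(self, world1,
                                                    world1_results):
        res = world1_results
        per_group = res.results[
            (res.results.product_group != AGGREGATE)
            & (res.results.derivation == "proportional")]
        agg = res.results[
            (res.results.product_group == AGGREGATE)
            & (res.results.derivation == "proportional")]
        for _, row in agg.iterrows():
            sub = per_group[per_group.country_id == row.country_id]
            want = (sub.fmi_c * sub.consumption_t).sum() \
                / sub.consumption_t.sum()
            assert row.fmi_c == pytest.approx(want, abs=1e-12)


class TestDerivationSummary:
    def test_mean_of_three_aggregates(self, world1_results):
        s = world1_results.summary_frame
        want = s[["proportional", "gephart", "guillen"]].mean(axis=1)
        assert np.allclose(s["mean_fmi_c"], want)
        assert (s["min_fmi_c"] <= s["mean_fmi_c"] + 1e-15).all()
        assert (s["mean_fmi_c"] <= s["max_fmi_c"] + 1e-15).all()


class TestOracleEquivalence:
    def test_pipeline_equals_brute_force_on_random_worlds(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            world = make_world(
                seed=int(rng.integers(0, 2**31)),
                n_countries=int(rng.integers(3, 7)),
                n_groups=int(rng.integers(1, 4)),
                n_hubs=1, trade_density=float(rng.uniform(0.3, 0.9)),
                reexport_fraction=float(rng.uniform(0.0, 0.9)),
                missing_fmi_fraction=0.0)
            res = st.SeafoodSustainabilityModel.from_world(world).fit()
            oracle = brute_force_fmi_c(
                world.balance, world.trade, cf_map_from_world(world),
                res.fmi, ("proportional", "gephart", "guillen"))
            for row in res.results.itertuples(index=False):
                want = oracle[(row.country_id, row.product_group,
                               row.derivation)]
                assert abs(row.fmi_c - want) < 1e-12


class TestConservationAndBounds:
    def test_weight_vectors_sum_to_one(self, world1_results):
        prop = world1_results.propagation
        s = prop.import_shares.groupby(
            ["reporter_id", "product_group"])["share"].sum()
        assert np.allclose(s, 1.0, atol=1e-9)
        comp = prop.composition.dropna(subset=["p_pe"])
        assert np.allclose(comp.p_pe + comp.p_ie, 1.0, atol=1e-9)
        p = prop.production_shares.groupby("product_group")["p_pglbl"].sum()
        assert np.allclose(p, 1.0, atol=1e-9)

    def test_scores_in_unit_interval_and_convex(self, world1,
                                                world1_results):
        res = world1_results
        fmi = res.fmi.set_index("country_id")["fmi"]
        lo, hi = fmi.min(), fmi.max()
        for col, df in (("fmi_c", res.results),
                        ("fmi_i", res.results.dropna(subset=["fmi_i"])),
                        ("fmi_glbl", res.propagation.global_fmi)):
            v = df[col]
            assert (v >= lo - 1e-12).all() and (v <= hi + 1e-12).all()
            assert v.between(0, 1).all()

    def test_monotone_in_partner_score(self, world1):
        base = st.SeafoodSustainabilityModel.from_world(
            world1, use_true_fmi=True).fit()
        bumped_fmi = world1.fmi_true.copy()
        exporters = [c for c, r in world1.audit["roles"].items()
                     if r == "exporter"]
        target = exporters[0]
        ix = bumped_fmi.country_id == target
        bumped_fmi.loc[ix, "fmi"] = np.minimum(
            bumped_fmi.loc[ix, "fmi"] + 0.05, 1.0)
        model = st.SeafoodSustainabilityModel.from_world(
            world1, use_true_fmi=True)
        model.fmi = bumped_fmi
        bumped = model.fit()
        merged = base.results.merge(
            bumped.results,
            on=["country_id", "product_group", "derivation"],
            suffixes=("_base", "_bumped"))
        assert (merged.fmi_c_bumped >= merged.fmi_c_base - 1e-12).all()


class TestExactnessAtZeroReexport:
    def test_proportional_equals_ledger_truth(self, clean_world):
        res = st.SeafoodSustainabilityModel.from_world(clean_world).fit(
            derivations=("proportional",))
        truth = st.true_consumption_fmi(clean_world.ledger,
                                        clean_world.fmi_true)
        merged = res.results.merge(
            truth, left_on=["country_id", "product_group"],
            right_on=["consumer_id", "product_group"])
        assert len(merged) == len(res.results)
        assert (merged.fmi_c - merged.true_fmi_c).abs().max() < 1e-12


@given(
    shares=hyp_st.lists(hyp_st.floats(0.01, 1.0), min_size=1, max_size=6),
    scores=hyp_st.lists(hyp_st.floats(0.0, 1.0), min_size=6, max_size=6),
    p_pe=hyp_st.lists(hyp_st.floats(0.0, 1.0), min_size=6, max_size=6),
    glbl=hyp_st.floats(0.0, 1.0),
)
def test_import_score_is_convex_combination(shares, scores, p_pe, glbl):
    """The import-side score always lies in the hull of the scores
    feeding it (partner scores and the global regularizer)."""
    k = len(shares)
    total = sum(shares)
    rows = pd.DataFrame({
        "reporter_id": "R", "product_group": "Pelagic Fish",
        "partner_id": [f"J{i}" for i in range(k)],
        "live_weight_t": shares, "share": [s / total for s in shares]})
    comp = pd.DataFrame({
        "country_id": [f"J{i}" for i in range(k)],
        "product_group": "Pelagic Fish", "p_pe": p_pe[:k]})
    comp["p_ie"] = 1 - comp["p_pe"]
    fmi = pd.DataFrame({"country_id": [f"J{i}" for i in range(k)],
                        "fmi": scores[:k]})
    glbl_df = pd.DataFrame({"product_group": ["Pelagic Fish"],
                            "fmi_glbl": [glbl]})
    out = st.compute_fmi_imports(rows, comp, fmi, glbl_df)
    val = out["fmi_i"].iloc[0]
    feeding = scores[:k] + [glbl]
    assert min(feeding) - 1e-9 <= val <= max(feeding) + 1e-9
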