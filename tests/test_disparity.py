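from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hyp_st

import seatrace as st
from seatrace.definitions import AGGREGATE
from seatrace.propagation import DerivationSpec

from _oracles import normal_equations_ols
from conftest import make_world


class TestPercentChange:
    def test_reference_worked_example(self):
        # a producer at 0.932 consuming at a mean score of 0.742 sees a
        # ~20.4% drop from production to consumption sustainability
        assert st.percent_change(0.932, 0.742) == pytest.approx(20.39,
                                                                abs=0.005)

    @pytest.mark.parametrize("p,c,want", [
        (0.5, 0.5, 0.0),
        (0.5, 0.6, -20.0),   # consuming better than producing -> negative
    ])
    def test_sign_convention(self, p, c, want):
        assert st.percent_change(p, c) == pytest.approx(want)

    def test_zero_production_score_undefined(self):
        assert np.isnan(st.percent_change(0.0, 0.5))

    @given(p=hyp_st.floats(0.05, 1.0), d=hyp_st.floats(0.0, 0.04))
    def test_antisymmetric_around_equal_scores(self, p, d):
        gain = st.percent_change(p, p - d)
        loss = st.percent_change(p, p + d)
        assert gain == pytest.approx(-loss, abs=1e-9)


class TestRegression:
    def test_identity_relationship(self):
        rng = np.random.default_rng(0)
        fmi_p = rng.uniform(0.1, 0.9, 20)
        summary = pd.DataFrame({"fmi_p": fmi_p, "proportional": fmi_p})
        reg = st.fit_fmi_relationship(summary, "proportional")
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_import_score_recovers_mixing_weight(self):
        balance, trade, fmi, g = st.constant_import_mix_world(
            n_importers=20, seed=3)
        res = st.run_derivations(balance, trade, fmi,
                                 derivations=("guillen",))
        reg = st.fit_fmi_relationship(res.summary, "guillen")
        assert reg.slope == pytest.approx(0.74, abs=1e-9)
        assert reg.intercept == pytest.approx(0.26 * g, abs=1e-9)

    def test_degenerate_full_domestic_spec_gives_identity(self):
        balance, trade, fmi, _g = st.constant_import_mix_world(
            n_importers=12, seed=5)
        spec = DerivationSpec("all_domestic", 1.0)
        res = st.run_derivations(balance, trade, fmi, derivations=(spec,))
        reg = st.fit_fmi_relationship(res.summary, "all_domestic")
        assert reg.slope == pytest.approx(1.0, abs=1e-9)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        assert reg.r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations(self, world1_results):
        summary = world1_results.summary_frame
        reg = st.fit_fmi_relationship(summary, "gephart")
        slope, intercept, r2 = normal_equations_ols(
            summary["fmi_p"].tolist(), summary["gephart"].tolist())
        assert reg.slope == pytest.approx(slope, abs=1e-9)
        assert reg.intercept == pytest.approx(intercept, abs=1e-9)
        assert reg.r2 == pytest.approx(r2, abs=1e-9)

    def test_needs_three_countries(self):
        summary = pd.DataFrame({"fmi_p": [0.1, 0.2],
                                "proportional": [0.1, 0.2]})
        with pytest.raises(st.ValidationError, match="3 countries"):
            st.fit_fmi_relationship(summary, "proportional")


class TestRankTraders:
    @staticmethod
    def _trade(rows):
        return pd.DataFrame([{
            "reporter_id": r, "partner_id": p, "direction": d,
            "live_weight_t": w, "product_group": "Pelagic Fish"}
            for r, p, d, w in rows])

    def test_single_exporter(self):
        out = st.rank_traders(self._trade([("A", "B", "export", 5.0)]))
        row = out[out.country_id == "A"].iloc[0]
        assert row["share_of_global_exports"] == 1.0
        assert row["export_rank"] == 1

    def test_constructed_shares(self):
        out = st.rank_traders(self._trade([
            ("A", "Z", "export", 5.0), ("B", "Z", "export", 3.0),
            ("C", "Z", "export", 2.0)]))
        shares = out.set_index("country_id")["share_of_global_exports"]
        assert shares["A"] == pytest.approx(0.5)
        assert shares["B"] == pytest.approx(0.3)
        assert shares["C"] == pytest.approx(0.2)

    def test_lexicographic_tie_break(self):
        out = st.rank_traders(self._trade([
            ("B", "Z", "export", 5.0), ("A", "Z", "export", 5.0)]))
        assert out["country_id"].tolist()[:2] == ["A", "B"]

    def test_seed1_matches_groupby_oracle(self, world1_results):
        trade = world1_results.trade
        out = st.rank_traders(trade)
        exp = trade[trade.direction == "export"].groupby(
            "reporter_id")["live_weight_t"].sum()
        for _, row in out.iterrows():
            want = exp.get(row.country_id, 0.0) / exp.sum()
            assert row["share_of_global_exports"] == pytest.approx(
                want, abs=1e-12)
        npartners = trade[trade.live_weight_t > 0].groupby(
            "reporter_id")["partner_id"].nunique()
        for _, row in out.iterrows():
            assert row["n_partners"] == npartners.get(row.country_id, 0)


class TestPartnerBreakdown:
    def test_topk_and_coverage(self, world1_results):
        ts = world1_results.trade_summary()
        top_importer = ts.sort_values(
            ["share_of_global_imports", "country_id"],
            ascending=[False, True])["country_id"].iloc[0]
        rows, coverage = world1_results.partner_breakdown(
            top_importer, "import", k=3)
        assert len(rows) <= 3
        assert 0 < coverage <= 1.0 + 1e-12
        assert rows["share"].is_monotonic_decreasing
        assert "partner_fmi_p" in rows.columns


class TestFullAnalysis:
    def test_unknown_derivation_rejected(self):
        with pytest.raises(st.ConfigError, match="unknown derivation"):
            st.AnalysisConfig(world=st.WorldConfig(seed=1),
                              derivations=("bogus",))

    def test_unknown_mode_rejected(self):
        with pytest.raises(st.ConfigError, match="mode"):
            st.AnalysisConfig(world=st.WorldConfig(seed=1),
                              modes=("core", "mystery"))

    def test_byte_identical_reruns(self, tmp_path):
        cfg = st.AnalysisConfig(
            world=dataclasses.replace(
                st.WorldConfig(seed=1), n_countries=10, n_groups=2,
                n_hubs=1, trade_density=0.5),
            modes=("core",))
        st.run_full_analysis(cfg, out_dir=tmp_path / "a")
        st.run_full_analysis(cfg, out_dir=tmp_path / "b")
        for rel in ("manifest.json", "core/disparity.csv",
                    "core/regression.csv", "core/results.csv",
                    "core/trade_summary.csv",
                    "core/partner_breakdown.csv"):
            a = (tmp_path / "a" / rel).read_bytes()
            b = (tmp_path / "b" / rel).read_bytes()
            assert a == b, rel

    def test_core_vs_exclusion_row_counts(self):
        world_cfg = dataclasses.replace(
            st.WorldConfig(seed=1), n_countries=10, n_groups=2, n_hubs=1,
            trade_density=0.6, farmed_fraction=0.3)
        bundle = st.run_full_analysis(st.AnalysisConfig(world=world_cfg))
        core = bundle["core"]
        excl = bundle["no_aquaculture"]
        # exclusion only removes farmed trade records
        removed = excl.audits["aquaculture"]["farmed_keyword"]
        world = st.generate_world(world_cfg)
        # every farmed flow has two reporting legs, minus any legs merged
        # with an unfarmed duplicate during filtering
        assert 0 < removed <= 2 * world.audit["n_farmed_flows"]
        assert len(excl.trade) == len(core.trade) - removed
        assert len(excl.results) <= len(core.results)

    def test_manifest_records_seed_and_modes(self):
        cfg = st.AnalysisConfig(
            world=dataclasses.replace(
                st.WorldConfig(seed=12), n_countries=8, n_groups=1,
                n_hubs=1),
            modes=("core",))
        bundle = st.run_full_analysis(cfg)
        m = bundle["manifest"]
        assert m["seed"] == 12
        assert set(m["modes"]) == {"core"}
        assert m["modes"]["core"]["n_countries"] > 0
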