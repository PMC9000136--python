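"""Scenario construction, pharmacology mappings, and the coupled
multicellular integration."""

import numpy as np
import pytest
from dataclasses import replace

from campnet.gap_junctions import CouplingParams
from campnet.model_core import IntracellularParams, LightProtocol
from campnet.tissue import (
    MonolayerGraph,
    apply_pharmacology,
    build_scenario,
    drug_spec,
    run_model_variant,
    simulate_tissue,
)

from conftest import adjacent_receiver_metrics, emitter_metrics


class TestBuildScenario:
    def test_all_emitter_counts(self):
        g = build_scenario("all_emitter", {"n": 46}, seed=0)
        assert g.n_cells == 46
        assert (g.roles == "emitter").all()
        assert np.array_equal(g.edges, np.sort(g.edges, axis=1))

    def test_single_emitter_cluster_default(self):
        g = build_scenario("single_emitter_cluster", seed=0)
        assert (g.roles == "emitter").sum() == 1
        assert (g.roles == "receiver").sum() == 45
        assert g.bpac[g.emitter_ids[0]] == 1.0
        assert np.all(g.bpac[g.receiver_ids] == 0.0)

    def test_degree_statistics(self):
        g = build_scenario("single_emitter_cluster", seed=0)
        deg = g.degrees
        assert 4.0 <= deg.mean() <= 5.5
        assert deg.max() <= 7

    def test_determinism(self):
        a = build_scenario("small_emitter_cluster", {"n_emitters": 5}, seed=11)
        b = build_scenario("small_emitter_cluster", {"n_emitters": 5}, seed=11)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.bpac, b.bpac)

    def test_large_cluster_warns(self):
        with pytest.warns(UserWarning, match="15 or fewer"):
            build_scenario("small_emitter_cluster", {"n_emitters": 16}, seed=0)

    def test_unknown_scenario_and_options(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("mystery", seed=0)
        with pytest.raises(ValueError, match="options"):
            build_scenario("all_emitter", {"bogus": 1}, seed=0)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            MonolayerGraph(
                roles=np.array(["emitter"] * 4, dtype=object),
                bpac=np.ones(4),
                edges=np.array([[0, 1], [2, 3]]),
            )


class TestPharmacology:
    def test_no_drug_is_identity(self, params):
        eff = apply_pharmacology(params, CouplingParams(), drug_spec("none"))
        assert eff.params == params
        assert eff.coupling_scale == 1.0

    def test_ibmx_zeroes_pde_degradation(self, params):
        eff = apply_pharmacology(params, CouplingParams(), drug_spec("ibmx"))
        assert eff.params.gamma_pde == 0.0

    def test_cx43_scales_permeability(self, params):
        eff = apply_pharmacology(params, CouplingParams(), drug_spec("cx43_ngfp"))
        assert eff.coupling_scale == pytest.approx(0.2)
        assert apply_pharmacology(
            params, CouplingParams(), drug_spec("brefeldin_a")
        ).coupling_scale == pytest.approx(0.25)

    def test_h89_freezes_regulation_keeps_basal(self, params):
        eff = apply_pharmacology(params, CouplingParams(), drug_spec("h89"))
        assert not eff.regulation_enabled
        assert eff.coupling_scale == 1.0

    def test_unknown_drug_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            drug_spec("aspirin")


class TestSimulateTissue:
    def test_uniform_all_emitter_has_no_net_flux(self, one_pulse):
        g = build_scenario("all_emitter", {"n": 16}, seed=0)
        ts = run_model_variant("delayed_regulation", graph=g, protocol=one_pulse)
        scale = ts.camp.max()
        assert np.abs(ts.flux).max() < 1e-8 * scale

    def test_total_camp_conserved_without_sinks(self, single45, one_pulse):
        # production stops at pulse shutoff; with all clearance off the
        # coupling terms must conserve total cAMP exactly
        p = IntracellularParams(gamma_pde=0.0, gamma_ex=0.0)
        ts = run_model_variant(
            "delayed_regulation", graph=single45, protocol=one_pulse, params=p
        )
        k_off = int(np.argmin(np.abs(ts.time - 80.0)))
        total = ts.camp.sum(axis=0)
        drift = np.abs(total[k_off:] - total[k_off]) / total[k_off]
        assert drift.max() < 1e-6

    def test_flux_antisymmetry_is_structural(self, delayed_ts):
        # flux is reported once per interface, into edges[:, 0]; the global
        # sum of signed flux contributions is identically zero
        influx = np.zeros_like(delayed_ts.camp)
        np.add.at(influx, delayed_ts.edges[:, 0], delayed_ts.flux)
        np.add.at(influx, delayed_ts.edges[:, 1], -delayed_ts.flux)
        assert np.abs(influx.sum(axis=0)).max() < 1e-12

    def test_concentrations_non_negative(self, delayed_ts):
        assert delayed_ts.camp.min() >= 0.0
        assert delayed_ts.ktr_nc.min() > 0.0

    def test_interface_outputs_shape(self, delayed_ts):
        m = len(delayed_ts.edges)
        assert delayed_ts.rho.shape == (m, delayed_ts.time.size)
        assert delayed_ts.gj_parsed_i.shape == delayed_ts.rho.shape
        assert np.all(delayed_ts.rho >= 0.0)


class TestModelVariants:
    def test_unknown_variant(self, single10):
        with pytest.raises(ValueError, match="variant"):
            run_model_variant("teleportation", graph=single10)

    def test_delayed_regulation_dichotomy(self, delayed_ts):
        m = emitter_metrics(delayed_ts)
        assert m.overshoot_ratio >= 1.2
        ratios = [x.overshoot_ratio for x in adjacent_receiver_metrics(delayed_ts)]
        assert np.nanmean(ratios) <= 1.1

    def test_constant_permeability_no_overshoot(self, single10, one_pulse):
        ts = run_model_variant(
            "constant_permeability", graph=single10, protocol=one_pulse
        )
        assert emitter_metrics(ts).overshoot_ratio <= 1.1

    def test_feedback_variant_receiver_mirrors(self, single10, one_pulse):
        ts = run_model_variant(
            "pka_pde_feedback", graph=single10, protocol=one_pulse
        )
        assert emitter_metrics(ts).overshoot_ratio > 1.1
        ratios = [x.overshoot_ratio for x in adjacent_receiver_metrics(ts)]
        assert np.nanmean(ratios) > 1.1

    def test_undershoot_requires_basal_asymmetry(self, single10, one_pulse):
        high = run_model_variant("undershoot", graph=single10, protocol=one_pulse)
        ctrl = run_model_variant(
            "undershoot", graph=single10, protocol=one_pulse, equal_basal=True
        )
        m_high, m_ctrl = emitter_metrics(high), emitter_metrics(ctrl)
        amp = m_high.s_end - m_high.s_start
        assert m_high.undershoot_depth > 0.05 * amp
        assert m_ctrl.undershoot_depth <= 0.05 * (m_ctrl.s_end - m_ctrl.s_start)

    def test_mid_run_drug_onset_changes_second_pulse_only(self, single10):
        proto = LightProtocol.two_pulse()
        wt = run_model_variant("delayed_regulation", graph=single10,
                               protocol=proto)
        mid = run_model_variant(
            "delayed_regulation", graph=single10, protocol=proto,
            pharm=replace(drug_spec("carbenoxolone"), onset_time=120.0),
        )
        # identical before the drug is added, decoupled afterwards
        k = int(np.argmin(np.abs(wt.time - 119.0)))
        assert np.allclose(wt.ktr_nc[:, :k], mid.ktr_nc[:, :k], atol=1e-6)
        m_wt = emitter_metrics(wt, pulse=1)
        m_mid = emitter_metrics(mid, pulse=1)
        assert m_mid.s_max > m_wt.s_max  # no drain: larger second-pulse peak
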