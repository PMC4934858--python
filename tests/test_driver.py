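import math

import numpy as np
import pandas as pd
import pytest

from dddfba.driver import (
    CultureState, ScenarioConfig, SetupError, initialize, simulate, step,
    update_culture, uptake_bound,
)
from dddfba.expression_dynamics import RegulatoryConfig
from dddfba.fba_core import FluxSolution, fba, pfba


def _config(**kw):
    reg = kw.pop("regulatory", RegulatoryConfig())
    return ScenarioConfig(regulatory=reg, **kw)


class TestUptakeBound:
    def test_no_substrate_closes_uptake(self):
        assert uptake_bound(0.0, 10.0) == 0.0
        assert uptake_bound(0.0, 10.0, "michaelis-menten", km=0.5) == 0.0

    def test_fixed_mode_is_all_or_nothing(self):
        assert uptake_bound(0.001, 10.0) == 10.0

    def test_michaelis_menten_saturation_and_half_saturation(self):
        assert uptake_bound(5000.0, 10.0, "michaelis-menten", km=0.5) == \
            pytest.approx(10.0, rel=1e-3)
        assert uptake_bound(0.5, 10.0, "michaelis-menten", km=0.5) == \
            pytest.approx(5.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            uptake_bound(-1, 10)
        with pytest.raises(ValueError):
            uptake_bound(1, 10, "michaelis-menten", km=-1)


class TestUpdateCulture:
    def test_zero_growth_linear_branch(self):
        culture = CultureState(biomass=1.0, concentrations={"EX_s": 5.0})
        sol = FluxSolution(fluxes=pd.Series({"EX_s": -1.0}), growth_rate=0.0,
                           objective_value=0.0)
        new = update_culture(culture, sol, 1.0)
        assert new.concentrations["EX_s"] == pytest.approx(4.0)
        assert new.biomass == pytest.approx(1.0)

    def test_exponential_growth_and_analytic_integral(self):
        mu, X, v, dt = 0.5, 0.2, -2.0, 0.25
        culture = CultureState(biomass=X, concentrations={"EX_s": 10.0})
        sol = FluxSolution(fluxes=pd.Series({"EX_s": v, "BIO": mu}),
                           growth_rate=mu, objective_value=mu)
        new = update_culture(culture, sol, dt)
        assert new.biomass == pytest.approx(X * math.exp(mu * dt))
        expected = 10.0 + v * X * (math.exp(mu * dt) - 1) / mu
        assert new.concentrations["EX_s"] == pytest.approx(expected)

    def test_concentration_floored_at_zero(self):
        culture = CultureState(biomass=10.0, concentrations={"EX_s": 0.01})
        sol = FluxSolution(fluxes=pd.Series({"EX_s": -5.0}), growth_rate=0.0,
                           objective_value=0.0)
        new = update_culture(culture, sol, 1.0)
        assert new.concentrations["EX_s"] == 0.0


class TestInitialize:
    def test_basal_state_has_positive_bounds_and_no_demand(
            self, anaerobic_model, kinetics):
        expr, culture, bounds = initialize(anaerobic_model, kinetics, _config())
        assert all(R == 0 for R in expr.signal.values())
        assert all(b > 0 for b in bounds.values())
        assert culture.biomass == pytest.approx(0.01)

    def test_zero_basal_rate_gives_zero_bound(self, anaerobic_model, kinetics):
        from dataclasses import replace
        kins = [replace(k, s_b=0.0) if k.reaction == "CYTBO" else k
                for k in kinetics]
        _, _, bounds = initialize(anaerobic_model, kins, _config())
        assert bounds["CYTBO"] == 0.0
        assert bounds["CYTBD"] > 0

    def test_bounds_scale_linearly_with_tau(self, anaerobic_model, kinetics):
        b1 = initialize(anaerobic_model, kinetics,
                        _config(regulatory=RegulatoryConfig(tau=0.6)))[2]
        b2 = initialize(anaerobic_model, kinetics,
                        _config(regulatory=RegulatoryConfig(tau=1.2)))[2]
        for rid in b1:
            assert b2[rid] == pytest.approx(2.0 * b1[rid], rel=1e-12)

    def test_anaerobically_non_growing_setup_raises(self, anaerobic_model,
                                                    kinetics):
        with pytest.raises(SetupError):
            initialize(anaerobic_model, kinetics, _config(glc_vmax=0.0))


class TestStepAndSimulate:
    def test_anaerobic_steady_state_is_a_fixed_point(self, anaerobic_model,
                                                     kinetics):
        config = _config(t_aer_min=1e9)  # never aerate
        expr, culture, bounds = initialize(anaerobic_model, kinetics, config)
        e, c, b = expr.copy(), culture.copy(), dict(bounds)
        for _ in range(20):
            _, e, c, b = step(anaerobic_model, e, c, kinetics, config, 0.5, b)
        for rid in bounds:
            assert e.mrna[rid] == pytest.approx(expr.mrna[rid], abs=1e-6)
            assert e.protein[rid] == pytest.approx(expr.protein[rid], abs=1e-9)
            assert b[rid] == pytest.approx(bounds[rid], abs=1e-6)
            assert e.signal[rid] == 0

    def test_no_balanced_enzymes_reduces_to_plain_dfba(self, anaerobic_model):
        config = _config(horizon_min=5.0, t_aer_min=1e9)
        traj = simulate(anaerobic_model, [], config)
        # every step must match a direct pFBA of the same static problem
        with anaerobic_model as m:
            m.reactions.EX_o2_e.lower_bound = 0.0
            m.reactions.EX_glc_e.lower_bound = -config.glc_vmax
            ref = pfba(m)
        for fluxes in traj.fluxes:
            for rid in ref.fluxes.index:
                assert fluxes[rid] == pytest.approx(ref.fluxes[rid], abs=1e-6)

    def test_bounds_respected_along_the_whole_trajectory(self, anaerobic_model,
                                                         kinetics):
        traj = simulate(anaerobic_model, kinetics,
                        _config(horizon_min=30.0, t_aer_min=5.0))
        for fluxes, bounds in zip(traj.fluxes, traj.bounds):
            for rid, b in bounds.items():
                assert abs(fluxes[rid]) <= b + 1e-9

    def test_demand_signal_audit(self, anaerobic_model, kinetics):
        config = _config(horizon_min=30.0, t_aer_min=5.0)
        theta = config.regulatory.theta
        traj = simulate(anaerobic_model, kinetics, config)
        for fluxes, bounds, signal in zip(traj.fluxes, traj.bounds, traj.signal):
            for rid in bounds:
                expected = 1 if abs(fluxes[rid]) >= theta * bounds[rid] else 0
                assert signal[rid] == expected

    def test_substrate_exhaustion_goes_dormant_not_fatal(self, anaerobic_model,
                                                         kinetics):
        config = _config(horizon_min=60.0, t_aer_min=1e9, biomass_init=5.0,
                         initial_concentrations={"EX_glc_e": 2.0})
        traj = simulate(anaerobic_model, kinetics, config)
        glc = [c["EX_glc_e"] for c in traj.concentrations]
        assert glc[-1] == 0.0
        assert traj.growth[-1] == 0.0
        assert any(tag == "dormant" for _, tag in traj.events)
        # biomass stops growing after depletion
        assert traj.biomass[-1] == pytest.approx(traj.biomass[-2])

    def test_growth_rises_after_aeration(self, anaerobic_model, kinetics):
        traj = simulate(anaerobic_model, kinetics,
                        _config(horizon_min=60.0, t_aer_min=10.0))
        mu = pd.Series(traj.growth, index=traj.times_min)
        assert mu.loc[:9.9].max() == pytest.approx(mu.loc[:9.9].min(), rel=1e-6)
        assert mu.iloc[-1] > 2.0 * mu.iloc[0]

    def test_halving_the_step_converges_the_culture_state(self, anaerobic_model,
                                                          kinetics):
        # Quasi-steady-state convergence: the integrated culture state
        # (biomass, substrate) converges as dt -> 0.  Instantaneous fluxes
        # and mRNA of genes whose demand signal chatters around j = theta*b
        # are switch-time quantized and are not expected to converge
        # pointwise.
        def culture(dt):
            cfg = _config(horizon_min=40.0, t_aer_min=10.0,
                          regulatory=RegulatoryConfig(dt_min=dt))
            return simulate(anaerobic_model, kinetics, cfg).culture_frame()

        ca, cb = culture(1.0), culture(0.5)
        common = ca.index.intersection(cb.index)
        for col in ("biomass_gdcw_l", "EX_glc_e"):
            diff = (ca.loc[common, col] - cb.loc[common, col]).abs().max()
            assert diff / cb[col].abs().max() < 0.01

    def test_fva_recording(self, anaerobic_model, kinetics):
        traj = simulate(anaerobic_model, kinetics,
                        _config(horizon_min=3.0, t_aer_min=1.0, run_fva=True))
        frame = traj.fva_frame()
        assert set(frame.reaction) == {k.reaction for k in kinetics}
        assert (frame["max"] + 1e-9 >= frame["min"]).all()

    def test_trajectory_tsv_round_trip(self, anaerobic_model, kinetics,
                                       tmp_path):
        traj = simulate(anaerobic_model, kinetics,
                        _config(horizon_min=2.0, t_aer_min=1.0))
        prefix = str(tmp_path / "run")
        traj.write_tsvs(prefix)
        fluxes = pd.read_csv(prefix + "_fluxes.tsv", sep="\t",
                             index_col="time_min")
        assert len(fluxes) == len(traj.times_min)
        expr = pd.read_csv(prefix + "_expression.tsv", sep="\t")
        assert {"mrna_rpkm", "protein_mmol_gdcw", "signal",
                "bound"} <= set(expr.columns)
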