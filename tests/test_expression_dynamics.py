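import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dddfba.expression_dynamics import (
    EnzymeKinetics, RegulatoryConfig, flux_bound, mrna_step, protein_step,
    read_kinetics_table, regulatory_signal, steady_state_expression,
    write_kinetics_table,
)

CYDA = EnzymeKinetics(reaction="CYTBD", gene="cydA", gene_length_bp=1569,
                      s_b=116.3, s_a=759.1, gamma=0.187, kcat=11.7)
CYOB = EnzymeKinetics(reaction="CYTBO", gene="cyoB", gene_length_bp=1992,
                      s_b=2.4, s_a=610.9, gamma=0.210, kcat=341.0)
MU_H = 0.26          # anaerobic growth rate, 1/h
MU_MIN = MU_H / 60.0


class TestRegulatorySignal:
    @pytest.mark.parametrize("j,b,theta,expected", [
        (0.3, 1.0, 0.6, 0),
        (0.6, 1.0, 0.6, 1),   # inclusive at the threshold
        (0.61, 1.0, 0.6, 1),
        (0.0, 0.0, 0.6, 1),   # degenerate zero bound: 0 >= 0
    ])
    def test_threshold_rule(self, j, b, theta, expected):
        assert regulatory_signal(j, b, theta) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            regulatory_signal(-0.1, 1.0)
        with pytest.raises(ValueError):
            regulatory_signal(0.1, -1.0)


class TestMrnaStep:
    def test_steady_state_is_a_fixed_point(self):
        m_ss = CYDA.s_b / (MU_MIN + CYDA.gamma)
        assert mrna_step(m_ss, 0, CYDA, MU_MIN, 1.0) == pytest.approx(m_ss, rel=1e-12)

    def test_long_time_limit_with_activation(self):
        target = (CYDA.s_b + CYDA.s_a) / (MU_MIN + CYDA.gamma)
        assert mrna_step(50.0, 1, CYDA, MU_MIN, 1e5) == pytest.approx(target, rel=1e-9)

    def test_matches_adaptive_integrator(self):
        def rhs(t, y):
            return [CYDA.s_b - (MU_MIN + CYDA.gamma) * y[0]]

        ref = solve_ivp(rhs, (0, 1.0), [100.0], rtol=1e-11, atol=1e-12)
        assert mrna_step(100.0, 0, CYDA, MU_MIN, 1.0) == pytest.approx(
            ref.y[0, -1], abs=1e-8)

    def test_zero_decay_branch_is_linear(self):
        kin = EnzymeKinetics(reaction="X", gene="x", gene_length_bp=1000,
                             s_b=2.0, s_a=0.0, gamma=0.0, kcat=1.0)
        assert mrna_step(1.0, 0, kin, 0.0, 3.0) == pytest.approx(7.0)

    @given(m0=st.floats(0, 1e4), sb=st.floats(0, 500), sa=st.floats(0, 2000),
           gamma=st.floats(0.001, 12), dt=st.floats(0.01, 10),
           R=st.integers(0, 1))
    def test_non_negative_from_non_negative(self, m0, sb, sa, gamma, dt, R):
        kin = EnzymeKinetics(reaction="X", gene="x", gene_length_bp=1000,
                             s_b=sb, s_a=sa, gamma=gamma, kcat=1.0)
        assert mrna_step(m0, R, kin, MU_MIN, dt) >= 0.0

    def test_monotone_rise_after_activation(self):
        m = CYDA.s_b / (MU_MIN + CYDA.gamma)
        target = (CYDA.s_b + CYDA.s_a) / (MU_MIN + CYDA.gamma)
        previous = m
        for _ in range(200):
            previous, m = m, mrna_step(m, 1, CYDA, MU_MIN, 0.5)
            assert m > previous
            assert m < target


class TestProteinStep:
    def test_steady_state_is_a_fixed_point(self):
        m = 100.0
        p_ss = CYDA.synthesis_rate() * m / MU_H
        assert protein_step(p_ss, m, CYDA, MU_H, 1.0) == pytest.approx(p_ss, rel=1e-12)

    def test_pure_dilution_decays_monotonically(self):
        p = 1.0
        for _ in range(50):
            p_next = protein_step(p, 0.0, CYDA, MU_H, 0.1)
            assert 0.0 < p_next < p
            p = p_next

    def test_semigroup_substepping(self):
        # with constant mRNA, 100 sub-steps compose to the single-step update
        p = 0.5
        one = protein_step(p, 80.0, CYDA, MU_H, 1.0)
        many = p
        for _ in range(100):
            many = protein_step(many, 80.0, CYDA, MU_H, 0.01)
        assert many == pytest.approx(one, abs=1e-10)

    def test_zero_growth_branch(self):
        assert protein_step(1.0, 10.0, CYDA, 0.0, 2.0) == pytest.approx(
            1.0 + CYDA.synthesis_rate() * 10.0 * 2.0)


class TestFluxBound:
    def test_proportional_to_protein(self):
        assert flux_bound(11.7, 1.0) == pytest.approx(11.7)
        assert flux_bound(341.0, 0.0) == 0.0

    def test_anaerobic_steady_state_bound_of_efficient_oxidase(self):
        # basal steady state of the cyo analog at mu = 0.26/h:
        # mRNA = 2.4/(0.210 + 0.26/60), protein = (0.6/1992)*mRNA/0.26
        _, p = steady_state_expression(CYOB, MU_H, R=0)
        assert p == pytest.approx(0.012972, abs=1e-5)
        assert flux_bound(CYOB.kcat, p) == pytest.approx(4.4235, abs=1e-3)

    def test_unit_factor_knob(self):
        assert flux_bound(2.0, 3.0, unit_factor=10.0) == pytest.approx(60.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flux_bound(-1.0, 1.0)


class TestSteadyState:
    def test_basal_mrna_of_mle_oxidase(self):
        m, _ = steady_state_expression(CYDA, MU_H, R=0)
        assert m == pytest.approx(116.3 / (0.187 + MU_MIN), rel=1e-12)
        assert m == pytest.approx(607.84, abs=0.01)

    def test_zero_basal_rate_gives_zero_state(self):
        kin = EnzymeKinetics(reaction="X", gene="x", gene_length_bp=1000,
                             s_b=0.0, s_a=10.0, gamma=0.2, kcat=1.0)
        assert steady_state_expression(kin, MU_H, R=0) == (0.0, 0.0)

    def test_iterated_steps_converge_to_steady_state(self):
        m_ss, p_ss = steady_state_expression(CYDA, MU_H, R=1)
        m, p = 10.0, 0.001
        for _ in range(5000):
            m_prev = m
            m = mrna_step(m, 1, CYDA, MU_MIN, 1.0)
            p = protein_step(p, m_prev, CYDA, MU_H, 1.0 / 60.0)
        assert m == pytest.approx(m_ss, rel=1e-6)
        assert p == pytest.approx(p_ss, rel=1e-4)

    def test_initial_bound_is_linear_in_tau(self):
        for tau in (0.3, 0.6, 0.9, 1.7):
            _, p = steady_state_expression(CYDA, MU_H, R=0, tau=tau)
            _, p1 = steady_state_expression(CYDA, MU_H, R=0, tau=1.0)
            assert flux_bound(CYDA.kcat, p) == pytest.approx(
                tau * flux_bound(CYDA.kcat, p1), rel=1e-12)

    def test_zero_growth_rejected(self):
        with pytest.raises(ValueError):
            steady_state_expression(CYDA, 0.0)


def test_apparent_length_feeds_synthesis_rate():
    akgdh = EnzymeKinetics(reaction="AKGDH", gene="sucA", gene_length_bp=2802,
                           copies=12, s_b=12.1, s_a=143.1, gamma=11.76,
                           kcat=49.0)
    assert akgdh.apparent_length_bp == 3666
    assert akgdh.synthesis_rate(0.6) == pytest.approx(0.6 / 3666)
    # explicit override wins
    akgdh.s_p = 1e-3
    assert akgdh.synthesis_rate(0.6) == 1e-3


def test_kinetics_table_round_trip(tmp_path, kinetics):
    path = tmp_path / "kin.tsv"
    write_kinetics_table(kinetics, path)
    again = read_kinetics_table(path)
    assert [k.reaction for k in again] == [k.reaction for k in kinetics]
    for a, b in zip(again, kinetics):
        assert a == b


def test_regulatory_config_validation(tmp_path):
    with pytest.raises(ValueError):
        RegulatoryConfig(theta=0.0)
    with pytest.raises(ValueError):
        RegulatoryConfig(dt_min=-1)
    path = tmp_path / "cfg.yaml"
    path.write_text("theta: 0.4\ntau: 0.9\n")
    cfg = RegulatoryConfig.from_yaml(path)
    assert cfg.theta == 0.4 and cfg.tau == 0.9
    path.write_text("thheta: 0.4\n")
    with pytest.raises(ValueError, match="thheta"):
        RegulatoryConfig.from_yaml(path)
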