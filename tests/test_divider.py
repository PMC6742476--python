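"""Single-cell model: derivatives, division events, adder, width fixed point."""

import math
from dataclasses import replace

import numpy as np
import pytest

import rodshape as rs
from rodshape.divider import StepSizeError


@pytest.fixture
def simple_fixed_w():
    """Simple-accumulation mode, constant width, no division noise."""
    return rs.ModelParams(delta_sigma=0.0, evolve_width=False)


class TestParams:
    def test_beta_of_k_values(self):
        assert rs.beta_of_k(0.0) == pytest.approx(0.996)
        assert rs.beta_of_k(1.0) == pytest.approx(4.697)
        assert rs.beta_of_k(0.75) == pytest.approx(3.77175)

    def test_steady_state_width(self):
        p = rs.ModelParams(k=0.75)
        assert rs.steady_state_width(p) == pytest.approx(4 * 0.75 / 3.77175, rel=1e-12)
        # doubling k and beta together leaves the fixed point unchanged
        p2 = rs.ModelParams(k=1.5, beta=2 * 3.77175)
        assert rs.steady_state_width(p2) == pytest.approx(rs.steady_state_width(
            rs.ModelParams(k=0.75, beta=3.77175)), rel=1e-12)

    def test_derived_rates_reslave_with_k(self):
        p = rs.ModelParams(k=0.75)
        q = p.with_k(1.5)
        assert q.kP_eff == pytest.approx(2 * p.kP_eff, rel=1e-12)
        assert q.beta_eff == pytest.approx(rs.beta_of_k(1.5), rel=1e-12)
        # explicit rates are preserved, not re-derived
        r = replace(p, kP=0.1).with_k(1.5)
        assert r.kP_eff == 0.1

    @pytest.mark.parametrize("kwargs", [
        {"k": 0.0}, {"rho": -1.0}, {"delta_sigma": 0.3}, {"mode": "bogus"},
        {"mode": "two_component", "kb": 0.0},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            rs.ModelParams(**kwargs)


class TestDerivatives:
    def test_width_fixed_point_is_stationary(self):
        p = rs.ModelParams(k=0.75)
        w_ss = rs.steady_state_width(p)
        for L in (2.0, 5.0, 50.0):
            _, dw, _, _ = rs.derivatives(rs.CellState(L=L, w=w_ss), p)
            assert dw == pytest.approx(0.0, abs=1e-12)

    def test_total_protein_conserved_without_production(self):
        p = rs.ModelParams(mode="two_component", kP=1e-12)  # kP ~ 0
        st = rs.CellState(L=3.0, w=1.0, Pc=2.0, Pr=1.0)
        _, _, dPc, dPr = rs.derivatives(st, p)
        assert dPc + dPr == pytest.approx(1e-12 * 3.0, abs=1e-10)

    def test_shape_factor_approaches_one_for_long_cells(self):
        p = rs.ModelParams(k=0.75, beta=1.0)
        w = 1.0
        bare = w * (p.k - p.beta_eff * w / 4.0)  # dw/dt without the shape factor
        _, dw, _, _ = rs.derivatives(rs.CellState(L=1000.0, w=w), p)
        assert dw == pytest.approx(bare, rel=1e-2)

    def test_fixed_point_is_stable(self):
        p = rs.ModelParams(k=0.75)
        w_ss = rs.steady_state_width(p)
        for eps in (-0.1, 0.1):
            _, dw, _, _ = rs.derivatives(rs.CellState(L=5.0, w=w_ss * (1 + eps)), p)
            assert dw * eps < 0  # restoring


class TestAnalyticCycle:
    def test_adder_is_independent_of_birth_length(self, simple_fixed_w):
        T1, dL1 = rs.analytic_cycle(simple_fixed_w, 1.0, 1.0)
        T2, dL2 = rs.analytic_cycle(simple_fixed_w, 2.0, 1.0)
        assert dL1 == dL2 == pytest.approx(
            simple_fixed_w.rho * math.pi * simple_fixed_w.k / simple_fixed_w.kP_eff)
        assert T1 > T2  # smaller newborn takes longer to accumulate

    def test_doubling_production_halves_added_length(self, simple_fixed_w):
        _, dL = rs.analytic_cycle(simple_fixed_w, 2.0, 1.0)
        fast = replace(simple_fixed_w, kP=2 * simple_fixed_w.kP_eff)
        _, dL2 = rs.analytic_cycle(fast, 2.0, 1.0)
        assert dL2 == pytest.approx(dL / 2, rel=1e-12)

    def test_numeric_integration_matches_closed_form(self, simple_fixed_w):
        Lb, w = 2.2, 1.0
        T, dL = rs.analytic_cycle(simple_fixed_w, Lb, w)
        rng = np.random.default_rng(0)
        st = rs.CellState(L=Lb, w=w)
        ev = None
        while ev is None:
            st, ev = rs.advance_cell(st, simple_fixed_w, 1e-3, rng)
        assert ev.time == pytest.approx(T, rel=1e-6)
        assert ev.mother_length - Lb == pytest.approx(dL, rel=1e-6)


class TestAdvanceCell:
    def test_symmetric_division_without_noise(self, simple_fixed_w):
        rng = np.random.default_rng(0)
        st = rs.CellState(L=2.83, w=1.0)
        ev = None
        while ev is None:
            st, ev = rs.advance_cell(st, simple_fixed_w, 1e-3, rng)
        assert ev.daughter_fraction == 0.5
        # daughter is half the mother at the division instant, then grows
        # exponentially for the remainder of the step
        rem = st.t - ev.time
        assert st.L == pytest.approx(
            0.5 * ev.mother_length * math.exp(simple_fixed_w.k * rem), rel=1e-9)
        # length conservation: the two daughters tile the mother exactly
        assert ev.daughter_fraction + (1 - ev.daughter_fraction) == 1.0

    def test_no_production_means_no_division(self, simple_fixed_w):
        p = replace(simple_fixed_w, kP=0.0)
        rng = np.random.default_rng(0)
        st = rs.CellState(L=2.0, w=1.0)
        for _ in range(500):
            st, ev = rs.advance_cell(st, p, 1e-2, rng)
            assert ev is None
        assert st.L == pytest.approx(2.0 * math.exp(p.k * 5.0), rel=1e-8)

    def test_oversized_step_rejected(self, simple_fixed_w):
        rng = np.random.default_rng(0)
        st = rs.CellState(L=2.83, w=1.0)
        # several generations in a single step cannot be resolved
        with pytest.raises(StepSizeError):
            for _ in range(10):
                st, _ = rs.advance_cell(st, simple_fixed_w, 5.0, rng)

    def test_cycle_becomes_periodic_without_noise(self, simple_fixed_w):
        # symmetric division halves the newborn-length deviation from the
        # adder value each generation, so periods converge geometrically to
        # the doubling time ln2/k
        rng = np.random.default_rng(0)
        st = rs.CellState(L=2.0, w=1.0)  # off the homeostatic newborn length
        times = []
        while len(times) < 32:
            st, ev = rs.advance_cell(st, simple_fixed_w, 2e-3, rng)
            if ev is not None:
                times.append(ev.time)
        periods = np.diff(times)
        gaps = np.abs(np.diff(periods))
        assert np.all(gaps[:20:2] > gaps[2:22:2])  # monotone convergence
        assert periods[-1] == pytest.approx(periods[-2], rel=1e-8)
        assert periods[-1] == pytest.approx(math.log(2) / simple_fixed_w.k, rel=1e-6)


class TestTwoComponentMode:
    def test_fast_binding_converges_to_simple_mode(self):
        # the ring lags the total accumulation by the standing cytoplasmic
        # pool ~kP*L/kb, so the division-time gap shrinks like 1/kb
        k = 0.75
        simple = rs.ModelParams(k=k, delta_sigma=0.0, evolve_width=False)
        T_simple, _ = rs.analytic_cycle(simple, 2.83, 1.0)
        gaps = []
        for kb_mult in (100, 400):
            two = replace(simple, mode="two_component",
                          kb=kb_mult * k, kd=kb_mult * k / 1000.0)
            rng = np.random.default_rng(0)
            st = rs.CellState(L=2.83, w=1.0)
            ev = None
            while ev is None:
                st, ev = rs.advance_cell(st, two, 2e-4, rng)
            gaps.append(abs(ev.time - T_simple) / T_simple)
        assert gaps[0] < 0.02
        assert gaps[1] < 0.005
        assert gaps[1] < gaps[0] / 2  # converging with kb

    def test_ring_resets_and_cytoplasm_restarts_at_pstar(self):
        p = rs.ModelParams(mode="two_component", delta_sigma=0.0,
                           evolve_width=False, Pstar=0.5)
        rng = np.random.default_rng(0)
        st = rs.CellState(L=2.83, w=1.0, Pc=0.5, Pr=0.0, Pstar=0.5)
        ev = None
        while ev is None:
            st, ev = rs.advance_cell(st, p, 5e-4, rng)
        # reset at the crossing is Pr = 0, Pc = Pstar; the tail of the step
        # re-accumulates a little, bounded by one step's production/binding
        assert st.Pr < p.kb_eff * p.Pstar * 5e-4
        assert abs(st.P) < 0.01


class TestAdderEnsemble:
    def test_added_length_exact_across_random_birth_lengths(self):
        """Many cycles, random newborn sizes: the added length has no spread."""
        p = rs.ModelParams(delta_sigma=0.0, evolve_width=False)
        rng = np.random.default_rng(9)
        L0 = rng.uniform(1.5, 4.5, size=300)
        trace = rs.run_ensemble(p, L0, 1.0, duration=1.6, dt=1e-3, seed=9)
        first = trace.events.sort_values("time_h").groupby("lineage").first()
        assert len(first) == 300  # every lineage divided once
        dL = first["mother_length_um"].to_numpy() - L0[first.index.to_numpy()]
        expect = p.rho * math.pi * 1.0 * p.k / p.kP_eff
        assert np.ptp(dL) / expect < 1e-6
        assert dL.mean() == pytest.approx(expect, rel=1e-6)

    def test_width_converges_from_any_start(self):
        p = rs.ModelParams(k=0.75, delta_sigma=0.0)
        w0 = np.array([0.5, 0.8, 1.2, 1.6, 2.0])
        trace = rs.run_ensemble(p, 3.0 * w0, w0, duration=20.0, dt=2e-3, seed=0)
        w_ss = rs.steady_state_width(p)
        assert np.all(np.abs(trace.final["w"] / w_ss - 1.0) < 0.005)

    def test_aspect_ratio_independent_of_beta(self):
        """Doubling beta moves w and L but not the newborn aspect ratio."""
        base = rs.ModelParams(k=0.75, delta_sigma=0.0)
        halfw = replace(base, beta=2 * base.beta_eff, kP=base.kP_eff)
        etas = {}
        for name, p in (("base", base), ("halfw", halfw)):
            w_ss = rs.steady_state_width(p)
            trace = rs.run_ensemble(p, 1.2 * w_ss, w_ss, duration=12.0, dt=2e-3, seed=1)
            last = trace.events[trace.events.time_h > 10.0]
            etas[name] = last["newborn_eta"].mean()
        assert rs.steady_state_width(halfw) == pytest.approx(
            rs.steady_state_width(base) / 2, rel=1e-12)
        assert etas["halfw"] == pytest.approx(etas["base"], rel=0.01)
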