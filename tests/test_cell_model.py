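"""Cell-model tests: transcription oracle, scaling hooks, pacing behaviour
and solver cross-validation."""

import numpy as np
import pytest

from torsim import ord_model as om
from torsim import metrics

# Frozen full derivative vector at the published ORd endocardial initial
# state (identity scaling, no stimulus). Regression oracle for the
# transcription; the structural tests below guard the bookkeeping
# independently of these values.
DY_AT_INIT = np.array([
    -8.1258143730490812e-02, -9.4895617265202045e-06, 4.4942515871834051e-05,
    6.3847601820053126e-06, 0.0, -1.0248754201172897e-07,
    -8.7743621967449569e-08, 1.3405462184873943e-04, 0.0,
    3.6486108218197127e-01, -4.2351599198881589e+00, -6.2583763324986802e-02,
    -1.0873934266213869e-02, -3.6907594673930399e-02, -7.4479001823382664e-03,
    9.7821438402490319e-03, -2.5183623834578216e-03, -1.1650494937284592e-03,
    1.3838310733745266e-03, -6.5988498602969641e-05, -5.7524808896197359e-07,
    7.0511120834431740e-04, -7.5313556897678893e-05, -6.5653834524989437e-07,
    4.2717698185394464e-09, -1.4394134999810377e-09, -1.0450422530994488e-11,
    -1.4929063306505659e-09, -1.0450422860221025e-10, -1.3933897147211381e-10,
    5.1155866810585170e-03, -5.7576539999241512e-10, -5.9716253226022629e-10,
    1.9281418890066010e-07, 8.9176539949384601e-09, 9.7456264370127299e-08,
    7.7409217004562130e-06, -2.2295962359121534e-04, 0.0, 0.0,
    4.8828125000000012e-07,
])


def apd90_of(trace):
    return metrics.compute_biomarkers(trace).apd90


class TestDerivatives:
    def test_full_vector_matches_oracle_to_six_sig_figs(self):
        dy = om.derivatives(om.initial_state())
        scale = np.maximum(np.abs(DY_AT_INIT), 1e-300)
        assert np.all(np.abs(dy - DY_AT_INIT) <= 5e-7 * scale + 1e-300)

    def test_resting_drift_is_small_at_published_init(self):
        # the rounded published init is close to (not exactly at) rest
        dy = om.derivatives(om.initial_state())
        assert abs(dy[0]) < 0.1

    def test_scaled_ikr_is_exactly_half_of_identity(self):
        y = om.initial_state()
        y[0] = -30.0  # polarize into the IKr activation range
        y[om.STATE_NAMES.index("xrf")] = 0.5
        y[om.STATE_NAMES.index("xrs")] = 0.5
        full = om.compute_currents(y)
        half = om.compute_currents(y, om.ConductanceScaling(scale_IKr=0.5))
        assert half["IKr"] == pytest.approx(0.5 * full["IKr"], rel=1e-12)
        assert half["INaK"] == full["INaK"]

    def test_every_scale_factor_scales_its_current_linearly(self):
        y = om.initial_state()
        y[0] = -20.0
        for g in range(9, 40):
            y[g] = 0.5  # open all gates partway so no current is zero
        base = om.compute_currents(y)
        grouped = {
            "INa": ("INa",), "INaL": ("INaL",), "Ito": ("Ito",),
            "IKr": ("IKr",), "IKs": ("IKs",), "IK1": ("IK1",),
            "ICaL": ("ICaL", "ICaNa", "ICaK"), "INaK": ("INaK",),
            "INaCa": ("INaCa_i", "INaCa_ss"),
        }
        for channel, currents in grouped.items():
            scaling = om.ConductanceScaling(**{f"scale_{channel}": 0.3})
            scaled = om.compute_currents(y, scaling)
            for cur in currents:
                assert scaled[cur] == pytest.approx(0.3 * base[cur], rel=1e-9)

    def test_sodium_bookkeeping_balances_membrane_flux(self):
        # d(Na)/dt summed over compartments must equal -sum(I_Na-carrying)
        # * Acap/F: catches sign or compartment-volume transcription slips
        y = om.initial_state()
        y[0] = -20.0
        for g in range(9, 40):
            y[g] = 0.5
        dy = om.derivatives(y)
        cur = om.compute_currents(y)
        lhs = dy[1] * om._VMYO + dy[2] * om._VSS
        total_na = (cur["INa"] + cur["INaL"] + cur["ICaNa"] + cur["INab"]
                    + 3.0 * (cur["INaCa_i"] + cur["INaCa_ss"] + cur["INaK"]))
        rhs = -total_na * om._ACAP / om._F
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_nonfinite_state_raises_naming_the_variable(self):
        y = om.initial_state()
        y[om.STATE_NAMES.index("cai")] = np.nan
        with pytest.raises(ValueError, match="cai"):
            om.derivatives(y)

    def test_scaling_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            om.ConductanceScaling(scale_IKr=-0.1)
        with pytest.raises(ValueError):
            om.ConductanceScaling(scale_INa=float("nan"))


class TestSimulate:
    def test_baseline_apd90_in_endocardial_band(self, fast_protocol):
        trace = om.simulate(protocol=fast_protocol, solver="rl")
        apd = apd90_of(trace)
        assert 200.0 <= apd <= 320.0

    def test_noop_block_is_bitwise_identical_to_no_drug(self, fast_protocol):
        a = om.simulate(protocol=fast_protocol, solver="rl")
        b = om.simulate(block_multipliers={c: 1.0 for c in om.BLOCKABLE_CHANNELS},
                        protocol=fast_protocol, solver="rl")
        assert np.array_equal(a.voltage, b.voltage)

    def test_two_identical_runs_are_bitwise_identical(self, fast_protocol):
        sc = om.ConductanceScaling(scale_IKr=0.7, scale_ICaL=1.3)
        a = om.simulate(sc, {"IKr": 0.8}, fast_protocol, solver="rl")
        b = om.simulate(sc, {"IKr": 0.8}, fast_protocol, solver="rl")
        assert np.array_equal(a.voltage, b.voltage)

    def test_solvers_agree_on_apd90(self):
        protocol = om.PacingProtocol(n_beats=10)
        fast = om.simulate(protocol=protocol, solver="rl")
        ref = om.simulate(protocol=protocol, solver="lsoda")
        assert apd90_of(fast) == pytest.approx(apd90_of(ref), abs=2.0)

    def test_diastolic_state_is_quasi_steady(self, fast_protocol):
        trace = om.simulate(protocol=fast_protocol, solver="rl")
        y_rest = np.asarray(trace.metadata["prestimulus_state"])
        dy = om.derivatives(y_rest)
        assert abs(dy[0]) < 0.01

    def test_gate_variables_bounded(self, fast_protocol):
        trace = om.simulate(protocol=fast_protocol, solver="rl",
                            record_currents=False)
        y = np.asarray(trace.metadata["prestimulus_state"])
        assert np.all(y[9:40] >= -1e-6) and np.all(y[9:40] <= 1.0 + 1e-6)

    def test_monotone_herg_block_prolongs_apd(self, fixture_population,
                                              fast_protocol):
        for _, scaling in list(fixture_population)[:3]:
            apds = []
            clean = True
            for blk in (1.0, 0.75, 0.5):
                tr = om.simulate(scaling, {"IKr": blk}, fast_protocol,
                                 solver="rl")
                if metrics.call_ra(tr).ra:
                    clean = False
                    break
                apds.append(apd90_of(tr))
            if clean:
                assert all(b >= a - 1e-9 for a, b in zip(apds, apds[1:]))

    def test_full_herg_block_on_low_reserve_member_causes_ra(self):
        scaling = om.ConductanceScaling(
            scale_IKr=0.3, scale_IKs=0.3, scale_INaK=0.7,
            scale_INaL=1.8, scale_ICaL=1.6, scale_INaCa=1.8)
        tr = om.simulate(scaling, {"IKr": 0.0},
                         om.PacingProtocol(n_beats=40), solver="rl")
        assert metrics.call_ra(tr).ra

    def test_unknown_ina_formulation_rejected(self):
        with pytest.raises(ValueError, match="formulation"):
            om.simulate(ina_formulation="grandi",
                        protocol=om.PacingProtocol(n_beats=1))

    def test_trace_grid_is_uniform_half_ms(self, fast_protocol):
        tr = om.simulate(protocol=fast_protocol, solver="rl")
        assert tr.time[0] == 0.0 and tr.time[-1] == fast_protocol.cycle_length
        assert np.allclose(np.diff(tr.time), om.OUTPUT_DT)


class TestTraceExport:
    def test_csv_with_metadata_sidecar(self, tmp_path):
        from torsim.synth import SyntheticTraceSpec, make_trace
        import json
        import pandas as pd
        tr = make_trace(SyntheticTraceSpec())
        path = tmp_path / "trace.csv"
        om.write_trace_csv(tr, path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time_ms", "voltage_mV"]
        assert len(frame) == len(tr.time)
        meta = json.loads((tmp_path / "trace.csv.meta.json").read_text())
        assert meta["kind"] == "normal"

    def test_population_bundle_round_trip(self, tmp_path):
        from torsim.synth import SyntheticTraceSpec, make_trace
        traces = {f"m{i}": make_trace(SyntheticTraceSpec()) for i in range(3)}
        path = tmp_path / "bundle.npz"
        om.write_population_bundle(traces, path)
        back = np.load(path)
        assert np.array_equal(back["m1__voltage"], traces["m1"].voltage)


class TestProtocolValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cycle_length": 0.0},
        {"n_beats": 0},
        {"n_beats": 5, "analyzed_beat": 6},
        {"stimulus_duration": 2000.0},
    ])
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            om.PacingProtocol(**kwargs)

    def test_trace_rejects_coarse_grid(self):
        t = np.arange(0.0, 1001.0, 2.0)
        with pytest.raises(ValueError, match="spacing"):
            om.APTrace(time=t, voltage=np.full_like(t, -85.0))
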