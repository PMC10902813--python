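import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfid import constants
from sulfid.errors import (
    ContractError,
    DegenerateTraceError,
    DomainError,
    RatioRangeError,
    ValidationError,
)
from sulfid.isotope_core import (
    IsotopeComposition,
    MassBiasModel,
    SpikeConfig,
    calibrate_mass_bias,
    correct_ratio,
    forward_ratio,
    mass_flow_point,
    mass_flow_trace,
    ratio_trace,
    standard_area_ratio,
)
from sulfid.signal_io import IsotopeTrace, RunConfig
from sulfid.simulate import SimPeak, SimSpec, simulate_run


class TestIsotopeComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            IsotopeComposition(x32=0.9, x34=0.05)

    def test_natural_atomic_weight_in_standard_range(self):
        aw = IsotopeComposition.natural().atomic_weight
        assert 32.05 < aw < 32.08

    def test_from_ratio_reproduces_requested_ratio(self):
        c = IsotopeComposition.from_ratio(22.555)
        assert c.r32_34 == pytest.approx(22.555, rel=1e-14)


class TestRatioTrace:
    def test_proportional_channels_give_constant_ratio(self):
        t = np.linspace(0, 10, 50)
        i34 = np.linspace(100, 200, 50)
        tr = IsotopeTrace(time=t, i32=22.555 * i34, i34=i34)
        rt = ratio_trace(tr)
        np.testing.assert_allclose(rt.r, 22.555, rtol=1e-14)
        assert not rt.corrected

    def test_zero_i34_point_is_masked_not_infinite(self):
        i34 = np.array([50.0, 0.0, 50.0])
        tr = IsotopeTrace(time=[0, 1, 2], i32=[1, 1, 1], i34=i34)
        rt = ratio_trace(tr)
        assert rt.mask.tolist() == [False, True, False]
        assert np.isfinite(rt.r[~rt.mask]).all()

    def test_all_masked_is_degenerate(self):
        tr = IsotopeTrace(time=[0, 1], i32=[1, 1], i34=[0, 0])
        with pytest.raises(DegenerateTraceError):
            ratio_trace(tr)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_unmasked_ratio_equals_elementwise_division(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        tr = IsotopeTrace(time=np.arange(n, dtype=float),
                          i32=rng.uniform(0.1, 1e5, n),
                          i34=rng.uniform(0.1, 1e5, n))
        rt = ratio_trace(tr)
        np.testing.assert_allclose(rt.r, tr.i32 / tr.i34, rtol=1e-15)


class TestMassBias:
    def test_unbiased_standard_gives_beta_zero(self):
        model = calibrate_mass_bias([22.555], r_reference=22.555)
        assert model.beta == pytest.approx(0.0, abs=1e-15)
        assert model.n_repetitions == 1

    def test_beta_substitutes_back_into_russell_law(self):
        model = calibrate_mass_bias([21.0], r_reference=22.555,
                                    m32=31.9720707, m34=33.9678668)
        recovered = 21.0 * (31.9720707 / 33.9678668) ** model.beta
        assert recovered == pytest.approx(22.555, rel=1e-14)

    def test_multiple_repetitions_average_per_run_exponents(self):
        m = calibrate_mass_bias([21.0, 22.555], r_reference=22.555)
        b1 = calibrate_mass_bias([21.0], r_reference=22.555).beta
        b2 = calibrate_mass_bias([22.555], r_reference=22.555).beta
        assert m.beta == pytest.approx((b1 + b2) / 2, rel=1e-14)
        assert m.n_repetitions == 2

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(DomainError):
            calibrate_mass_bias([22.0, -1.0])

    def test_beta_zero_correction_is_identity(self, small_trace):
        rt = ratio_trace(small_trace)
        out = correct_ratio(rt, MassBiasModel(beta=0.0))
        np.testing.assert_array_equal(out.r, rt.r)
        assert out.corrected

    def test_double_correction_refused(self, small_trace):
        rt = correct_ratio(ratio_trace(small_trace), MassBiasModel())
        with pytest.raises(ContractError):
            correct_ratio(rt, MassBiasModel())

    def test_closed_loop_recovers_reference_ratio(self):
        """Calibrating on a biased standard and correcting that same
        standard must return the certified ratio essentially exactly."""
        true_beta = 1.83
        r_meas = 22.555 * (constants.M32 / constants.M34) ** (-true_beta)
        model = calibrate_mass_bias([r_meas], r_reference=22.555)
        corrected = r_meas * model.correction_factor
        assert corrected == pytest.approx(22.555, rel=1e-13)


class TestMassFlowPoint:
    def test_pure_spike_ratio_gives_zero_mass_flow(self, spike, natural):
        r0 = spike.composition.r32_34
        eps = r0 * 1e-12
        assert mass_flow_point(r0 + eps, spike, natural) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(RatioRangeError) as ei:
            mass_flow_point(r0, spike, natural)
        assert ei.value.bound == "spike"

    def test_sample_ratio_bound_named(self, spike, natural):
        with pytest.raises(RatioRangeError) as ei:
            mass_flow_point(natural.r32_34, spike, natural)
        assert ei.value.bound == "sample"

    @pytest.mark.parametrize("mf_true", np.geomspace(1e-3, 1e3, 12).tolist())
    def test_forward_mixing_oracle_inverted(self, spike, natural, mf_true):
        """Independent isotope bookkeeping: mixing a known sample mass
        flow with the spike and inverting recovers it to 1e-10."""
        n_sample = mf_true * 1e-9 / natural.atomic_weight
        n_sp = (spike.w_spike * spike.f_spike * 1e3) / (
            constants.M34 * spike.composition.x34)
        r = ((n_sample * natural.x32 + n_sp * spike.composition.x32)
             / (n_sample * natural.x34 + n_sp * spike.composition.x34))
        assert mass_flow_point(r, spike, natural) == pytest.approx(
            mf_true, rel=1e-10)

    def test_monotone_increasing_in_ratio(self, spike, natural):
        r_lo, r_hi = spike.composition.r32_34, natural.r32_34
        grid = np.linspace(r_lo * (1 + 1e-6), r_hi * (1 - 1e-6), 100)
        mf = np.array([mass_flow_point(r, spike, natural) for r in grid])
        assert np.all(np.diff(mf) > 0)

    def test_doubling_spike_amount_doubles_mass_flow(self, spike, natural):
        r = forward_ratio(50.0, spike, natural)
        double = SpikeConfig(w_spike=2 * spike.w_spike, f_spike=spike.f_spike,
                             composition=spike.composition)
        assert mass_flow_point(r, double, natural) == pytest.approx(
            2 * mass_flow_point(r, spike, natural), rel=1e-12)


class TestMassFlowTrace:
    def test_noise_free_trace_matches_simulated_truth(self, clean_peak_run,
                                                      run_config, identity_bias):
        _, trace, truth = clean_peak_run
        mft = mass_flow_trace(trace, identity_bias, run_config)
        core = truth.mf_profile > 1e-3
        np.testing.assert_allclose(mft.mf[core], truth.mf_profile[core],
                                   rtol=1e-9)

    def test_zero_analyte_run_is_flat_zero(self, run_config, identity_bias):
        spec = SimSpec(duration=120.0, peaks=(), noise="none")
        trace, _ = simulate_run(spec)
        mft = mass_flow_trace(trace, identity_bias, run_config)
        assert np.nanmax(np.abs(mft.mf)) < 1e-9

    def test_intensity_scale_invariance(self, clean_peak_run, run_config,
                                        identity_bias):
        """Only the ratio enters: scaling both channels leaves MF unchanged."""
        _, trace, _ = clean_peak_run
        scaled = IsotopeTrace(time=trace.time, i32=7.3 * trace.i32,
                              i34=7.3 * trace.i34, dwell=trace.dwell)
        a = mass_flow_trace(trace, identity_bias, run_config)
        b = mass_flow_trace(scaled, identity_bias, run_config)
        np.testing.assert_allclose(b.mf, a.mf, rtol=1e-12, atol=1e-12,
                                   equal_nan=True)

    def test_empty_blank_regions_raise(self, clean_peak_run, identity_bias):
        _, trace, _ = clean_peak_run
        cfg = RunConfig(blank_regions=[(500.0, 600.0)])
        from sulfid.errors import BlankEstimationError
        with pytest.raises(BlankEstimationError):
            mass_flow_trace(trace, identity_bias, cfg)

    def test_masked_and_clipped_counts_reported(self, run_config, identity_bias):
        spec = SimSpec(duration=120.0, peaks=(SimPeak("p", 2.16, 60.0),),
                       noise="none")
        trace, _ = simulate_run(spec)
        i34 = trace.i34.copy()
        i34[:5] = 0.0
        t2 = IsotopeTrace(time=trace.time, i32=trace.i32, i34=i34)
        mft = mass_flow_trace(t2, identity_bias, run_config)
        assert mft.n_masked == 5
        assert mft.n_clipped > 0  # pure-spike baseline sits at the bound


def test_area_ratio_of_proportional_standard(small_trace):
    assert standard_area_ratio(small_trace) == pytest.approx(2.0, rel=1e-12)
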