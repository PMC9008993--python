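"""Delay compensation, circular membership, commands and session summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oida
from oida.pattern import (
    average_speed_kmh,
    compensate_interval,
    in_interval,
    shift_start,
    shift_stop,
)
from oida.signals_io import TIME_COL

from conftest import make_frames

CRANK_DELAYS = oida.DelayModel(200.0, 40.0, 200.0)


class TestShifts:
    def test_start_shift_at_60_rpm_crank(self):
        assert shift_start(CRANK_DELAYS, 1000.0, 360.0, "crank") == pytest.approx(144.0)

    def test_stop_shift_imu_at_60_rpm_phase(self):
        assert shift_stop(40.0, 1000.0, 100.0) == pytest.approx(4.0)

    def test_stop_shift_crank_at_50_rpm(self):
        assert shift_stop(200.0, 1200.0, 360.0) == pytest.approx(60.0)

    def test_zero_delays_give_zero_shifts(self):
        z = oida.DelayModel(0.0, 0.0, 0.0)
        assert shift_start(z, 1000.0) == 0.0
        assert shift_stop(0.0, 1000.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        muscle=st.floats(0.0, 500.0),
        sensor=st.floats(0.0, 500.0),
        duration=st.floats(100.0, 60000.0),
    )
    def test_closed_forms_and_inverse_proportionality(self, muscle, sensor, duration):
        d = oida.DelayModel(sensor, sensor, muscle)
        s1 = shift_start(d, duration, 360.0, "crank")
        s2 = shift_stop(sensor, duration, 360.0)
        assert s1 == pytest.approx((muscle + sensor) / duration * 360.0)
        assert s2 == pytest.approx(sensor / duration * 360.0)
        assert s1 >= s2
        assert shift_start(d, 2 * duration, 360.0, "crank") == pytest.approx(s1 / 2)


class TestCompensateInterval:
    def test_table_interval_at_60_rpm(self):
        iv = oida.StimulationInterval(259.0, 68.0)
        comp = compensate_interval(iv, CRANK_DELAYS, 1000.0, "crank")
        assert comp.start == pytest.approx(115.0)
        # stop shifts by 200/1000*360 = 72 deg: 68 - 72 wraps to 356
        assert comp.stop == pytest.approx(356.0)
        assert comp.shift_start == pytest.approx(144.0)
        assert comp.shift_stop == pytest.approx(72.0)

    def test_zero_delays_identity(self):
        iv = oida.StimulationInterval(259.0, 68.0)
        comp = compensate_interval(iv, oida.DelayModel(0, 0, 0), 1000.0, "crank")
        assert (comp.start, comp.stop) == (iv.start, iv.stop)

    def test_saturation_to_full_cycle_warns(self):
        iv = oida.StimulationInterval(0.0, 350.0)
        with pytest.warns(UserWarning, match="full cycle"):
            comp = compensate_interval(iv, CRANK_DELAYS, 1000.0, "crank")
        assert comp.full_cycle

    def test_compensation_commutes_with_domain_units(self):
        # same physical interval expressed in degrees and in percent
        iv_deg = oida.StimulationInterval(259.2, 68.4, span=360.0)
        iv_pct = oida.StimulationInterval(72.0, 19.0, span=100.0)
        d = oida.DelayModel(120.0, 120.0, 200.0)
        c_deg = compensate_interval(iv_deg, d, 1400.0, "crank")
        c_pct = compensate_interval(iv_pct, d, 1400.0, "phase")
        assert c_deg.start / 3.6 == pytest.approx(c_pct.start)
        assert c_deg.stop / 3.6 == pytest.approx(c_pct.stop)


class TestInInterval:
    @pytest.mark.parametrize(
        "interval,pos,expected",
        [
            ((259.0, 68.0, 360.0), 300.0, True),
            ((259.0, 68.0, 360.0), 100.0, False),
            ((99.0, 45.0, 100.0), 10.0, True),
            ((30.0, 210.0, 360.0), 30.0, True),   # half-open: start included
            ((30.0, 210.0, 360.0), 210.0, False),  # stop excluded
        ],
    )
    def test_membership_examples(self, interval, pos, expected):
        start, stop, span = interval
        iv = oida.StimulationInterval(start, stop, span=span)
        assert in_interval(pos, iv) is expected

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            span = 360
            a, b = rng.integers(0, span, 2)
            if a == b:
                continue
            iv = oida.StimulationInterval(float(a), float(b), span=float(span))
            positions = np.arange(span, dtype=float)
            got = in_interval(positions, iv)
            if a < b:
                expected = (positions >= a) & (positions < b)
            else:
                expected = (positions >= a) | (positions < b)
            np.testing.assert_array_equal(got, expected)
            assert got.sum() == iv.width


class TestStimulationCommand:
    def constant_session(self, rpm=60.0, seconds=30.0):
        rate = rpm * 360.0 / 60000.0
        t = 10.0 * np.arange(int(seconds * 100))
        return make_frames(t, crank=rate * t)

    def pattern(self, start=259.0, stop=68.0):
        return oida.StimulationPattern(
            domain="crank",
            channels={"LQ": oida.StimulationInterval(start, stop)},
        )

    def test_zero_delays_equal_raw_membership(self):
        frames = self.constant_session()
        cmds = oida.stimulation_command(frames, self.pattern(), oida.DelayModel(0, 0, 0))
        iv = oida.StimulationInterval(259.0, 68.0)
        expected = in_interval(frames["crank_angle_deg"].to_numpy(), iv)
        np.testing.assert_array_equal(cmds["cmd_LQ"].to_numpy(), expected)

    def test_on_transition_advanced_by_shift_start(self):
        frames = self.constant_session(rpm=60.0)
        raw = oida.stimulation_command(frames, self.pattern(), oida.DelayModel(0, 0, 0))
        comp = oida.stimulation_command(frames, self.pattern(), CRANK_DELAYS)
        ang = frames["crank_angle_deg"].to_numpy()

        def on_positions(cmds):
            c = cmds["cmd_LQ"].to_numpy()
            idx = np.nonzero(c[1:] & ~c[:-1])[0] + 1
            return ang[idx[-3:]]  # steady-state transitions

        # at 60 RPM shift_start = (200+200)/1000*360 = 144 deg; sampling
        # quantization at this cadence is 3.6 deg/sample
        for p_raw, p_comp in zip(on_positions(raw), on_positions(comp)):
            assert (p_raw - p_comp) % 360.0 == pytest.approx(144.0, abs=4.0)

    def test_on_fraction_equals_compensated_width(self):
        frames = self.constant_session(rpm=60.0)
        cmds = oida.stimulation_command(frames, self.pattern(), CRANK_DELAYS)
        cycles = oida.detect_crank_cycles(frames)
        comp = compensate_interval(
            oida.StimulationInterval(259.0, 68.0), CRANK_DELAYS, cycles[-1].duration
        )
        c = cycles[-1]
        sel = (frames[TIME_COL] >= c.start_t) & (frames[TIME_COL] < c.end_t)
        frac = cmds.loc[sel, "cmd_LQ"].mean()
        width = (comp.stop - comp.start) % 360.0
        assert frac == pytest.approx(width / 360.0, abs=0.02)

    def test_cadence_halving_halves_the_shift_in_degrees(self):
        # the shift is a time converted to position: at half the cadence the
        # same latency spans half the angle (two constant halves: 60 then 30 RPM)
        rate1, rate2 = 0.36, 0.18  # deg/ms
        t = 10.0 * np.arange(6000)
        split = 30000.0
        ang = np.where(t < split, rate1 * t, rate1 * split + rate2 * (t - split))
        frames = make_frames(t, crank=ang)
        cmds = oida.stimulation_command(frames, self.pattern(), CRANK_DELAYS)
        c = cmds["cmd_LQ"].to_numpy()
        onsets = np.nonzero(c[1:] & ~c[:-1])[0] + 1
        ang_on = np.mod(ang[onsets], 360.0)
        early = (259.0 - ang_on[2]) % 360.0   # steady 60 RPM cycle
        late = (259.0 - ang_on[-1]) % 360.0   # steady 30 RPM cycle
        assert late == pytest.approx(early / 2, rel=0.05)


class TestSummarizeSession:
    def test_printed_overground_numbers(self):
        # 96 wheel revolutions of a 2.1 m wheel in 03:58 -> 201.6 m, 3.05 km/h
        assert average_speed_kmh(201.6, 238.0) == pytest.approx(3.05, abs=0.005)
        t = np.arange(0.0, 238000.0 + 1, 100.0)
        wheel = np.zeros(len(t))
        step = int(len(t) / 96)
        wheel[step::step][:96] = 1
        frames = make_frames(t, wheel_rev=wheel)
        s = oida.summarize_session(frames, wheel_circumference=2.1)
        assert s.distance_m == pytest.approx(201.6)
        assert s.speed_avg_kmh == pytest.approx(3.05, abs=0.01)
        assert s.duration_mmss == "03:58"

    def test_stationary_session(self):
        frames = make_frames(10.0 * np.arange(500), wheel_rev=0.0)
        s = oida.summarize_session(frames, 2.1)
        assert s.distance_m == 0.0
        assert s.speed_avg_kmh == 0.0
        assert s.cadence_avg_rpm is None

    def test_no_distance_source_reports_unavailable(self):
        frames = make_frames(10.0 * np.arange(500))
        s = oida.summarize_session(frames, 2.1)
        assert s.distance_m is None
        assert s.speed_avg_kmh is None

    def test_constant_speed_wheel_events(self):
        # 10 km/h = 2.7778 m/s; 2.1 m wheel -> one event every 756 ms
        t = np.arange(0.0, 60001.0, 2.0)
        wheel = np.isin(t, np.arange(756.0, 60000.0, 756.0)).astype(float)
        frames = make_frames(t, wheel_rev=wheel)
        s = oida.summarize_session(frames, 2.1)
        assert s.speed_max_kmh == pytest.approx(10.0, rel=0.01)
        assert s.speed_avg_kmh == pytest.approx(10.0, rel=0.02)

    def test_power_and_cadence_on_synthetic_constant_session(self):
        # 60 RPM, constant total torque 10 N*m -> power = 10 * 2*pi rad/s
        rate = 0.36
        t = 10.0 * np.arange(3000)
        frames = make_frames(t, crank=rate * t, torque_left=6.0, torque_right=4.0)
        s = oida.summarize_session(frames, 2.1)
        assert s.cadence_avg_rpm == pytest.approx(60.0, rel=0.01)
        assert s.power_avg_w == pytest.approx(10.0 * 2 * np.pi, rel=0.01)
        assert s.power_avg_w <= s.power_max_w
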