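"""Protocol representation, the common head/tail, square waves, and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcdesign.fixtures import paper_squarewave_spec, squarewave_protocol
from vcdesign.protocols import (
    Protocol,
    Segment,
    SquareWaveSpec,
    common_head,
    common_tail,
    read_protocol,
    square_wave_to_segments,
    square_wave_voltage,
    with_head_and_tail,
    write_protocol,
)


class TestSegmentsAndVoltage:
    def test_step_requires_equal_voltages(self):
        with pytest.raises(ValueError, match="v_start == v_end"):
            Segment("step", 100.0, -80.0, 40.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            Segment.step(0.0, -80.0)

    def test_leak_ramp_midpoint(self, head):
        # third head segment: 400 ms linear ramp -120 -> -80
        t_mid = 250.0 + 50.0 + 200.0
        assert head.voltage_at(t_mid) == pytest.approx(-100.0)

    def test_step_constant_inside(self, head):
        for t in (0.0, 100.0, 249.9):
            assert head.voltage_at(t) == -80.0

    def test_boundary_belongs_to_next_segment(self, head):
        # 250 ms is the start of the -120 mV step
        assert head.voltage_at(250.0) == -120.0

    def test_out_of_range_time_rejected(self, head):
        with pytest.raises(ValueError, match="outside"):
            head.voltage_at(-1.0)
        with pytest.raises(ValueError, match="outside"):
            head.voltage_at(head.total_duration)

    def test_half_open_sampling_counts(self, toy_protocol):
        # per-segment sample counts partition the uniform grid exactly
        dt = 1.0
        times = np.arange(int(np.ceil(toy_protocol.total_duration / dt))) * dt
        b = toy_protocol.boundaries
        counts = [np.sum((times >= b[i] - 1e-9) & (times < b[i + 1] - 1e-9))
                  for i in range(len(toy_protocol))]
        assert sum(counts) == times.size


class TestCommonHeadTail:
    def test_head_rows(self, head):
        expected = [("step", 250, -80, -80), ("step", 50, -120, -120),
                    ("ramp", 400, -120, -80), ("step", 200, -80, -80),
                    ("step", 1000, 40, 40), ("step", 500, -120, -120),
                    ("step", 1000, -80, -80)]
        assert [(s.kind, s.duration, s.v_start, s.v_end)
                for s in head.segments] == expected
        assert head.total_duration == 3400.0

    def test_tail_rows(self):
        tail = common_tail()
        assert len(tail) == 6
        assert [s.kind for s in tail.segments].count("ramp") == 1
        ramp = [s for s in tail.segments if s.kind == "ramp"][0]
        assert (ramp.duration, ramp.v_start, ramp.v_end) == (100.0, -70.0, -110.0)
        assert tail.total_duration == 2500.0

    def test_wrapping_adds_thirteen_commands(self):
        body = Protocol(tuple(Segment.step(100.0, v) for v in (-40.0, 0.0)))
        assert len(with_head_and_tail(body)) == 13 + 2

    def test_hardware_limit_enforced(self):
        p = Protocol(tuple(Segment.step(10.0, -80.0) for _ in range(65)))
        with pytest.raises(ValueError, match="64"):
            p.validate_for_hardware()


class TestSquareWave:
    def test_paper_spec_at_zero(self):
        # all sines vanish at t=0 and sign(0)=0, leaving only the offset
        assert square_wave_voltage(paper_squarewave_spec(), 0.0) == -30.0

    def test_single_component_sign(self):
        spec = SquareWaveSpec(-30.0, (10.0,), (np.pi / 1000.0,), (0.0,))
        assert square_wave_voltage(spec, 500.0) == pytest.approx(-20.0)
        assert square_wave_voltage(spec, 1500.0) == pytest.approx(-40.0)

    @given(st.floats(0, 5000))
    @settings(derandomize=True, max_examples=50)
    def test_voltage_bounded_by_amplitude_sum(self, t):
        spec = paper_squarewave_spec()
        v = square_wave_voltage(spec, t)
        assert spec.offset - 90.0 <= v <= spec.offset + 90.0

    def test_full_period_gives_two_equal_steps(self):
        spec = SquareWaveSpec(0.0, (10.0,), (2 * np.pi / 500.0,), (0.0,))
        p = square_wave_to_segments(spec, 500.0)
        assert len(p) == 2
        assert p.segments[0].duration == pytest.approx(250.0)
        assert p.segments[1].duration == pytest.approx(250.0)
        assert p.segments[0].v_start == pytest.approx(10.0)
        assert p.segments[1].v_start == pytest.approx(-10.0)

    def test_duration_before_first_crossing_gives_one_step(self):
        spec = SquareWaveSpec(0.0, (10.0,), (1e-4,), (0.0,))
        assert len(square_wave_to_segments(spec, 100.0)) == 1

    def test_segments_match_pointwise_evaluation(self):
        # the step list reproduces the closed form away from switch instants
        spec = paper_squarewave_spec()
        p = square_wave_to_segments(spec, 680.0)
        t = np.arange(0.0, 680.0, 0.1)
        direct = square_wave_voltage(spec, t)
        stepped = p.voltage_trace(t)
        # switching instants (incl. t=0, where every sign(0) term vanishes)
        crossings = np.concatenate(
            [(np.arange(0, int(w * 680.0 / np.pi) + 1) * np.pi) / w
             for w in spec.frequencies])
        away = np.all(np.abs(t[:, None] - crossings[None, :]) > 1e-6, axis=1)
        assert np.array_equal(stepped[away], direct[away])

    def test_segment_count_cap(self):
        spec = SquareWaveSpec(0.0, (10.0,), (1.0,), (0.0,))
        with pytest.raises(ValueError, match="segments"):
            square_wave_to_segments(spec, 1000.0, max_segments=10)

    def test_fixture_fits_hardware(self):
        squarewave_protocol().validate_for_hardware()


class TestProtocolIO:
    def test_head_roundtrip(self, tmp_path, head):
        path = tmp_path / "head.tsv"
        write_protocol(head, path)
        again = read_protocol(path)
        assert again.segments == head.segments

    def test_designed_body_command_count(self, tmp_path):
        body = Protocol(tuple(Segment.step(100.0, -80.0) for _ in range(51)))
        full = with_head_and_tail(body)
        path = tmp_path / "design.tsv"
        write_protocol(full, path)
        assert len(read_protocol(path)) == 64

    def test_negative_duration_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("kind\tduration_ms\tv_start_mV\tv_end_mV\n"
                        "step\t100\t-80\t-80\n"
                        "step\t-5\t-80\t-80\n")
        with pytest.raises(ValueError, match="row 2"):
            read_protocol(path)

    def test_inconsistent_step_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("kind\tduration_ms\tv_start_mV\tv_end_mV\n"
                        "step\t100\t-80\t40\n")
        with pytest.raises(ValueError, match="row 1"):
            read_protocol(path)

    @given(st.lists(st.tuples(st.sampled_from(["step", "ramp"]),
                              st.integers(1, 10000),
                              st.integers(-1200, 600),
                              st.integers(-1200, 600)),
                    min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=25)
    def test_roundtrip_random_protocols(self, tmp_path_factory, rows):
        segs = []
        for kind, d, v0, v1 in rows:
            v0, v1 = v0 / 10.0, v1 / 10.0
            segs.append(Segment(kind, d / 10.0, v0, v0 if kind == "step" else v1))
        p = Protocol(tuple(segs), "rand")
        path = tmp_path_factory.mktemp("io") / "p.tsv"
        write_protocol(p, path)
        assert read_protocol(path).segments == p.segments
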