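"""Trigger, reduction, decimation and frame assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import otstream as ot
from otstream.stream_pipeline import (AOPSeries, AOPState, TriggerConfig,
                                      apply_skip, assemble_frames, block_average,
                                      compute_aop, count_events_window,
                                      detect_roi, form_lines, process_stream,
                                      reduce_line)


def make_aop(values, baseline=1000.0, threshold=50.0, first=0):
    values = np.asarray(values, dtype=float)
    base = np.full(len(values), baseline)
    return AOPSeries(values, base, threshold, first,
                     AOPState(baseline, threshold, np.zeros(64)))


class TestBlockAverage:
    def test_constant_input(self):
        assert block_average(np.full(64, 1234)) == 1234.0

    def test_alternating_extremes(self):
        w = np.tile([0, 2**16 - 1], 32)
        assert block_average(w) == (2**16 - 1) / 2

    def test_equals_direct_sum_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            w = rng.integers(0, 2**16, 64)
            assert block_average(w) == w.sum() / 64  # exact, integer partials

    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError):
            block_average(np.zeros(60))


class TestComputeAop:
    def test_clear_stream_constant_baseline(self):
        scene = ot.make_cell(10.0, 0.0, None, pitch=0.2, seed=0)
        stream = ot.synthesize_stream(
            scene, 1.0, ot.AcqParams(noise_sigma=0.0, envelope="flat"))
        aop = compute_aop(stream)
        assert np.all(aop.values == stream.params.full_scale)
        assert np.all(aop.baseline == stream.params.full_scale)

    def test_single_cell_dip_width(self, stream_12um):
        _, stream = stream_12um
        aop = compute_aop(stream)
        dip = aop.baseline - aop.values >= aop.threshold
        runs = np.flatnonzero(np.diff(np.concatenate(([0], dip.view(np.int8), [0]))))
        assert len(runs) == 2  # one contiguous dip
        # 12 µm at 2.4 m/s -> 12e-6 * 80e6 / 2.4 = 400 pulses, minus taper
        assert 360 <= runs[1] - runs[0] <= 400

    def test_chunked_equals_batch(self, stream_12um):
        _, stream = stream_12um
        cfg = TriggerConfig()
        batch = compute_aop(stream, cfg)
        first = stream.slice_pulses(0, 150)
        second = stream.slice_pulses(150, stream.n_pulses)
        a = compute_aop(first, cfg)
        b = compute_aop(second, cfg, state=a.state)
        np.testing.assert_array_equal(
            np.concatenate([a.values, b.values]), batch.values)
        np.testing.assert_allclose(
            np.concatenate([a.baseline, b.baseline]), batch.baseline)

    def test_too_few_pulses(self):
        scene = ot.make_cell(4.0, 0.0, None, pitch=0.2, seed=0)
        stream = ot.synthesize_stream(scene, 20.0, ot.AcqParams(noise_sigma=0.0))
        with pytest.raises(ValueError, match="calibration"):
            compute_aop(stream, TriggerConfig(calibration_pulses=10_000))


def _brute_force_rois(dip_mask, guard, merge_gap):
    """Independent scan: extend every dipped pulse by guard, then merge."""
    n = len(dip_mask)
    marked = np.zeros(n, bool)
    for i in np.flatnonzero(dip_mask):
        marked[max(i - guard, 0):min(i + guard + 1, n)] = True
    rois = []
    i = 0
    while i < n:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j < n and marked[j]:
            j += 1
        if rois and i - rois[-1][1] <= merge_gap:
            rois[-1] = (rois[-1][0], j)
        else:
            rois.append((i, j))
        i = j
    return rois


class TestDetectRoi:
    def test_flat_aop_no_events(self):
        aop = make_aop(np.full(200, 1000.0))
        assert detect_roi(aop, TriggerConfig()) == []

    def test_single_dip_with_guard(self):
        values = np.full(300, 1000.0)
        values[100:140] = 900.0
        aop = make_aop(values)
        cfg = TriggerConfig(threshold=50.0, guard_pulses=2, merge_gap=2)
        assert detect_roi(aop, cfg) == [(98, 142)]

    def test_dips_separated_by_merge_gap_merge(self):
        values = np.full(300, 1000.0)
        values[100:110] = 900.0
        values[116:126] = 900.0  # gap of 2 after guard extension
        cfg = TriggerConfig(threshold=50.0, guard_pulses=2, merge_gap=2)
        assert detect_roi(make_aop(values), cfg) == [(98, 128)]

    def test_threshold_tie_triggers(self):
        values = np.full(100, 1000.0)
        values[50] = 950.0  # deviation exactly == threshold
        cfg = TriggerConfig(threshold=50.0, guard_pulses=0, merge_gap=0)
        assert detect_roi(make_aop(values), cfg) == [(50, 51)]

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_brute_force_scan(self, data):
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        guard = data.draw(st.integers(0, 4))
        merge_gap = data.draw(st.integers(0, 4))
        rng = np.random.default_rng(rng_seed)
        values = np.full(200, 1000.0)
        values[rng.random(200) < 0.1] = 900.0
        cfg = TriggerConfig(threshold=50.0, guard_pulses=guard, merge_gap=merge_gap)
        got = detect_roi(make_aop(values), cfg)
        assert got == _brute_force_rois(values < 950.0, guard, merge_gap)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           t1=st.floats(10.0, 80.0), t2=st.floats(10.0, 80.0))
    def test_trigger_monotone_in_threshold(self, seed, t1, t2):
        """Raising the threshold never increases the triggered pulse count."""
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(seed)
        values = 1000.0 - 100.0 * (rng.random(300) < 0.15) * rng.random(300)
        total = {}
        for t in (lo, hi):
            rois = detect_roi(make_aop(values, threshold=t),
                              TriggerConfig(threshold=t))
            total[t] = sum(e - s for s, e in rois)
        assert total[hi] <= total[lo]


class TestCountEventsWindow:
    def test_window_duration_is_20_us(self):
        cfg = TriggerConfig(mode="large_window", window_pulses=1600)
        assert cfg.window_pulses / 80e6 == pytest.approx(20e-6)

    def test_counts_constructed_dips(self):
        values = np.full(3200, 1000.0)
        for k in range(25):  # 25 dips inside the first window
            values[40 * k + 10:40 * k + 20] = 900.0
        values[1700:1710] = 900.0  # one event in the second window
        cfg = TriggerConfig(threshold=50.0, mode="large_window", window_pulses=1600)
        counts = count_events_window(make_aop(values), cfg)
        assert counts.tolist() == [25, 1]

    def test_flat_aop_all_zero(self):
        cfg = TriggerConfig(threshold=50.0, mode="large_window", window_pulses=100)
        counts = count_events_window(make_aop(np.full(350, 1000.0)), cfg)
        assert counts.tolist() == [0, 0, 0, 0]  # last window truncated

    def test_requires_large_window_mode(self):
        with pytest.raises(ValueError):
            count_events_window(make_aop(np.ones(10)), TriggerConfig())


class TestFormLines:
    def test_synchronous_index_arithmetic(self, stream_12um):
        _, stream = stream_12um
        lines = form_lines(stream)
        assert lines.shape == (stream.n_pulses, 64)
        for i in (0, 17, stream.n_pulses - 1):
            np.testing.assert_array_equal(
                lines[i], stream.samples[128 * i + 32:128 * i + 96])

    def test_async_nonzero_offset_tracks_drift(self):
        scene = ot.make_cell(10.0, 0.5, None, pitch=0.2, seed=0)
        params = ot.AcqParams(noise_sigma=0.0, clock_mode="asynchronous",
                              offset_ppm=300.0)
        stream = ot.synthesize_stream(scene, 1.0, params)
        sync = ot.synthesize_stream(
            scene, 1.0, ot.AcqParams(noise_sigma=0.0))
        np.testing.assert_array_equal(form_lines(stream), form_lines(sync))

    def test_line_count_conserved(self, stream_12um):
        _, stream = stream_12um
        assert len(form_lines(stream)) == stream.n_pulses


class TestReduceLine:
    def test_background_identity_gives_zero(self):
        bg = np.full(64, 50000.0)
        assert np.all(reduce_line(bg.astype(np.uint16), bg) == 0)

    def test_hand_arithmetic(self):
        bg = np.full(64, 60000.0)
        line = np.full(64, 30000, dtype=np.uint16)
        assert np.all(reduce_line(line, bg, gain_shift=0) == 117)

    def test_gain_shift_doubles_before_clipping(self):
        bg = np.full(64, 60000.0)
        line = np.full(64, 55000, dtype=np.uint16)
        once = reduce_line(line, bg, 0).astype(int)
        twice = reduce_line(line, bg, 1).astype(int)
        np.testing.assert_array_equal(twice, np.clip(2 * ((bg - 55000)) / 256, 0, 255).round())
        assert np.all(twice >= once)


class TestApplySkip:
    def test_identity(self):
        lines = np.arange(50).reshape(10, 5)
        np.testing.assert_array_equal(apply_skip(lines, 1), lines)

    @pytest.mark.parametrize("n,skip,kept", [(2400, 64, 38), (2400, 8, 300)])
    def test_kept_counts(self, n, skip, kept):
        lines = np.zeros((n, 64), dtype=np.uint8)
        assert len(apply_skip(lines, skip)) == kept

    def test_rejects_bad_skip(self):
        with pytest.raises(ValueError):
            apply_skip(np.zeros((4, 4)), 0)


class TestAssembleFrames:
    def test_exact_fit_no_flags(self):
        frames = assemble_frames(np.ones((38, 64), np.uint8), 38, 1, 0)
        assert len(frames) == 1 and frames[0].header.flags == frozenset()

    def test_remainder_zero_padded_and_split(self):
        frames = assemble_frames(np.ones((40, 64), np.uint8), 38, 1, 0)
        assert len(frames) == 2
        assert "padded" in frames[1].header.flags
        assert "split" in frames[1].header.flags
        assert np.all(frames[1].image[2:] == 0)
        assert np.all(frames[1].image[:2] == 1)

    def test_empty_input(self):
        assert assemble_frames(np.zeros((0, 64), np.uint8), 38, 1, 0) == []

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(1, 500), n_seg=st.integers(1, 64), skip=st.integers(1, 16))
    def test_row_conservation(self, n, n_seg, skip):
        """ceil(n/skip) decimated rows survive framing minus padding."""
        lines = np.ones((n, 8), np.uint8)
        kept = apply_skip(lines, skip)
        frames = assemble_frames(kept, n_seg, skip, 0)
        total_rows = sum(f.image.shape[0] for f in frames)
        padded_rows = sum(int((f.image.sum(axis=1) == 0).sum()) for f in frames)
        assert total_rows - padded_rows == len(kept) == -(-n // skip)


class TestProcessStream:
    def test_clear_stream_no_frames(self):
        scene = ot.make_cell(10.0, 0.0, None, pitch=0.2, seed=0)
        stream = ot.synthesize_stream(scene, 1.0, ot.AcqParams(noise_sigma=0.0))
        frames, report = process_stream(stream)
        assert frames == []
        assert report.data_rate_mib_s == 0.0

    def test_small_population_one_frame_per_cell(self):
        scene = ot.make_population(10, ("fixed", 8.0), 50.0, pitch=0.2, seed=4)
        stream = ot.synthesize_stream(scene, 10.0, ot.AcqParams(noise_sigma=0.0))
        frames, _ = process_stream(stream, skip=8)
        assert len(frames) == 10

    def test_chunked_equals_batch(self):
        scene = ot.make_population(3, ("fixed", 8.0), 60.0, pitch=0.2, seed=8)
        stream = ot.synthesize_stream(scene, 10.0, ot.AcqParams(noise_sigma=0.0))
        cfg = TriggerConfig()
        batch, _ = process_stream(stream, cfg, skip=4)
        cut = stream.n_pulses // 2  # between cells for this seed
        first = stream.slice_pulses(0, cut)
        second = stream.slice_pulses(cut, stream.n_pulses)
        f1, _ = process_stream(first, cfg, skip=4)
        state = compute_aop(first, cfg).state
        f2, _ = process_stream(second, cfg, skip=4, state=state,
                               pulse_offset=cut, frame_index_start=len(f1))
        chunked = f1 + f2
        assert len(chunked) == len(batch)
        for a, b in zip(chunked, batch):
            np.testing.assert_array_equal(a.image, b.image)
            assert a.header == b.header

    def test_large_window_mode_flags(self, stream_12um):
        _, stream = stream_12um
        cfg = TriggerConfig(mode="large_window", window_pulses=256)
        frames, _ = process_stream(stream, cfg, skip=1)
        assert frames and all("large_window" in f.header.flags for f in frames)

    def test_reduced_byte_accounting(self, frames_12um):
        frames, report, _ = frames_12um
        n_seg = frames[0].image.shape[0]
        duration = None
        # reduced bytes = n_frames * (header + payload); rate = bytes / duration
        expected_bytes = len(frames) * (32 + n_seg * 64)
        assert report.data_rate_mib_s > 0
        assert report.drp == pytest.approx(
            1 - report.data_rate_mib_s * 2**20 / report.raw_rate_bytes_s)
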