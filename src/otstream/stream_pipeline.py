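"""Real-time processing chain: trigger, reduce, reconstruct, frame.

Mirrors the hardware pipeline stage for stage: 32-sample block packing
and pairwise ("two-divide") averaging, per-pulse window means (AOP, the
trigger statistic), line-buffer formation under synchronous or
asynchronous sample clocks, ROI triggering against a slowly adapting
background baseline, per-pixel background removal with 16→8-bit
requantization, pulse-skip decimation of oversampled lines, and packing
into fixed-pulse-count cell frames with a morphometry-tagged header.

Stages are pure functions over arrays so that batch and chunked
(streaming) execution are bit-identical; ``AOPState`` carries the
calibration products across chunk boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .acquisition import SampleStream, line_pitch

__all__ = [
    "BLOCK", "HEADER_BYTES",
    "TriggerConfig", "AOPState", "AOPSeries", "FrameHeader", "CellFrame",
    "AlignmentError",
    "block_average", "compute_aop", "detect_roi", "count_events_window",
    "form_lines", "reduce_line", "apply_skip", "assemble_frames",
    "default_n_seg", "process_stream",
]

#: hardware block size in samples (one parallel word)
BLOCK = 32
#: fixed per-segment header length in bytes (see segio)
HEADER_BYTES = 32


class AlignmentError(RuntimeError):
    """Asynchronous window re-alignment failed for a given pulse."""

    def __init__(self, pulse_index: int, message: str):
        self.pulse_index = pulse_index
        super().__init__(f"pulse {pulse_index}: {message}")


@dataclass(frozen=True)
class TriggerConfig:
    """Event-trigger settings.

    ``threshold`` is the AOP deviation below baseline (16-bit counts)
    that marks a cell pulse; ``None`` selects the default rule
    ``max(8 * 1.4826 * MAD(calibration AOP), 1)``.  ``guard_pulses``
    extend each triggered run on both sides, runs separated by at most
    ``merge_gap`` pulses are merged.  The first ``calibration_pulses``
    pulses are assumed cell-free and set the baseline and the per-pixel
    background.  ``large_window`` mode partitions the stream into fixed
    multi-cell frames of ``window_pulses`` (dense-sample operation).
    """

    threshold: float | None = None
    guard_pulses: int = 2
    merge_gap: int = 2
    calibration_pulses: int = 64
    mode: Literal["per_cell", "large_window"] = "per_cell"
    window_pulses: int = 1600
    ema_alpha: float = 1.0 / 256.0
    pulse_amp_threshold: float | None = None  # async alignment; default full_scale/4

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.calibration_pulses < 64:
            raise ValueError("calibration_pulses must be at least 64")
        if self.guard_pulses < 0 or self.merge_gap < 0:
            raise ValueError("guard_pulses and merge_gap must be non-negative")


@dataclass
class AOPState:
    """Calibration products carried across stream chunks."""

    baseline: float
    threshold: float
    background: np.ndarray | None = None  # per-pixel 16-bit reference


@dataclass
class AOPSeries:
    """Per-pulse window means plus the running baseline used to trigger."""

    values: np.ndarray      # float, one per pulse
    baseline: np.ndarray    # baseline in force at each pulse
    threshold: float
    first_triggerable: int  # pulses before this are calibration
    state: AOPState         # state after the last pulse

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FrameHeader:
    frame_index: int
    start_pulse: int
    skip: int
    size_um: float = 0.0
    opacity: int = 0
    granularity: float = 0.0
    nx: int = 0
    ny: int = 0
    flags: frozenset[str] = frozenset()


@dataclass
class CellFrame:
    """Fixed-pulse-count 8-bit image segment (rows = decimated pulses)."""

    image: np.ndarray  # (n_seg, window_px) uint8
    header: FrameHeader

    def validate(self, n_seg: int | None = None) -> None:
        if self.image.dtype != np.uint8 or self.image.ndim != 2:
            raise ValueError("frame image must be a 2-D uint8 array")
        if n_seg is not None and self.image.shape[0] != n_seg:
            raise ValueError("frame row count must equal the configured n_seg")


# ---------------------------------------------------------------------------
# stage 1: block averaging

def block_average(window_samples: np.ndarray) -> float:
    """Exact mean of a power-of-two window via a balanced pairwise tree.

    Emulates the hardware's two-way divide-and-add over 32-sample blocks;
    integer partial sums make the result identical to direct summation.
    """
    x = np.asarray(window_samples).ravel().astype(np.int64)
    n = len(x)
    if n == 0 or (n & (n - 1)) != 0:
        raise ValueError("window length must be a positive power of two")
    while len(x) > 1:
        x = x[0::2] + x[1::2]
    return float(x[0]) / n


# ---------------------------------------------------------------------------
# stage 2: line formation

def form_lines(stream: SampleStream,
               pulse_amp_threshold: float | None = None) -> np.ndarray:
    """Cut one ``window_px``-sample line per pulse; (n_pulses, window_px) u16.

    Synchronous clock: line ``i`` is samples
    ``[period*i + phase, period*i + phase + window_px)`` — two 32-sample
    blocks at the configured phase.  Asynchronous clock: three blocks
    (96 samples) are captured around the predicted window position and
    the window start is re-aligned to the first sample at or above the
    pulse amplitude threshold, tracking the clock drift pulse by pulse.
    """
    stream.validate()
    p = stream.params
    if p.clock_mode == "synchronous" or p.offset_ppm == 0.0:
        period = p.samples_per_period
        usable = stream.n_pulses * period
        lines = stream.samples[:usable].reshape(stream.n_pulses, period)
        return lines[:, p.window_phase:p.window_phase + p.window_px].copy()

    thr = pulse_amp_threshold if pulse_amp_threshold is not None else p.full_scale / 4.0
    period = p.samples_per_period
    w = p.window_px
    capture = 3 * BLOCK  # 96-sample capture region
    lines = np.empty((stream.n_pulses, w), dtype=np.uint16)
    prev_start = p.window_phase  # prediction for pulse 0
    samples = stream.samples
    for n in range(stream.n_pulses):
        expected = prev_start if n == 0 else prev_start + period
        region_start = max(expected - (capture - w) // 2, 0)
        region = samples[region_start:region_start + capture]
        above = np.nonzero(region >= thr)[0]
        if len(above) == 0:
            raise AlignmentError(n, "no sample crosses the pulse threshold")
        start = region_start + int(above[0])
        if start + w > len(samples) or start + w > region_start + capture:
            raise AlignmentError(n, "window would overrun the capture region")
        lines[n] = samples[start:start + w]
        prev_start = start
    return lines


# ---------------------------------------------------------------------------
# stage 3: AOP + baseline

def compute_aop(stream: SampleStream, cfg: TriggerConfig | None = None,
                state: AOPState | None = None,
                lines: np.ndarray | None = None) -> AOPSeries:
    """Per-pulse window means with a cell-aware running baseline.

    The baseline starts as the mean AOP of the calibration pulses
    (assumed cell-free) and is then updated by an exponential moving
    average (``alpha = 1/256``) over non-triggered pulses only, so cells
    do not drag it down.  Passing ``state`` resumes a previous chunk:
    calibration is skipped and the carried baseline/threshold are used,
    which makes chunked processing identical to batch processing.
    """
    cfg = cfg or TriggerConfig()
    if lines is None:
        lines = form_lines(stream, cfg.pulse_amp_threshold)
    values = lines.astype(np.int64).sum(axis=1) / lines.shape[1]

    if state is None:
        if len(values) < cfg.calibration_pulses:
            raise ValueError("stream shorter than the calibration window")
        cal = values[:cfg.calibration_pulses]
        baseline0 = float(cal.mean())
        if cfg.threshold is not None:
            threshold = float(cfg.threshold)
        else:
            mad = float(np.median(np.abs(cal - np.median(cal))))
            threshold = max(8.0 * 1.4826 * mad, 1.0)
        background = lines[:cfg.calibration_pulses].mean(axis=0)
        state = AOPState(baseline0, threshold, background)
        first_triggerable = cfg.calibration_pulses
    else:
        first_triggerable = 0

    baseline = np.empty(len(values))
    b = state.baseline
    alpha = cfg.ema_alpha
    for i, v in enumerate(values):
        baseline[i] = b
        if i < first_triggerable:
            continue
        if b - v >= state.threshold:  # triggered: freeze the baseline
            continue
        b += alpha * (v - b)
    out_state = AOPState(b, state.threshold, state.background)
    return AOPSeries(values, baseline, state.threshold, first_triggerable, out_state)


def _trigger_mask(aop: AOPSeries) -> np.ndarray:
    mask = (aop.baseline - aop.values) >= aop.threshold  # tie triggers
    mask[:aop.first_triggerable] = False
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, end) intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def detect_roi(aop: AOPSeries, cfg: TriggerConfig | None = None
               ) -> list[tuple[int, int]]:
    """Triggered pulse intervals: half-open, non-overlapping, in order.

    Maximal runs where the AOP dips at least ``threshold`` below the
    baseline, each extended by ``guard_pulses`` on both sides, then runs
    separated by at most ``merge_gap`` pulses merged.
    """
    cfg = cfg or TriggerConfig()
    runs = _runs(_trigger_mask(aop))
    n = len(aop)
    g = cfg.guard_pulses
    extended = [(max(s - g, 0), min(e + g, n)) for s, e in runs]
    merged: list[tuple[int, int]] = []
    for s, e in extended:
        if merged and s - merged[-1][1] <= cfg.merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def count_events_window(aop: AOPSeries, cfg: TriggerConfig) -> np.ndarray:
    """Event counts per fixed pulse window (dense-sample operation).

    Pulses are partitioned into consecutive windows of
    ``cfg.window_pulses``; each threshold-crossing run counts once, in
    the window where it starts.  A final short window is kept truncated.
    """
    if cfg.mode != "large_window":
        raise ValueError("count_events_window requires large_window mode")
    n = len(aop)
    w = cfg.window_pulses
    n_windows = max(int(np.ceil(n / w)), 1)
    counts = np.zeros(n_windows, dtype=np.int64)
    for s, _ in _runs(_trigger_mask(aop)):
        counts[s // w] += 1
    return counts


# ---------------------------------------------------------------------------
# stage 4: reduction

def reduce_line(line: np.ndarray, background: np.ndarray,
                gain_shift: int = 0) -> np.ndarray:
    """Background removal + 16→8-bit requantization (absorbance-positive).

    ``pixel' = clip(round((background - pixel) * 2**gain_shift / 256),
    0, 255)``: a cell appears bright on a zero background, saturation is
    clipping by contract.
    """
    diff = (np.asarray(background, dtype=float) - np.asarray(line, dtype=float))
    out = np.round(diff * (2 ** gain_shift) / 256.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def apply_skip(lines: np.ndarray, skip: int) -> np.ndarray:
    """Keep one line in ``skip`` (indices 0, skip, 2·skip, …).

    The phase resets at the start of each triggered interval, so the kept
    count is ``ceil(n / skip)``; ``skip=1`` is the identity.
    """
    if skip < 1:
        raise ValueError("skip must be at least 1")
    return np.asarray(lines)[::skip]


def default_n_seg(fov_flow_um: float, flow_speed: float, f_rep: float,
                  skip: int) -> int:
    """Rows per frame covering ``fov_flow_um`` of travel at this decimation."""
    return int(np.ceil(fov_flow_um * f_rep / (flow_speed * 1e6 * skip)))


def assemble_frames(lines: np.ndarray, n_seg: int, skip: int,
                    start_pulse: int, frame_index_start: int = 0,
                    extra_flags: frozenset[str] = frozenset()) -> list[CellFrame]:
    """Pack one ROI's decimated lines into fixed-row frames.

    Each frame has exactly ``n_seg`` rows; a short remainder is
    zero-padded (flag ``padded``), an ROI longer than one frame is split
    into consecutive frames (flag ``split``).
    """
    if n_seg < 1:
        raise ValueError("n_seg must be at least 1")
    lines = np.asarray(lines, dtype=np.uint8)
    if len(lines) == 0:
        return []
    n_frames = int(np.ceil(len(lines) / n_seg))
    frames: list[CellFrame] = []
    for j in range(n_frames):
        chunk = lines[j * n_seg:(j + 1) * n_seg]
        flags = set(extra_flags)
        if len(chunk) < n_seg:
            pad = np.zeros((n_seg - len(chunk), lines.shape[1]), dtype=np.uint8)
            chunk = np.vstack([chunk, pad])
            flags.add("padded")
        if n_frames > 1:
            flags.add("split")
        header = FrameHeader(frame_index=frame_index_start + j,
                             start_pulse=start_pulse + j * n_seg * skip,
                             skip=skip, flags=frozenset(flags))
        frames.append(CellFrame(chunk.copy(), header))
    return frames


# ---------------------------------------------------------------------------
# end-to-end composition

def process_stream(stream: SampleStream, cfg: TriggerConfig | None = None,
                   skip: int = 1, n_seg: int | None = None,
                   gain_shift: int = 0, fov_flow_um: float = 30.0,
                   granularity_k: float = 1.0, state: AOPState | None = None,
                   pulse_offset: int = 0, frame_index_start: int = 0
                   ) -> tuple[list[CellFrame], "object"]:
    """Full chain: AOP → trigger → reduce → skip → frame → tag header.

    Returns the cell frames and a :class:`~otstream.rates.RateReport`
    comparing the reduced byte rate against the raw digitizer rate.
    Chunked streaming: pass the previous chunk's ``aop.state`` as
    ``state`` plus the global ``pulse_offset`` / ``frame_index_start``;
    frames then match batch processing when chunk cuts fall between
    cells.
    """
    from . import morphology, rates  # local import: avoids a module cycle

    cfg = cfg or TriggerConfig()
    p = stream.params
    lines16 = form_lines(stream, cfg.pulse_amp_threshold)
    aop = compute_aop(stream, cfg, state=state, lines=lines16)
    background = aop.state.background
    if background is None:
        raise ValueError("no per-pixel background available (state lacks calibration)")

    if n_seg is None:
        if cfg.mode == "large_window":
            n_seg = int(np.ceil(cfg.window_pulses / skip))
        else:
            n_seg = default_n_seg(fov_flow_um, stream.flow_speed, p.f_rep, skip)

    geom = morphology.PixelGeometry(
        pitch_cross=p.fov_cross / p.window_px,
        pitch_flow=line_pitch(stream.flow_speed, p.f_rep, skip),
    )

    if cfg.mode == "large_window":
        rois = [(s, min(s + cfg.window_pulses, len(aop)))
                for s in range(aop.first_triggerable, len(aop), cfg.window_pulses)]
        extra = frozenset({"large_window"})
    else:
        rois = detect_roi(aop, cfg)
        extra = frozenset()

    frames: list[CellFrame] = []
    for s, e in rois:
        reduced = reduce_line(lines16[s:e], background, gain_shift)
        kept = apply_skip(reduced, skip)
        frames.extend(assemble_frames(kept, n_seg, skip,
                                      start_pulse=s + pulse_offset,
                                      frame_index_start=frame_index_start + len(frames),
                                      extra_flags=extra))
    for f in frames:
        morphology.tag_header(f, geom, k=granularity_k)

    duration = stream.duration_s
    reduced_bytes = len(frames) * (HEADER_BYTES + n_seg * p.window_px)
    report = rates.stream_report(
        raw_rate_bytes_s=p.f_s * 2.0,
        reduced_rate_bytes_s=reduced_bytes / duration if duration > 0 else 0.0,
        n_frames=len(frames), n_seg=n_seg, window_px=p.window_px,
        skip=skip, flow_speed=stream.flow_speed, f_rep=p.f_rep,
    )
    return frames, report
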