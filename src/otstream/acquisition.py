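"""Pulse-train digitizer model.

Each broadband laser pulse images one cross-flow line of the scene; the
stretched pulse is read out serially by a single detector and digitized.
This module converts a moving :class:`~otstream.phantom.Scene` into the
16-bit sample stream that the real-time pipeline consumes, reproducing
the pulse/clock geometry of the instrument: pulse repetition rate
``f_rep`` (default 80 MHz), sampling rate ``f_s`` (default 10.24 GS/s,
so 128 samples per pulse period), and a 64-sample imaging window
occupying at most half the period.

Spectral/dispersion physics is out of scope: the mapping from cross-flow
position to intra-window sample index is taken as linear, and blur within
the ~ns exposure of one pulse is handled analytically in
:mod:`otstream.rates`, not simulated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .phantom import Scene

__all__ = ["AcqParams", "SampleStream", "synthesize_stream", "line_pitch",
           "save_stream", "load_stream"]

U16_MAX = 2**16 - 1


@dataclass(frozen=True)
class AcqParams:
    """Acquisition geometry and digitizer settings.

    ``window_px`` pixels are cut from each pulse period starting at
    ``window_phase`` samples (host-set threshold position that exactly
    covers the pulse width); the duty cycle ``window_px * f_rep / f_s``
    may not exceed one half.
    """

    f_rep: float = 80.00e6        # pulses / s
    f_s: float = 10.24e9          # samples / s
    window_px: int = 64
    window_phase: int = 32        # window start sample within the period
    fov_cross: float = 30.0       # µm mapped onto window_px pixels
    bit_depth: int = 16
    clock_mode: Literal["synchronous", "asynchronous"] = "synchronous"
    offset_ppm: float = 0.0       # asynchronous sample-clock offset
    envelope: Literal["flat", "gaussian"] = "gaussian"
    envelope_fwhm_fraction: float = 0.9
    noise_sigma: float = 0.0      # counts on the 16-bit scale
    full_scale: int = 60000       # clear-background in-window level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_rep <= 0 or self.f_s <= 0:
            raise ValueError("f_rep and f_s must be positive")
        if self.window_px * self.f_rep / self.f_s > 0.5 + 1e-12:
            raise ValueError("duty cycle exceeds 1/2")
        if self.f_s / self.f_rep < 2 * self.window_px:
            raise ValueError("sampling rate too low for the window size")
        if self.full_scale > U16_MAX:
            raise ValueError("full_scale exceeds 16-bit range")

    @property
    def samples_per_period(self) -> int:
        """Nominal (synchronous) integer samples per pulse period."""
        return int(round(self.f_s / self.f_rep))

    @property
    def effective_f_s(self) -> float:
        if self.clock_mode == "asynchronous":
            return self.f_s * (1.0 + self.offset_ppm * 1e-6)
        return self.f_s

    def envelope_profile(self) -> np.ndarray:
        """Per-pixel window envelope, normalized to peak 1."""
        if self.envelope == "flat":
            return np.ones(self.window_px)
        x = (np.arange(self.window_px) + 0.5) / self.window_px - 0.5
        fwhm = self.envelope_fwhm_fraction
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        prof = np.exp(-0.5 * (x / sigma) ** 2)
        return prof / prof.max()


@dataclass
class SampleStream:
    """Digitized pulse train: 16-bit samples plus acquisition metadata."""

    samples: np.ndarray           # uint16
    params: AcqParams
    flow_speed: float             # m/s
    n_pulses: int
    window_offsets: np.ndarray    # per-pulse start sample of the window

    def validate(self) -> None:
        if self.samples.dtype != np.uint16:
            raise ValueError("samples must be uint16")
        if len(self.window_offsets) != self.n_pulses:
            raise ValueError("one window offset per pulse required")
        period = self.params.samples_per_period
        if self.params.clock_mode == "synchronous":
            if len(self.samples) != self.n_pulses * period:
                raise ValueError("synchronous stream length must be n_pulses * period")
        last_end = self.window_offsets[-1] + self.params.window_px if self.n_pulses else 0
        if last_end > len(self.samples):
            raise ValueError("final window overruns the stream")

    @property
    def duration_s(self) -> float:
        return self.n_pulses / self.params.f_rep

    def slice_pulses(self, start: int, end: int) -> "SampleStream":
        """Sub-stream covering pulses ``[start, end)`` (synchronous only)."""
        if self.params.clock_mode != "synchronous":
            raise ValueError("pulse slicing requires a synchronous clock")
        if not (0 <= start < end <= self.n_pulses):
            raise ValueError("pulse range out of bounds")
        period = self.params.samples_per_period
        sub = SampleStream(
            self.samples[start * period:end * period].copy(), self.params,
            self.flow_speed, end - start,
            self.window_offsets[start:end] - start * period)
        sub.validate()
        return sub


def line_pitch(flow_speed: float, f_rep: float, skip: int = 1) -> float:
    """Along-flow image row pitch in µm: ``flow_speed * skip / f_rep``.

    One pulse advances the sample by ``v / f_rep``; keeping one line in
    ``skip`` multiplies the pitch accordingly.
    """
    if flow_speed <= 0 or f_rep <= 0 or skip <= 0:
        raise ValueError("all arguments must be positive")
    return flow_speed * skip / f_rep * 1e6


def synthesize_stream(scene: Scene, flow_speed: float, params: AcqParams) -> SampleStream:
    """Digitize a scene flowing past the imaging line at ``flow_speed`` m/s.

    Pulse ``n`` samples the scene row nearest to flow position
    ``flow_speed * n / f_rep`` (nearest-row lookup, no interpolation).
    Within the 64-sample window, pixel ``i`` carries
    ``envelope(i) * transmittance`` at cross position
    ``(i + 0.5) / window_px * fov_cross``, scaled to ``full_scale``, with
    additive Gaussian noise, clipped and quantized to 16 bits.  Samples
    outside windows are noise only, near zero.
    """
    scene.validate()
    if flow_speed <= 0:
        raise ValueError("flow_speed must be positive")
    if scene.extent_cross + 1e-9 < params.fov_cross:
        raise ValueError("scene narrower than the cross-flow field of view")
    pitch_line = line_pitch(flow_speed, params.f_rep, 1)  # µm per pulse
    n_pulses = int(np.floor(scene.extent_flow / pitch_line))
    if n_pulses < 1:
        raise ValueError("scene shorter than one pulse period of travel")

    # nearest scene row per pulse (row i spans [i, i+1) * pitch)
    y_um = np.arange(n_pulses) * pitch_line
    rows = np.minimum((y_um / scene.pitch).astype(int), scene.grid.shape[0] - 1)
    # nearest scene column per window pixel (FOV centered on the scene)
    x_um = (np.arange(params.window_px) + 0.5) / params.window_px * params.fov_cross
    x_um += (scene.extent_cross - params.fov_cross) / 2.0
    cols = np.minimum((x_um / scene.pitch).astype(int), scene.grid.shape[1] - 1)

    envelope = params.envelope_profile()
    signal = scene.grid[np.ix_(rows, cols)] * envelope[None, :] * params.full_scale

    period = params.samples_per_period
    if params.clock_mode == "asynchronous":
        ratio = params.effective_f_s / params.f_rep
        offsets = (np.round(np.arange(n_pulses) * ratio).astype(np.int64)
                   + params.window_phase)
        n_samples = int(np.ceil(n_pulses * ratio)) + period
    else:
        offsets = np.arange(n_pulses, dtype=np.int64) * period + params.window_phase
        n_samples = n_pulses * period

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xACD]))
    if params.noise_sigma > 0:
        stream = rng.normal(0.0, params.noise_sigma, n_samples)
    else:
        stream = np.zeros(n_samples)
    idx = offsets[:, None] + np.arange(params.window_px)[None, :]
    stream[idx.ravel()] += signal.ravel()
    samples = np.clip(np.round(stream), 0, U16_MAX).astype(np.uint16)

    out = SampleStream(samples, params, flow_speed, n_pulses, offsets)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# raw binary persistence: little-endian uint16 payload + JSON sidecar

def save_stream(stream: SampleStream, path: str | Path) -> None:
    stream.validate()
    path = Path(path)
    stream.samples.astype("<u2").tofile(path)
    meta = {
        "params": asdict(stream.params),
        "flow_speed_m_s": stream.flow_speed,
        "n_pulses": stream.n_pulses,
        "window_offsets_start": int(stream.window_offsets[0]) if stream.n_pulses else 0,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_stream(path: str | Path) -> SampleStream:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    params = AcqParams(**meta["params"])
    samples = np.fromfile(path, dtype="<u2").astype(np.uint16)
    n_pulses = int(meta["n_pulses"])
    if params.clock_mode == "asynchronous":
        ratio = params.effective_f_s / params.f_rep
        offsets = (np.round(np.arange(n_pulses) * ratio).astype(np.int64)
                   + params.window_phase)
    else:
        offsets = (np.arange(n_pulses, dtype=np.int64) * params.samples_per_period
                   + params.window_phase)
    stream = SampleStream(samples, params, float(meta["flow_speed_m_s"]),
                          n_pulses, offsets)
    stream.validate()
    return stream
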