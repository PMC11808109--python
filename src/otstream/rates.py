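"""Closed-form throughput, data-rate, reduction and motion-blur accounting.

All byte rates use the binary convention: 1 MiB = 2^20 bytes.  This is
the unique convention under which the instrument's headline figures
(4888.3 MB/s for the full 80.09 MHz pulse stream at 64 px × 8 bit,
4000 MB/s for 40,960 fps × 1600 pulses × 64 px, and the 366–732 MB/s
single-cell detection band) are all reproduced simultaneously.

Two pulse-count conventions coexist deliberately: rate accounting uses
the exact (unrounded) pulses per image, while frame assembly uses the
ceiling — a segment cannot hold a fractional row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import math

__all__ = [
    "MIB", "RateReport",
    "pulses_per_image", "data_rate", "reduction_fold", "max_flow_speed",
    "motion_blur", "drp_budget", "stream_report",
]

MIB = 2 ** 20  # bytes
#: minimum data-reduction proportion for sustained host transfer
DRP_REQUIRED = 18.0 / 25.0
#: default optical resolution used for blur fractions (nm)
DEFAULT_RESOLUTION_NM = 780.0
#: sustained host-link ceiling, GB/s (rate contract, not emulated I/O)
HOST_LINK_CEILING_GB_S = 5.6


@dataclass
class RateReport:
    """Derived throughput quantities for one configuration or run."""

    pulses_per_image: int = 0
    mean_pulses_per_image: float = 0.0
    raw_rate_bytes_s: float = 0.0
    data_rate_mib_s: float = 0.0
    reduction_fold: float = 0.0
    drp: float = 0.0
    drp_sufficient: bool = False
    max_flow_speed_m_s: float = 0.0
    blur_nm: float = 0.0
    blur_fraction: float = 0.0
    n_frames: int = 0

    def validate(self) -> None:
        for name in ("pulses_per_image", "raw_rate_bytes_s", "data_rate_mib_s",
                     "reduction_fold", "blur_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.drp <= 1.0):
            raise ValueError("drp must lie in [0, 1]")


def pulses_per_image(fov_flow_um: float, flow_speed: float, f_rep: float,
                     skip: int = 1,
                     rounding: Literal["ceil", "exact"] = "ceil") -> float:
    """Pulses (image rows) spanning ``fov_flow_um`` of travel.

    ``N = fov * f_rep / (flow_speed * skip)``; ``ceil`` for per-segment
    accounting, ``exact`` for rate-based accounting.
    """
    if min(fov_flow_um, flow_speed, f_rep, skip) <= 0:
        raise ValueError("all arguments must be positive")
    n = fov_flow_um * 1e-6 * f_rep / (flow_speed * skip)
    return float(math.ceil(n)) if rounding == "ceil" else n


def data_rate(events_per_s: float, pulses_per_event: float, pixels: int,
              bytes_per_px: int) -> float:
    """Image byte rate in MiB/s: events × pulses × pixels × bytes / 2^20."""
    if min(events_per_s, pulses_per_event, pixels, bytes_per_px) < 0:
        raise ValueError("arguments must be non-negative")
    return events_per_s * pulses_per_event * pixels * bytes_per_px / MIB


def reduction_fold(f_s: float, raw_bytes_per_sample: int, events_per_s: float,
                   fov_flow_um: float, flow_speed: float, f_rep: float,
                   skip: int, pixels: int, bytes_per_px: int) -> int:
    """Raw-to-reduced data-rate fold, rounded to the nearest integer.

    Raw is the full digitizer output ``f_s * raw_bytes_per_sample``;
    reduced uses the exact (unrounded) pulses per image.
    """
    if events_per_s <= 0:
        raise ZeroDivisionError("zero event rate gives an infinite fold")
    raw = f_s * raw_bytes_per_sample
    pulses = pulses_per_image(fov_flow_um, flow_speed, f_rep, skip, "exact")
    reduced = events_per_s * pulses * pixels * bytes_per_px
    return int(round(raw / reduced))


def max_flow_speed(line_pitch_um: float, f_rep: float) -> float:
    """Fastest flow (m/s) at which consecutive lines still tile the object
    at the stated pitch: ``pitch * f_rep``."""
    if line_pitch_um <= 0 or f_rep <= 0:
        raise ValueError("arguments must be positive")
    return line_pitch_um * 1e-6 * f_rep


def motion_blur(flow_speed: float, exposure_s: float = 5.5e-9,
                resolution_nm: float = DEFAULT_RESOLUTION_NM
                ) -> tuple[float, float]:
    """In-pulse displacement (nm) and its fraction of the resolution.

    The stretched pulse illuminates the moving cell for ``exposure_s``
    (a few ns once the temporal disperser precedes the spatial one); the
    head-to-tail displacement is ``v * t``.
    """
    if flow_speed < 0 or exposure_s < 0:
        raise ValueError("arguments must be non-negative")
    blur_nm = flow_speed * exposure_s * 1e9
    return blur_nm, blur_nm / resolution_nm


def drp_budget(duty: float, trigger_occupancy: float, bit_fold: float,
               skip: int) -> tuple[float, bool]:
    """Total data-reduction proportion from the four redundancy parts.

    Retained fraction = duty (inter-pulse noise discarded) ×
    trigger occupancy (inter-cell pulses discarded) × bit fold (16→8 bit
    is 1/2) × 1/skip (adjoining-pulse decimation); DRP = 1 − retained.
    Returns ``(drp, drp > 18/25)`` — the flag marks whether the budget
    meets the sustained-transfer requirement.
    """
    for name, v in (("duty", duty), ("trigger_occupancy", trigger_occupancy),
                    ("bit_fold", bit_fold)):
        if not (0 < v <= 1):
            raise ValueError(f"{name} must lie in (0, 1]")
    if skip < 1:
        raise ValueError("skip must be at least 1")
    retained = duty * trigger_occupancy * bit_fold / skip
    drp = 1.0 - retained
    return drp, drp > DRP_REQUIRED


def stream_report(raw_rate_bytes_s: float, reduced_rate_bytes_s: float,
                  n_frames: int, n_seg: int, window_px: int, skip: int,
                  flow_speed: float, f_rep: float) -> RateReport:
    """Measured-rate report for one processed stream."""
    drp = 1.0 - reduced_rate_bytes_s / raw_rate_bytes_s if raw_rate_bytes_s else 0.0
    fold = raw_rate_bytes_s / reduced_rate_bytes_s if reduced_rate_bytes_s else math.inf
    report = RateReport(
        pulses_per_image=n_seg,
        mean_pulses_per_image=float(n_seg),
        raw_rate_bytes_s=raw_rate_bytes_s,
        data_rate_mib_s=reduced_rate_bytes_s / MIB,
        reduction_fold=fold,
        drp=drp,
        drp_sufficient=drp > DRP_REQUIRED,
        max_flow_speed_m_s=max_flow_speed(0.8, f_rep),
        n_frames=n_frames,
    )
    report.validate()
    return report
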