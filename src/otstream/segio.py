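"""Fixed-length segment format and buffered producer–consumer storage.

Every cell frame serializes to a constant-length binary segment — a
32-byte little-endian header (magic ``OTS1``, indices, skip factor,
geometry, flags, and the fixed-point morphometry tags) followed by the
``n_seg × window_px`` 8-bit payload.  Constant length is the storage
contract that lets segments be cut back out of large write buffers
without any framing scan.

``buffered_store`` reproduces the host-side caching architecture as a
correctness contract: one producer queues frames into a bounded buffer,
multiple consumer threads drain it FIFO and append to the store file.
No segment may be lost or duplicated under any interleaving (drops under
the ``drop`` overflow policy are counted, never silent); in-file order
is arbitrary and is restored by ``frame_index`` on read.  Sustained-rate
behaviour is handled analytically in :mod:`otstream.rates`, not here.
"""

from __future__ import annotations

import csv
import queue
import struct
import threading
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image

from .stream_pipeline import CellFrame, FrameHeader, HEADER_BYTES

__all__ = [
    "MAGIC", "HEADER_STRUCT", "SegmentFormatError", "StoreContract",
    "StoreReport", "segment_length", "write_segments", "read_segments",
    "buffered_store", "export_images",
]

MAGIC = b"OTS1"
#: little-endian: magic, frame_index u32, start_pulse u64, skip u16,
#: n_seg u16, window_px u16, flags u16, size_um_x100 u16,
#: granularity_x100 u16, opacity u32  — 32 bytes total
HEADER_STRUCT = struct.Struct("<4sIQHHHHHHI")
assert HEADER_STRUCT.size == HEADER_BYTES

_FLAG_BITS = {"padded": 1, "split": 2, "large_window": 4}


class SegmentFormatError(ValueError):
    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class StoreContract:
    buffer_capacity: int = 64          # segments queued at most
    n_consumers: int = 2
    overflow: Literal["block", "drop"] = "block"

    def __post_init__(self) -> None:
        if self.buffer_capacity < 1 or self.n_consumers < 1:
            raise ValueError("capacity and consumer count must be at least 1")


@dataclass
class StoreReport:
    produced: int
    stored: int
    dropped: int
    max_queue_depth: int


def segment_length(n_seg: int, window_px: int) -> int:
    return HEADER_BYTES + n_seg * window_px


def _encode(frame: CellFrame) -> bytes:
    h = frame.header
    n_seg, window_px = frame.image.shape
    flags = 0
    for name, bit in _FLAG_BITS.items():
        if name in h.flags:
            flags |= bit
    header = HEADER_STRUCT.pack(
        MAGIC, h.frame_index, h.start_pulse, h.skip, n_seg, window_px, flags,
        min(int(round(h.size_um * 100)), 0xFFFF),
        min(int(round(h.granularity * 100)), 0xFFFF),
        min(int(h.opacity), 0xFFFFFFFF),
    )
    return header + frame.image.astype(np.uint8).tobytes()


def _decode(buf: bytes, offset: int) -> tuple[CellFrame, int]:
    if len(buf) - offset < HEADER_BYTES:
        raise SegmentFormatError("truncated header", offset)
    (magic, frame_index, start_pulse, skip, n_seg, window_px, flags,
     size_x100, gran_x100, opac) = HEADER_STRUCT.unpack_from(buf, offset)
    if magic != MAGIC:
        raise SegmentFormatError("bad magic", offset)
    payload_len = n_seg * window_px
    end = offset + HEADER_BYTES + payload_len
    if end > len(buf):
        raise SegmentFormatError("truncated payload", offset)
    image = np.frombuffer(buf[offset + HEADER_BYTES:end],
                          dtype=np.uint8).reshape(n_seg, window_px).copy()
    names = frozenset(n for n, b in _FLAG_BITS.items() if flags & b)
    header = FrameHeader(frame_index, start_pulse, skip,
                         size_um=size_x100 / 100.0, opacity=opac,
                         granularity=gran_x100 / 100.0, flags=names)
    return CellFrame(image, header), end


def write_segments(frames: Sequence[CellFrame], path: str | Path) -> int:
    """Serialize frames to a constant-segment-length file; returns count."""
    shapes = {f.image.shape for f in frames}
    if len(shapes) > 1:
        raise SegmentFormatError(f"non-uniform frame dimensions {shapes}")
    with open(path, "wb") as fh:
        for f in frames:
            fh.write(_encode(f))
    return len(frames)


def read_segments(path: str | Path) -> list[CellFrame]:
    """Read a segment file back, ordered by ``frame_index``."""
    buf = Path(path).read_bytes()
    frames: list[CellFrame] = []
    offset = 0
    while offset < len(buf):
        frame, offset = _decode(buf, offset)
        frames.append(frame)
    seg_lens = {f.image.size + HEADER_BYTES for f in frames}
    if len(seg_lens) > 1:
        raise SegmentFormatError("segment length varies within file")
    frames.sort(key=lambda f: f.header.frame_index)
    return frames


def buffered_store(producer: Iterable[CellFrame], path: str | Path,
                   contract: StoreContract = StoreContract()) -> StoreReport:
    """Stream frames through a bounded queue into the store file.

    One producer feeds ``contract.n_consumers`` consumer threads through
    a FIFO queue of ``buffer_capacity`` segments.  ``block`` overflow
    back-pressures the producer; ``drop`` discards the newest frame and
    counts it.  The on-disk census always equals produced − dropped.
    """
    q: queue.Queue = queue.Queue(maxsize=contract.buffer_capacity)
    lock = threading.Lock()
    fh = open(path, "wb")
    stored = 0
    max_depth = 0
    stop = object()

    def consume() -> None:
        nonlocal stored
        while True:
            item = q.get()
            if item is stop:
                q.task_done()
                return
            data = _encode(item)
            with lock:
                fh.write(data)
                stored += 1
            q.task_done()

    threads = [threading.Thread(target=consume) for _ in range(contract.n_consumers)]
    for t in threads:
        t.start()

    produced = dropped = 0
    try:
        for frame in producer:
            produced += 1
            if contract.overflow == "block":
                q.put(frame)
            else:
                try:
                    q.put_nowait(frame)
                except queue.Full:
                    dropped += 1
            max_depth = max(max_depth, q.qsize())
    finally:
        for _ in threads:
            q.put(stop)
        for t in threads:
            t.join()
        fh.close()
    return StoreReport(produced, stored, dropped, max_depth)


def export_images(frames: Sequence[CellFrame], directory: str | Path) -> int:
    """One grayscale PNG per frame plus a CSV manifest of the headers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "file", "start_pulse", "skip",
                         "size_um", "opacity", "granularity", "flags"])
        for f in frames:
            name = f"frame_{f.header.frame_index:06d}.png"
            try:
                Image.fromarray(f.image, mode="L").save(directory / name)
            except OSError as exc:  # pragma: no cover - I/O failure path
                raise OSError(f"frame {f.header.frame_index}: {exc}") from exc
            writer.writerow([f.header.frame_index, name, f.header.start_pulse,
                             f.header.skip, f"{f.header.size_um:.2f}",
                             f.header.opacity, f"{f.header.granularity:.2f}",
                             "|".join(sorted(f.header.flags))])
    return len(frames)
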