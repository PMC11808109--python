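"""Synthetic transmittance phantoms.

The imaging line of a time-stretch flow cytometer reads one cross-flow
section of whatever passes the field of view per laser pulse.  This module
builds the 2-D transmittance scenes that stand in for the samples: single
cells, mixed populations strung out along the flow axis, and bar targets
for resolution checks.  A :class:`Scene` is a dimensionless transmittance
map (1.0 = clear background, 0.0 = fully opaque) on an isotropic grid,
with a ground-truth object list so that downstream recovery can be scored.

Conventions
-----------
* Row index = flow axis (first-acquired row first), column index =
  cross-flow axis.  All geometry in microns, half-open ``[0, extent)``.
* Cells absorb: transmittance inside a cell dips below 1.
* One integer seed per generator call; every stochastic draw derives from
  it through a counter-based split (``SeedSequence([seed, counter])``) so
  adding a draw never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ObjectTruth",
    "Scene",
    "SpeckleTexture",
    "make_cell",
    "make_population",
    "make_bar_target",
    "save_scene",
    "load_scene",
    "export_scene_png",
]

#: default cross-flow extent, matched to the instrument field of view (µm)
DEFAULT_EXTENT_CROSS = 30.0
#: hard cap on along-flow scene extent (µm) unless overridden
DEFAULT_MAX_EXTENT_FLOW = 1.0e5


@dataclass(frozen=True)
class ObjectTruth:
    """Ground truth for one object placed in a scene."""

    center: tuple[float, float]  # (flow_um, cross_um)
    diameter: float  # µm
    class_label: str = "cell"
    absorbance_peak: float = 0.5  # peak 1 - transmittance, in (0, 1]
    texture_seed: int = 0
    edge: bool = False  # object not fully inside the grid

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not (0 < self.absorbance_peak <= 1):
            raise ValueError("absorbance_peak must lie in (0, 1]")


@dataclass
class Scene:
    """2-D transmittance map plus ground truth.

    ``grid[row, col]`` is transmittance in [0, 1]; row = flow axis,
    col = cross-flow axis; ``pitch`` µm per grid cell, isotropic.
    """

    grid: np.ndarray
    pitch: float
    truth: list[ObjectTruth] = field(default_factory=list)

    @property
    def extent_flow(self) -> float:
        return self.grid.shape[0] * self.pitch

    @property
    def extent_cross(self) -> float:
        return self.grid.shape[1] * self.pitch

    def validate(self) -> None:
        if self.grid.ndim != 2:
            raise ValueError("scene grid must be 2-D")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("transmittance values must lie in [0, 1]")
        for obj in self.truth:
            r = obj.diameter / 2
            inside = (
                r <= obj.center[0] <= self.extent_flow - r
                and r <= obj.center[1] <= self.extent_cross - r
            )
            if not inside and not obj.edge:
                raise ValueError(f"object at {obj.center} leaves the grid but is not flagged edge")


@dataclass(frozen=True)
class SpeckleTexture:
    """Band-limited multiplicative texture inside the cell mask.

    grain_um sets the correlation length of the noise; contrast the
    relative modulation depth.  Gives the cells a nonzero granularity
    ground truth.
    """

    grain_um: float
    contrast: float


def _rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(counter)]))


def _radial_profile(r: np.ndarray, radius: float) -> np.ndarray:
    """Cosine-tapered disk: 1 out to 0.8 R, cosine down to 0 at R.

    The taper avoids hard-edge aliasing on the sampling grid; the sample
    images in this modality are smooth bright-field-like blobs.
    """
    core = radius * 0.8
    taper = radius - core
    p = np.zeros_like(r, dtype=float)
    p[r <= core] = 1.0
    band = (r > core) & (r <= radius)
    p[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - core) / taper))
    return p


def _speckle_field(shape: tuple[int, int], grain_um: float, contrast: float,
                   pitch: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma = max(grain_um / pitch, 1e-6) / 2.0  # grain ≈ 2 sigma of the smoothing kernel
    smooth = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return 1.0 + contrast * smooth


def _stamp_object(grid: np.ndarray, pitch: float, center: tuple[float, float],
                  diameter: float, absorbance_peak: float,
                  texture: SpeckleTexture | None, seed: int) -> None:
    """Multiply a cosine-tapered absorbing disk into the grid in place.

    Only the object's bounding box is touched, so stamping stays cheap on
    long population scenes.
    """
    radius = diameter / 2.0
    r0 = max(int((center[0] - radius) / pitch) - 1, 0)
    r1 = min(int((center[0] + radius) / pitch) + 2, grid.shape[0])
    c0 = max(int((center[1] - radius) / pitch) - 1, 0)
    c1 = min(int((center[1] + radius) / pitch) + 2, grid.shape[1])
    rows = (np.arange(r0, r1) + 0.5) * pitch
    cols = (np.arange(c0, c1) + 0.5) * pitch
    r = np.hypot(rows[:, None] - center[0], cols[None, :] - center[1])
    profile = _radial_profile(r, radius)
    absorb = absorbance_peak * profile
    if texture is not None:
        tex = _speckle_field(profile.shape, texture.grain_um, texture.contrast,
                             pitch, _rng(seed, 1))
        absorb = absorb * np.where(profile > 0, tex, 1.0)
    box = grid[r0:r1, c0:c1]
    np.clip(box * (1.0 - absorb), 0.0, 1.0, out=box)


def make_cell(diameter: float, absorbance_peak: float,
              texture: SpeckleTexture | None = None,
              pitch: float = 0.1, seed: int = 0,
              extent_cross: float = DEFAULT_EXTENT_CROSS,
              class_label: str = "cell") -> Scene:
    """One cell centered in a clear scene padded by ≥ diameter/2 on all sides.

    Transmittance inside the disk is ``1 - absorbance_peak * profile *
    texture``; ``absorbance_peak = 0`` leaves the background untouched.
    """
    if diameter <= 0 or pitch <= 0:
        raise ValueError("diameter and pitch must be positive")
    if diameter < 2 * pitch:
        raise ValueError("diameter must be at least 2 pitch")
    extent_flow = 2.0 * diameter  # ≥ diameter/2 clear padding on each side
    extent_cross = max(extent_cross, 2.0 * diameter)
    n_rows = int(np.ceil(extent_flow / pitch))
    n_cols = int(np.ceil(extent_cross / pitch))
    grid = np.ones((n_rows, n_cols))
    center = (n_rows * pitch / 2.0, n_cols * pitch / 2.0)
    if absorbance_peak > 0:
        _stamp_object(grid, pitch, center, diameter, absorbance_peak, texture, seed)
    truth = [ObjectTruth(center, diameter, class_label,
                         absorbance_peak if absorbance_peak > 0 else 1e-9, seed)]
    scene = Scene(grid, pitch, truth)
    scene.validate()
    return scene


SizeDist = (
    tuple[Literal["fixed"], float]
    | tuple[Literal["lognormal"], float, float]
    | tuple[Literal["two_class"], float, float, float]
)


def _draw_diameters(n: int, size_dist: SizeDist, rng: np.random.Generator
                    ) -> tuple[np.ndarray, list[str]]:
    kind = size_dist[0]
    if kind == "fixed":
        return np.full(n, float(size_dist[1])), ["cell"] * n
    if kind == "lognormal":
        _, mu, sigma = size_dist
        return rng.lognormal(mu, sigma, n), ["cell"] * n
    if kind == "two_class":
        _, d1, d2, frac1 = size_dist
        pick = rng.random(n) < frac1
        d = np.where(pick, d1, d2)
        labels = ["class1" if p else "class2" for p in pick]
        return d.astype(float), labels
    raise ValueError(f"unknown size distribution {kind!r}")


def make_population(n: int, size_dist: SizeDist, mean_gap_um: float,
                    pitch: float = 0.1, seed: int = 0,
                    absorbance_peak: float = 0.5,
                    texture: SpeckleTexture | None = None,
                    extent_cross: float = DEFAULT_EXTENT_CROSS,
                    lead_um: float | None = None,
                    min_gap_um: float = 0.0,
                    max_extent_flow: float = DEFAULT_MAX_EXTENT_FLOW) -> Scene:
    """``n`` objects strung along the flow axis with exponential gaps.

    Gaps between consecutive object edges are exponential with the stated
    mean; ``mean_gap_um = 0`` packs objects edge to edge and permits
    overlaps (flagged per object via the edge flag staying False — overlap
    only changes transmittance multiplicatively).  ``min_gap_um`` adds a
    hard-core exclusion (shifted exponential), emulating the
    hydrodynamically ordered, coincidence-free spacing of a sample diluted
    for single-cell imaging.  Truth is in flow order.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if mean_gap_um < 0 or min_gap_um < 0:
        raise ValueError("gap parameters must be non-negative")
    if min_gap_um > mean_gap_um > 0:
        raise ValueError("min_gap_um may not exceed mean_gap_um")
    rng = _rng(seed, 0)
    diameters, labels = _draw_diameters(n, size_dist, rng)
    if mean_gap_um > 0:
        gaps = min_gap_um + rng.exponential(mean_gap_um - min_gap_um, n)
    else:
        gaps = np.zeros(n)
    lead = max(diameters.max(), 2.0) if lead_um is None else lead_um
    centers_flow = []
    y = lead
    for d, g in zip(diameters, gaps):
        y += g + d / 2.0
        centers_flow.append(y)
        y += d / 2.0
    extent_flow = centers_flow[-1] + diameters[-1] / 2.0 + lead
    if extent_flow > max_extent_flow:
        raise ValueError(
            f"scene extent {extent_flow:.0f} µm exceeds cap {max_extent_flow:.0f} µm")
    extent_cross = max(extent_cross, diameters.max() * 1.5)
    n_rows = int(np.ceil(extent_flow / pitch))
    n_cols = int(np.ceil(extent_cross / pitch))
    grid = np.ones((n_rows, n_cols))
    cross_center = n_cols * pitch / 2.0
    truth: list[ObjectTruth] = []
    for i, (cy, d, label) in enumerate(zip(centers_flow, diameters, labels)):
        obj_seed = int(rng.integers(0, 2**31 - 1))
        _stamp_object(grid, pitch, (cy, cross_center), d, absorbance_peak,
                      texture, obj_seed)
        truth.append(ObjectTruth((cy, cross_center), float(d), label,
                                 absorbance_peak, obj_seed))
    scene = Scene(grid, pitch, truth)
    scene.validate()
    return scene


def make_bar_target(line_width: float, n_pairs: int,
                    orientation: Literal["cross", "flow"] = "cross",
                    pitch: float = 0.1,
                    extent_cross: float = DEFAULT_EXTENT_CROSS) -> Scene:
    """Alternating opaque/clear bars of equal width (resolution target).

    ``orientation="cross"`` lays bars across the flow axis (bars vary with
    the column index); ``"flow"`` varies them with the row index.  Duty is
    exactly 1/2 by construction.
    """
    if line_width < pitch:
        raise ValueError("line_width must be at least one pitch")
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    width_px = max(int(round(line_width / pitch)), 1)
    pattern = np.ones(2 * n_pairs * width_px)
    for k in range(n_pairs):
        pattern[2 * k * width_px:(2 * k + 1) * width_px] = 0.0
    pad = width_px  # one clear bar of padding each side
    pattern = np.concatenate([np.ones(pad), pattern, np.ones(pad)])
    if orientation == "cross":
        n_cols = max(len(pattern), int(np.ceil(extent_cross / pitch)))
        grid = np.ones((len(pattern), n_cols))
        offset = (n_cols - len(pattern)) // 2
        grid[:, offset:offset + len(pattern)] = pattern[None, :]
    elif orientation == "flow":
        n_cols = int(np.ceil(extent_cross / pitch))
        grid = np.tile(pattern[:, None], (1, n_cols))
    else:
        raise ValueError("orientation must be 'cross' or 'flow'")
    center = (grid.shape[0] * pitch / 2.0, grid.shape[1] * pitch / 2.0)
    truth = [ObjectTruth(center, line_width, "bar_target", 1.0, 0, edge=True)]
    scene = Scene(grid, pitch, truth)
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# persistence

def save_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene to HDF5: grid dataset, pitch/extent attrs, truth table."""
    scene.validate()
    with h5py.File(path, "w") as f:
        d = f.create_dataset("grid", data=scene.grid)
        d.attrs["pitch_um"] = scene.pitch
        d.attrs["extent_flow_um"] = scene.extent_flow
        d.attrs["extent_cross_um"] = scene.extent_cross
        t = f.create_group("truth")
        t.create_dataset("center_flow_um", data=[o.center[0] for o in scene.truth])
        t.create_dataset("center_cross_um", data=[o.center[1] for o in scene.truth])
        t.create_dataset("diameter_um", data=[o.diameter for o in scene.truth])
        t.create_dataset("absorbance_peak", data=[o.absorbance_peak for o in scene.truth])
        t.create_dataset("texture_seed", data=[o.texture_seed for o in scene.truth])
        t.create_dataset("edge", data=[o.edge for o in scene.truth])
        t.create_dataset("class_label",
                         data=np.array([o.class_label for o in scene.truth], dtype="S32"))


def load_scene(path: str | Path) -> Scene:
    with h5py.File(path, "r") as f:
        grid = f["grid"][...]
        pitch = float(f["grid"].attrs["pitch_um"])
        t = f["truth"]
        truth = [
            ObjectTruth(
                (float(cy), float(cx)), float(d), label.decode(),
                float(a), int(s), bool(e))
            for cy, cx, d, label, a, s, e in zip(
                t["center_flow_um"][...], t["center_cross_um"][...],
                t["diameter_um"][...], t["class_label"][...],
                t["absorbance_peak"][...], t["texture_seed"][...],
                t["edge"][...])
        ]
    scene = Scene(grid, pitch, truth)
    scene.validate()
    return scene


def export_scene_png(scene: Scene, path: str | Path) -> None:
    """8-bit grayscale preview (255 = clear background)."""
    img = np.round(scene.grid * 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
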