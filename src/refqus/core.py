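"""Core data types: RF frames, tumor ROI polygons, and the analysis block grid.

Coordinate conventions
----------------------
- ``samples[i, j]`` is the RF sample at axial index ``i`` (0 = transducer
  face) and scan line ``j``.
- A pixel's physical position is ``(lateral = j · lateral_pitch,
  axial = i · axial_pitch)`` in mm.
- Depths used in attenuation formulas (``z``, ``z_i``, ``z_m``) are in cm,
  measured from the transducer face; ``z = z_i + z_m`` always holds, where
  ``z_i`` is the depth of the tissue–tumor interface above the block and
  ``z_m`` the path inside the tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .constants import ASSUMED_SOUND_SPEED_M_S

__all__ = [
    "RFFrame",
    "ROIPolygon",
    "Block",
    "BlockGrid",
    "rasterize_roi",
    "build_block_grid",
]


@dataclass
class RFFrame:
    """One beamformed RF frame: an axial × lateral sample grid plus geometry.

    ``axial_pitch_mm`` must be consistent (within 1 %) with the sampling
    rate and the assumed imaging sound speed, axial_pitch = c / (2 fs).
    """

    samples: np.ndarray
    profile: object | None = None  # TransducerProfile; kept loose to avoid cycles
    axial_pitch_mm: float = 0.0
    lateral_pitch_mm: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (axial × lateral)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.profile is not None:
            if not self.axial_pitch_mm:
                self.axial_pitch_mm = self.profile.axial_pitch_mm
            if not self.lateral_pitch_mm:
                self.lateral_pitch_mm = self.profile.lateral_pitch_mm
        if self.axial_pitch_mm <= 0 or self.lateral_pitch_mm <= 0:
            raise ValueError("pitches must be positive")
        if self.profile is not None:
            fs_hz = self.profile.sampling_rate_mhz * 1e6
            expected_mm = ASSUMED_SOUND_SPEED_M_S / (2.0 * fs_hz) * 1e3
            if abs(self.axial_pitch_mm - expected_mm) / expected_mm > 0.01:
                raise ValueError(
                    "axial pitch %.5f mm inconsistent with c/(2 fs) = %.5f mm"
                    % (self.axial_pitch_mm, expected_mm)
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def depth_mm(self) -> float:
        return self.n_samples * self.axial_pitch_mm

    @property
    def width_mm(self) -> float:
        return self.n_lines * self.lateral_pitch_mm

    @property
    def sampling_rate_mhz(self) -> float:
        if self.profile is not None:
            return self.profile.sampling_rate_mhz
        return ASSUMED_SOUND_SPEED_M_S / (2.0 * self.axial_pitch_mm * 1e-3) / 1e6


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass
class ROIPolygon:
    """Polygonal tumor region of interest in frame coordinates (mm).

    Vertices are ordered ``(lateral_mm, axial_mm)`` pairs.  The polygon
    must be simple (non-self-intersecting) and have at least 3 vertices.
    """

    vertices: Sequence[tuple[float, float]]
    frame_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI polygon needs at least 3 (lateral, axial) vertices")
        n = v.shape[0]
        for i in range(n):
            a1, a2 = v[i], v[(i + 1) % n]
            for j in range(i + 1, n):
                if j == i or (j + 1) % n == i or (i + 1) % n == j:
                    continue  # adjacent edges share a vertex
                b1, b2 = v[j], v[(j + 1) % n]
                if _segments_intersect(a1, a2, b1, b2):
                    raise ValueError("ROI polygon is self-intersecting")
        self.vertices = v

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        v = np.asarray(self.vertices)
        return v[:, 0].min(), v[:, 0].max(), v[:, 1].min(), v[:, 1].max()


def rasterize_roi(roi: ROIPolygon, frame: RFFrame) -> np.ndarray:
    """Boolean mask (axial × lateral) of pixels whose centers lie in the ROI.

    A pixel center is ``(j · lateral_pitch, i · axial_pitch)`` mm; the
    inside test is the even-odd rule (equivalent to winding for the
    simple polygons :class:`ROIPolygon` enforces).
    """
    n_ax, n_lat = frame.samples.shape
    # an open Path is implicitly closed by the containment test
    path = MplPath(np.asarray(roi.vertices))
    xmin, xmax, zmin, zmax = roi.bounds
    # restrict the point-in-polygon test to the bounding box
    j0 = max(0, int(np.floor(xmin / frame.lateral_pitch_mm)))
    j1 = min(n_lat, int(np.ceil(xmax / frame.lateral_pitch_mm)) + 1)
    i0 = max(0, int(np.floor(zmin / frame.axial_pitch_mm)))
    i1 = min(n_ax, int(np.ceil(zmax / frame.axial_pitch_mm)) + 1)
    mask = np.zeros((n_ax, n_lat), dtype=bool)
    if j0 >= j1 or i0 >= i1:
        raise ValueError("ROI polygon lies outside the frame (empty mask)")
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    pts = np.column_stack(
        [jj.ravel() * frame.lateral_pitch_mm, ii.ravel() * frame.axial_pitch_mm]
    )
    inside = path.contains_points(pts).reshape(ii.shape)
    mask[i0:i1, j0:j1] = inside
    if not mask.any():
        raise ValueError("ROI polygon contains no pixel centers (empty mask)")
    return mask


@dataclass
class Block:
    """One 2 mm analysis window retained inside the ROI."""

    axial_start: int
    lateral_start: int
    n_axial: int
    n_lateral: int
    z_cm: float  # depth of block center from the transducer face
    zi_cm: float  # depth of the tissue–tumor interface above the block
    zm_cm: float  # path inside the tumor; z = z_i + z_m exactly
    inside_fraction: float


@dataclass
class BlockGrid:
    """Overlapping square analysis windows inside a rasterized ROI."""

    blocks: list[Block]
    block_size_mm: float
    overlap_fraction: float
    n_axial: int  # block extent in samples
    n_lateral: int  # block extent in lines
    step_axial: int
    step_lateral: int
    empty: bool = False  # ROI smaller than one block (warning, not an error)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def build_block_grid(
    mask: np.ndarray,
    frame: RFFrame,
    block_size_mm: float = 2.0,
    overlap: float = 0.94,
    inclusion: float = 0.7,
) -> BlockGrid:
    """Decompose a rasterized ROI into overlapping square data blocks.

    Block pixel dimensions are ``round(block_size / pitch)`` per axis and
    the step between block origins is ``max(1, round((1 − overlap) ·
    block_pixels))``; a block is retained iff at least ``inclusion`` of
    its pixels lie inside the ROI mask.  Depths: ``z`` is measured to the
    block center; ``z_i`` is the mean over the block's lateral columns of
    the depth of the shallowest ROI pixel in each column; ``z_m = z − z_i``.

    Deterministic: no randomness is involved.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.samples.shape:
        raise ValueError("mask shape must equal frame shape")
    if not mask.any():
        raise ValueError("mask is empty")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    b_ax = max(1, round(block_size_mm / frame.axial_pitch_mm))
    b_lat = max(1, round(block_size_mm / frame.lateral_pitch_mm))
    step_ax = max(1, round((1.0 - overlap) * b_ax))
    step_lat = max(1, round((1.0 - overlap) * b_lat))

    n_ax, n_lat = mask.shape
    # per-column depth (cm) of the shallowest ROI pixel
    has_roi = mask.any(axis=0)
    first_idx = np.where(has_roi, mask.argmax(axis=0), -1)
    col_zi_cm = np.where(has_roi, first_idx * frame.axial_pitch_mm / 10.0, np.nan)

    blocks: list[Block] = []
    if b_ax <= n_ax and b_lat <= n_lat:
        col_counts = np.cumsum(mask, axis=0)  # cumulative ROI pixels per column
        for s in range(0, n_ax - b_ax + 1, step_ax):
            rows = col_counts[s + b_ax - 1] - (col_counts[s - 1] if s > 0 else 0)
            for t in range(0, n_lat - b_lat + 1, step_lat):
                frac = rows[t : t + b_lat].sum() / (b_ax * b_lat)
                if frac < inclusion:
                    continue
                z_cm = (s + b_ax / 2.0) * frame.axial_pitch_mm / 10.0
                zi_cols = col_zi_cm[t : t + b_lat]
                zi_cols = zi_cols[np.isfinite(zi_cols)]
                zi_cm = float(zi_cols.mean()) if zi_cols.size else z_cm
                blocks.append(
                    Block(
                        axial_start=s,
                        lateral_start=t,
                        n_axial=b_ax,
                        n_lateral=b_lat,
                        z_cm=z_cm,
                        zi_cm=zi_cm,
                        zm_cm=z_cm - zi_cm,
                        inside_fraction=float(frac),
                    )
                )
    empty = len(blocks) == 0
    if empty:
        warnings.warn("ROI smaller than one analysis block: empty block grid")
    return BlockGrid(
        blocks=blocks,
        block_size_mm=block_size_mm,
        overlap_fraction=overlap,
        n_axial=b_ax,
        n_lateral=b_lat,
        step_axial=step_ax,
        step_lateral=step_lat,
        empty=empty,
    )
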