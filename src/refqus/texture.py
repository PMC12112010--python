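"""Parametric maps and gray-level co-occurrence texture features.

For each of the five primary features (MBF, SS, SI, ASD, AAC) a per-pixel
parametric map is built by averaging the estimates of all overlapping
analysis blocks covering that pixel.  Each map is min–max quantized to
``n_levels`` gray levels and 16 co-occurrence matrices are computed (four
angles 0°, 45°, 90°, 135° × four distances 1–4 pixels, symmetric and
normalized).  Contrast, correlation, homogeneity and energy are averaged
over the 16 matrices, giving 4 texture features per map — 20 in total.

The GLCM is implemented here (rather than delegated) because pixels
outside the valid mask carry a sentinel level and must never be paired;
off-the-shelf co-occurrence routines have no notion of invalid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ParametricMap",
    "GLCMSpec",
    "INVALID_LEVEL",
    "build_parametric_map",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_of_map",
    "aggregate_texture",
    "TEXTURE_NAMES",
]

#: Sentinel gray level for pixels outside the valid mask.
INVALID_LEVEL = -1

TEXTURE_NAMES = ("con", "cor", "hom", "ene")

#: (row, col) offsets with row = axial; distance d multiplies the unit offset.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class ParametricMap:
    """Per-pixel map of one QUS feature on the frame pixel grid."""

    values: np.ndarray
    valid_mask: np.ndarray
    name: str = ""
    empty: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not self.empty and self.valid_mask.any():
            if not np.all(np.isfinite(self.values[self.valid_mask])):
                raise ValueError("map values must be finite on the valid mask")


@dataclass(frozen=True)
class GLCMSpec:
    """Configuration of the co-occurrence analysis."""

    n_levels: int = 16
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    distances: tuple[int, ...] = (1, 2, 3, 4)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if any(a not in _ANGLE_OFFSETS for a in self.angles_deg):
            raise ValueError("angles must be among 0, 45, 90, 135 degrees")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive")


def build_parametric_map(
    values: Iterable[float], blocks, shape: tuple[int, int], name: str = ""
) -> ParametricMap:
    """Average overlapping block estimates at each pixel position.

    ``blocks`` is an iterable of objects with ``axial_start``,
    ``lateral_start``, ``n_axial``, ``n_lateral`` (e.g.
    :class:`~refqus.core.Block`); ``values`` the corresponding feature
    values.  Pixels covered by no block are invalid.
    """
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    n_blocks = 0
    for v, b in zip(values, blocks):
        total[
            b.axial_start : b.axial_start + b.n_axial,
            b.lateral_start : b.lateral_start + b.n_lateral,
        ] += v
        count[
            b.axial_start : b.axial_start + b.n_axial,
            b.lateral_start : b.lateral_start + b.n_lateral,
        ] += 1
        n_blocks += 1
    valid = count > 0
    out = np.zeros(shape)
    np.divide(total, count, out=out, where=valid)
    return ParametricMap(out, valid, name=name, empty=(n_blocks == 0))


def quantize_map(pmap: ParametricMap, n_levels: int = 16) -> np.ndarray:
    """Uniform min–max quantization of the valid pixels to integer levels.

    Returns an integer grid with levels in [0, n_levels) on valid pixels
    and :data:`INVALID_LEVEL` elsewhere.  A constant map maps to level 0.
    Because binning is min–max based, the result is invariant to affine
    rescaling (with positive gain) of the map values.
    """
    if not pmap.valid_mask.any():
        raise ValueError("map has no valid pixels")
    v = pmap.values
    lo = v[pmap.valid_mask].min()
    hi = v[pmap.valid_mask].max()
    levels = np.full(v.shape, INVALID_LEVEL, dtype=int)
    if hi == lo:
        levels[pmap.valid_mask] = 0
        return levels
    q = np.floor((v - lo) / (hi - lo) * n_levels).astype(int)
    np.clip(q, 0, n_levels - 1, out=q)
    levels[pmap.valid_mask] = q[pmap.valid_mask]
    return levels


def compute_glcm(
    levels: np.ndarray,
    angle_deg: int,
    distance: int,
    spec: GLCMSpec | None = None,
) -> np.ndarray | None:
    """Normalized (symmetric) co-occurrence matrix at one offset.

    Pairs ``(p, p + offset)`` are counted where both pixels are valid;
    with ``symmetric`` both orderings are accumulated.  The matrix is
    divided by the number of counted pairs so it sums to one and equals
    its transpose.  Returns ``None`` when no valid pair exists at the
    offset (the caller excludes such matrices from averaging).
    """
    spec = spec or GLCMSpec()
    levels = np.asarray(levels)
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    n_r, n_c = levels.shape
    r0, r1 = max(0, -dr), min(n_r, n_r - dr)
    c0, c1 = max(0, -dc), min(n_c, n_c - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = (a != INVALID_LEVEL) & (b != INVALID_LEVEL)
    if not ok.any():
        return None
    i, j = a[ok].ravel(), b[ok].ravel()
    n = spec.n_levels
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    if spec.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> tuple[float, float, float, float]:
    """Contrast, correlation, homogeneity and energy of a normalized GLCM.

    CON = Σ P(i,j)(i−j)²; COR = Σ P(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ);
    HOM = Σ P(i,j)/(1+|i−j|); ENE = Σ P(i,j)².  Correlation is undefined
    (NaN) when either marginal standard deviation vanishes.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    con = float((P * (i - j) ** 2).sum())
    hom = float((P / (1.0 + np.abs(i - j))).sum())
    ene = float((P**2).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        cor = float("nan")
    else:
        cor = float(
            (P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j)
        )
    return con, cor, hom, ene


def texture_of_map(
    pmap: ParametricMap, spec: GLCMSpec | None = None
) -> dict[str, float]:
    """Mean of the four GLCM features over the 16 offset configurations.

    Matrices with no valid pairs, and undefined correlations, are
    excluded from (rather than zero-filled into) the average.
    """
    spec = spec or GLCMSpec()
    if pmap.empty or not pmap.valid_mask.any():
        return {t: float("nan") for t in TEXTURE_NAMES}
    levels = quantize_map(pmap, spec.n_levels)
    feats: dict[str, list[float]] = {t: [] for t in TEXTURE_NAMES}
    for ang in spec.angles_deg:
        for d in spec.distances:
            P = compute_glcm(levels, ang, d, spec)
            if P is None:
                continue
            con, cor, hom, ene = glcm_features(P)
            feats["con"].append(con)
            feats["hom"].append(hom)
            feats["ene"].append(ene)
            if np.isfinite(cor):
                feats["cor"].append(cor)
    return {
        t: (float(np.mean(v)) if v else float("nan")) for t, v in feats.items()
    }


def aggregate_texture(
    maps: Mapping[str, ParametricMap], spec: GLCMSpec | None = None
) -> dict[str, float]:
    """Texture features for a set of parametric maps.

    Returns ``{map}-{feature}`` keys (e.g. ``MBF-con``); a fully invalid
    map contributes NaNs for its four features.
    """
    out: dict[str, float] = {}
    for name, pmap in maps.items():
        tex = texture_of_map(pmap, spec)
        for t in TEXTURE_NAMES:
            out[f"{name}-{t}"] = tex[t]
    return out
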