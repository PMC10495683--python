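"""Hematoxylin/AEC colour deconvolution in optical-density space.

Chromogenic stains absorb light multiplicatively, so their contributions
combine (approximately) linearly in optical density, ``OD = -log10(I/I0)``
(Beer-Lambert). Each stain is characterised by a unit 3-vector giving its
relative absorbance in R, G and B; stacking the hematoxylin vector, the AEC
vector and an orthogonal "residual" completion gives an invertible 3x3 stain
matrix M. A pixel's OD row-vector then decomposes as ``od = c @ M`` with
``c`` the per-stain concentrations, recovered by ``c = od @ inv(M)``.

The module exposes both a whole-image path and a tiled path; unmixing is
strictly pixel-wise, so the tiled path is bit-identical to the whole-image
path while touching only one tile of the source at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HEMATOXYLIN_RGB_OD",
    "AEC_RGB_OD",
    "StainMatrix",
    "ConcentrationMaps",
    "default_stain_matrix",
    "estimate_background",
    "rgb_to_od",
    "od_to_rgb",
    "complete_stain_matrix",
    "unmix",
    "unmix_tiled",
]

#: Published colour-deconvolution absorbance directions (Ruifrok & Johnston
#: lineage), normalised at load.  Overridable wherever a stain matrix is taken.
HEMATOXYLIN_RGB_OD = (0.650, 0.704, 0.286)
AEC_RGB_OD = (0.274, 0.679, 0.680)

_MIN_ANGLE_DEG = 1.0
_MAX_CONDITION = 1e6


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (3,):
        raise ValueError(f"{name} stain vector must have 3 components, got {v.shape}")
    n = float(np.linalg.norm(v))
    if n == 0.0 or not np.isfinite(n):
        raise ValueError(f"{name} stain vector has zero or non-finite norm")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Ordered unit-norm stain basis: hematoxylin, AEC, residual.

    The residual row is the normalised cross product of the first two, so the
    matrix is invertible by construction whenever the chromogen vectors are
    not (near-)parallel.
    """

    hematoxylin: np.ndarray
    aec: np.ndarray
    residual: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "aec", "residual")

    @property
    def matrix(self) -> np.ndarray:
        """Rows are stain OD directions; shape (3, 3)."""
        return np.stack([self.hematoxylin, self.aec, self.residual])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-9):
            raise ValueError("stain matrix rows must be unit-norm")
        if self.condition_number >= _MAX_CONDITION:
            raise ValueError(
                f"stain matrix is ill-conditioned (cond={self.condition_number:.3g})"
            )


def complete_stain_matrix(hema, aec, names=("hematoxylin", "aec", "residual")) -> StainMatrix:
    """Build a full stain matrix from the two chromogen vectors.

    The third row is the normalised cross product of hematoxylin and AEC.
    Raises ``ValueError`` when the two vectors are parallel within 1 degree.
    """
    h = _unit(hema, "hematoxylin")
    a = _unit(aec, "aec")
    cosang = float(np.clip(np.dot(h, a), -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) < _MIN_ANGLE_DEG:
        raise ValueError("stain vectors are (near-)parallel; matrix would be degenerate")
    r = np.cross(h, a)
    r = r / np.linalg.norm(r)
    sm = StainMatrix(h, a, r, tuple(names))
    sm.validate()
    return sm


def default_stain_matrix() -> StainMatrix:
    return complete_stain_matrix(HEMATOXYLIN_RGB_OD, AEC_RGB_OD)


@dataclass
class ConcentrationMaps:
    """Per-stain concentration fields (OD units along each stain direction).

    ``clipped_fraction`` is the fraction of pixel-stain entries whose raw
    solution was negative and was clipped to zero; it is reported rather
    than silently discarded so QC can flag a mismatched stain basis.
    """

    hematoxylin: np.ndarray
    aec: np.ndarray
    residual: np.ndarray
    clipped_fraction: float = 0.0
    names: tuple[str, str, str] = ("hematoxylin", "aec", "residual")

    def __post_init__(self):
        shapes = {self.hematoxylin.shape, self.aec.shape, self.residual.shape}
        if len(shapes) != 1:
            raise ValueError("concentration maps must share one shape")

    @property
    def stacked(self) -> np.ndarray:
        """(3, H, W) array in basis order."""
        return np.stack([self.hematoxylin, self.aec, self.residual])

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return (self.hematoxylin, self.aec, self.residual)[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None


def _check_rgb(img) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    return img


def estimate_background(img, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background white point at the given intensity percentile.

    Brightfield background is the brightest broad population in the image;
    the 99th percentile is robust against specular / saturated pixels.
    Values are floored at 1 so the Beer-Lambert log stays finite.
    """
    img = _check_rgb(img)
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must be in (0, 100]")
    i0 = np.percentile(img.reshape(-1, 3).astype(np.float64), percentile, axis=0)
    return np.maximum(i0, 1.0)


def rgb_to_od(img, bg=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert 8-bit RGB to optical density: ``OD_c = -log10(max(I_c,1)/I0_c)``.

    Intensities above the background give negative OD and are clamped to 0;
    zeros are floored to 1 (max OD ~2.41 against a 255 background).
    """
    img = _check_rgb(img)
    bg = np.asarray(bg, dtype=np.float64).reshape(3)
    if np.any(bg <= 0):
        raise ValueError("background intensities must be > 0")
    i = np.maximum(img.astype(np.float64), 1.0)
    od = -np.log10(i / bg)
    return np.maximum(od, 0.0)


def od_to_rgb(od, bg=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Inverse Beer-Lambert: ``I_c = round(I0_c * 10**(-OD_c))``, uint8."""
    od = np.asarray(od, dtype=np.float64)
    if not np.all(np.isfinite(od)):
        raise ValueError("optical densities must be finite")
    bg = np.asarray(bg, dtype=np.float64).reshape(3)
    i = np.rint(bg * np.power(10.0, -od))
    return np.clip(i, 0, 255).astype(np.uint8)


def unmix(od, M: StainMatrix) -> ConcentrationMaps:
    """Solve ``od = c @ M.matrix`` per pixel and clip negative concentrations.

    ``od`` is (H, W, 3); the return carries one (H, W) map per basis stain
    plus the clipped-entry fraction.
    """
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 OD image, got shape {od.shape}")
    M.validate()
    raw = od @ M.inverse  # (H, W, 3) concentrations, stain order = basis order
    clipped = float(np.mean(raw < -1e-12))
    c = np.maximum(raw, 0.0)
    return ConcentrationMaps(
        c[..., 0].copy(), c[..., 1].copy(), c[..., 2].copy(),
        clipped_fraction=clipped, names=M.names,
    )


def unmix_tiled(source, M: StainMatrix, bg=(255.0, 255.0, 255.0), tile: int = 1024) -> ConcentrationMaps:
    """Tile-streamed ``rgb_to_od`` + ``unmix``, bit-identical to the whole-image path.

    ``source`` is anything indexable as ``source[y0:y1, x0:x1]`` returning an
    RGB block (an ndarray, a memory-mapped TIFF page, a zarr array...). Only
    one ``tile x tile`` block of the source is materialised at a time; the
    three full-size float64 output planes are the only whole-image buffers.
    """
    if tile < 1:
        raise ValueError("tile size must be >= 1")
    h, w = source.shape[0], source.shape[1]
    M.validate()
    minv = M.inverse
    out = np.empty((h, w, 3), dtype=np.float64)
    n_clipped = 0
    for y0 in range(0, h, tile):
        for x0 in range(0, w, tile):
            block = np.asarray(source[y0:y0 + tile, x0:x0 + tile])
            od = rgb_to_od(block, bg)
            raw = od @ minv
            n_clipped += int(np.count_nonzero(raw < -1e-12))
            out[y0:y0 + tile, x0:x0 + tile] = np.maximum(raw, 0.0)
    return ConcentrationMaps(
        out[..., 0].copy(), out[..., 1].copy(), out[..., 2].copy(),
        clipped_fraction=n_clipped / out.size, names=M.names,
    )
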