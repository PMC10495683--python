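"""Affine registration from manually paired control points.

Sequential chromogenic rounds image the same physical section after repeated
coverslipping, so rounds differ by a near-rigid 2-D transform. A handful of
manually clicked landmark pairs per round (moving -> reference) is enough to
fit the six affine parameters by least squares; the residual RMSE over the
pairs is the per-round alignment QC.

Coordinates are (x, y) pixel positions: 0-based, origin at the top-left
corner, x rightward (columns), y downward (rows).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

__all__ = [
    "ControlPointSet",
    "AffineTransform2D",
    "RegistrationReport",
    "estimate_affine",
    "transform_points",
    "invert",
    "compose",
    "residual_report",
    "warp_image",
]

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-6  # px^2, twice the max triangle area over point triples
_SUSPICIOUS_RESIDUAL_PX = 5.0


def _spread_area(pts: np.ndarray) -> float:
    """Twice the largest triangle area formed with the first point as apex."""
    d = pts - pts[0]
    cross = d[:, None, 0] * d[None, :, 1] - d[:, None, 1] * d[None, :, 0]
    return float(np.max(np.abs(cross)))


@dataclass(frozen=True)
class ControlPointSet:
    """Paired landmark coordinates, ``moving[i] <-> reference[i]``, (n, 2) float."""

    moving: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        mov = np.atleast_2d(np.asarray(self.moving, dtype=np.float64))
        ref = np.atleast_2d(np.asarray(self.reference, dtype=np.float64))
        object.__setattr__(self, "moving", mov)
        object.__setattr__(self, "reference", ref)
        if mov.shape != ref.shape or mov.ndim != 2 or mov.shape[1] != 2:
            raise ValueError("moving and reference must be matching (n, 2) arrays")
        if len(mov) < 3:
            raise ValueError(f"need >= 3 control point pairs, got {len(mov)}")
        if _spread_area(mov) <= _COLLINEAR_TOL:
            raise ValueError("moving control points are collinear; affine is underdetermined")

    def __len__(self) -> int:
        return len(self.moving)

    @classmethod
    def from_pairs(cls, pairs) -> "ControlPointSet":
        """From ``[((x_mov, y_mov), (x_ref, y_ref)), ...]``."""
        pairs = list(pairs)
        return cls(np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))

    @classmethod
    def read_csv(cls, path) -> "ControlPointSet":
        """Plain-text table, header + comma-separated x_mov,y_mov,x_ref,y_ref."""
        tbl = np.genfromtxt(path, delimiter=",", names=True, dtype=np.float64)
        tbl = np.atleast_1d(tbl)
        try:
            mov = np.column_stack([tbl["x_mov"], tbl["y_mov"]])
            ref = np.column_stack([tbl["x_ref"], tbl["y_ref"]])
        except (KeyError, ValueError) as e:
            raise ValueError(
                f"{path}: expected columns x_mov,y_mov,x_ref,y_ref"
            ) from e
        return cls(mov, ref)

    def write_csv(self, path) -> None:
        data = np.column_stack([self.moving, self.reference])
        np.savetxt(path, data, delimiter=",", header="x_mov,y_mov,x_ref,y_ref",
                   comments="", fmt="%.6f")


@dataclass(frozen=True)
class AffineTransform2D:
    """Mapping ``p_ref = A @ p_mov + t`` with A (2, 2) and t (2,)."""

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=np.float64).reshape(2, 2)
        t = np.asarray(self.t, dtype=np.float64).reshape(2)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "t", t)
        if abs(np.linalg.det(A)) <= 1e-9:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def __call__(self, pts) -> np.ndarray:
        return transform_points(self, pts)

    def invert(self) -> "AffineTransform2D":
        ainv = np.linalg.inv(self.A)
        return AffineTransform2D(ainv, -ainv @ self.t)

    def compose(self, first: "AffineTransform2D") -> "AffineTransform2D":
        """``self.compose(first)`` maps through ``first`` then ``self``."""
        return AffineTransform2D(self.A @ first.A, self.A @ first.t + self.t)

    @property
    def matrix3(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on (x, y, 1) columns."""
        m = np.eye(3)
        m[:2, :2] = self.A
        m[:2, 2] = self.t
        return m

    def to_json(self, path=None) -> str:
        payload = json.dumps({"A": self.A.tolist(), "t": self.t.tolist()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "AffineTransform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["A"]), np.array(d["t"]))


@dataclass(frozen=True)
class RegistrationReport:
    rmse_px: float
    max_residual_px: float
    n_points: int


def transform_points(T: AffineTransform2D, pts) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    return pts @ T.A.T + T.t


def estimate_affine(cps: ControlPointSet) -> AffineTransform2D:
    """Least-squares affine fit minimising sum ||A p_mov + t - p_ref||^2.

    Solved through an SVD-based factorisation (``numpy.linalg.lstsq``) rather
    than explicit normal equations, which matters when manual points cluster
    in one image region. With exactly 3 non-collinear pairs the fit is the
    exact interpolant (zero residual).
    """
    design = np.column_stack([cps.moving, np.ones(len(cps))])  # (n, 3)
    params, *_ = np.linalg.lstsq(design, cps.reference, rcond=None)  # (3, 2)
    T = AffineTransform2D(params[:2].T, params[2])
    rep = residual_report(cps, T)
    if rep.max_residual_px > _SUSPICIOUS_RESIDUAL_PX:
        resid = np.linalg.norm(transform_points(T, cps.moving) - cps.reference, axis=1)
        for i in np.nonzero(resid > _SUSPICIOUS_RESIDUAL_PX)[0]:
            logger.warning(
                "control point %d has residual %.2f px (> %.1f px): possible mispairing",
                i, resid[i], _SUSPICIOUS_RESIDUAL_PX,
            )
    return T


def invert(T: AffineTransform2D) -> AffineTransform2D:
    return T.invert()


def compose(T2: AffineTransform2D, T1: AffineTransform2D) -> AffineTransform2D:
    """Composite transform applying ``T1`` first, then ``T2``."""
    return T2.compose(T1)


def residual_report(cps: ControlPointSet, T: AffineTransform2D) -> RegistrationReport:
    resid = np.linalg.norm(transform_points(T, cps.moving) - cps.reference, axis=1)
    return RegistrationReport(
        rmse_px=float(np.sqrt(np.mean(resid**2))),
        max_residual_px=float(np.max(resid)),
        n_points=len(cps),
    )


def warp_image(img, T: AffineTransform2D, out_shape=None, interpolation: str = "bilinear",
               fill_value=None) -> np.ndarray:
    """Resample ``img`` (moving frame) onto the reference grid defined by ``T``.

    The output pixel at reference position p is sampled from the moving image
    at ``T.invert()(p)``. ``out_shape`` is (H, W) of the reference frame
    (defaults to the input's). Out-of-frame samples take ``fill_value``
    (default: 255 for uint8 inputs — background white — else 0).

    Integer images round-trip exactly under nearest interpolation.
    """
    img = np.asarray(img)
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    if out_shape is None:
        out_shape = img.shape[:2]
    if fill_value is None:
        fill_value = 255 if img.dtype == np.uint8 else 0.0
    # skimage's inverse_map takes output (x, y) coords -> input (x, y) coords,
    # matching this module's convention directly.
    inv = T.invert()
    sk = _SkAffine(matrix=inv.matrix3)
    shape = tuple(out_shape) + img.shape[2:]
    out = _sk_warp(img.astype(np.float64), sk, output_shape=shape,
                   order=orders[interpolation], cval=float(fill_value),
                   preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out
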