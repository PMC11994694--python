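"""Fisheye distortion, undistortion and central cropping.

The side cameras of the field robot carry fisheye lenses; frames come off the
video at a native 1,920 x 1,080 and must be undistorted before annotation or
counting, after which a central 1,000 x 1,000 window is cropped to discard the
blurry, still-distorted margins.

The lens is modelled as an equidistant fisheye with a polynomial distortion
term — the standard calibration model: for a ray at angle ``theta`` from the
optical axis,

    theta_d = theta * (1 + k1*theta^2 + k2*theta^4 + k3*theta^6 + k4*theta^8)

and the distorted image radius is ``f * theta_d`` (pixels), versus the pinhole
radius ``f * tan(theta)``.  Forward distortion is analytic; inversion solves
for ``theta`` by Newton iteration.  Image warps resample with bilinear
interpolation via :func:`scipy.ndimage.map_coordinates`.

Conventions: 0-based pixel indices, x rightward, y downward, a point sits at a
pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class OpticsError(ValueError):
    """Contract violation in an optics operation (size mismatch, bad crop)."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Fisheye camera intrinsics.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels. Must be positive.
    cx, cy : float
        Principal point in pixels; must lie inside ``native_size``.
    k : tuple of float
        Radial polynomial distortion coefficients (k1..k4), dimensionless.
    native_size : (width, height)
        Native frame size in pixels.
    """

    fx: float = 410.0
    fy: float = 410.0
    cx: float = 383.0
    cy: float = 526.0
    k: tuple[float, ...] = (-0.05, 0.01, 0.0, 0.0)
    native_size: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise OpticsError(f"focal lengths must be positive, got ({self.fx}, {self.fy})")
        w, h = self.native_size
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise OpticsError(
                f"principal point ({self.cx}, {self.cy}) outside native size {self.native_size}"
            )
        if not np.all(np.isfinite(self.k)):
            raise OpticsError("distortion coefficients must be finite")


#: Intrinsics of the robot's side camera as calibrated in the source study
#: (f = (410, 410) px, principal point = (383, 526) px, native 1920x1080).
#: Distortion coefficients were not published; these defaults give visible
#: but cleanly invertible curvature.
DEFAULT_INTRINSICS = CameraIntrinsics()


def _theta_d(theta: np.ndarray, k: tuple[float, ...]) -> np.ndarray:
    t2 = theta * theta
    poly = np.ones_like(theta)
    acc = np.ones_like(theta)
    for ki in k:
        acc = acc * t2
        poly = poly + ki * acc
    return theta * poly


def _theta_d_prime(theta: np.ndarray, k: tuple[float, ...]) -> np.ndarray:
    t2 = theta * theta
    deriv = np.ones_like(theta)
    acc = np.ones_like(theta)
    for i, ki in enumerate(k):
        acc = acc * t2
        deriv = deriv + (2 * i + 3) * ki * acc
    return deriv


def _invert_theta_d(theta_d: np.ndarray, k: tuple[float, ...], iters: int = 10) -> np.ndarray:
    """Solve theta from theta_d by Newton iteration (small-|k| regime)."""
    theta = theta_d.copy()
    for _ in range(iters):
        theta = theta - (_theta_d(theta, k) - theta_d) / _theta_d_prime(theta, k)
    return theta


def distort_points(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Map undistorted (pinhole) pixel points to fisheye pixel points.

    ``points`` is an (N, 2) array of (x, y). The principal point maps to
    itself.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x = (pts[:, 0] - intr.cx) / intr.fx
    y = (pts[:, 1] - intr.cy) / intr.fy
    r = np.hypot(x, y)
    theta = np.arctan(r)
    theta_d = _theta_d(theta, intr.k)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, theta_d / r, 1.0)
    out = np.empty_like(pts)
    out[:, 0] = intr.cx + intr.fx * x * scale
    out[:, 1] = intr.cy + intr.fy * y * scale
    return out


def undistort_points(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Map fisheye pixel points back to undistorted (pinhole) pixel points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x = (pts[:, 0] - intr.cx) / intr.fx
    y = (pts[:, 1] - intr.cy) / intr.fy
    rd = np.hypot(x, y)
    theta = _invert_theta_d(rd, intr.k)
    r = np.tan(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rd > 0, r / rd, 1.0)
    out = np.empty_like(pts)
    out[:, 0] = intr.cx + intr.fx * x * scale
    out[:, 1] = intr.cy + intr.fy * y * scale
    return out


def _check_native(image: np.ndarray, intr: CameraIntrinsics) -> None:
    h, w = image.shape[:2]
    if (w, h) != tuple(intr.native_size):
        raise OpticsError(
            f"image size {(w, h)} does not match intrinsics native_size {intr.native_size}"
        )


def _warp(image: np.ndarray, src_xy: np.ndarray) -> np.ndarray:
    """Bilinear resample of ``image`` at source coordinates (H, W, 2 as x,y)."""
    coords = np.stack([src_xy[..., 1], src_xy[..., 0]])  # row, col order
    if image.ndim == 2:
        return ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(image[..., c], coords, order=1, mode="nearest")
    return out


def _pixel_grid(w: int, h: int) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return np.stack([xs, ys], axis=-1)


def apply_fisheye(image: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Apply forward equidistant fisheye distortion to a pinhole image."""
    _check_native(image, intr)
    h, w = image.shape[:2]
    grid = _pixel_grid(w, h).reshape(-1, 2)
    # an output (distorted) pixel q shows the scene point whose pinhole
    # position p satisfies distort(p) == q, i.e. p = undistort(q)
    src = undistort_points(grid, intr).reshape(h, w, 2)
    return _warp(image, src)


def undistort_image(image: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Invert :func:`apply_fisheye` up to interpolation error."""
    _check_native(image, intr)
    h, w = image.shape[:2]
    grid = _pixel_grid(w, h).reshape(-1, 2)
    src = distort_points(grid, intr).reshape(h, w, 2)
    return _warp(image, src)


def center_crop(
    image: np.ndarray,
    crop: int | tuple[int, int] = 1000,
    points: np.ndarray | None = None,
):
    """Crop a centered ``crop`` x ``crop`` window; no resampling.

    With odd leftover margins the extra pixel goes to the bottom/right (the
    window is shifted toward the top-left) so the operation is deterministic.

    If ``points`` (N, 2) is given, returns ``(cropped, shifted_points)`` where
    points falling outside the window are dropped.
    """
    cw, ch = (crop, crop) if np.isscalar(crop) else crop
    h, w = image.shape[:2]
    if cw > w or ch > h:
        raise OpticsError(f"crop {(cw, ch)} exceeds image size {(w, h)}")
    x0 = (w - cw) // 2
    y0 = (h - ch) // 2
    out = image[y0 : y0 + ch, x0 : x0 + cw]
    if points is None:
        return out
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    shifted = pts - np.array([x0, y0], dtype=float)
    keep = (
        (shifted[:, 0] >= 0)
        & (shifted[:, 0] < cw)
        & (shifted[:, 1] >= 0)
        & (shifted[:, 1] < ch)
    )
    return out, shifted[keep]
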