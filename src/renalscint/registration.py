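"""Rigid frame registration by iterative MSE minimisation.

Every frame of a dynamic series is aligned to the first frame with a rigid
model (rotation about the image centre, translation, isotropic scale),
optimised by adaptive-moment gradient descent on the mean squared error
between the warped source and the target.  This mirrors the image-based
motion-correction step used when preparing gamma-camera dynamic data for
frame summation: residual patient motion between 1-minute frames blurs the
composite image and the training targets built from it.

Transform convention
--------------------
``RigidTransform`` maps *source* coordinates to *target* coordinates:

    y = s * R(phi) @ (x - c) + c + t

with ``c`` the geometric image centre, coordinates as 0-based (row, col)
pixel positions, ``phi`` the rotation angle and ``t`` the translation in
pixels.  ``resample(image, T)`` evaluates the source at ``T^{-1}(y)`` for
each output pixel ``y`` by bilinear interpolation, so applying a transform
with translation (0, +3) moves image content 3 columns to the right.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import DynamicSeries

__all__ = ["RigidTransform", "RegistrationResult", "resample", "register_frame", "register_series"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation + isotropic scale, source -> target.

    rotation_deg : rotation about the image centre, degrees, positive from
        +row axis towards +col axis.
    translation_px : (drow, dcol) in pixels.
    scale : isotropic scale factor, > 0.
    """

    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0), 1.0)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1), about the origin.

        The centre offset is handled by the caller (``_coords``/``compose``)
        because the centre depends on the image the transform is applied to.
        """
        phi = math.radians(self.rotation_deg)
        c, s = math.cos(phi), math.sin(phi)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation_px[0]],
                [self.scale * s, self.scale * c, self.translation_px[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``.

        Composition is exact for the centre-relative form because both
        factors share the same centre fixed point convention.
        """
        phi = self.rotation_deg + other.rotation_deg
        scale = self.scale * other.scale
        # centre-relative linear parts compose; translations: t = s_a R_a t_b + t_a
        ra = _rot2(math.radians(self.rotation_deg)) * self.scale
        t = ra @ np.asarray(other.translation_px) + np.asarray(self.translation_px)
        return RigidTransform(phi, (float(t[0]), float(t[1])), scale)

    def inverse(self) -> "RigidTransform":
        phi = -self.rotation_deg
        scale = 1.0 / self.scale
        rinv = _rot2(math.radians(phi)) * scale
        t = -(rinv @ np.asarray(self.translation_px))
        return RigidTransform(phi, (float(t[0]), float(t[1])), scale)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "translation_px": [float(self.translation_px[0]), float(self.translation_px[1])],
            "scale": float(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["rotation_deg"], tuple(d["translation_px"]), d["scale"])


def _rot2(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    registered_image: np.ndarray
    final_mse: float
    mse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _source_coords(shape: tuple[int, int], transform: RigidTransform) -> np.ndarray:
    """Source-domain sampling coordinates of each output pixel, shape (2, H, W)."""
    h, w = shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    y = np.stack([rr.ravel(), cc.ravel()])  # (2, H*W), target coords
    inv = transform.inverse()
    rinv = _rot2(math.radians(inv.rotation_deg)) * inv.scale
    # x = Rinv (y - c - t_fwd) + c  ==  Rinv (y - c) + c + t_inv  (same thing)
    x = rinv @ (y - centre[:, None]) + centre[:, None] + np.asarray(inv.translation_px)[:, None]
    return x.reshape(2, h, w)


def resample(image: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Warp ``image`` by ``transform`` with bilinear interpolation.

    Samples that map outside the source domain are filled with 0.  The
    identity transform returns the input unchanged (bit-exact).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("resample expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("resample expects finite-valued input")
    if transform == RigidTransform.identity():
        return image.copy()
    coords = _source_coords(image.shape, transform)
    return ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def register_frame(
    source: np.ndarray,
    target: np.ndarray,
    iterations: int = 100,
    learning_rate: float = 0.01,
) -> RegistrationResult:
    """Find the rigid transform minimising MSE(resample(source, T), target).

    Optimises (rotation, translation, log-scale) with Adam for a fixed
    number of iterations; translations are optimised in units of half the
    image size so one step size suits all image and count scales.  Images
    are divided by their means before the MSE is evaluated, decoupling the
    step size from the count level; the returned registered image is the
    unnormalised source warped by the best transform encountered.

    ``mse_trace`` holds the running best (cumulative minimum) normalised
    MSE after each iteration; ``final_mse`` is its last entry and is never
    above the MSE at the identity initialisation.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2:
        raise ValueError(f"source/target must be same-shape 2-D images, got {source.shape} vs {target.shape}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    smean, tmean = source.mean(), target.mean()
    if smean == 0 or tmean == 0:
        log.warning("all-zero source or target: returning identity transform")
        ident = RigidTransform.identity()
        m = _mse(source, target)
        return RegistrationResult(ident, source.copy(), m, np.array([m]))

    srcn = source / smean
    tgtn = target / tmean
    h, w = source.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    tscale = max(h, w) / 2.0  # translation parametrised in units of half-size

    gr_img, gc_img = np.gradient(srcn)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    y_rel = np.stack([rr - centre[0], cc - centre[1]])  # (2, H, W) target coords rel. centre

    # params: [phi (rad), t_row/tscale, t_col/tscale, log(scale)]
    theta = np.zeros(4)

    def unpack(th):
        return th[0], np.array([th[1], th[2]]) * tscale, math.exp(th[3])

    def objective_and_grad(th):
        phi, t, s = unpack(th)
        # inverse map: x = R(-phi)/s @ (y_rel - t) + centre
        rinv = _rot2(-phi) / s
        u = y_rel - t[:, None, None]
        x = np.einsum("ij,jhw->ihw", rinv, u) + centre[:, None, None]
        warped = ndimage.map_coordinates(srcn, x, order=1, mode="constant", cval=0.0)
        res = warped - tgtn
        mse = float(np.mean(res**2))
        gr = ndimage.map_coordinates(gr_img, x, order=1, mode="constant", cval=0.0)
        gc = ndimage.map_coordinates(gc_img, x, order=1, mode="constant", cval=0.0)
        # derivatives of the sampling coordinates w.r.t. parameters
        drot = _drot2(-phi) / s  # d(rinv)/dphi * dphi... sign handled below
        dx_dphi = -np.einsum("ij,jhw->ihw", drot, u)  # d(-phi)/dphi = -1
        dx_dlogs = -np.einsum("ij,jhw->ihw", rinv, u)  # d(1/s)/dlogs = -1/s
        common = 2.0 * res / res.size
        g = np.empty(4)
        g[0] = np.sum(common * (gr * dx_dphi[0] + gc * dx_dphi[1]))
        # translation: dx/dt_k = -rinv[:, k]; theta stores t/tscale so chain by tscale
        g[1] = np.sum(common * (gr * (-rinv[0, 0]) + gc * (-rinv[1, 0]))) * tscale
        g[2] = np.sum(common * (gr * (-rinv[0, 1]) + gc * (-rinv[1, 1]))) * tscale
        g[3] = np.sum(common * (gr * dx_dlogs[0] + gc * dx_dlogs[1]))
        return mse, g

    # Adam
    m1 = np.zeros(4)
    m2 = np.zeros(4)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_theta = theta.copy()
    best_mse, _ = objective_and_grad(theta)
    trace = []
    for it in range(1, iterations + 1):
        mse, g = objective_and_grad(theta)
        if mse < best_mse:
            best_mse = mse
            best_theta = theta.copy()
        trace.append(best_mse)
        m1 = beta1 * m1 + (1 - beta1) * g
        m2 = beta2 * m2 + (1 - beta2) * g**2
        mhat = m1 / (1 - beta1**it)
        vhat = m2 / (1 - beta2**it)
        theta = theta - learning_rate * mhat / (np.sqrt(vhat) + eps)
    # account for the final parameter vector as well
    mse, _ = objective_and_grad(theta)
    if mse < best_mse:
        best_mse = mse
        best_theta = theta.copy()
    trace[-1] = best_mse

    phi, t, s = unpack(best_theta)
    transform = RigidTransform(math.degrees(phi), (float(t[0]), float(t[1])), float(s))
    registered = resample(source, transform)
    return RegistrationResult(transform, registered, best_mse, np.asarray(trace))


def _drot2(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[-s, -c], [c, -s]])


def register_series(
    series: DynamicSeries, iterations: int = 100, learning_rate: float = 0.01
) -> tuple[DynamicSeries, list[RigidTransform]]:
    """Register every frame of a dynamic series to its first frame.

    Frame 0 is returned unchanged; each later frame is replaced by its
    registered (warped) image.  The per-frame transforms are returned for
    audit alongside the corrected series.
    """
    if series.n_frames < 2:
        raise ValueError("register_series needs at least 2 frames")
    target = series.frames[0].astype(float)
    out = [target.copy()]
    transforms = [RigidTransform.identity()]
    for f in range(1, series.n_frames):
        result = register_frame(series.frames[f].astype(float), target, iterations, learning_rate)
        out.append(result.registered_image)
        transforms.append(result.transform)
    registered = DynamicSeries(
        frames=np.clip(np.stack(out), 0.0, None),
        pixel_size_mm=series.pixel_size_mm,
        frame_duration_s=series.frame_duration_s,
        meta={**series.meta, "registered": True},
    )
    return registered, transforms
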