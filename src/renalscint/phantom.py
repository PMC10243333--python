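"""Synthetic dynamic planar phantom with known geometry, counts and uptake.

The phantom emulates a posterior dynamic renal acquisition: two elliptical
kidney uptake regions over a low-count elliptical body background, imaged
as ``n_frames`` consecutive frames of independent Poisson counts.  Count
levels default to the clinical regime of pediatric DMSA imaging, where the
kidney accumulates on the order of 20 counts/pixel per 1-minute frame
(about 210 counts/pixel in a 10-minute composite).  Optional per-frame
rigid motion displaces the noiseless activity map before the Poisson draw,
so the motion belongs to the patient, not the noise.

Sensitivity model
-----------------
Counts equal the activity map directly: no separate camera-sensitivity
constant.  The whole-dose reference count ``D`` links region counts to
uptake fractions through

    fraction_i = (kidney_i counts - background counts in the same area) / D

evaluated on the noiseless ``n_frames``-frame sum.  Because one ``D`` cannot
in general satisfy two independently chosen kidney means *and* two uptake
fractions, the spec is closed in one of two ways:

* ``total_dose_counts`` is ``None`` (default): ``D`` is derived from kidney
  0's mean and fraction, and every other kidney's mean is solved from its
  requested fraction.  All requested fractions are then realised exactly.
* ``total_dose_counts`` is given: all kidney means are honoured as given
  and the *realised* fractions (stored in :class:`GroundTruth`) are
  computed from the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import DynamicSeries
from .registration import RigidTransform, resample

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "GroundTruth",
    "ellipse_mask",
    "intensity_map",
    "generate_phantom",
    "make_phantom_cases",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-then-rotated ellipse in pixel coordinates.

    center: (row, col), 0-based pixel centres; semi_axes: (a_row, a_col) in
    pixels along the unrotated axes; rotation_deg rotates the ellipse about
    its centre.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0


def ellipse_mask(shape: tuple[int, int], ellipse: Ellipse) -> np.ndarray:
    """Rasterise: a pixel belongs to the ellipse if its centre lies inside.

    Pixel centres sit at integer (row, col) coordinates with the origin at
    the image corner.
    """
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - ellipse.center[0]
    dc = cc - ellipse.center[1]
    phi = np.deg2rad(ellipse.rotation_deg)
    u = np.cos(phi) * dr + np.sin(phi) * dc
    v = -np.sin(phi) * dr + np.cos(phi) * dc
    return (u / ellipse.semi_axes[0]) ** 2 + (v / ellipse.semi_axes[1]) ** 2 <= 1.0


def _default_kidneys(shape: tuple[int, int]) -> tuple[Ellipse, Ellipse]:
    h, w = shape
    return (
        Ellipse((h * 0.5, w * 0.31), (h * 0.16, w * 0.094), -15.0),
        Ellipse((h * 0.5, w * 0.69), (h * 0.16, w * 0.094), 15.0),
    )


def _default_body(shape: tuple[int, int]) -> Ellipse:
    h, w = shape
    return Ellipse((h * 0.5, w * 0.5), (h * 0.44, w * 0.41), 0.0)


@dataclass
class PhantomSpec:
    """Full description of one synthetic dynamic acquisition.

    ``kidney_mean_counts_per_frame`` may be a scalar (anchoring kidney 0;
    remaining kidney means are solved from their uptake fractions) or a
    per-kidney sequence.  See the module docstring for how the fractions,
    the means and ``total_dose_counts`` are kept mutually consistent.
    """

    image_shape: tuple[int, int] = (64, 64)
    pixel_size_mm: float = 5.4
    n_frames: int = 10
    frame_duration_s: float = 60.0
    kidney_geometry: Sequence[Ellipse] | None = None
    body_geometry: Ellipse | None = None
    kidney_mean_counts_per_frame: float | Sequence[float] = 21.0
    background_mean_counts_per_frame: float = 2.0
    true_uptake_fraction: Sequence[float] = (0.21, 0.19)
    total_dose_counts: float | None = None
    motion: Sequence[RigidTransform] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kidney_geometry is None:
            self.kidney_geometry = _default_kidneys(self.image_shape)
        if self.body_geometry is None:
            self.body_geometry = _default_body(self.image_shape)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        h, w = self.image_shape
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        means = self._kidney_mean_list()
        b = self.background_mean_counts_per_frame
        if b < 0 or any(m < 0 for m in means):
            raise ValueError("mean counts must be non-negative")
        if any(m < b for m in means) or (any(m > 0 for m in means) and not any(m > b for m in means)):
            raise ValueError(
                "kidney mean counts must exceed the background mean (no kidney/background contrast)"
            )
        fr = list(self.true_uptake_fraction)
        if len(fr) != len(self.kidney_geometry):
            raise ValueError("one uptake fraction per kidney is required")
        if any(not (0 < f < 1) for f in fr) or sum(fr) >= 1:
            raise ValueError("uptake fractions must lie in (0, 1) and sum to < 1")
        for e in self.kidney_geometry:
            if not self._ellipse_inside(e, h, w):
                raise ValueError(f"kidney ellipse {e} extends outside the {h}x{w} image")
        if self.motion is not None and len(self.motion) != self.n_frames:
            raise ValueError("motion must provide one transform per frame")

    @staticmethod
    def _ellipse_inside(e: Ellipse, h: int, w: int) -> bool:
        r = max(e.semi_axes)
        return (e.center[0] - r >= 0 and e.center[0] + r <= h - 1
                and e.center[1] - r >= 0 and e.center[1] + r <= w - 1)

    def _kidney_mean_list(self) -> list[float]:
        m = self.kidney_mean_counts_per_frame
        if np.isscalar(m):
            return [float(m)] * len(self.kidney_geometry or ()) if self.kidney_geometry else [float(m)]
        return [float(v) for v in m]

    # -- derived, mutually consistent quantities --------------------------
    def resolved_counts(self) -> tuple[list[float], float, list[float]]:
        """Return (per-kidney means, D, realised uptake fractions).

        Applies the consistency rules in the module docstring; masks are
        rasterised with the pixel-centre convention to obtain region areas.
        """
        masks = [ellipse_mask(self.image_shape, e) for e in self.kidney_geometry]
        areas = [int(m.sum()) for m in masks]
        b = self.background_mean_counts_per_frame
        means = self._kidney_mean_list()
        fr = list(self.true_uptake_fraction)
        F = self.n_frames
        excess0 = (means[0] - b) * F * areas[0]
        if self.total_dose_counts is None:
            if excess0 <= 0:
                return means, 1.0, [0.0] * len(means)
            D = excess0 / fr[0]
            if np.isscalar(self.kidney_mean_counts_per_frame):
                means = [means[0]] + [b + fr[i] * D / (F * areas[i]) for i in range(1, len(means))]
                realised = fr
            else:
                realised = [(means[i] - b) * F * areas[i] / D for i in range(len(means))]
            return means, float(D), [float(f) for f in realised]
        D = float(self.total_dose_counts)
        realised = [(means[i] - b) * F * areas[i] / D for i in range(len(means))]
        return means, D, [float(f) for f in realised]


@dataclass
class GroundTruth:
    """Everything the downstream stages may hold the phantom to account for."""

    kidney_masks: list[np.ndarray]
    background_mask: np.ndarray
    true_uptake_fraction: list[float]
    total_dose_counts: float
    applied_motion: list[RigidTransform]
    kidney_mean_counts_per_frame: list[float]
    noiseless_map: np.ndarray


def intensity_map(spec: PhantomSpec) -> np.ndarray:
    """Noiseless expected counts/pixel for one frame.

    Piecewise constant: the background mean inside the body ellipse, the
    per-kidney mean inside each kidney ellipse (kidney tissue replaces
    background), zero outside the body.
    """
    means, _, _ = spec.resolved_counts()
    body = ellipse_mask(spec.image_shape, spec.body_geometry)
    out = np.where(body, float(spec.background_mean_counts_per_frame), 0.0)
    for m, e in zip(means, spec.kidney_geometry):
        out[ellipse_mask(spec.image_shape, e)] = m
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, GroundTruth]:
    """Draw one seeded dynamic series from the phantom model.

    Each pixel of each frame is an independent Poisson draw with mean given
    by the (optionally motion-displaced) noiseless map.  Identical spec and
    seed give bit-identical output.
    """
    spec.validate()
    means, dose, realised = spec.resolved_counts()
    base_map = intensity_map(spec)
    rng = np.random.default_rng(spec.seed)
    frames = []
    motions = list(spec.motion) if spec.motion is not None else [RigidTransform.identity()] * spec.n_frames
    for f in range(spec.n_frames):
        lam = base_map if motions[f] == RigidTransform.identity() else np.clip(resample(base_map, motions[f]), 0.0, None)
        frames.append(rng.poisson(lam))
    series = DynamicSeries(
        frames=np.stack(frames).astype(np.int64),
        pixel_size_mm=spec.pixel_size_mm,
        frame_duration_s=spec.frame_duration_s,
        meta={"seed": spec.seed, "phantom": True},
    )
    kidney_masks = [ellipse_mask(spec.image_shape, e) for e in spec.kidney_geometry]
    body = ellipse_mask(spec.image_shape, spec.body_geometry)
    background = body.copy()
    for m in kidney_masks:
        background &= ~m
    gt = GroundTruth(
        kidney_masks=kidney_masks,
        background_mask=background,
        true_uptake_fraction=realised,
        total_dose_counts=dose,
        applied_motion=motions,
        kidney_mean_counts_per_frame=means,
        noiseless_map=base_map,
    )
    return series, gt


def make_phantom_cases(
    n_cases: int,
    seed: int = 0,
    base: PhantomSpec | None = None,
    uptake_range: tuple[float, float] = (0.14, 0.28),
    motion_max_px: float = 0.0,
    motion_max_deg: float = 0.0,
) -> list[tuple[PhantomSpec, DynamicSeries, GroundTruth]]:
    """Generate a cohort of phantom cases with varied per-case uptake.

    Per-kidney uptake fractions are drawn uniformly from ``uptake_range``
    (kidney count levels stay anchored by the base spec's kidney mean);
    optional uniform per-frame rigid motion up to ``motion_max_px`` /
    ``motion_max_deg`` is applied to frames 1..F-1.
    """
    if base is None:
        base = PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        fr = rng.uniform(*uptake_range, size=len(base.kidney_geometry))
        motion = None
        if motion_max_px > 0 or motion_max_deg > 0:
            motion = [RigidTransform.identity()]
            for _ in range(base.n_frames - 1):
                motion.append(
                    RigidTransform(
                        rotation_deg=float(rng.uniform(-motion_max_deg, motion_max_deg)),
                        translation_px=tuple(rng.uniform(-motion_max_px, motion_max_px, size=2)),
                        scale=1.0,
                    )
                )
        spec = replace(
            base,
            true_uptake_fraction=tuple(fr),
            motion=motion,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series, gt = generate_phantom(spec)
        series.meta["case_id"] = f"case{i:03d}"
        cases.append((spec, series, gt))
    return cases
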