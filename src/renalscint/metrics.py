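"""Image-quality metrics for count images: NMSE, PSNR, SSIM, joint histograms.

All three similarity metrics treat ``y`` as the reference full-time image
and ``x`` as the short-time or predicted image:

* NMSE(x, y) = 100 * sum((y - x)^2) / sum(y^2), in percent.
* PSNR(x, y) = 20 * log10(max(y) / sqrt(MSE(x, y))), in dB; +inf when the
  images are identical (excluded from aggregate means with a logged count).
* SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
               ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))
  with c1 = (0.01 L)^2, c2 = (0.03 L)^2 and L the dynamic range.  The
  default evaluates this formula once with global image statistics; a
  windowed mode (11x11 Gaussian weights, mean-aggregated) is available.
  L defaults to max(y), mirroring the PSNR peak convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QualityMetrics",
    "nmse",
    "psnr",
    "ssim",
    "compute_metrics",
    "joint_histogram",
    "evaluate_split",
    "summarize_metric",
]

log = logging.getLogger(__name__)


@dataclass
class QualityMetrics:
    nmse_percent: float
    psnr_db: float
    ssim: float


def _check(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def nmse(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized mean squared error of x against reference y, in percent."""
    x, y = _check(x, y)
    denom = float(np.sum(y**2))
    if denom == 0:
        raise ValueError("NMSE undefined for an all-zero reference image")
    return 100.0 * float(np.sum((y - x) ** 2)) / denom


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf when MSE is zero."""
    x, y = _check(x, y)
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("PSNR undefined when the reference has no positive pixel")
    mse = float(np.mean((y - x) ** 2))
    if mse == 0:
        return math.inf
    return 20.0 * math.log10(peak / math.sqrt(mse))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    dynamic_range: float | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity of x and y.

    ``dynamic_range`` (L) defaults to max(y); pass e.g. 65535 for a fixed
    16-bit range.  ``windowed=True`` switches from the single global-
    statistics evaluation to the common local form (11x11 Gaussian window,
    sigma 1.5, mean-aggregated).
    """
    x, y = _check(x, y)
    L = float(y.max()) if dynamic_range is None else float(dynamic_range)
    if L <= 0:
        raise ValueError("SSIM dynamic range must be positive")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                x, y, data_range=L, gaussian_weights=True, win_size=11, sigma=1.5,
                use_sample_covariance=False,
            )
        )
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def compute_metrics(x: np.ndarray, y: np.ndarray, **ssim_kwargs) -> QualityMetrics:
    return QualityMetrics(
        nmse_percent=nmse(x, y), psnr_db=psnr(x, y), ssim=ssim(x, y, **ssim_kwargs)
    )


def joint_histogram(
    x: np.ndarray | list[np.ndarray],
    y: np.ndarray | list[np.ndarray],
    bins: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Voxel-wise joint histogram of paired images with Pearson correlation.

    Pools all voxel pairs of the (lists of) images and returns
    (histogram, x_edges, y_edges, r, r_squared).
    """
    xs = [np.asarray(a, dtype=float) for a in (x if isinstance(x, (list, tuple)) else [x])]
    ys = [np.asarray(a, dtype=float) for a in (y if isinstance(y, (list, tuple)) else [y])]
    if len(xs) != len(ys) or any(a.shape != b.shape for a, b in zip(xs, ys)):
        raise ValueError("joint_histogram needs paired same-shape images")
    xv = np.concatenate([a.ravel() for a in xs])
    yv = np.concatenate([b.ravel() for b in ys])
    hist, xe, ye = np.histogram2d(xv, yv, bins=bins)
    if xv.std() == 0 or yv.std() == 0:
        log.warning("degenerate joint histogram: constant input, correlation undefined")
        r = math.nan
    else:
        r = float(np.corrcoef(xv, yv)[0, 1])
    return hist, xe, ye, r, r * r


def summarize_metric(values: list[float], name: str = "") -> dict:
    """Mean (SD) and median (Q1, Q3) with linear-interpolation quartiles.

    Infinite values (identical-image PSNR) are excluded with a logged count.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    n_inf = arr.size - finite.size
    if n_inf:
        log.warning("%s: excluded %d infinite value(s) from aggregation", name or "metric", n_inf)
    if finite.size == 0:  # every value infinite (e.g. PSNR of identical images)
        inf = math.inf
        return {"mean": inf, "sd": 0.0, "median": inf, "q1": inf, "q3": inf,
                "n_excluded_inf": int(n_inf)}
    return {
        "mean": float(finite.mean()),
        "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        "median": float(np.percentile(finite, 50)),
        "q1": float(np.percentile(finite, 25)),
        "q3": float(np.percentile(finite, 75)),
        "n_excluded_inf": int(n_inf),
    }


def evaluate_split(
    predictions: dict[str, list[np.ndarray]],
    short_times: list[np.ndarray],
    references: list[np.ndarray],
    **ssim_kwargs,
) -> pd.DataFrame:
    """Per-method metric summary table over a test split.

    ``predictions`` maps a method name (e.g. "DnCNN") to its predicted
    full-time images, aligned with ``short_times`` and ``references``.
    The returned table has one row per (method, metric, statistic) in the
    conventional layout: short-time first, then each model.
    """
    methods: dict[str, list[np.ndarray]] = {"short-time": short_times, **predictions}
    rows = []
    for method, images in methods.items():
        if len(images) != len(references):
            raise ValueError(f"{method}: {len(images)} images vs {len(references)} references")
        per_metric: dict[str, list[float]] = {"nmse_percent": [], "psnr_db": [], "ssim": []}
        for img, ref in zip(images, references):
            m = compute_metrics(img, ref, **ssim_kwargs)
            per_metric["nmse_percent"].append(m.nmse_percent)
            per_metric["psnr_db"].append(m.psnr_db)
            per_metric["ssim"].append(m.ssim)
        for metric, vals in per_metric.items():
            s = summarize_metric(vals, f"{method}/{metric}")
            rows.append({"method": method, "metric": metric, **s})
    return pd.DataFrame(rows)
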