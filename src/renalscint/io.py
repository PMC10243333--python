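"""Dynamic planar series container and on-disk formats.

A dynamic acquisition is an ordered stack of same-shaped count frames
(e.g. ten 1-minute posterior frames) plus the acquisition metadata needed
downstream: pixel size and frame duration.  Series are stored as a
compressed ``.npz`` holding the frame stack next to a JSON sidecar with
the metadata, so the on-disk form is portable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DynamicSeries", "save_series", "load_series", "export_png", "export_dicom"]


@dataclass
class DynamicSeries:
    """Ordered stack of count frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` of non-negative counts.
    pixel_size_mm
        Edge length of one square pixel in millimetres.
    frame_duration_s
        Duration of each frame in seconds.
    meta
        Free-form metadata (case id, seed, ...), JSON-serialisable.
    """

    frames: np.ndarray
    pixel_size_mm: float = 1.35
    frame_duration_s: float = 60.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n_frames, rows, cols), got shape {self.frames.shape}")
        if np.any(self.frames < 0):
            raise ValueError("count frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_sum(self, indices=None) -> np.ndarray:
        """Sum of the selected frames (all frames when ``indices`` is None)."""
        if indices is None:
            return self.frames.sum(axis=0)
        indices = list(indices)
        return self.frames[indices].sum(axis=0)


def save_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write a series as ``<path>.npz`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez_compressed(base.with_suffix(".npz"), frames=series.frames)
    sidecar = {
        "pixel_size_mm": series.pixel_size_mm,
        "frame_duration_s": series.frame_duration_s,
        "n_frames": int(series.n_frames),
        "shape": list(series.shape),
        "meta": series.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=_jsonify))
    return base.with_suffix(".npz")


def load_series(path: str | Path) -> DynamicSeries:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    frames = np.load(base.with_suffix(".npz"))["frames"]
    sidecar = json.loads(base.with_suffix(".json").read_text())
    return DynamicSeries(
        frames=frames,
        pixel_size_mm=sidecar["pixel_size_mm"],
        frame_duration_s=sidecar["frame_duration_s"],
        meta=sidecar.get("meta", {}),
    )


def _jsonify(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def export_png(series: DynamicSeries, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Export each frame as a 16-bit grayscale PNG (counts clipped to uint16)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(series.frames):
        p = out_dir / f"{prefix}_{i:03d}.png"
        iio.imwrite(p, np.clip(np.round(frame), 0, 65535).astype(np.uint16))
        paths.append(p)
    return paths


def export_dicom(series: DynamicSeries, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Export frames as DICOM secondary-capture objects (16-bit grayscale)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for i, frame in enumerate(series.frames):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "NM"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = frame.shape
        ds.PixelSpacing = [series.pixel_size_mm, series.pixel_size_mm]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.clip(np.round(frame), 0, 65535).astype("<u2").tobytes()
        p = out_dir / f"{prefix}_{i:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths
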