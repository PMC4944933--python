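"""Multi-contrast image series: a stack of co-registered 2-D magnitude frames.

A series is written either as a single-file NIfTI volume (frames stacked on
the third axis) or as a multi-page TIFF, always accompanied by a YAML
sidecar recording the protocol (kind, schedule, units). Reading requires
the sidecar so that the fit variable is never guessed from file names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .protocols import AcquisitionProtocol

__all__ = ["ImageSeries", "write_series", "read_series",
           "write_label_map", "read_label_map"]


@dataclass
class ImageSeries:
    """Stack of 2-D non-negative magnitude frames indexed by one variable."""

    frames: np.ndarray  # (n_frames, rows, cols)
    protocol: AcquisitionProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        n = len(self.protocol.schedule)
        if self.frames.shape[0] != n:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != schedule length {n}"
            )
        if np.any(self.frames < 0):
            raise ValueError("magnitude frames must be non-negative")

    @property
    def kind(self) -> str:
        return self.protocol.kind

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def fit_schedule(self) -> np.ndarray:
        return self.protocol.fit_schedule


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.suffix not in (
        ".nii", ".tif", ".tiff") else path.with_suffix(".yaml")


def write_series(series: ImageSeries, path) -> Path:
    """Write frames (NIfTI ``.nii`` or multi-page TIFF ``.tif``/``.tiff``)
    plus a YAML protocol sidecar; returns the image path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".nii":
        # NIfTI stores fastest axis first; keep (rows, cols, frames)
        vol = np.moveaxis(series.frames, 0, -1)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, series.frames.astype(np.float32),
                         photometric="minisblack")
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "protocol": series.protocol.to_dict(),
        "schedule_units": series.protocol.fit_units,
        "meta": dict(series.meta),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_series(path) -> ImageSeries:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"protocol sidecar not found: {sidecar}")
    info = yaml.safe_load(sidecar.read_text())
    protocol = AcquisitionProtocol.from_dict(info["protocol"])
    if path.suffix == ".nii":
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        frames = np.moveaxis(vol, -1, 0)
    elif path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path).astype(float)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return ImageSeries(frames=frames, protocol=protocol,
                       meta=info.get("meta", {}))


def write_label_map(labels: np.ndarray, names: list, path) -> Path:
    """Write an integer compartment label map (NIfTI or TIFF) with a YAML
    sidecar mapping integer codes to compartment names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    if path.suffix == ".nii":
        nib.save(nib.Nifti1Image(labels.astype(np.int16), affine=np.eye(4)),
                 str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, labels.astype(np.int16),
                         photometric="minisblack")
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    _sidecar_path(path).write_text(
        yaml.safe_dump({"labels": {int(i): n for i, n in enumerate(names)}}))
    return path


def read_label_map(path) -> tuple:
    path = Path(path)
    if path.suffix == ".nii":
        labels = np.asarray(nib.load(str(path)).dataobj).astype(int)
    else:
        labels = tifffile.imread(path).astype(int)
    sidecar = _sidecar_path(path)
    names = None
    if sidecar.exists():
        m = yaml.safe_load(sidecar.read_text())["labels"]
        names = [m[k] for k in sorted(m)]
    return labels, names
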