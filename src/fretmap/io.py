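"""Image stacks, ROI sets and result tables.

Coordinate convention (used everywhere in this package): 0-based,
``(row, col)`` order, pixel centers at integer coordinates. ROI vertices and
patch centers live in the same frame. Images are stored ``(frame, row, col)``.

Stacks are written as multi-page 16-bit TIFF with a YAML sidecar manifest
carrying channel, per-frame phase tags, time stamps and pixel size; ROI sets
and configs are YAML; measurement tables are CSV with a ``schema_version``
column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon2mask

SCHEMA_VERSION = 1

PHASES = ("pre", "bleach", "post")
ROI_ROLES = ("patches", "cytoplasm", "whole_cell", "frap_spot", "reference",
             "background")


@dataclass
class ImageSeries:
    """An ordered multi-frame single-channel image stack.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Pixel data; float during processing, integer counts straight off the
        simulator/camera.
    channel : str
        e.g. ``"donor"``, ``"acceptor"``, ``"marker"``.
    phases : sequence of str
        Per-frame phase tag, each one of ``pre | bleach | post``, non-
        decreasing in that order.
    times_s : sequence of float
        Per-frame acquisition time stamps, strictly increasing.
    pixel_size_nm : float
        Lateral pixel size; 178 nm for the wide-field EMCCD setup emulated
        by the simulator.
    """

    frames: np.ndarray
    channel: str
    phases: tuple[str, ...]
    times_s: np.ndarray
    pixel_size_nm: float = 178.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, H, W), got {self.frames.shape}")
        self.phases = tuple(self.phases)
        self.times_s = np.asarray(self.times_s, dtype=float)
        n = len(self.frames)
        if len(self.phases) != n or len(self.times_s) != n:
            raise ValueError("phases/times length must match frame count")
        for p in self.phases:
            if p not in PHASES:
                raise ValueError(f"unknown phase tag {p!r}")
        order = [PHASES.index(p) for p in self.phases]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("phase tags must be non-decreasing pre -> bleach -> post")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frames_in_phase(self, phase: str) -> np.ndarray:
        """All frames carrying the given phase tag, shape (k, H, W)."""
        idx = [i for i, p in enumerate(self.phases) if p == phase]
        return self.frames[idx]

    def times_in_phase(self, phase: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.phases) if p == phase]
        return self.times_s[idx]

    def with_frames(self, frames: np.ndarray) -> "ImageSeries":
        return dataclasses.replace(self, frames=np.asarray(frames))


@dataclass
class Roi:
    """A named region: polygon (vertex list) or oval (center + radii).

    Vertices/centers are ``(row, col)`` in pixel units, sub-pixel allowed.
    """

    name: str
    role: str
    kind: str  # "polygon" | "oval"
    vertices: np.ndarray | None = None      # (N, 2) for polygon
    center: tuple[float, float] | None = None
    radii: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}")
        if self.kind == "polygon":
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
                raise ValueError("polygon needs >= 3 (row, col) vertices")
        elif self.kind == "oval":
            if self.center is None or self.radii is None:
                raise ValueError("oval needs center and radii")
            if min(self.radii) <= 0:
                raise ValueError("oval radii must be positive")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def rasterize(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask on the given image shape.

        Ovals use the inclusive ellipse test at pixel centers,
        ``((r-cr)/rr)**2 + ((c-cc)/rc)**2 <= 1``; polygons are filled by
        scanline (pixel centers inside the polygon).
        """
        if self.kind == "oval":
            cr, cc = self.center
            rr, rc = self.radii
            r = np.arange(image_shape[0])[:, None]
            c = np.arange(image_shape[1])[None, :]
            mask = ((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2 <= 1.0
        else:
            mask = polygon2mask(image_shape, self.vertices)
        if not mask.any():
            raise ValueError(f"ROI {self.name!r} rasterizes to zero pixels")
        return mask


@dataclass
class RoiSet:
    rois: list[Roi] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def by_role(self, role: str) -> list[Roi]:
        return [r for r in self.rois if r.role == role]

    def get(self, name: str) -> Roi:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def mask(self, role: str, image_shape: tuple[int, int]) -> np.ndarray:
        """Union mask of all ROIs with the given role."""
        rois = self.by_role(role)
        if not rois:
            raise KeyError(f"no ROI with role {role!r}")
        m = np.zeros(image_shape, dtype=bool)
        for r in rois:
            m |= r.rasterize(image_shape)
        return m


def rasterize_roi(roi: Roi, image_shape: tuple[int, int]) -> np.ndarray:
    """Functional alias for :meth:`Roi.rasterize`."""
    return roi.rasterize(image_shape)


# ---------------------------------------------------------------------------
# serialization

def write_image_series(series: ImageSeries, tiff_path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a ``.yaml`` sidecar."""
    tiff_path = Path(tiff_path)
    data = np.clip(np.rint(series.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(tiff_path, data, photometric="minisblack")
    meta = {
        "channel": series.channel,
        "phases": list(series.phases),
        "times_s": [float(t) for t in series.times_s],
        "pixel_size_nm": float(series.pixel_size_nm),
        "n_frames": series.n_frames,
        "schema_version": SCHEMA_VERSION,
    }
    tiff_path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_image_series(tiff_path: str | Path,
                      metadata: dict | str | Path | None = None) -> ImageSeries:
    """Read a stack written by :func:`write_image_series`.

    ``metadata`` may be a dict, a path to a YAML sidecar, or None (the
    ``.yaml`` file next to the TIFF is used).
    """
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if isinstance(metadata, (str, Path)):
        metadata = yaml.safe_load(Path(metadata).read_text())
    elif metadata is None:
        metadata = yaml.safe_load(tiff_path.with_suffix(".yaml").read_text())
    if metadata.get("n_frames", len(frames)) != len(frames):
        raise ValueError("frame count does not match metadata")
    if "phases" not in metadata:
        raise ValueError("metadata missing per-frame phase tags")
    return ImageSeries(
        frames=frames,
        channel=metadata.get("channel", "unknown"),
        phases=tuple(metadata["phases"]),
        times_s=np.asarray(metadata["times_s"], dtype=float),
        pixel_size_nm=float(metadata.get("pixel_size_nm", 178.0)),
    )


def _roi_to_record(roi: Roi) -> dict:
    rec: dict = {"name": roi.name, "role": roi.role, "kind": roi.kind}
    if roi.kind == "polygon":
        rec["vertices"] = [[float(a), float(b)] for a, b in roi.vertices]
    else:
        rec["center"] = [float(roi.center[0]), float(roi.center[1])]
        rec["radii"] = [float(roi.radii[0]), float(roi.radii[1])]
    return rec


def write_roi_set(rois: RoiSet, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "rois": [_roi_to_record(r) for r in rois]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_roi_set(path: str | Path) -> RoiSet:
    doc = yaml.safe_load(Path(path).read_text())
    rois = []
    for rec in doc["rois"]:
        if rec["kind"] == "polygon":
            rois.append(Roi(rec["name"], rec["role"], "polygon",
                            vertices=np.asarray(rec["vertices"])))
        else:
            rois.append(Roi(rec["name"], rec["role"], "oval",
                            center=tuple(rec["center"]), radii=tuple(rec["radii"])))
    return RoiSet(rois)


def write_table(records: Iterable[dict] | "pandas.DataFrame", path: str | Path) -> None:
    """Write a measurement/screen table as CSV with a schema-version column."""
    import pandas as pd

    df = records if hasattr(records, "to_csv") else pd.DataFrame(list(records))
    df = df.copy()
    df["schema_version"] = SCHEMA_VERSION
    df.to_csv(path, index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)


def shoelace_area(vertices: Sequence[Sequence[float]]) -> float:
    """Polygon area by the shoelace formula (order-independent sign)."""
    v = np.asarray(vertices, dtype=float)
    r, c = v[:, 0], v[:, 1]
    return float(abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2)
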