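"""Multi-channel 3D+time movie container and OME-TIFF round-trip.

The in-memory layout is TCZYX (time, channel, z, y, x), 0-based voxel
indices, with physical coordinates in micrometres and the origin at the
centre of voxel (0, 0, 0).  Movies written by this package are OME-TIFF
with channel names and physical voxel sizes embedded; plain TIFFs can be
read only when the caller supplies the calibration explicitly — pixel
units are never silently assumed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, FormatError
from ._util import atomic_replace

__all__ = ["Movie", "read_movie", "write_movie"]


@dataclass
class Movie:
    """Voxel time series with physical calibration.

    Parameters
    ----------
    data
        Array of shape (T, C, Z, Y, X).
    channels
        Unique channel names, length C (e.g. ``("reporter", "prey")``).
    voxel_size
        (x, y, z) voxel edge lengths in µm.
    frame_interval
        Time between frames in seconds.
    t0_offset_min
        Acquisition start relative to infection/phagocytosis, minutes
        (metadata only; analysis time axes start at each track's origin).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    frame_interval: float
    t0_offset_min: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise FormatError(f"movie data must be 5D (TCZYX), got {self.data.ndim}D")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise FormatError(
                f"{len(self.channels)} channel names for {self.data.shape[1]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError(f"channel names not unique: {self.channels}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise CalibrationError(f"voxel sizes must be three positive values, got {vs}")
        self.voxel_size = vs
        if not self.frame_interval > 0:
            raise CalibrationError(f"frame interval must be > 0, got {self.frame_interval}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[2:])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise FormatError(f"movie has no channel {name!r}; channels are {self.channels}")

    def frame(self, t: int, channel: str | int) -> np.ndarray:
        """One 3D (Z, Y, X) volume."""
        c = channel if isinstance(channel, int) else self.channel_index(channel)
        return self.data[t, c]

    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def with_channel(self, name: str, stack: np.ndarray) -> "Movie":
        """Return a new movie with an extra channel appended (T, Z, Y, X)."""
        if name in self.channels:
            raise FormatError(f"channel {name!r} already present")
        if stack.shape != (self.n_frames, *self.shape_zyx):
            raise FormatError(
                f"extra channel shape {stack.shape} != {(self.n_frames, *self.shape_zyx)}"
            )
        data = np.concatenate([self.data, stack[:, None]], axis=1)
        return replace(self, data=data, channels=self.channels + (name,))


def write_movie(movie: Movie, path: str | os.PathLike) -> None:
    """Write an OME-TIFF (TCZYX) with voxel size, frame interval and channel names."""
    path = Path(path)
    sx, sy, sz = movie.voxel_size
    metadata = {
        "axes": "TCZYX",
        "PhysicalSizeX": sx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": sy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": sz,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": movie.frame_interval,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(movie.channels)},
    }
    tmp = atomic_replace(path)
    try:
        tifffile.imwrite(tmp, movie.data, ome=True, metadata=metadata)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _parse_ome(xml: str):
    """Pull voxel sizes, frame interval and channel names out of OME-XML."""
    from lxml import etree

    root = etree.fromstring(xml.encode())
    ns = {"ome": root.nsmap.get(None) or root.nsmap.get("ome", "")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None, None
    def fget(attr):
        v = pixels.get(attr)
        return float(v) if v is not None else None
    voxel = (fget("PhysicalSizeX"), fget("PhysicalSizeY"), fget("PhysicalSizeZ"))
    dt = fget("TimeIncrement")
    names = [c.get("Name") for c in pixels.findall("ome:Channel", ns)]
    if voxel[0] is None or voxel[1] is None or voxel[2] is None:
        voxel = None
    return voxel, dt, (names if names and all(names) else None)


def read_movie(
    path: str | os.PathLike,
    voxel_size: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
    channels: tuple[str, ...] | None = None,
) -> Movie:
    """Read a TIFF/OME-TIFF as a calibrated Movie.

    Calibration comes from the OME metadata; explicit arguments override it.
    A plain TIFF with neither embedded calibration nor overrides raises
    :class:`CalibrationError` rather than silently using pixel units.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper().replace("S", "C").replace("Q", "T")
        data = series.asarray()
        if tf.ome_metadata:
            ome_voxel, ome_dt, ome_names = _parse_ome(tf.ome_metadata)
        else:
            ome_voxel = ome_dt = ome_names = None

    # normalise axis order to TCZYX, inserting singleton axes for missing ones
    unknown = [a for a in axes if a not in "TCZYX"]
    if unknown:
        raise FormatError(f"ambiguous axes {series.axes!r} in {path}: cannot place {unknown}")
    if len(set(axes)) != len(axes):
        raise FormatError(f"repeated axes {series.axes!r} in {path}")
    arr = data
    cur = list(axes)
    for target in "TCZYX":
        if target not in cur:
            arr = arr[None]
            cur = [target] + cur
    perm = [cur.index(t) for t in "TCZYX"]
    arr = np.transpose(arr, perm)

    vs = voxel_size or ome_voxel
    if vs is None:
        raise CalibrationError(
            f"{path}: no voxel size in metadata and no override supplied"
        )
    dt = frame_interval if frame_interval is not None else ome_dt
    if dt is None:
        raise CalibrationError(
            f"{path}: no frame interval in metadata and no override supplied"
        )
    names = channels or ome_names
    if names is None:
        names = tuple(f"ch{i}" for i in range(arr.shape[1]))
    return Movie(arr, tuple(names), tuple(vs), float(dt))
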