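"""Ring-of-radius-6 angular intensity profiles over time (kymographs).

For each tracked phagosome and frame, the intensities of all pixels within
a ring of radius 6 pixels around the (sub-pixel) centroid are extracted in
the z-slice nearest the centroid.  Pixels are binned into 21 equal angular
sectors to visualise whether recruitment is uniform around the ring or
one-sided; the ring mean is the mean over all ring pixels (not the mean of
sector means).  A track's kymograph is a (frames x 21) matrix plus the
ring-mean trace, which is low-pass filtered, min-max normalised per track,
shifted so every track starts at time 0, and averaged across tracks.

Angle convention: sector k covers [2*pi*k/n, 2*pi*(k+1)/n); pixel angle is
atan2(dy, dx) with the image y-axis pointing down, measured from the
centroid.  "Within a ring" is interpreted by default as an annulus of
half-width 1.5 px centred at the stated radius (the membrane the reporter
decorates); a filled-disc mode is retained for parity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateGeometryError
from .movie import Movie
from .tracking import Track
from ._util import atomic_write

__all__ = [
    "RingSpec",
    "RingProfileSeries",
    "ring_pixels",
    "angular_profile",
    "build_kymograph",
    "lowpass",
    "normalize_track",
    "normalize_tracks",
    "align_and_average",
    "AlignedCohort",
]


@dataclass(frozen=True)
class RingSpec:
    """Geometry of the ring extraction."""

    radius: float = 6.0           # pixels
    half_width: float = 1.5       # annulus half-width, pixels
    n_sectors: int = 21
    mode: str = "annulus"         # "annulus" | "disc"
    plane_rule: str = "nearest"   # "nearest" | "maxproj3"

    def __post_init__(self):
        if not self.radius > 0:
            raise ConfigurationError(f"ring radius must be > 0, got {self.radius}")
        if self.n_sectors < 1:
            raise ConfigurationError(f"n_sectors must be >= 1, got {self.n_sectors}")
        if self.mode == "annulus" and not self.half_width < self.radius:
            raise ConfigurationError(
                f"annulus half-width ({self.half_width}) must be < radius ({self.radius})")
        if self.mode not in ("annulus", "disc"):
            raise ConfigurationError(f"unknown ring mode {self.mode!r}")
        if self.plane_rule not in ("nearest", "maxproj3"):
            raise ConfigurationError(f"unknown plane rule {self.plane_rule!r}")


def ring_pixels(
    center: tuple[float, float],
    spec: RingSpec,
    plane_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Pixels of the ring around a sub-pixel centre.

    Returns ``(ys, xs, angles, clipped)`` where angles are in [0, 2*pi)
    (atan2(dy, dx), y down) and ``clipped`` flags that part of the ring
    fell outside the plane and was dropped.
    """
    cx, cy = center
    h, w = plane_shape
    r_out = spec.radius + spec.half_width if spec.mode == "annulus" else spec.radius
    r_in = spec.radius - spec.half_width if spec.mode == "annulus" else 0.0
    x0, x1 = int(np.floor(cx - r_out)), int(np.ceil(cx + r_out))
    y0, y1 = int(np.floor(cy - r_out)), int(np.ceil(cy + r_out))
    clipped = x0 < 0 or y0 < 0 or x1 >= w or y1 >= h
    x0c, x1c = max(x0, 0), min(x1, w - 1)
    y0c, y1c = max(y0, 0), min(y1, h - 1)
    if x0c > x1c or y0c > y1c:
        return (np.empty(0, int), np.empty(0, int), np.empty(0), True)
    ys, xs = np.mgrid[y0c:y1c + 1, x0c:x1c + 1]
    dx = xs - cx
    dy = ys - cy
    r = np.hypot(dx, dy)
    keep = (r >= r_in) & (r <= r_out)
    ys, xs, dx, dy = ys[keep], xs[keep], dx[keep], dy[keep]
    angles = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    return ys, xs, angles, bool(clipped)


def angular_profile(
    plane: np.ndarray,
    center: tuple[float, float],
    spec: RingSpec,
) -> tuple[np.ndarray, float, dict]:
    """Sector means and ring mean at one centre.

    Empty sectors (possible near image borders) are filled by circular
    linear interpolation from the nearest populated neighbours and flagged.
    """
    ys, xs, angles, clipped = ring_pixels(center, spec, plane.shape)
    if len(ys) == 0:
        raise DegenerateGeometryError(f"empty ring at centre {center}")
    vals = np.asarray(plane)[ys, xs].astype(float)
    ring_mean = float(vals.mean())
    n = spec.n_sectors
    bins = np.minimum((angles / (2 * np.pi) * n).astype(int), n - 1)
    sums = np.bincount(bins, weights=vals, minlength=n)
    counts = np.bincount(bins, minlength=n)
    sector_means = np.full(n, np.nan)
    nz = counts > 0
    sector_means[nz] = sums[nz] / counts[nz]
    interpolated = ~nz
    if interpolated.any():
        if not nz.any():
            raise DegenerateGeometryError(f"no populated sectors at centre {center}")
        idx = np.arange(n)
        # circular interpolation: unwrap by tiling populated sectors
        good = idx[nz]
        for i in idx[~nz]:
            # nearest populated neighbours on the circle
            d = np.minimum(np.mod(good - i, n), np.mod(i - good, n))
            j = good[np.argmin(d)]
            sector_means[i] = sector_means[j]
    flags = {"clipped": clipped, "interpolated_sectors": interpolated}
    return sector_means, ring_mean, flags


@dataclass
class RingProfileSeries:
    """Per-frame angular profiles plus the ring-mean trace for one track."""

    track_id: int
    frames: np.ndarray                 # absolute frame indices
    sectors: np.ndarray                # (T, n_sectors)
    ring_mean: np.ndarray              # (T,)
    state: str = "raw"                 # raw | filtered | normalized | aligned
    frame_interval_s: float | None = None
    clipped: np.ndarray = None         # (T,) bool
    constant_flag: bool = False        # set when a constant track was normalised

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        self.sectors = np.atleast_2d(np.asarray(self.sectors, float))
        self.ring_mean = np.asarray(self.ring_mean, float)
        if self.clipped is None:
            self.clipped = np.zeros(len(self.frames), bool)
        if not (len(self.frames) == len(self.sectors) == len(self.ring_mean)
                == len(self.clipped)):
            raise ConfigurationError("series arrays have inconsistent lengths")

    @property
    def n_sectors(self) -> int:
        return self.sectors.shape[1]

    def times_min(self) -> np.ndarray:
        if self.frame_interval_s is None:
            raise ConfigurationError(f"track {self.track_id}: no frame interval set")
        return (self.frames - self.frames[0]) * self.frame_interval_s / 60.0

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.sectors,
                          columns=[f"sector_{k}" for k in range(self.n_sectors)])
        df.insert(0, "frame", self.frames)
        df["ring_mean"] = self.ring_mean
        with atomic_write(path) as fh:
            df.to_csv(fh, index=False)

    def to_heatmap_png(self, path, cmap: str = "viridis") -> None:
        """Kymograph heatmap (time on x, angular sector on y)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 2.5))
        im = ax.imshow(self.sectors.T, aspect="auto", origin="lower", cmap=cmap,
                       extent=[self.frames[0], self.frames[-1], 0, 360])
        ax.set_xlabel("frame")
        ax.set_ylabel("angle (deg)")
        fig.colorbar(im, ax=ax, label=f"intensity ({self.state})")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_kymograph(
    track: Track,
    movie: Movie,
    spec: RingSpec = RingSpec(),
    channel: str = "reporter",
) -> RingProfileSeries:
    """Raw kymograph for one track: one angular profile per track point.

    The plane is the z-slice nearest the centroid z (default), or a maximum
    projection over the three nearest slices in ``maxproj3`` mode.
    """
    c = movie.channel_index(channel)
    nz = movie.shape_zyx[0]
    rows, means, clipped = [], [], []
    for f, (x, y, z) in zip(track.frames, track.positions_vox):
        if not 0 <= f < movie.n_frames:
            raise IndexError(f"track {track.track_id}: frame {f} outside movie "
                             f"time range [0, {movie.n_frames})")
        zi = int(np.clip(round(z), 0, nz - 1))
        if spec.plane_rule == "maxproj3":
            z0, z1 = max(0, zi - 1), min(nz, zi + 2)
            plane = movie.data[f, c, z0:z1].max(axis=0)
        else:
            plane = movie.data[f, c, zi]
        sec, rm, flags = angular_profile(plane, (x, y), spec)
        rows.append(sec)
        means.append(rm)
        clipped.append(flags["clipped"])
    return RingProfileSeries(track.track_id, track.frames.copy(), np.array(rows),
                             np.array(means), state="raw",
                             frame_interval_s=movie.frame_interval,
                             clipped=np.array(clipped, bool))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with reflected ends, along axis 0."""
    half = window // 2
    pad = np.concatenate([x[half:0:-1], x, x[-2:-2 - half:-1]], axis=0)
    kernel = np.ones(window) / window
    if x.ndim == 1:
        return np.convolve(pad, kernel, mode="valid")
    return np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, pad)


def lowpass(series: RingProfileSeries, window: int = 5) -> RingProfileSeries:
    """Low-pass filter the kymograph in time (centred moving average).

    Applied independently to each sector column and to the ring mean;
    window must be odd; window 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 1, got {window}")
    if window > len(series.frames):
        raise ConfigurationError(
            f"window {window} exceeds series length {len(series.frames)}")
    if window == 1:
        return replace(series, state="filtered")
    return replace(series,
                   sectors=_moving_average(series.sectors, window),
                   ring_mean=_moving_average(series.ring_mean, window),
                   state="filtered")


def normalize_track(series: RingProfileSeries) -> RingProfileSeries:
    """Min-max normalise one track to [0, 1].

    A single minimum and maximum are taken jointly over all sector values
    and the ring mean of the track, then x' = (x - min) / (max - min) is
    applied to both.  Constant tracks map to zero and are flagged.
    """
    lo = min(series.sectors.min(), series.ring_mean.min())
    hi = max(series.sectors.max(), series.ring_mean.max())
    if hi <= lo:
        return replace(series, sectors=np.zeros_like(series.sectors),
                       ring_mean=np.zeros_like(series.ring_mean),
                       state="normalized", constant_flag=True)
    return replace(series, sectors=(series.sectors - lo) / (hi - lo),
                   ring_mean=(series.ring_mean - lo) / (hi - lo),
                   state="normalized")


def normalize_tracks(series_list: list[RingProfileSeries]) -> list[RingProfileSeries]:
    """Per-track min-max normalisation of a set of kymographs."""
    return [normalize_track(s) for s in series_list]


@dataclass
class AlignedCohort:
    """Per-time-index mean and s.d. over aligned tracks."""

    time_index: np.ndarray      # 0, 1, ... frames since each track's start
    mean: np.ndarray            # ring-mean average over contributing tracks
    sd: np.ndarray              # population s.d. (single track -> 0)
    n: np.ndarray               # contributing track count per time index

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_index": self.time_index, "mean": self.mean,
                           "sd": self.sd, "n": self.n})
        with atomic_write(path) as fh:
            df.to_csv(fh, index=False)


def align_and_average(
    series_list: list[RingProfileSeries],
) -> tuple[list[RingProfileSeries], AlignedCohort]:
    """Shift every track to start at time 0 and average the ring means.

    Tracks are ragged: at each aligned time index only the tracks that are
    still present contribute, and that count is reported.  The s.d. is the
    population standard deviation (a cohort of one track has s.d. 0).
    """
    if not series_list:
        raise ConfigurationError("align_and_average requires at least one series")
    aligned = [replace(s, frames=s.frames - s.frames[0], state="aligned")
               for s in series_list]
    max_len = max(len(s.frames) for s in aligned)
    mean = np.empty(max_len)
    sd = np.empty(max_len)
    n = np.empty(max_len, int)
    for t in range(max_len):
        vals = [s.ring_mean[t] for s in aligned if len(s.ring_mean) > t]
        v = np.asarray(vals)
        mean[t] = v.mean()
        sd[t] = v.std(ddof=0)
        n[t] = len(v)
    return aligned, AlignedCohort(np.arange(max_len), mean, sd, n)
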