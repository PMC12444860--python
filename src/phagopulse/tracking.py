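"""Phagosome identity over time: TrackMate XML ingestion and a built-in linker.

The built-in linker performs, per consecutive frame pair, an optimal
one-to-one assignment (Hungarian algorithm) minimising total Euclidean
displacement in µm — anisotropic voxels are honoured by converting to
physical coordinates before matching.  Links longer than
``max_displacement`` µm per frame of gap are forbidden; detections left
unmatched start new tracks; tracks unmatched for more than ``max_gap``
frames terminate.  Gap frames are filled by linear interpolation and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lxml import etree
from scipy.optimize import linear_sum_assignment

from .errors import CalibrationError, FormatError
from ._util import atomic_write

__all__ = ["Track", "link_detections", "read_trackmate", "write_trackmate", "tracks_to_csv"]

_FORBIDDEN = 1e9


@dataclass
class Track:
    """One phagosome's centroid sequence.

    positions are (N, 3) arrays of (x, y, z); ``positions_vox`` in voxel
    units, ``positions_um`` in µm.  ``gap_flags[i]`` marks interpolated
    (gap-filled) points.
    """

    track_id: int
    frames: np.ndarray
    positions_vox: np.ndarray
    positions_um: np.ndarray
    source: str = "builtin"       # "builtin" | "trackmate"
    gap_flags: np.ndarray = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        self.positions_vox = np.asarray(self.positions_vox, float).reshape(-1, 3)
        self.positions_um = np.asarray(self.positions_um, float).reshape(-1, 3)
        if self.gap_flags is None:
            self.gap_flags = np.zeros(len(self.frames), bool)
        self.gap_flags = np.asarray(self.gap_flags, bool)
        if not (len(self.frames) == len(self.positions_vox)
                == len(self.positions_um) == len(self.gap_flags)):
            raise FormatError("track arrays have inconsistent lengths")
        if np.any(np.diff(self.frames) <= 0):
            raise FormatError(f"track {self.track_id}: frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])


class _Builder:
    """Mutable track under construction."""

    __slots__ = ("tid", "frames", "pos_um", "pos_vox", "gaps", "last_frame")

    def __init__(self, tid, frame, um, vox):
        self.tid = tid
        self.frames = [frame]
        self.pos_um = [um]
        self.pos_vox = [vox]
        self.gaps = [False]
        self.last_frame = frame

    def extend(self, frame, um, vox):
        gap = frame - self.last_frame
        if gap > 1:  # interpolate missed frames
            base_um, base_vox = self.pos_um[-1], self.pos_vox[-1]
            for g in range(1, gap):
                w = g / gap
                self.frames.append(self.last_frame + g)
                self.pos_um.append(base_um * (1 - w) + um * w)
                self.pos_vox.append(base_vox * (1 - w) + vox * w)
                self.gaps.append(True)
        self.frames.append(frame)
        self.pos_um.append(um)
        self.pos_vox.append(vox)
        self.gaps.append(False)
        self.last_frame = frame


def link_detections(
    centroids_by_frame: dict[int, np.ndarray],
    voxel_size: tuple[float, float, float],
    max_displacement: float = 2.0,
    max_gap: int = 2,
) -> list[Track]:
    """Link per-frame (x, y, z) voxel centroids into tracks.

    Parameters
    ----------
    centroids_by_frame
        Mapping frame index -> (n, 3) array of (x, y, z) centroids in voxels.
    voxel_size
        (x, y, z) µm per voxel; matching costs are Euclidean distances in µm.
    max_displacement
        Maximum allowed µm of movement per frame of time gap.
    max_gap
        Tracks survive this many consecutive undetected frames.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    scale = np.asarray(voxel_size, float)
    frames = sorted(centroids_by_frame)
    active: list[_Builder] = []
    finished: list[_Builder] = []
    next_id = 0
    for f in frames:
        dets_vox = np.asarray(centroids_by_frame[f], float).reshape(-1, 3)
        dets_um = dets_vox * scale
        # retire tracks that exceeded the gap allowance
        still = []
        for b in active:
            (finished if f - b.last_frame > max_gap + 1 else still).append(b)
        active = still
        if len(dets_um) and len(active):
            cost = np.full((len(active), len(dets_um)), _FORBIDDEN)
            for i, b in enumerate(active):
                gap = f - b.last_frame
                d = np.linalg.norm(dets_um - b.pos_um[-1], axis=1)
                allowed = d <= max_displacement * gap
                cost[i, allowed] = d[allowed]
            rows, cols = linear_sum_assignment(cost)
            matched_dets = set()
            matched_tracks = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _FORBIDDEN:
                    active[i].extend(f, dets_um[j], dets_vox[j])
                    matched_dets.add(j)
                    matched_tracks.add(i)
        else:
            matched_dets, matched_tracks = set(), set()
        for j in range(len(dets_um)):
            if j not in matched_dets:
                active.append(_Builder(next_id, f, dets_um[j], dets_vox[j]))
                next_id += 1
    finished.extend(active)
    finished.sort(key=lambda b: b.tid)
    return [
        Track(b.tid, np.array(b.frames), np.array(b.pos_vox), np.array(b.pos_um),
              source="builtin", gap_flags=np.array(b.gaps))
        for b in finished
    ]


# --------------------------------------------------------------------------
# TrackMate XML
# --------------------------------------------------------------------------

def read_trackmate(path) -> list[Track]:
    """Read a TrackMate XML file (Spots + Tracks) into Track objects.

    Spot positions are in µm (TrackMate convention); voxel coordinates are
    derived from the pixel sizes in the Settings/ImageData element, which
    must be present.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FormatError(f"malformed TrackMate XML {path}: {e}") from e
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise FormatError(f"{path}: missing element /TrackMate/Model")
    allspots = model.find("AllSpots")
    alltracks = model.find("AllTracks")
    if allspots is None or alltracks is None:
        raise FormatError(f"{path}: missing /TrackMate/Model/AllSpots or AllTracks")
    imagedata = root.find("Settings/ImageData")
    cal = {}
    for attr in ("pixelwidth", "pixelheight", "voxeldepth"):
        v = imagedata.get(attr) if imagedata is not None else None
        if v is None:
            raise CalibrationError(
                f"{path}: missing calibration attribute {attr!r} in Settings/ImageData")
        cal[attr] = float(v)
    scale = np.array([cal["pixelwidth"], cal["pixelheight"], cal["voxeldepth"]])

    spots = {}
    for spot in allspots.iter("Spot"):
        sid = int(spot.get("ID"))
        spots[sid] = (
            int(float(spot.get("FRAME"))),
            np.array([float(spot.get("POSITION_X")), float(spot.get("POSITION_Y")),
                      float(spot.get("POSITION_Z"))]),
        )
    tracks = []
    for tr in alltracks.iter("Track"):
        tid = int(tr.get("TRACK_ID"))
        sids = set()
        for edge in tr.iter("Edge"):
            sids.add(int(edge.get("SPOT_SOURCE_ID")))
            sids.add(int(edge.get("SPOT_TARGET_ID")))
        pts = sorted((spots[s][0], spots[s][1]) for s in sids)
        frames = np.array([f for f, _ in pts])
        um = np.array([p for _, p in pts])
        tracks.append(Track(tid, frames, um / scale, um, source="trackmate"))
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def write_trackmate(tracks: list[Track], path, voxel_size: tuple[float, float, float]) -> None:
    """Write a minimal TrackMate-compatible XML (enough for read_trackmate)."""
    root = etree.Element("TrackMate", version="7.0.0")
    model = etree.SubElement(root, "Model", spatialunits="micron", timeunits="sec")
    allspots = etree.SubElement(model, "AllSpots")
    alltracks = etree.SubElement(model, "AllTracks")
    settings = etree.SubElement(root, "Settings")
    etree.SubElement(settings, "ImageData",
                     pixelwidth=str(voxel_size[0]), pixelheight=str(voxel_size[1]),
                     voxeldepth=str(voxel_size[2]))
    by_frame: dict[int, etree._Element] = {}
    sid = 0
    for tr in tracks:
        ids = []
        for f, um in zip(tr.frames, tr.positions_um):
            frame_el = by_frame.get(int(f))
            if frame_el is None:
                frame_el = etree.SubElement(allspots, "SpotsInFrame", frame=str(int(f)))
                by_frame[int(f)] = frame_el
            etree.SubElement(frame_el, "Spot", ID=str(sid), FRAME=str(int(f)),
                             POSITION_X=repr(float(um[0])), POSITION_Y=repr(float(um[1])),
                             POSITION_Z=repr(float(um[2])))
            ids.append(sid)
            sid += 1
        tr_el = etree.SubElement(alltracks, "Track", TRACK_ID=str(tr.track_id))
        for a, b in zip(ids, ids[1:]):
            etree.SubElement(tr_el, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b))
        if len(ids) == 1:  # single-spot track still needs its spot discoverable
            etree.SubElement(tr_el, "Edge", SPOT_SOURCE_ID=str(ids[0]),
                             SPOT_TARGET_ID=str(ids[0]))
    with atomic_write(path, "wb") as fh:
        fh.write(etree.tostring(root, pretty_print=True, xml_declaration=True,
                                encoding="UTF-8"))


def tracks_to_csv(tracks: list[Track], path, frame_interval_s: float) -> None:
    rows = []
    for tr in tracks:
        for f, vox, um, gap in zip(tr.frames, tr.positions_vox, tr.positions_um, tr.gap_flags):
            rows.append({
                "track_id": tr.track_id, "frame": int(f),
                "t_seconds": float(f) * frame_interval_s,
                "x_um": um[0], "y_um": um[1], "z_um": um[2],
                "x_vox": vox[0], "y_vox": vox[1], "z_vox": vox[2],
                "gap_flag": bool(gap), "source": tr.source,
            })
    df = pd.DataFrame(rows)
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)
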