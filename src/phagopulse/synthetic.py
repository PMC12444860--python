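"""Ground-truthed synthetic 4D movies of bacteria-bearing neutrophil phagosomes.

Each simulated field of view holds one neutrophil (a dim cytosolic body in
the reporter channel) containing 1–25 phagosomes.  A phagosome is rendered
as a spherical membrane shell with Gaussian radial cross-section in the
reporter channel and a solid spherical bacterium (prey) at its centre in
the prey channel.  The reporter intensity on the shell follows the
membrane-recruitment kinetics observed in vivo: a surge as the phagosome
closes at engulfment, an exponential fade, then optional scheduled pulses
(re-surges), each of which may transiently open a pore in the shell.

The prey channel emulates a pH reporter (pHrodo-style): bright while the
bacterium is extracellular or the phagosome is open to the outside, dimmed
while the phagosome is sealed and alkaline.

Every stochastic choice is drawn from streams keyed to ``SimConfig.seed``,
so identical configurations reproduce bit-identical movies and logs, and
the full event schedule is returned as a :class:`GroundTruthLog` for use
as a test oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import ConfigurationError, FormatError, GenerationError
from .movie import Movie
from ._util import rng_stream, atomic_write

__all__ = [
    "SimConfig",
    "PhagosomeTruth",
    "NeutrophilTruth",
    "GroundTruthLog",
    "plan_cohort",
    "iter_movies",
    "simulate_cohort",
    "truth_tracks",
    "add_dye_channel",
]

#: categorical outcomes of a pulse (what happens to the prey)
OUTCOMES = ("recaptured-same-cell", "released", "transferred")


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the cohort study conditions.

    The per-phagosome pulse probability, pulses-per-pulsing-phagosome
    distribution, first-pulse latency distribution and leak probability
    default to values calibrated against the in vivo / human-neutrophil
    cohort estimates (12.4% pulsing, mode ~4 pulses with support 1–18,
    latency mean 10.5 min with s.d. 12.49 min, 20.1% dye-positive).
    """

    # geometry / acquisition
    image_shape_xy: int | None = None      # square xy size in px; None → auto from layout
    n_z: int = 7
    voxel_size_xy: float = 0.33            # µm per px (x and y)
    voxel_size_z: float = 1.5              # µm per z-step
    frame_interval_s: float = 30.0
    n_frames: int = 180

    # cohort structure
    n_neutrophils: int = 1
    phagosomes_min: int = 1
    phagosomes_max: int = 25

    # pulsing schedule
    p_pulse: float = 0.124                 # P(phagosome pulses at least once)
    pulse_count_lambda: float = 3.0        # n_pulses = min(1 + Poisson(λ), pulse_count_max)
    pulse_count_max: int = 18
    pulse_count_fixed: int | None = None   # exact pulses per pulsing phagosome (overrides)
    latency_mean_min: float = 10.5         # first-pulse latency (lognormal, matched moments)
    latency_sd_min: float = 12.49
    interpulse_mean_min: float = 8.0       # extra wait beyond the minimum gap
    interpulse_min_gap_min: float = 2.0
    engulfment_max_frame: int = 0          # engulfment uniform on [0, this]

    # pore / openness / dye
    open_interval_frames: int = 4          # pore stays open this many frames per pulse
    pore_angle_deg: float = 60.0
    p_leak: float = 0.201                  # P(phagosome persistently unsealed)
    p_recapture: float = 29 / 31           # outcome probabilities per pulse
    p_release: float = 1 / 31
    p_transfer: float = 1 / 31

    # reporter kinetics and optics
    surge_amplitude: float = 100.0
    pulse_amplitude_rel: float = 0.8
    fade_tau_s: float = 45.0
    pulse_rise_frames: int = 2
    shell_radius_um: float = 2.0           # phagosome membrane radius
    shell_sigma_um: float = 0.4            # Gaussian cross-section of the shell
    prey_radius_um: float = 1.0            # S. aureus / bead scale
    cell_intensity: float = 15.0           # cytosolic reporter level (low seg. level)
    prey_intensity: float = 160.0
    prey_dim_factor: float = 0.5           # pH dimming while sealed/alkaline
    dye_intensity: float = 100.0
    background: float = 10.0

    # noise: Var = shot_noise_gain * signal + read_noise_sd²
    read_noise_sd: float = 0.0
    shot_noise_gain: float = 0.0

    # motion
    drift_px_per_frame: float = 0.0

    seed: int = 0

    def __post_init__(self):
        for name in ("p_pulse", "p_leak", "p_recapture", "p_release", "p_transfer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if abs(self.p_recapture + self.p_release + self.p_transfer - 1.0) > 1e-9:
            raise ConfigurationError("pulse outcome probabilities must sum to 1")
        for name in ("voxel_size_xy", "voxel_size_z", "frame_interval_s", "fade_tau_s",
                     "shell_radius_um", "shell_sigma_um", "prey_radius_um",
                     "latency_mean_min", "latency_sd_min"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if not 1 <= self.phagosomes_min <= self.phagosomes_max:
            raise ConfigurationError(
                f"invalid phagosome count range [{self.phagosomes_min}, {self.phagosomes_max}]"
            )
        if self.phagosomes_max > 25:
            raise ConfigurationError("phagosomes_max above supported range (25)")
        if not 1 <= self.pulse_count_max <= 18:
            raise ConfigurationError("pulse_count_max must lie in [1, 18]")
        if self.pulse_count_fixed is not None and not 1 <= self.pulse_count_fixed <= 18:
            raise ConfigurationError("pulse_count_fixed must lie in [1, 18]")
        if self.read_noise_sd < 0 or self.shot_noise_gain < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    @property
    def snr(self) -> float:
        """Closure-surge amplitude over additive read-noise s.d. (inf if noise-free)."""
        return math.inf if self.read_noise_sd == 0 else self.surge_amplitude / self.read_noise_sd

    @classmethod
    def with_snr(cls, snr: float, shot_noise_gain: float = 1.0, **kwargs) -> "SimConfig":
        """Config with additive noise set so surge_amplitude / read_sd == snr."""
        cfg = cls(**kwargs)
        return replace(cfg, read_noise_sd=cfg.surge_amplitude / float(snr),
                       shot_noise_gain=shot_noise_gain)


@dataclass
class PhagosomeTruth:
    """Ground-truth schedule for one phagosome (the test oracle)."""

    phagosome_id: int
    neutrophil_id: int
    movie_index: int
    center_xyz_vox: tuple[float, float, float]
    drift_xyz_vox_per_frame: tuple[float, float, float]
    engulfment_frame: int
    pulse_onset_frames: list[int] = field(default_factory=list)
    pulse_peak_frames: list[int] = field(default_factory=list)
    open_intervals: list[tuple[int, int]] = field(default_factory=list)  # [start, end)
    pulse_outcomes: list[str] = field(default_factory=list)
    pore_angle_rad: float = 0.0
    leaky: bool = False
    dye_positive: bool = False

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.pulse_onset_frames, self.pulse_onset_frames[1:])):
            raise ConfigurationError("pulse frames must be strictly increasing")
        iv = sorted(self.open_intervals)
        if any(b[0] < a[1] for a, b in zip(iv, iv[1:])):
            raise ConfigurationError("open intervals must not overlap")

    @property
    def pulsing(self) -> bool:
        return len(self.pulse_onset_frames) > 0

    def first_pulse_latency_min(self, frame_interval_s: float) -> float | None:
        if not self.pulsing:
            return None
        return (self.pulse_onset_frames[0] - self.engulfment_frame) * frame_interval_s / 60.0

    def position_at(self, frame: int) -> np.ndarray:
        c = np.asarray(self.center_xyz_vox, float)
        d = np.asarray(self.drift_xyz_vox_per_frame, float)
        return c + d * frame

    def is_open(self, frame: int) -> bool:
        return any(a <= frame < b for a, b in self.open_intervals)


@dataclass
class NeutrophilTruth:
    neutrophil_id: int
    movie_index: int
    n_bacteria: int
    phagosome_ids: list[int]
    cell_center_xy_vox: tuple[float, float]
    cell_radius_vox: float


@dataclass
class GroundTruthLog:
    """Full event schedule of a simulated cohort."""

    config: SimConfig
    neutrophils: list[NeutrophilTruth]
    phagosomes: list[PhagosomeTruth]
    dye_add_frame: int | None = None

    def phagosomes_of(self, neutrophil_id: int) -> list[PhagosomeTruth]:
        return [p for p in self.phagosomes if p.neutrophil_id == neutrophil_id]

    def phagosomes_in_movie(self, movie_index: int) -> list[PhagosomeTruth]:
        return [p for p in self.phagosomes if p.movie_index == movie_index]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "dye_add_frame": self.dye_add_frame,
            "neutrophils": [asdict(n) for n in self.neutrophils],
            "phagosomes": [asdict(p) for p in self.phagosomes],
        }
        with atomic_write(path) as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLog":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = SimConfig(**payload["config"])
        neuts = [NeutrophilTruth(**{**n, "cell_center_xy_vox": tuple(n["cell_center_xy_vox"])})
                 for n in payload["neutrophils"]]
        phags = []
        for p in payload["phagosomes"]:
            p = dict(p)
            p["center_xyz_vox"] = tuple(p["center_xyz_vox"])
            p["drift_xyz_vox_per_frame"] = tuple(p["drift_xyz_vox_per_frame"])
            p["open_intervals"] = [tuple(iv) for iv in p["open_intervals"]]
            phags.append(PhagosomeTruth(**p))
        return cls(cfg, neuts, phags, payload.get("dye_add_frame"))


# --------------------------------------------------------------------------
# event scheduling
# --------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and s.d."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _schedule_pulses(cfg: SimConfig, rng: np.random.Generator, engulfment: int) -> list[int]:
    """Pulse onset frames for one pulsing phagosome (may be truncated by movie end)."""
    mu, sigma = _lognormal_params(cfg.latency_mean_min, cfg.latency_sd_min)
    latency_min = rng.lognormal(mu, sigma)
    if cfg.pulse_count_fixed is not None:
        n_pulses = cfg.pulse_count_fixed
    else:
        n_pulses = min(1 + rng.poisson(cfg.pulse_count_lambda), cfg.pulse_count_max)
    dt_min = cfg.frame_interval_s / 60.0
    onsets = []
    t = engulfment + latency_min / dt_min
    for _ in range(n_pulses):
        f = int(round(t))
        if f >= cfg.n_frames - 1:
            break
        if onsets and f <= onsets[-1]:
            f = onsets[-1] + 1
            if f >= cfg.n_frames - 1:
                break
        onsets.append(f)
        wait_min = cfg.interpulse_min_gap_min + rng.exponential(cfg.interpulse_mean_min)
        t = f + wait_min / dt_min
    return onsets


def _grid_layout(n: int, pitch: int, margin: int) -> tuple[np.ndarray, int]:
    """(x, y) centres for n phagosomes on a square grid, and the image xy size."""
    g = math.ceil(math.sqrt(n))
    size = g * pitch + 2 * margin
    coords = []
    for k in range(n):
        i, j = divmod(k, g)
        coords.append((margin + pitch // 2 + j * pitch, margin + pitch // 2 + i * pitch))
    return np.asarray(coords, float), size


def plan_cohort(cfg: SimConfig) -> GroundTruthLog:
    """Draw the full event schedule (no rendering)."""
    rng = rng_stream(cfg.seed, 1)
    shell_px = cfg.shell_radius_um / cfg.voxel_size_xy
    pitch = int(math.ceil(2 * (shell_px + 3 * cfg.shell_sigma_um / cfg.voxel_size_xy) + 6))
    margin = int(math.ceil(shell_px + 4))
    neutrophils: list[NeutrophilTruth] = []
    phagosomes: list[PhagosomeTruth] = []
    pid = 0
    zc = cfg.n_z // 2
    for nid in range(cfg.n_neutrophils):
        n_ph = int(rng.integers(cfg.phagosomes_min, cfg.phagosomes_max + 1))
        coords, base_size = _grid_layout(n_ph, pitch, margin)
        # size the field of view so the cell encloses every shell with margin
        # and extracellular space remains outside the cell everywhere
        grid_c = base_size / 2.0
        half_extent = float(np.max(np.hypot(coords[:, 0] - grid_c, coords[:, 1] - grid_c)))
        cell_r = half_extent + shell_px + 4.0
        size = int(2 * math.ceil(cell_r + 6.0))
        if cfg.image_shape_xy is not None:
            if cfg.image_shape_xy < size:
                raise GenerationError(
                    f"neutrophil {nid}: {n_ph} phagosomes need {size} px, "
                    f"image_shape_xy={cfg.image_shape_xy}"
                )
            size = cfg.image_shape_xy
        coords = coords + (size / 2.0 - grid_c)
        center = (size / 2.0, size / 2.0)
        ids = []
        drift = (cfg.drift_px_per_frame, cfg.drift_px_per_frame, 0.0)
        for (x, y) in coords:
            engulf = int(rng.integers(0, cfg.engulfment_max_frame + 1)) \
                if cfg.engulfment_max_frame > 0 else 0
            pulsing = rng.random() < cfg.p_pulse
            onsets = _schedule_pulses(cfg, rng, engulf) if pulsing else []
            peaks = [o + cfg.pulse_rise_frames for o in onsets]
            outcomes = list(rng.choice(OUTCOMES, size=len(onsets),
                                       p=[cfg.p_recapture, cfg.p_release, cfg.p_transfer]))
            opens = []
            for o in onsets:
                a, b = o, min(o + cfg.open_interval_frames, cfg.n_frames)
                if opens and a < opens[-1][1]:
                    a = opens[-1][1]
                if a < b:
                    opens.append((a, b))
            leaky = rng.random() < cfg.p_leak
            if leaky:
                # persistently unsealed: open from shortly after engulfment onward
                start = min(engulf + 2, cfg.n_frames - 1)
                opens = _merge_intervals(opens + [(start, cfg.n_frames)])
            phagosomes.append(PhagosomeTruth(
                phagosome_id=pid, neutrophil_id=nid, movie_index=nid,
                center_xyz_vox=(float(x), float(y), float(zc)),
                drift_xyz_vox_per_frame=drift,
                engulfment_frame=engulf,
                pulse_onset_frames=onsets, pulse_peak_frames=peaks,
                open_intervals=opens, pulse_outcomes=[str(o) for o in outcomes],
                pore_angle_rad=float(rng.uniform(0, 2 * math.pi)),
                leaky=bool(leaky),
            ))
            ids.append(pid)
            pid += 1
        neutrophils.append(NeutrophilTruth(
            neutrophil_id=nid, movie_index=nid, n_bacteria=n_ph,
            phagosome_ids=ids, cell_center_xy_vox=center, cell_radius_vox=cell_r,
        ))
    return GroundTruthLog(cfg, neutrophils, phagosomes)


def _merge_intervals(intervals):
    out = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return [tuple(iv) for iv in out]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def reporter_amplitude_trace(cfg: SimConfig, truth: PhagosomeTruth) -> np.ndarray:
    """Noise-free shell amplitude per frame: closure surge + scheduled pulses.

    Each event is a linear rise over ``pulse_rise_frames`` followed by an
    exponential decay with time constant ``fade_tau_s``; events superpose.
    """
    t = np.arange(cfg.n_frames, dtype=float)
    tau_frames = cfg.fade_tau_s / cfg.frame_interval_s
    out = np.zeros(cfg.n_frames)
    events = [(truth.engulfment_frame, cfg.surge_amplitude)]
    events += [(f, cfg.surge_amplitude * cfg.pulse_amplitude_rel)
               for f in truth.pulse_onset_frames]
    for onset, amp in events:
        rel = t - onset
        rise = np.clip(rel / cfg.pulse_rise_frames, 0.0, 1.0)
        decay = np.where(rel > cfg.pulse_rise_frames,
                         np.exp(-(rel - cfg.pulse_rise_frames) / tau_frames), 1.0)
        out += np.where(rel >= 0, amp * rise * decay, 0.0)
    return out


def _shell_patch(cfg: SimConfig, shape_zyx, pos_xyz, pore_angle, open_now):
    """Render one shell into a local patch; returns (patch, (z0,y0,x0) offset)."""
    nz, ny, nx = shape_zyx
    sx = sy = cfg.voxel_size_xy
    sz = cfg.voxel_size_z
    r_um = cfg.shell_radius_um + 3 * cfg.shell_sigma_um
    rx = int(math.ceil(r_um / sx))
    rz = int(math.ceil(r_um / sz))
    x0, y0, z0 = pos_xyz
    xi0, xi1 = max(0, int(x0) - rx), min(nx, int(x0) + rx + 2)
    yi0, yi1 = max(0, int(y0) - rx), min(ny, int(y0) + rx + 2)
    zi0, zi1 = max(0, int(z0) - rz), min(nz, int(z0) + rz + 2)
    if xi0 >= xi1 or yi0 >= yi1 or zi0 >= zi1:
        raise GenerationError(f"phagosome at {pos_xyz} lies outside image bounds {shape_zyx}")
    zz, yy, xx = np.meshgrid(np.arange(zi0, zi1), np.arange(yi0, yi1),
                             np.arange(xi0, xi1), indexing="ij")
    dx = (xx - x0) * sx
    dy = (yy - y0) * sy
    dz = (zz - z0) * sz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    patch = np.exp(-((d - cfg.shell_radius_um) ** 2) / (2 * cfg.shell_sigma_um ** 2))
    if open_now and cfg.pore_angle_deg > 0:
        ang = np.mod(np.arctan2(dy, dx), 2 * math.pi)
        width = math.radians(cfg.pore_angle_deg)
        in_pore = np.mod(ang - pore_angle, 2 * math.pi) < width
        patch = np.where(in_pore, 0.0, patch)
    return patch, (zi0, yi0, xi0), (dx, dy, dz, d)


def _render_movie(cfg: SimConfig, neut: NeutrophilTruth,
                  phags: list[PhagosomeTruth], rng: np.random.Generator) -> Movie:
    size = int(2 * neut.cell_center_xy_vox[0])
    shape = (cfg.n_z, size, size)
    T = cfg.n_frames
    reporter = np.full((T, *shape), cfg.background, dtype=np.float32)
    prey = np.full((T, *shape), cfg.background, dtype=np.float32)

    # neutrophil body: soft-edged disc through the central z slices
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - neut.cell_center_xy_vox[0], yy - neut.cell_center_xy_vox[1])
    edge = 2.0
    cell2d = np.clip((neut.cell_radius_vox - r) / edge, 0.0, 1.0).astype(np.float32)
    zc = cfg.n_z // 2
    z_extent = max(1, cfg.n_z // 2 - 1)
    cell3d = np.zeros(shape, np.float32)
    for z in range(cfg.n_z):
        if abs(z - zc) <= z_extent:
            cell3d[z] = cell2d
    reporter += cfg.cell_intensity * cell3d[None]

    amp = {p.phagosome_id: reporter_amplitude_trace(cfg, p) for p in phags}
    prey_r = cfg.prey_radius_um
    for p in phags:
        a = amp[p.phagosome_id]
        open_flags = np.array([p.is_open(t) for t in range(T)])
        brights = np.where(np.arange(T) >= p.engulfment_frame,
                           np.where(open_flags, 1.0, cfg.prey_dim_factor), 1.0)
        static = np.allclose(p.drift_xyz_vox_per_frame, 0.0)
        if static:
            # one patch per (closed, open) state, broadcast over frames
            patch_c, (z0, y0, x0), (dx, dy, dz, d) = _shell_patch(
                cfg, shape, p.position_at(0), p.pore_angle_rad, False)
            patch_o, _, _ = _shell_patch(
                cfg, shape, p.position_at(0), p.pore_angle_rad, True)
            sl = np.s_[:, z0:z0 + patch_c.shape[0], y0:y0 + patch_c.shape[1],
                       x0:x0 + patch_c.shape[2]]
            stack = np.where(open_flags[:, None, None, None],
                             patch_o[None], patch_c[None])
            reporter[sl] += (a[:, None, None, None] * stack).astype(np.float32)
            prey_mask = d <= prey_r
            if prey_mask.any():
                target = (cfg.background + cfg.prey_intensity * brights).astype(np.float32)
                sub = prey[sl]
                sub[:, prey_mask] = np.maximum(sub[:, prey_mask], target[:, None])
                prey[sl] = sub
        else:
            for t in range(T):
                patch, (z0, y0, x0), (dx, dy, dz, d) = _shell_patch(
                    cfg, shape, p.position_at(t), p.pore_angle_rad, open_flags[t])
                if a[t] > 1e-12:
                    reporter[t, z0:z0 + patch.shape[0], y0:y0 + patch.shape[1],
                             x0:x0 + patch.shape[2]] += (a[t] * patch).astype(np.float32)
                prey_mask = d <= prey_r
                if prey_mask.any():
                    sub = prey[t, z0:z0 + patch.shape[0], y0:y0 + patch.shape[1],
                               x0:x0 + patch.shape[2]]
                    np.maximum(sub, np.float32(cfg.background
                                               + cfg.prey_intensity * brights[t]),
                               out=sub, where=prey_mask)

    data = np.stack([reporter, prey], axis=1)
    data = _apply_noise(cfg, data, rng)
    return Movie(data, ("reporter", "prey"),
                 (cfg.voxel_size_xy, cfg.voxel_size_xy, cfg.voxel_size_z),
                 cfg.frame_interval_s)


def _apply_noise(cfg: SimConfig, data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Signal-dependent (shot-like) plus additive Gaussian read noise."""
    if cfg.read_noise_sd == 0 and cfg.shot_noise_gain == 0:
        return data
    var = (cfg.shot_noise_gain * np.clip(data, 0, None)
           + np.float32(cfg.read_noise_sd) ** 2).astype(np.float32)
    noise = rng.standard_normal(data.shape, dtype=np.float32)
    return data + np.sqrt(var) * noise


def iter_movies(log: GroundTruthLog):
    """Render the cohort lazily, one movie (field of view) at a time.

    Yields exactly the movies :func:`simulate_cohort` would return, in
    order, without holding the whole cohort in memory.
    """
    cfg = log.config
    for neut in log.neutrophils:
        rng = rng_stream(cfg.seed, 2, neut.neutrophil_id)
        yield _render_movie(cfg, neut, log.phagosomes_of(neut.neutrophil_id), rng)


def simulate_cohort(cfg: SimConfig) -> tuple[list[Movie], GroundTruthLog]:
    """Simulate one movie per neutrophil plus the ground-truth event log."""
    log = plan_cohort(cfg)
    return list(iter_movies(log)), log


def truth_tracks(log: GroundTruthLog, movie_index: int):
    """Ground-truth tracks (one per phagosome) for oracle-driven profiling.

    Bypasses detection/linking: each track follows the scheduled centroid
    path from the engulfment frame to the end of the movie.
    """
    from .tracking import Track

    cfg = log.config
    scale = np.array([cfg.voxel_size_xy, cfg.voxel_size_xy, cfg.voxel_size_z])
    out = []
    for p in log.phagosomes_in_movie(movie_index):
        frames = np.arange(p.engulfment_frame, cfg.n_frames)
        vox = np.stack([p.position_at(t) for t in frames])
        out.append(Track(p.phagosome_id, frames, vox, vox * scale, source="builtin"))
    return out


def add_dye_channel(movie: Movie, log: GroundTruthLog, dye_add_frame: int,
                    movie_index: int = 0) -> Movie:
    """Append a fluid-phase dye channel (Lucifer Yellow emulation).

    Extracellular voxels carry dye from ``dye_add_frame`` onward; the
    interior of a phagosome fills with dye only if it is flagged leaky and
    only during/after an open interval that overlaps the post-addition
    period.  Updates ``log`` in place (``dye_add_frame``, per-phagosome
    ``dye_positive`` flags).
    """
    if "reporter" not in movie.channels or "prey" not in movie.channels:
        raise FormatError(f"movie channels {movie.channels} lack reporter/prey layout")
    if not 0 <= dye_add_frame < movie.n_frames:
        raise ConfigurationError(
            f"dye_add_frame {dye_add_frame} outside movie duration {movie.n_frames}")
    cfg = log.config
    neut = next(n for n in log.neutrophils if n.movie_index == movie_index)
    nz, ny, nx = movie.shape_zyx
    T = movie.n_frames

    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - neut.cell_center_xy_vox[0], yy - neut.cell_center_xy_vox[1])
    zc = cfg.n_z // 2
    z_extent = max(1, cfg.n_z // 2 - 1)
    inside_cell2d = r <= neut.cell_radius_vox
    extra3d = np.ones((nz, ny, nx), bool)
    for z in range(nz):
        if abs(z - zc) <= z_extent:
            extra3d[z] = ~inside_cell2d

    dye = np.full((T, nz, ny, nx), cfg.background, dtype=np.float32)
    dye[dye_add_frame:] += np.where(extra3d, np.float32(cfg.dye_intensity), np.float32(0))

    zz3, yy3, xx3 = np.mgrid[0:nz, 0:ny, 0:nx]
    for p in log.phagosomes_in_movie(movie_index):
        p.dye_positive = False
        if not p.leaky:
            continue
        # first open interval overlapping [dye_add_frame, end)
        start = None
        for a, b in p.open_intervals:
            if b > dye_add_frame:
                start = max(a, dye_add_frame)
                break
        if start is None:
            continue
        p.dye_positive = True
        x0, y0, z0 = p.center_xyz_vox
        dx = (xx3 - x0) * cfg.voxel_size_xy
        dy = (yy3 - y0) * cfg.voxel_size_xy
        dz = (zz3 - z0) * cfg.voxel_size_z
        interior = dx * dx + dy * dy + dz * dz <= cfg.shell_radius_um ** 2
        # one-frame fill ramp, then full dye level
        for t in range(start, T):
            frac = min(1.0, (t - start + 1) / 2.0)
            dye[t][interior] += np.float32(cfg.dye_intensity * frac)

    rng = rng_stream(cfg.seed, 3, movie_index)
    dye = _apply_noise(cfg, dye, rng)
    out = movie.with_channel("dye", dye)
    log.dye_add_frame = int(dye_add_frame)
    return out
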