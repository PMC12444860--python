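"""Ring extraction, angular profiling, filtering, normalisation, alignment."""

import numpy as np
import pytest

from phagopulse.errors import ConfigurationError, DegenerateGeometryError
from phagopulse.ring import (AlignedCohort, RingProfileSeries, RingSpec, align_and_average,
                             angular_profile, build_kymograph, lowpass, normalize_track,
                             normalize_tracks, ring_pixels)
from phagopulse.synthetic import truth_tracks


def brute_force_ring(center, spec, plane_shape):
    """Oracle: exhaustive scan of the plane applying the radius predicate."""
    cx, cy = center
    h, w = plane_shape
    r_out = spec.radius + spec.half_width if spec.mode == "annulus" else spec.radius
    r_in = spec.radius - spec.half_width if spec.mode == "annulus" else 0.0
    pix = []
    for y in range(h):
        for x in range(w):
            r = np.hypot(x - cx, y - cy)
            if r_in <= r <= r_out:
                pix.append((y, x))
    return set(pix)


@pytest.mark.parametrize("mode", ["annulus", "disc"])
def test_ring_pixels_match_brute_force_scan(mode, rng):
    """Pixel membership equals the exhaustive bounding-box scan for random centres."""
    spec = RingSpec(radius=6.0, half_width=1.5, mode=mode)
    for _ in range(25):
        center = tuple(rng.uniform(10, 30, size=2))
        ys, xs, angles, clipped = ring_pixels(center, spec, (40, 40))
        assert not clipped
        assert set(zip(ys, xs)) == brute_force_ring(center, spec, (40, 40))
        assert np.all((angles >= 0) & (angles < 2 * np.pi))


def test_ring_radius1_contains_four_neighbours():
    spec = RingSpec(radius=1.0, half_width=0.99)
    ys, xs, _, _ = ring_pixels((5.0, 5.0), spec, (11, 11))
    got = set(zip(ys, xs))
    assert {(5, 4), (5, 6), (4, 5), (6, 5)} <= got


def test_ring_at_corner_is_clipped_subset():
    spec = RingSpec()
    ys, xs, _, clipped = ring_pixels((0.0, 0.0), spec, (64, 64))
    full_ys, full_xs, _, ok = ring_pixels((32.0, 32.0), spec, (64, 64))
    assert clipped and not ok
    assert 0 < len(ys) < len(full_ys)


def test_angular_profile_uniform_field():
    """A constant plane gives every sector mean and the ring mean equal to it."""
    plane = np.full((40, 40), 7.5)
    sec, rm, flags = angular_profile(plane, (20.0, 20.0), RingSpec())
    assert sec.shape == (21,)
    np.testing.assert_allclose(sec, 7.5)
    assert rm == pytest.approx(7.5)
    assert not flags["clipped"]


def test_angular_profile_ring_mean_matches_oracle(rng):
    """Ring mean equals the brute-force mean over oracle pixels to 1e-9 relative."""
    plane = rng.random((50, 50))
    for mode in ("annulus", "disc"):
        spec = RingSpec(mode=mode)
        center = (24.3, 26.7)
        _, rm, _ = angular_profile(plane, center, spec)
        pix = brute_force_ring(center, spec, plane.shape)
        oracle = np.mean([plane[y, x] for y, x in pix])
        assert rm == pytest.approx(oracle, rel=1e-9)


def test_angular_profile_empty_ring_raises():
    with pytest.raises(DegenerateGeometryError):
        angular_profile(np.zeros((30, 30)), (-50.0, -50.0), RingSpec())


def test_pore_sectors_are_minimal(noisefree_pulsing_cohort):
    """Sectors overlapping the rendered pore drop to background during open intervals."""
    cfg, movies, log = noisefree_pulsing_cohort
    p = next(p for p in log.phagosomes if p.open_intervals)
    m = movies[p.movie_index]
    t_open = p.open_intervals[0][0] + 1
    x, y, z = p.center_xyz_vox
    plane = m.frame(t_open, "reporter")[int(round(z))]
    sec, _, _ = angular_profile(plane, (x, y), RingSpec())
    n = len(sec)
    width = np.radians(cfg.pore_angle_deg)
    pore_sectors = {int(((p.pore_angle_rad + f * width) % (2 * np.pi)) / (2 * np.pi) * n)
                    for f in (0.25, 0.5, 0.75)}
    # every fully-pore sector must be among the dimmest sectors of the ring
    order = np.argsort(sec)
    dimmest = set(order[: len(pore_sectors) + 2].tolist())
    assert pore_sectors <= dimmest


def test_rotation_by_one_sector_permutes_profile():
    """Rotating the plane by one sector width cyclically permutes sector means."""
    from scipy.ndimage import rotate

    yy, xx = np.mgrid[0:81, 0:81]
    r = np.hypot(xx - 40, yy - 40)
    ang = np.arctan2(yy - 40, xx - 40)
    shell = np.exp(-((r - 6.0) ** 2) / 2.0) * (1.2 + np.cos(ang))  # smooth asymmetry
    spec = RingSpec()
    sec0, _, _ = angular_profile(shell, (40.0, 40.0), spec)
    rot = rotate(shell, 360.0 / spec.n_sectors, reshape=False, order=3)
    sec1, _, _ = angular_profile(rot, (40.0, 40.0), spec)
    corr = {sh: np.corrcoef(np.roll(sec0, sh), sec1)[0, 1] for sh in (-1, 0, 1)}
    # image rotation by one sector width shifts the profile by exactly one bin
    assert corr[-1] > 0.98  # interpolation of the rotated image limits exactness
    assert corr[-1] > corr[0] and corr[-1] > corr[1]


def _series(vals, track_id=0, dt=30.0):
    vals = np.asarray(vals, float)
    T = len(vals)
    return RingProfileSeries(track_id, np.arange(T), np.tile(vals[:, None], (1, 21)),
                             vals, frame_interval_s=dt)


def test_lowpass_window1_is_identity_and_constant_fixed_point(rng):
    s = _series(rng.random(30))
    out = lowpass(s, 1)
    np.testing.assert_array_equal(out.ring_mean, s.ring_mean)
    const = _series(np.full(20, 3.3))
    np.testing.assert_allclose(lowpass(const, 5).ring_mean, 3.3)


def test_lowpass_matches_sliding_mean_oracle(rng):
    """Centred moving average equals the direct sliding-window oracle."""
    vals = rng.random(40)
    out = lowpass(_series(vals), 5).ring_mean
    pad = np.concatenate([vals[2:0:-1], vals, vals[-2:-4:-1]])
    oracle = np.array([pad[i:i + 5].mean() for i in range(40)])
    np.testing.assert_allclose(out, oracle, rtol=1e-12)


def test_lowpass_rejects_bad_windows(rng):
    s = _series(rng.random(10))
    with pytest.raises(ConfigurationError):
        lowpass(s, 4)
    with pytest.raises(ConfigurationError):
        lowpass(s, 11)


def test_normalization_definition_and_degenerate_cases(rng):
    """Midpoint maps to 0.5; range becomes exactly [0,1]; constant tracks flag."""
    vals = np.array([10.0, 20.0, 30.0])
    out = normalize_track(_series(vals))
    assert out.ring_mean[1] == pytest.approx(0.5)
    r = rng.random(50) * 7 + 3
    out2 = normalize_track(_series(r))
    assert out2.ring_mean.min() == pytest.approx(0.0)
    assert out2.ring_mean.max() == pytest.approx(1.0)
    const = normalize_track(_series(np.full(10, 4.0)))
    assert const.constant_flag and np.all(const.ring_mean == 0)


def test_normalization_is_idempotent(rng):
    s = _series(rng.random(30) * 100)
    once = normalize_track(s)
    twice = normalize_track(once)
    np.testing.assert_allclose(twice.ring_mean, once.ring_mean, atol=1e-12)
    np.testing.assert_allclose(twice.sectors, once.sectors, atol=1e-12)


def test_normalization_uses_joint_min_max():
    """A single min/max over sectors and ring mean, not per-column scaling."""
    T = 6
    sectors = np.zeros((T, 21))
    sectors[0, 0] = 40.0          # global max lives in a sector
    ring = np.linspace(0, 20, T)  # ring mean never reaches it
    s = RingProfileSeries(0, np.arange(T), sectors, ring, frame_interval_s=30.0)
    out = normalize_track(s)
    assert out.sectors.max() == pytest.approx(1.0)
    assert out.ring_mean.max() == pytest.approx(0.5)


def test_align_single_track_and_identical_offsets():
    a = _series(np.array([1.0, 2.0, 3.0]))
    aligned, cohort = align_and_average([a])
    np.testing.assert_allclose(cohort.mean, a.ring_mean)
    np.testing.assert_allclose(cohort.sd, 0.0)
    b = RingProfileSeries(1, np.arange(5, 8), a.sectors, a.ring_mean,
                          frame_interval_s=30.0)
    aligned, cohort = align_and_average([a, b])
    assert aligned[1].frames[0] == 0
    np.testing.assert_allclose(cohort.mean, a.ring_mean)
    np.testing.assert_allclose(cohort.sd, 0.0)
    np.testing.assert_array_equal(cohort.n, [2, 2, 2])


def test_align_nine_tracks_matches_column_statistics(rng):
    """Cohort mean/s.d. equal brute-force column statistics on the aligned matrix."""
    lengths = rng.integers(8, 15, size=9)
    series = [_series(rng.random(n), track_id=i) for i, n in enumerate(lengths)]
    _, cohort = align_and_average(series)
    for t in range(max(lengths)):
        col = [s.ring_mean[t] for s in series if len(s.ring_mean) > t]
        assert cohort.mean[t] == pytest.approx(np.mean(col))
        assert cohort.sd[t] == pytest.approx(np.std(col))
        assert cohort.n[t] == len(col)


def test_kymograph_single_frame_track(noisefree_pulsing_cohort):
    cfg, movies, log = noisefree_pulsing_cohort
    tr = truth_tracks(log, 0)[0]
    import dataclasses
    one = dataclasses.replace(tr, frames=tr.frames[:1], positions_vox=tr.positions_vox[:1],
                              positions_um=tr.positions_um[:1], gap_flags=tr.gap_flags[:1])
    s = build_kymograph(one, movies[0])
    assert s.sectors.shape == (1, 21)


def test_kymograph_peaks_match_scheduled_pulses(noisefree_pulsing_cohort):
    """Noise-free ring-mean local maxima coincide with generator pulse peaks ±1 frame."""
    cfg, movies, log = noisefree_pulsing_cohort
    for i, m in enumerate(movies):
        p = log.phagosomes_in_movie(i)[0]
        s = build_kymograph(truth_tracks(log, i)[0], m)
        trace = s.ring_mean
        for peak in p.pulse_peak_frames:
            k = peak - s.frames[0]
            if 1 <= k < len(trace) - 1:
                window = trace[max(0, k - 2):k + 3]
                assert trace[k] >= window.max() - 1e-6 or \
                    max(trace[k - 1], trace[k + 1]) >= window.max() - 1e-6


def test_disc_mode_dimmer_than_annulus_on_shell_phantom(noisefree_pulsing_cohort):
    """With a dim interior and zero-ish background, the filled disc dilutes the shell."""
    cfg, movies, log = noisefree_pulsing_cohort
    p = log.phagosomes_in_movie(0)[0]
    m = movies[0]
    t = p.engulfment_frame + cfg.pulse_rise_frames  # surge peak: shell bright
    x, y, z = p.center_xyz_vox
    plane = m.frame(t, "reporter")[int(round(z))]
    _, rm_annulus, _ = angular_profile(plane, (x, y), RingSpec(mode="annulus"))
    _, rm_disc, _ = angular_profile(plane, (x, y), RingSpec(mode="disc"))
    assert rm_disc < rm_annulus


def test_kymograph_heatmap_export(tmp_path, rng):
    s = _series(rng.random(12))
    out = tmp_path / "kymo.png"
    s.to_heatmap_png(out)
    assert out.stat().st_size > 0


def test_kymograph_rejects_out_of_range_frames(noisefree_pulsing_cohort):
    cfg, movies, log = noisefree_pulsing_cohort
    tr = truth_tracks(log, 0)[0]
    import dataclasses
    bad = dataclasses.replace(tr, frames=tr.frames + movies[0].n_frames)
    with pytest.raises(IndexError, match="frame"):
        build_kymograph(bad, movies[0])
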