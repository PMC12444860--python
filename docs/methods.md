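# Methods

This note documents the models, conventions and numerical choices behind
`phagopulse`: what the synthetic movies emulate, how each analysis stage is
defined, which parameters matter, and what the validation results do and do
not demonstrate.

## The synthetic cohort model

Each field of view holds one neutrophil rendered as a soft-edged disc of dim
cytosolic reporter signal spanning the central z-slices, containing 1–25
phagosomes laid out on a grid. The field of view is sized so that the cell
body encloses every phagosome with margin and genuine extracellular space
remains outside the cell — this matters for the fluid-phase dye channel,
where extracellular voxels carry dye and intracellular ones must not.

**Phagosome geometry.** The membrane is a spherical shell with a Gaussian
radial cross-section (σ = 0.4 µm) at radius 2 µm; the bacterium (prey) is a
solid sphere of radius 1 µm at its centre. The 2 µm membrane radius
corresponds to 6 px at the default 0.33 µm/px, so the default analysis ring
(radius 6 px) sits on the membrane; the 1 µm prey radius matches the scale of
*S. aureus* clusters and 1 µm beads. Voxels are anisotropic: 0.33 µm in x/y
and 1.5 µm in z (the acquisition z-step), and all rendering uses Euclidean
distance in µm, so shells span only ±1 z-slice — as in the real data.

**Reporter kinetics.** Shell intensity follows a sum of event waveforms: a
closure surge at engulfment (amplitude 100, arbitrary camera units) and one
waveform per scheduled pulse (relative amplitude 0.8). Each waveform rises
linearly over 2 frames and decays exponentially with τ = 45 s, consistent
with the observed timeline of recruitment surging at phagosome closure and
visibly diminishing by ~90 s. Between events the noise-free ring-mean trace
is therefore monotone non-increasing — a property the tests assert.

**Event schedule.** A phagosome pulses with probability `p_pulse` = 0.124
(the cohort estimate of the per-phagosome pulsing fraction, 12.4 %). Pulsing
phagosomes receive `min(1 + Poisson(3), 18)` pulses — mode near four, hard
support 1–18, matching the observed "typically four, up to 18" counts. The
first-pulse latency is lognormal with arithmetic mean 10.5 min and s.d.
12.49 min (moment-matched); a lognormal was chosen over a truncated normal
because it has the right support, reproduces the heavy right skew implied by
s.d. > mean, and its arithmetic mean equals the calibration value exactly, so
latency-recovery checks compare like with like. Inter-pulse gaps are
2 min + Exp(8 min). Each pulse opens a 60° pore in the shell for 4 frames
(sectors overlapping the pore drop to background, enabling angular-asymmetry
tests); with probability `p_leak` = 0.201 (the human-neutrophil dye-positive
estimate, 20.1 %) a phagosome is persistently unsealed — open from shortly
after engulfment — and is the substrate for dye accumulation. Pulse outcomes
(recapture / release / transfer) are drawn at 29:1:1 in 31.

**Prey (pH reporter) brightness.** The prey channel emulates a
pHrodo-like stain: full brightness while extracellular or while the
phagosome is open, dimmed by a factor 0.5 while sealed (the early phagosome
alkalinises, dimming the dye). Prey brightness defaults to 160 units: a
1 µm bacterium occupies a single z-slice, so the 3×3×3 smoothing used before
segmentation attenuates its peak roughly threefold, and 160 keeps the
smoothed contrast-to-noise near 10 at the reference noise level — i.e.
bacteria are clearly resolvable, as the one-level prey segmentation of the
emulated workflow presumes.

**Dye channel.** `add_dye_channel` adds a third channel: extracellular
voxels carry dye intensity (100 units) from the addition frame onward;
the interior of a leaky phagosome fills (one-frame ramp) from the first open
interval overlapping the post-addition period. Sealed phagosomes never
accumulate dye.

**Noise.** Var(v) = g·signal + σ_r², a Gaussian approximation of shot noise
(gain g = 1) plus additive read noise. SNR is defined as closure-surge
amplitude over σ_r; the reference condition is SNR 8 (σ_r = 12.5).

**Determinism.** All randomness derives from `SimConfig.seed` through keyed
`SeedSequence` streams (planning, per-movie rendering, dye noise), so a
configuration reproduces bit-identical movies and logs, and movies can be
rendered lazily (`iter_movies`) in any consumption order.

**What the generator does not emulate:** photobleaching, chromatic shift,
cell deformation and chemotaxis, phagosome fusion, prey displacement during
release, and a real PSF (rendering is geometric). Passing tests therefore
demonstrate correctness of the measurement pipeline under controlled,
favourable imaging conditions — not robustness to every artefact of live
tissue imaging.

## Analysis pipeline

**Smoothing and segmentation.** Volumes are smoothed with a 3×3×3 box kernel
(reflected borders; a constant volume is a fixed point). The reporter channel
is segmented at two levels — low (whole neutrophil) and high (phagosome) —
and the prey channel at one level; components are labelled with
26-connectivity (6 available), objects under 5 voxels discarded, volumes
reported in µm³ via the voxel size without resampling. Automatic levels use
3-class multi-level Otsu (reporter) and Otsu (prey) on the smoothed
histogram, validated on bimodal phantoms (<1 % interior misclassification at
SNR 8); fixed numeric levels are accepted via config for reproducibility.
Levels are chosen per movie (from one reference frame), not per frame — the
per-frame option exists but is off by default. The *pipeline's* automatic
prey detection uses a robust background rule instead (median + 6·MAD·1.4826):
isolated bacteria occupy ~0.03 % of voxels, a regime where Otsu's
between-class criterion collapses onto the background mode.

**Inside/outside ratio.** Prey voxels are split by the cell mask;
inside + outside equals the total exactly (voxel counts); the ratio is
inside/outside with a flagged +∞ sentinel when the prey is fully internal.

**Tracking.** Per-frame prey centroids are linked by optimal one-to-one
assignment (Hungarian algorithm) on Euclidean distance in µm, honouring
anisotropy. Links longer than 2 µm per frame of gap are forbidden; tracks
survive gaps up to 2 frames, with gap frames linearly interpolated and
flagged; unmatched detections found new tracks. Tracking runs on the prey
channel because bacteria are persistently bright while the reporter fades
between pulses. TrackMate XML (spots in µm plus the pixel calibration from
`Settings/ImageData`) can be ingested instead of the built-in linker.

**Ring profiles.** For each track point, the z-slice nearest the centroid is
selected (an optional 3-slice maximum projection exists for low SNR) and all
pixels within an annulus of radius 6 px, half-width 1.5 px around the
sub-pixel centroid are extracted (exact Euclidean distance; no rounding of
the centre; a filled-disc mode is retained for parity checks, since "within
a ring" admits both readings). Pixels are binned into 21 equal angular
sectors — sector k covers [2πk/21, 2π(k+1)/21), angle measured by
atan2(dy, dx) with the image y-axis pointing down. The ring mean is the mean
over all ring pixels, not the mean of sector means; empty sectors (image
borders) are filled from their nearest populated neighbour and flagged. The
trace is low-pass filtered with a centred 5-frame moving average (reflected
ends; window 1 is the identity), min–max normalised per track with a single
min/max taken jointly over sector values and ring mean (constant tracks map
to 0 and are flagged), shifted so each track starts at t = 0, and averaged
across tracks with the population s.d. and the contributing track count
reported per time index.

**Pulse calling.** On a normalised trace, the closure surge — the global
structure from t = 0, from the first crossing above the fade threshold until
the first drop below it — is excluded; thereafter local maxima with
topographic prominence ≥ `prominence_min` separated by ≥ `min_separation`
frames are pulses. Of two maxima closer than the separation the higher
survives, ties to the earlier. Pulse onset is the last pre-peak frame at or
below the half-prominence level (the foot of the rise — stable under the
moving-average smoothing, landing within ±1 frame of the scheduled onset);
first-pulse latency is onset minus engulfment, in minutes via the frame
interval. Tracks with fewer than 10 post-fade frames are flagged
low-confidence, not dropped.

**Operating point.** The detector thresholds are conventions, not measured
quantities; they were fixed with the packaged sweep harness
(`sweep_operating_point`: detected peak within ±2 frames of a scheduled peak
counts as a true positive, one-to-one matching) on the SNR-8 reference
cohort (80 pulsing phagosomes, 240 frames). The adopted operating point is
`prominence_min = 0.1`, `fade_threshold = 0.7`, `min_separation = 3`
(F1 = 0.956, precision 1.0); the relatively high fade threshold ends the
surge-exclusion window early, which is what recovers first pulses scheduled
only a few minutes after engulfment. Pulses scheduled *inside* the surge
window, or closer together than the smoothing width, are structurally
invisible to any threshold detector; detector-validation cohorts that assert
perfect F1 therefore use well-separated schedules (latency lognormal mean
20 / s.d. 5 min, gaps 4 + Exp(10) min), while all parameter-recovery checks
keep the cohort-calibrated schedule and absorb the residual censoring, which
biases the recovered mean latency by well under one standard error at the
cohort sizes used.

**Cohort statistics.** The per-neutrophil fraction of pulsing phagosomes is
the primary unit (mean ± s.d. over neutrophils), with the pooled
per-phagosome rate also emitted and labelled, since both weightings are
defensible; neutrophils with zero phagosomes are excluded and counted.
Burden correlation is Spearman's rank correlation with midrank ties
(two-sided p). Dye positivity is mean dye intensity within each bacterium
mask against a background + 3·s.d. threshold, background taken from the
same masks before dye addition. The ROS shell is all voxels within 0.5 µm
(Euclidean, anisotropic) of a bacterium mask excluding the mask, ratioed
against a reference phagocyte mean. Group comparisons wrap standard
routines (Kruskal–Wallis with hand-rolled Dunn z-tests and Holm adjustment,
Mann–Whitney, Welch t); categorical event tallies get exact Clopper–Pearson
95 % intervals, and the packaged tally fixture is a regression anchor for
the printed percentages.

## Problem sizes

Validation cohorts were sized to keep statistical power while remaining
desk-scale: the full-pipeline pulsing-fraction recovery uses 100 neutrophils
(tests: 30), latency recovery 200 pulsing phagosomes at 240 frames (tests:
80), dye classification 2000 phagosomes (tests: 800); recovery bands are
three standard errors throughout, so reduced test cohorts simply widen the
band by 1/√n. Movies default to 7 z-slices and 180 frames at 30 s.

## Known limitations

- Engulfment is at frame 0 for every phagosome in the default cohorts
  (staggered engulfment is configurable); time-zero alignment is exercised
  by construction rather than estimated from the movie.
- The linker handles neither merging nor splitting; phagosome fusion would
  appear as track termination plus a new track.
- The dye classifier assumes the prey mask samples the phagosome lumen;
  with a real PSF and z-undersampling this is an approximation.
- Mixed-effects modelling of raw in vivo data is out of scope; the group
  comparison API is a thin wrapper over standard routines on user tables.
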