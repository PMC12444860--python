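# phagopulse

Quantification of pulsatile reporter recruitment on neutrophil phagosomes in
3D time-lapse fluorescence microscopy, with a ground-truthed synthetic movie
generator.

## The problem

Neutrophils engulf bacteria into phagosomes. On the nascent phagosome
membrane, Class I PI3-kinases produce PIP3/PI(3,4)P₂, which a fluorescent
reporter (the PH domain of Akt fused to GFP) decorates: recruitment surges as
the phagosome closes, fades within a minute or two, and — on a subset of
phagosomes — re-surges repeatedly in *pulses*. Pulses coincide with transient
re-opening of the phagosome: the membrane parts, prey is partially released
and usually re-captured, extracellular dye can flood in, and the pH-sensitive
brightness of stained prey changes. Quantifying this behaviour requires
tracking individual phagosomes in anisotropic 3D+t movies, measuring reporter
intensity on a ring around each phagosome over time, and calling pulses on
the resulting traces.

`phagopulse` packages that analysis as a tested, reusable pipeline for
microscopists and image analysts:

- **synthetic** — a generator of two/three-channel 3D+t movies (reporter,
  prey, optional fluid-phase dye) with a complete ground-truth event log
  (engulfment, scheduled pulses, open intervals, leak flags), so every
  downstream stage is testable without external data;
- **segmentation** — 3×3×3 box smoothing and intensity-level segmentation:
  two levels on the reporter channel (whole cell / phagosome), one on the
  prey channel, inside/outside bacterial volume ratios, volumes in µm³ on
  the anisotropic voxel grid;
- **tracking** — TrackMate XML ingestion, or a built-in frame-to-frame
  Hungarian linker with gap closing;
- **ring** — the core quantification: for each tracked phagosome and frame,
  all pixels within a ring of radius 6 px around the centroid are binned
  into 21 angular sectors; kymographs (frames × 21) plus the ring-mean
  trace are low-pass filtered, min–max normalised per track, aligned to a
  common time zero and averaged;
- **pulses** — a deterministic pulse caller on normalised ring-mean traces
  (closure surge excluded, then prominence/separation criteria), with a
  precision/recall sweep harness that fixes the operating point;
- **stats** — cohort summaries (percent pulsing phagosomes per neutrophil,
  first-pulse latency, pulse-count distribution), Spearman burden
  correlation, relative intensity change inside phagosome masks, dye-positive
  classification, peri-bacterial ROS shell ratios, group tests, and exact
  binomial summaries of categorical event tallies.

## Worked example

```python
import phagopulse as pp
from phagopulse.pipeline import PipelineConfig, run_pipeline

sim = pp.SimConfig.with_snr(8.0, n_neutrophils=10, phagosomes_min=1,
                            phagosomes_max=25, seed=11)
report = run_pipeline(PipelineConfig(sim=sim, seed=11, outdir="demo_out"))
s = report["summary"]
print(f"{s['n_neutrophils']} neutrophils, {s['n_phagosomes']} phagosomes")
print(f"pulsing per neutrophil: {s['pct_pulsing_per_neutrophil_mean']:.1f}"
      f" ± {s['pct_pulsing_per_neutrophil_sd']:.1f} % (mean ± s.d.)")
print(f"first-pulse latency: {s['latency_min_mean']:.1f} min"
      f" (n = {s['n_latencies']})")
```

prints (seed 11):

```
10 neutrophils, 128 phagosomes
pulsing per neutrophil: 11.2 ± 15.2 % (mean ± s.d.)
first-pulse latency: 7.4 min (n = 12)
```

The cohort was generated with a per-phagosome pulse probability of 12.4 % and
a mean scheduled latency of 10.5 min; the pipeline — which never sees the
schedule — re-estimates both from the rendered voxels (small cohorts scatter
around the generative values). `demo_out/` then contains `calls.csv` (one row
per phagosome: pulse count, latency, per-pulse onsets/peaks/amplitudes),
`report.json`/`report.txt`, the ground-truth log, and a run manifest with the
config hash and seed; rerunning with the same config and seed reproduces
every output byte-for-byte.

The same stages are available from the shell:

```sh
phagopulse run --config cohort.yaml --seed 11 --outdir out/
phagopulse simulate --config cohort.yaml    # movies + ground truth only
phagopulse track out/movie_000.ome.tif --trackmate-xml spots.xml
```

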