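# chromamotion

Analysis toolkit for chromatic ON/OFF motion-vision experiments in the fly:
UV/green stimulus generation, behavioral and neuronal **isoluminance**
estimation, a calcium-imaging ROI pipeline, and a hexagonal-lattice
chromatic motion model — all exercisable on synthetic data with known
ground truth.

## The scientific problem

Flies detect moving brightenings (ON) and darkenings (OFF) with parallel
pathways (the directionally selective T4 and T5 cells).  If the two
pathways weigh UV and green light differently, then the UV intensity at
which a moving UV/green pattern produces *no* net motion signal — the
isoluminance level — differs between ON and OFF motion.  This package
implements the computational machinery used to measure that asymmetry:

- **Stimulus geometry** (`chromamotion.stimulus`).  Looming discs follow
  the constant-velocity approach law θ(t) = arctan((r/v)/t_c), with
  r/v = 120 ms so the disc grows from θ ≈ 6.8° to 90° in 1 s.  Competing
  motion splits the display into 30° windows in which a green and a UV
  edge sweep oppositely at 120 °/s (4 Hz).  OFF stimuli are the ON frames
  time-reversed; counterclockwise stimuli are mirrored clockwise frames.
  A calibration mask fixes green irradiance at 2.3 × UV irradiance at
  every display location.
- **Behavioral analysis** (`chromamotion.behavior`).  Turning responses
  (ΔWBA, 500 Hz) to mirrored stimulus pairs are folded with sign
  inversion; the tuning curve of response vs UV level (mean over 2 s for
  edges, over the 100 ms after full expansion for discs) is scanned
  upward from UV = 0 for its first positive-going zero crossing, located
  by linear interpolation.  Restricted-range (UV 3–9) protocols cap the
  estimate at the range ends.
- **Calcium-imaging pipeline** (`chromamotion.imaging`).  Binary-template
  rigid alignment (recordings moving > 25 px are rejected), Gaussian
  smoothing (11 px FWHM) + flood-fill ROI detection at column spacing,
  ΔF/F₀ against a 1.5 s pre-stimulus baseline, polarity-specific response
  windows and responsiveness thresholds, and zero-crossing isoluminance
  per ROI (ON cells scanned downward from UV = 15, OFF cells upward from
  UV = 0; no crossing → curve minimum), aggregated ROIs → fly → grand
  mean with equal fly weighting.
- **Hexagonal-lattice motion model** (`chromamotion.hexmotion`).  An RGB
  image is averaged over 120 × 104 px hexagons (9360 px each); per site
  and cardinal direction a Weber contrast C = (I_h − I_b)/I_b compares
  the home facet group against the background facets along the motion
  direction; ON (positive C) and OFF (negative C) vector sums, computed
  under channel-specific spectral weights, are projected radially to
  estimate approaching vs receding motion energy.
- **Synthetic data** (`chromamotion.synthetic`, `chromamotion.cohorts`)
  generate ΔWBA recordings, calcium movies with planted ROIs/jitter, and
  disc test images with known ground truth; `chromamotion.stats` provides
  the Wilcoxon/t-test and Benjamini–Hochberg FDR support.

## Worked example

Recover a fly's ON/OFF isoluminance from simulated competing-edge data:

```python
from chromamotion import behavior, stats, synthetic

gt = synthetic.GroundTruth(i_on=4.5, i_off=9.2, noise_sd=0.05, n_trials=5, seed=0)
for protocol in ("edges_on", "edges_off"):
    rec = synthetic.simulate_behavior(gt, protocol)
    curve = behavior.tuning_from_recording(rec, protocol)
    est = behavior.estimate_isoluminance(curve)
    print(protocol, round(est.value, 3), est.capped)
```

prints

```
edges_on 4.526 False
edges_off 9.211 False
```

— the estimator finds the zero crossing of each tuning curve at the
planted ON (4.5) and OFF (9.2) isoluminance levels; the ON value is the
lower one, i.e. the ON pathway is the more UV-sensitive.  The same
recovery through the imaging pipeline:

```python
from chromamotion import imaging, synthetic

syn = synthetic.simulate_movie(
    [((64, 64), "ON", 5.0), ((64, 192), "ON", 5.0), ((192, 128), "ON", 5.0)],
    jitter_sd=2.0, noise_sd=4.0, seed=3)
res = imaging.run_pipeline(syn.movie, "ON")
print([round(est.value, 3) for _, est in res.estimates])
```

prints `[4.997, 5.006, 5.011]`: three detected ROIs, each recovered at the
planted isoluminance of UV = 5 despite 2 px frame jitter and additive
noise.

A CLI mirrors the library (`chromamotion render disc`, `chromamotion
simulate movie`, `chromamotion analyze imaging`, `chromamotion hexmotion`,
`chromamotion stats-fdr`; see `--help`).

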