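# actinflow

Quantify intracellular F-actin flow from time-lapse fluorescence
microscopy. The package was built for the analysis of actin dynamics in
the *Arabidopsis* central cell — the large female gamete whose
myosin-driven, inward-directed F-actin movement transports the sperm
nucleus toward the central cell nucleus — but it applies to any 2-D
time-lapse of a textured fluorescent structure moving inside a cell.

It provides, end to end:

1. **Masked multi-pass PIV** — frame-to-frame displacement fields by FFT
   cross-correlation of interrogation windows with multi-pass window
   deformation (default schedule 64 → 32 → 16 px, 50 % overlap), 3-point
   Gaussian subpixel peak fitting, and normalized-median-test outlier
   validation, restricted to a cell-shaped mask.
2. **Inward/outward decomposition** — each vector around the nucleus is
   projected onto the unit vector from its node toward the nuclear
   center; the signed component is positive for motion toward the
   nucleus (inward) and negative for motion away (outward). Samples are
   pooled over space and time.
3. **Gamma velocimetry statistics** — pooled velocity distributions are
   fitted with the gamma density

   f(x; k, θ) = x^(k−1) e^(−x/θ) / (Γ(k) θ^k),  x ≥ 0,  k, θ > 0,

   and each cell is summarized by its mean velocity **kθ**. Replicate
   means are compared with a two-sided Student's t-test
   (***, p < 0.001; **, p < 0.01; n.s. otherwise), with SD and SEM both
   reported.
4. **A synthetic speckle-flow generator** — speckle/cable textures
   advected by known flows (uniform, radial-inward, rotation, zero,
   composites) with photon-like noise and bleaching, so every stage is
   benchmarked against analytic ground truth.
5. **A temporal color projection** — each frame tinted by a time-indexed
   hue and max-composited, so static structures appear white and moving
   structures leave rainbow trails.

## Worked example

Simulate a radial inward flow (peak 1.5 px/frame, decay length 40 px)
toward a "nucleus" at the frame center, run the full pipeline, and read
off the gamma summary:

```python
from actinflow import FlowSpec, RunConfig, run_pipeline

config = RunConfig(
    name="demo",
    flow=FlowSpec("radial_inward",
                  {"peak_speed": 1.5, "decay_length": 40.0,
                   "center": (63.5, 63.5)}),
    n_frames=8, seed=7, out_dir="demo_out", make_figures=False,
)
report = run_pipeline(config)
print(f"k       = {report.fit_all.k:.3f}")
print(f"theta   = {report.fit_all.theta:.4f} px/frame")
print(f"ktheta  = {report.mean_velocity_px_per_frame:.3f} px/frame "
      f"({report.mean_velocity_um_per_min:.3f} um/min)")
```

prints

```
k       = 19.893
theta   = 0.0652 px/frame
ktheta  = 1.298 px/frame (0.276 um/min)
```

`kθ = 1.298 px/frame` is the fitted mean speed over the whole cell and
all frame pairs — within 15 % of the prescribed flow's true mean in-mask
speed — and the µm/min figure applies the default calibration
(0.10625 µm/px, 30 s between frames). In the same run the inward class
around the nucleus held 336 samples with mean 1.077 px/frame and the
outward class was empty, as expected for a purely converging flow.

The same stages are exposed as a CLI (`actinflow run|simulate|piv|
decompose|stats|project|benchmark`), each verb a thin wrapper over one
library call, configured by a YAML file.

## Units

PIV computes px/frame throughout; µm/min values are derived at reporting
time as `px/frame × pixel_size_um × 60 / frame_interval_s`. Velocity
distributions from uncalibrated acquisitions should be treated as
arbitrary-but-consistent units.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the end-to-end synthetic benchmark — three fast-flow and three
slow-flow replicates through simulation, PIV, decomposition and gamma
fitting — prints the group comparison, and writes the JSON result file.
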