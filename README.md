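# synaptrack

Quantitative analysis of TCR microcluster transport and cortical actin
dynamics at the immunological synapse, together with a synthetic
TIRF-movie generator so that every stage is testable against exact ground
truth — no experimental data required.

At the T cell / antigen-presenting surface interface, ligated T-cell
receptor (TCR) microclusters are carried across a circular synapse whose
center (the cSMAC) is depleted of actin. Cortical actin flows retrogradely
(inward) at ~40–50 nm/s, but in primary T cells outward-expanding actin
wavefronts coexist with this flow, and microclusters that couple to a
passing front move anterogradely (outward). `synaptrack` implements the
full measurement chain for two-channel movies (TCR + LifeAct):

* **Detection** — 8-bit conversion, Gaussian filtering (3 px radius),
  percentile thresholding with watershed splitting, sub-pixel centroids,
  and an actin-derived positive mask restricting analysis to the
  pSMAC/dSMAC annulus.
* **Predictive tracking** — features are linked by minimizing distance to
  the velocity-extrapolated position
  `P(t1) = x(t0) + (x(t0) − x(t−1)) / (t0 − t−1) · (t1 − t0)`,
  followed by a 3.5 px (146 nm) end-to-end motility filter and
  anterograde/retrograde classification from initial vs final radial
  distance.
* **Actin flow PIV** — windowed FFT cross-correlation (32 px windows,
  16 px overlap, sub-pixel Gaussian peak fit) with directional summaries,
  plus a particle-based cross-check.
* **Wavefront detection** — band-pass Sobel edge detection (gradient
  magnitude in [10, 40] AU after 5×5 Gaussian smoothing) and
  TCR–wavefront colocalization under the 8-neighbor (~60 nm) rule.
* **Tracer simulation** — 100 tracers with default 50 nm/s retrograde
  drift and a 300 nm scan radius couple either to wavefronts (mode 1) or
  to supra-threshold PIV flow (mode 2); model and reference trajectories
  are compared through KDE-smoothed outward/inward run-time distributions
  and their mean squared error.
* **Synthetic data** — profiles (`primary`, `jurkat`, `wasp_ko`, `ck666`)
  encode the cell types' reported anterograde fractions and speeds as
  generator ground truth; movies carry realistic PSF, Poisson and read
  noise.

See `docs/methods.md` for the models, parameters and their rationale.

## Worked example

```python
from synaptrack.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(profile="primary", n_cells=5, seed=0))
print(report.summary())
```

prints

```
profile=primary  n_cells=5  seed=0
metric                         mean      sem
detection_accuracy               0.9970   0.0011
n_tracks                        44.6000   4.7181
n_motile                        39.6000   4.9960
tcr_anterograde_fraction         0.3581   0.0629
tcr_mean_speed_nm_s             43.6822   1.0082
tcr_speed_anterograde_nm_s      29.3385   0.8968
tcr_speed_retrograde_nm_s       52.3735   1.8467
gt_anterograde_fraction          0.3677   0.0613
actin_piv_anterograde_fraction   0.4113   0.0409
actin_piv_mean_speed_nm_s       39.9472   0.2839
tcr_wave_colocalization          0.8320   0.0365
```

Each row is a per-cell metric averaged over the five simulated primary
cells (mean ± SEM): essentially all ground-truth clusters are detected
(99.7%), roughly four in ten motile TCR tracks move net outward — matching
the generator's own label fraction (`gt_anterograde_fraction`) cell for
cell — at a mean step speed of ~44 nm/s, the PIV flow field shows a
similar outward vector fraction at ~40 nm/s, and ~83% of TCR time points
lie within ~60 nm of a detected actin wavefront edge. (Five cells is a
quick look; the calibrated fraction converges to ~0.43 over larger batches.)
Running the same config with `profile="jurkat"` (no waves) drops the
anterograde fraction to ~0.10 and the PIV outward fraction to ~0.

The same pipeline is available from the shell:

```bash
synaptrack analyze --profile jurkat --n-cells 3 --seed 0 --outdir out/
synaptrack all --config run.yaml        # every stage incl. tracer simulation
```

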