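# Methods

This note documents the models, algorithms and numerical choices behind
`synaptrack`: what each stage computes, what the synthetic movie generator
does and does not emulate, and where design decisions were genuinely open.

## The system being modeled

At the immunological synapse, ligated T-cell receptor (TCR) microclusters
are transported across a roughly circular contact interface organized into
concentric zones: a central, actin-depleted cSMAC surrounded by the
actin-rich pSMAC/dSMAC annulus. Cortical actin flows retrogradely (inward)
through the annulus at ~40-50 nm/s and normally sweeps microclusters toward
the center. In primary T cells a second motif coexists with this flow:
annular actin wavefronts that nucleate in the lamella and expand outward at
a similar speed. Microclusters that couple to a passing front (a
WASP-dependent linkage) ride it outward, so a substantial fraction of
motile clusters shows net anterograde (outward) movement.

The package quantifies this behavior from two-channel time-lapse movies
(TCR channel + LifeAct/actin channel) and reproduces it in silico: every
analysis stage is exercised against a generator whose ground truth is known
exactly.

## Analysis pipeline

**Detection.** Each stack is linearly rescaled to 8-bit over the whole
movie, smoothed with a Gaussian of 3 px radius (sigma = radius/2, truncated
at 2 sigma), and thresholded at a per-frame intensity percentile (default
0.95). Pixels above the cut form 8-connected components; components with at
least `min_size` = 4 px become features. Components containing several
intensity maxima are split between them by marker-based watershed (the
standard threshold / watershed / analyze-particles sequence) so touching
microclusters are not fused. Centroids are intensity-weighted with the
threshold value subtracted, which makes them track the spot peak at
sub-pixel precision. A 99th-percentile default was tried first and
abandoned: a 1% pixel budget cannot cover ~25 clusters spanning a ~3x
brightness range, so dim clusters always fell below a global cut.

**Actin positive mask.** The temporal *median* actin image (the median
suppresses transient wave transits that skew the mean) is smoothed and
Otsu-thresholded to the cell footprint; the cSMAC is the low-intensity
region nearest the centroid below a percentile-anchored cut, the midpoint
of the 2nd-percentile and median intensities inside the footprint. Otsu is
not used for this second split because the cSMAC holds only a few percent
of the footprint pixels — too little histogram weight for a variance-based
criterion. Analysis is restricted to footprint minus cSMAC.

**Predictive linking.** A track whose last two observed positions are
x(t-1) and x(t0) is expected at

    P(t1) = x(t0) + v(t0) (t1 - t0),   v(t0) = (x(t0) - x(t-1)) / (t0 - t-1).

Features of the next frame are assigned to tracks by minimum-cost bipartite
assignment on distance to the predicted positions, gated at `search_range`
(default 5 px, about twice the largest per-frame step at 50 nm/s); a track
with one point predicts zero velocity; tracks survive up to `memory` = 2
missed frames, extrapolating across the gap. Velocity extrapolation is what
keeps identities through crossings and through the inward-to-outward
reversal at wave capture; the test suite contrasts it against a
zero-velocity baseline on a crossing scenario.

**Track statistics.** Tracks with end-to-end displacement below 3.5 px
(146 nm, ~5% of the cell radius) are discarded as immotile debris; exactly
3.5 px is kept. Direction compares first and last radial distance from the
cell center (outward = anterograde); exact equality is a "tie" and is
excluded from fractions but counted. Speed is the mean frame-to-frame step
speed in nm/s (gap-aware); radial positions can be normalized so 0 is the
cSMAC boundary and 1 the cell edge. Intensity histograms use density =
frequency / (sum of frequencies x bin width) on 20 equal-width bins.

**PIV.** Actin flow is estimated by windowed cross-correlation (32 px
windows, 16 px overlap): windows are mean-subtracted, correlated by FFT,
the correlation is divided by the per-lag overlap area (otherwise the
linear-correlation envelope biases peaks toward zero displacement), and the
peak is refined by a three-point Gaussian fit per axis. The per-pixel
temporal mean is subtracted first (movies of >= 10 frames): static
structure such as the cell boundary otherwise anchors a spurious zero-lag
peak. The displacement search is capped at 4 px/frame (~165 nm/s), well
above any real motion in these movies. A vector is anterograde iff its
radial component is positive; vectors slower than 10 nm/s are excluded as
sub-noise. A particle-based cross-check reuses the detection/tracking chain
on the brightest actin features.

**Wavefront detection.** The 8-bit actin frame is smoothed with a 5x5
Gaussian kernel (sigma 1 px) and the Sobel gradient magnitude computed
(standard 3x3 kernels, Euclidean norm). Edge pixels are those with
magnitude between 10 and 40 AU on this 8-bit scale; the lower bound
suppresses speckle noise, the upper bound rejects saturated boundaries such
as the cell edge. A TCR point is colocalized with a wavefront when any edge
pixel lies within the 8 nearest pixel neighbors of its rounded position
(3x3 Chebyshev neighborhood; one pixel is 41.6 nm, so the diagonal is
~59 nm, i.e. a ~60 nm capture radius). The reported fraction pools all
(track, frame) points.

**Statistics.** Per-cell metrics are aggregated as mean +/- SEM (sample
standard deviation, n-1); groups are compared with the two-tailed
Mann-Whitney rank-sum test, exact for groups of at most 8 without ties and
normal-approximated with tie correction otherwise. No multiple-testing
correction is applied; comparisons are single pairwise tests.

## Tracer-transport model

Tracers are featureless particles confined to the synapse plane with a
constitutive retrograde drift of 50 nm/s. Each step (dt = frame interval) a
tracer scans a 300 nm disc. In **mode 1** it couples to any wavefront edge
coordinate inside the disc and moves radially outward at the front speed
(the analytic wave speed when driven by generator fronts; otherwise a
median nearest-edge radial displacement between consecutive frames);
without an edge in range it moves inward. It detaches as soon as no edge is
within the scan radius. In **mode 2** the PIV vectors whose grid points
fall inside the disc are averaged; if the mean speed exceeds a threshold
the tracer moves with the mean velocity, else it drifts inward. Tracers
stop at the cSMAC boundary (they may still be recaptured outward) and never
leave the cell disc. With no wavefronts and an unreachable threshold the
two modes are identical — a tested invariant.

Model output is summarized by the outward/inward time distribution: maximal
runs of consecutive positive (negative) radial increments, with zero
increments breaking a run without starting one; run lengths x dt are pooled
over tracers, histogram-normalized, and smoothed by sampling a Gaussian KDE
(Scott's rule bandwidth) at the bin centers. Two distributions are compared
by the mean squared difference of their KDE curves on the union of their
bin centers. A degenerate sample (all runs equal) falls back to a narrow
Gaussian bump so the comparison stays defined. Reference distributions come
from the generator's own cluster trajectories and are synthetic stand-ins
for experimental track pools.

On these synthetic scenarios, mode 1 matches the reference closely and a
no-outward-motion control is two to three orders of magnitude worse. In the
mode-2 threshold sweep, thresholds above the real flow speeds degrade the
match sharply, while thresholds from the low end up through ~33 nm/s
perform equally well: the rendered movies do not produce the slow,
directionally random PIV vectors that penalize very low thresholds on
experimental data, so the lower end of the optimum is not resolved here.

## Synthetic movie generator

The generator realizes one cell scenario (geometry, cluster paths,
wavefront arcs) and renders it into a noisy two-channel movie. Defaults
define the study conditions:

* **Geometry/acquisition:** 41.6 nm/px, 1 s/frame, 200 frames, cell radius
  3 um, cSMAC radius 0.75 um; image side = cell diameter + 16 px margin.
* **Clusters:** 25 at steady state. Each drifts inward with a radial speed
  drawn once from N(retro_speed, retro_speed_sd) — 43 +/- 30 nm/s for
  primary-type cells, 46 +/- 37.5 for jurkat, 43 +/- 39 for the
  WASP-deficient profile — plus 8 nm Brownian positional jitter per step. The heterogeneous drift is the source of the
  wave-independent anterograde baseline (a cluster with a negative inward
  drift moves net outward): per-step jitter alone large enough to flip ~11%
  of long tracks would require ~4 px/frame of noise, which is neither
  physical nor linkable. Clusters exclude each other below 6.5 px (they are
  extended objects at the imaging resolution); clusters reaching the cSMAC
  leave the annulus and are replaced by a new cluster nucleating in the
  outer annulus. Brightness is lognormal (sigma 0.2) around 1500
  photons/frame; PSF sigma 60 nm (TIRF-SIM scale resolution; a
  conventional-TIRF 120 nm sigma makes neighboring clusters unresolvable
  and detection accuracy targets unreachable by any detector).
* **Waves:** fronts nucleate at 0.15/s (primary-type profiles) at radii
  between the cSMAC and half the cell radius, as arcs of 0.9 rad (FWHM of a
  Gaussian angular envelope), expand at 40 nm/s and dissipate at 0.92 of
  the cell radius — real waves die in the lamellipodium, and fronts parked
  at the membrane would sit inside the saturated boundary gradient that the
  Sobel band deliberately rejects.
* **Coupling:** contact capture — the WASP-mediated linkage forms when a
  front's leading edge reaches a cluster (the cluster sits between 600 nm
  inside the front and ~2 px ahead of the crest, within the arc); clusters
  further ahead simply keep drifting until the crest arrives. A captured
  cluster advances with the front while relaxing toward a point 1 px ahead
  of the crest (approach capped at 1.5 px/frame so the motion stays
  trackable) and decouples when the front dies. Coupling probabilities are
  calibrated once against the target anterograde fractions and frozen in
  the profile table: primary/ck666 1.0 per contact, wasp_ko 0.02 (its
  anterograde fraction is drift-dominated, matching the observation that
  WASP loss abolishes TCR-wave coupling but not the anterograde actin
  flow itself), jurkat 0 (no waves).
* **Actin rendering:** lamellar cortex at 6000 photons/px/frame, dimmed to
  0.30x inside the cSMAC, carrying a frozen speckle texture (polar
  coordinates, periodic in radius) advected inward with the true flow so
  PIV has matchable structure; speckle contrast 0.06 with a (6, 10)
  sample correlation scale keeps speckle gradients near the floor of the
  Sobel band while leaving ample correlation energy for PIV. Waves render
  as a Gaussian body (sigma 330 nm, 0.15x lamella) plus a sharp crest
  ridge (sigma 1.2 px, half the body amplitude): the ridge's flanks pass
  through the [10, 40] AU band right at the crest, so edge pixels hug the
  fronts and the colocalization measure genuinely discriminates coupled
  riders from bystanders. Both channels receive Poisson photon noise and
  additive Gaussian read noise.

**Profile table** (anterograde track fractions the profiles are calibrated
to produce, with the values measured over ten cells at freeze):

| profile  | waves | coupling | design target | measured |
|----------|-------|----------|---------------|----------|
| primary  | yes   | 1.0      | 0.43          | 0.411    |
| jurkat   | no    | --       | 0.11          | 0.097    |
| wasp_ko  | yes   | 0.02     | 0.19          | 0.164    |
| ck666    | yes   | 1.0      | 0.45          | (as primary) |

## What passing tests do and do not show

The generator emulates the geometry, kinematics, photon statistics and the
cluster-wave coupling logic of the real experiment; it does not emulate
photobleaching, axial structure, SIM reconstruction artifacts, cluster
merging/splitting beyond contact exclusion, or the slow directionally
random PIV jitter of real LifeAct movies. Two consequences are documented
rather than papered over: (i) the particle-based actin cross-check
over-samples wave-borne bright features (waves are additive brightness
here), so its outward fraction exceeds the PIV fraction by more than the
corresponding gap on real data — the tests assert the direction of the
bias, not a tight agreement; (ii) the mode-2 threshold sweep resolves only
the upper end of the optimal-threshold range (see above). Passing tests
demonstrate that the algorithms recover known ground truth under realistic
noise, not that the biological conclusions hold for any particular real
movie.

## Problem sizes

Study conditions use ten simulated cells per profile in the test suite and
twenty in the acceptance script (seeds base+0, base+1, ...), 200 frames of
162x162 px each; a full three-profile acceptance run completes in about
five minutes on one CPU. Unit tests use the same machinery on
shorter movies where full length is not needed.
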