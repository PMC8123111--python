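# Methods

This note documents the models, numerical choices and limitations behind
`wcdetect`. Everything quantitative below is either a documented default or
a quantity the test suite / `scripts/acceptance.py` computes at run time.

## Survey simulator

The simulator emulates a compact dual-transducer hydrographic multibeam:
256 equiangular receive beams per transducer over a 75.1° across-track fan
(0.29° per beam), the two fans tilted so their union is exactly 130.1° over
512 beams (20.1° overlap at nadir), 2.6 Hz ping rate, 0.64 m range bins and
a nominal 1° along-track beam opening. The vessel runs parallel transects
lawnmower-style; ping positions advance by `vessel_speed / ping_rate` along
track (0.77 m at the default 2 m/s).

Modelling choices:

* **Backscatter units.** Values are uncalibrated volume backscattering
  strengths (dB, relative). The background level (−85 dB default) and all
  thresholds are configuration values expressed as offsets from it, since
  an uncalibrated system defines no absolute scale.
* **Speckle.** Additive Gaussian noise in the dB domain, σ = 2 dB by
  default. Real reverberation statistics (Rayleigh-like in amplitude) are
  not modelled; dB-domain Gaussianity is a simple stand-in that exercises
  the cleaning chain.
* **Seafloor.** Flat, constant depth (77 m default, matching a muddy-sand
  shelf site) with smoothed seeded roughness (σ = 0.3 m); the echo is a
  strong (+45 dB) return spread over two range bins per beam, and samples
  more than 10 m of slant range beyond it are no-data.
* **Targets.** Fish schools are anisotropic ellipsoids drifting
  horizontally below 5 m/s; gas seeps are narrow cylinders with jittered
  radius, released at the seabed, rising (default 11–13 m/s) and
  re-spawning at the bottom so the seep spans seabed to surface over time;
  platform legs are static rectangular pillars spanning the water column
  whose backscatter grows toward the bottom (which pushes the apparent
  mass centre deep, as observed for real structures); noise patches are
  weak diffuse boxes. Each target's along-track footprint is widened by
  `r·tan(0.5°)` per side — the along-track beam opening — so that narrow
  static targets are insonified over several consecutive pings, as they
  are in real data; without this a 2 m leg would appear in only two pings
  and be erased by the 3×3 erosion filter.
* **Structured noise.** Sidelobe arcs replicate strong water-column
  samples (> background + 30 dB) across ±4 neighbouring beams at constant
  range (+7 dB); a near-surface entrained-air layer (3 m, +12 dB) and
  optional full-range glare pings complete the noise model. Arc and layer
  samples are ground-truthed NOISE. The default noise intensity was chosen
  so the synthetic class mix resembles a platform-site survey: fish
  dominant, noise a small minority.
* **Determinism.** One survey-level seed drives a single `numpy`
  Generator plus per-target spawned streams; identical configuration and
  seed reproduce the ping sequence bit-for-bit.

What passing tests on this generator do *not* show: performance under
calibrated absolute Sv, realistic reverberation statistics, vessel-motion
residuals, multipath, or biological variability of school shape. The
end-to-end accuracy below is a statement about the pipeline's internal
consistency at a realistic geometry and SNR, not about any real survey.

## Echogram cleaning

Stacking takes the per-range maximum over all beams of both transducers
(no-data ignored; all-no-data stays no-data). Order-statistic filters
(3×3 median, 3×3 minimum/erosion, 3×3 dilation over the *eight surrounding*
samples, centre excluded) are computed in dB, where they equal their
linear-domain counterparts; the 45-sample smoother (3 beams × 5 pings × 3
range bins, centre included) averages in linear power and returns to dB.
Edges are replicate-padded everywhere. The smoother's neighbourhood is the
true consecutive ping sequence — not the subset of selected pings — so
targets never smear across survey gaps.

Bad-ping rejection removes pings whose fraction of valid stacked bins
above `background + 15 dB` reaches 0.98. Glare pings measure ≈ 1.0 under
this rule; a nadir pass over a full-column target plus the outer-beam
seafloor band legitimately reaches ≈ 0.94, which is why the cut sits where
it does.

The bottom line takes, per ping, the strongest stacked sample beyond the
4 m near field (the minimum slant range of the seafloor), then a median
consensus over a 5-ping window; it is undefined where no peak exceeds
`background + 30 dB`. The surface-exclusion line scans from a reference
line (the surface) for the first threshold crossing between consecutive
bins, adds a configurable offset, and falls back to reference + offset when
no crossing exists; the pipeline caps it at 12 m so that a spurious deep
crossing can never mask the whole column. Ping-of-interest selection masks
outside the two lines, dilates the above-threshold bitmap and keeps pings
with any surviving sample.

Because the stacked view is a range (not depth) axis, everything beyond
the *minimum* seafloor range is invisible to ping selection even when, at
outer beams, it is genuine water column. Selected pings are therefore
re-examined in the fan domain, where masking is depth-based (4 m near
field; deeper than the TIN minus a 2 m offset is excluded — 1 m proved too
small once the smoother smears the bottom echo upward).

## Extraction and metrics

School detection labels 8-connected above-threshold components on the
angle-sorted 512-beam lattice (detection threshold `background + 10 dB`,
minimum height and width 1 m; all configurable). Each component's polygon
is the union of its true cell footprints — quadrilaterals spanned by
θ±Δθ/2 and r±Δr/2 — simplified with a 2 cm tolerance; lattice-adjacent
cells share edges exactly, so a component is always one polygon. Slices are
extruded ±0.4 m along track into a prism (n cross-section vertices → 2n
prism vertices, 2(n−2) cap + 2n wall triangles via ear clipping), giving
surface area, and volume = 0.8 × cross-section area.

Tracking links slices in pings at most one apart whose 3D world centroids
lie within 5 m, and takes connected components of the link graph; at
2.6 Hz and < 2.6 m/s ping spacing is below 1 m, so persistent targets form
multi-slice objects. Centroid linkage was chosen over overlap because
rising gas displaces its cross-section by several metres between pings.

The 24-metric schema is computed per slice. Conventions that the source
description leaves open, fixed here once: mass weights and Sv sample means
use linear power (10^(Sv/10)); "surface area" is the prism's total surface
area, making Base = surface area / height an identity; bounding-box
lengths are the two largest of (across-track extent, vertical extent,
0.8 m); relative depth in time is (depth_i − depth_{i+1}) / Δt using
geometric-centre depths, so rising targets are positive, the last slice of
an object inherits the previous value and singletons are 0; flattened
coordinates use a local equirectangular projection (111 319.49 m per
degree at the equator) about the survey's own centroid; the k-means
cluster feature (k = 4, seeded, standardized inputs: prism vertex count
and mass-centre latitude/longitude) is refit per survey.

## Classification

Operator review is emulated by labelling a seeded ~15% of slices from
ground truth, portioned equally among the classes present. Ground truth for
a slice is the linear-power-weighted class vote pooled over its whole
multi-ping object: a per-ping vote would mislabel the along-track halo
slices of a moving target, which an operator — who judges the object, not
the single cross-section — would not.

Labels are first extended within multi-ping objects (majority; exact ties
logged and left unresolved). All features except the six raw-coordinate
columns and the categorical cluster code are Yeo-Johnson transformed and
standardized, with the transform fitted on the training survey and stored
for transfer. Mutual-information scores are reported for inspection but do
not alter the fixed schema.

Pseudo-labelling fits a distance-weighted Euclidean kNN (k = 5) on the
labelled rows and labels the rest in one unconditional pass (a confidence
threshold exists but is off by default). The kNN operates on the same
coordinate-free feature space as the ensemble: with raw coordinates
included, labels propagate by position, and a fish school adjacent to the
seep field inherits GAS. Its quality is reported on a stratified 30%
hold-out of the labelled rows.

The pseudo-labelled table is stratified-split 70:30. A gradient-boosting
classifier is grid-searched (learning rate {0.05, 0.1} × trees {100, 300}
× depth {2, 3}) by mean 5-fold stratified CV accuracy, ties broken toward
fewer trees, then shallower depth, then lower learning rate, and refitted
on the full training part. The six raw-coordinate columns are removed so
the model transfers across sites. The persisted bundle carries the
normalizer, the ordered feature schema, the exclusion list, the kNN spec
and all metadata; prediction on an unseen survey validates the schema,
recomputes the survey-local features (flattened coordinates about the new
centroid, cluster refit with the stored seed) and applies the stored
normalization.

## Problem sizes and tolerances

The reference scene used by the tests and the acceptance script is a 500
ping survey (5 transects × 100 pings) of a 200 m square in 77 m of water —
full instrument geometry (512 beams × ~310 range bins per ping) with six
fish schools, four gas seeps, four platform legs and three noise patches.
This desk-scale layout keeps a complete end-to-end run at a few minutes on
one CPU while exercising every stage; the real surveys it is patterned on
cover 1.5 km squares over ~10× more pings.

Numerical tolerances used in validation: filter outputs match brute-force
window oracles exactly (same arithmetic); polygon areas match summed cell
areas to 2% (corner buffering + 2 cm simplification); prism volume and
surface-area identities hold to 1e−9 relative; depth ratio of a uniform
symmetric slice is 1 within 0.02 (polar cells widen with range, so the
area centroid sits slightly deeper than the sample mean); end-to-end
slice-level classification accuracy is required to reach 0.90 on three
replicate seeds, with rising gas showing positive relative depth in time
and platform legs within 0.1 m/s of zero.

## Known limitations

* The stacked-beam stage cannot select pings whose only targets lie
  beyond the minimum seafloor range (deep targets at outer beams); such
  targets are recovered only when the ping is selected for another reason.
* Slice polygons drop interior holes (a ring-shaped cross-section is
  filled); none arise from the simulated target shapes.
* Tracking is purely proximity-based; two targets crossing within 5 m
  merge into one object, and label extension would then blend them.
* The Echoview algorithms this pipeline mirrors (Best Bottom Candidate,
  school detection, region tracking) are proprietary; the implementations
  here follow their documented behaviour, not their internals, and
  parameter defaults are this package's own.
* Real-data effects outside the simulator (calibration drift, motion
  residuals, multipath, turbidity) are untested by construction.
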