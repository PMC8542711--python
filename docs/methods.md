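# Methods

`pulseid` implements an offline workflow for studying dyadic interactions of
pulse-type weakly electric fish (mormyrids such as *Gnathonemus petersii*):
every electric organ discharge (EOD) in a multichannel tank recording is
detected, normalized, and attributed to one of two video-tracked
individuals, and the electrosensory consequences of each discharge are
reconstructed with a boundary element model. This note documents the models,
their assumptions, the default parameters, and what the synthetic test bed
does and does not establish.

## Dipole field model

A swimming fish is mimicked by a two-point dipole: charges of equal
magnitude and opposite sign at the head and tail, separated by the body
length L. The potential at a point is

    V = kq (1/R1 − 1/R2)

with R1, R2 the distances (cm) to the head and tail pole. The
proportionality constant and the charge are folded into a single scale
`kq` (default 1, i.e. the charge is the reciprocal of the constant):
only relative channel amplitudes matter for localization, and with cm
units and a 10 cm wall margin this convention keeps every simulated
channel within ±1 V. The model is two-dimensional (electrodes 5 cm above
the floor in 12 cm of water) and deliberately ignores tank-wall boundary
effects; it is a screening tool for electrode layouts, not a quantitative
field model.

Placement sampling draws 2,500 positions/orientations of 20 fixed body
lengths spaced evenly over 8–15 cm. Orientations are uniform on [0, 2π);
the *whole* fish (both poles) stays at least `wall_margin` = 10 cm from
every wall — the stricter of the two possible margin readings. Whether the
placements should be balanced across the 20 lengths is unspecified; we
assign lengths uniformly at random.

### Electrode configurations

The six benchmark layouts are reconstructions: the original study shows
them only graphically, without coordinates. We place seven recording rods
on the walls of a 66 × 72 cm tank:

1. short-baseline (10 cm) differential pairs spread around the perimeter,
   pair axes alternating between wall-tangential and inward-normal
   (the layout used everywhere downstream);
2. fourteen perimeter electrodes paired diametrically, so the differential
   axis rotates from pair to pair and every axis crosses the middle of the
   tank — this layout is nearly blind to the mirror position of a fish
   about the tank centre and localizes poorly near the walls;
3. seven perimeter electrodes recorded single-ended against a ground
   electrode in the tank centre;
4. as 1 but with all pair axes wall-tangential;
5. pairs clustered on the two short walls;
6. a perpendicular net of five tank-spanning pairs plus two
   corner-to-corner diagonals.

Because the reconstruction is ours, only the robust qualitative outcome is
asserted in tests: layout 2 ranks worse than layouts 1, 3 and 4, and
layout 1 supports held-out R² ≥ 0.9 with median position error ≤ 2 cm.

## Localization from channel potentials

`DipoleLocalizer` is a scikit-learn estimator wrapping a 25-tree random
forest predicting the 5-target vector (x, y, sin θ, cos θ, L) from the 7
channel potentials. Training uses a seeded 75/25 split; a randomized
search over a declared grid (max depth, min leaf size, feature fraction,
bootstrap on/off) evaluates exactly 25 candidate settings by 3-fold
cross-validation on the training split — a budgeted search standing in for
an unspecified 25-iteration grid search. The score is the aggregate
coefficient of determination R² = 1 − u/v with u the residual and v the
total sum of squares over all samples and targets. The spatial error is
the per-sample Euclidean distance between true and predicted (x, y); error
maps aggregate mean error on a 2 × 2 cm grid and keep cells above a 3 cm
threshold (cell size is our choice).

An optional single-hidden-layer perceptron baseline (width 50/100/200,
identity output, 10,000-iteration cap) is provided for model comparison;
it is not on any acceptance path.

## EOD detection and waveform vectors

Detection applies a separate threshold to the absolute voltage of each of
the seven channels (polarity depends on fish orientation, so absolute
crossings are the documented choice; a 6-sigma default is derived from a
robust per-channel noise estimate). Each crossing is aligned to the peak
of the channel-averaged absolute trace; aligned events closer than the
400 µs refractory time are merged, keeping the earlier event. Windows of
272 µs before and 128 µs after the peak are cut identically on all
channels — at 125 kHz exactly 34 + 1 + 16 = 51 samples — concatenated
channel-major and divided by the global absolute maximum, giving a
357-sample vector with max |v| = 1 exactly. Events whose window would
cross a recording edge are dropped and logged, not padded.

Doublets (two fish discharging within one extraction window) are screened
by the L1 distance between each event's normalized mean-absolute trace
and the normalized average trace (L2 selectable); the flag threshold is
the (1 − f) quantile of the residuals with f = 0.01 by default, roughly
matching the observed ~0.75 % contamination of real dyadic data. Flags are
resolved by the user (CSV decisions file); confirmed doublet times are
credited to both fish after automatic assignment.

## Identity assignment

`EodPositionRegressor` (100-tree random forest) maps normalized waveform
vectors to the 12 coordinates of the six-node skeleton
(Schnauzenorgan, head1, head2, mid1, mid2, tail; head2 is the anchor).
Training data come from single-fish sessions only, where identity is
unambiguous. At each dyad EOD the predicted skeleton is compared to both
tracked skeletons; the default aggregate is the sum of the six
node-to-node distances (RMS selectable — the two orderings differ only in
edge cases), nodes invisible in either candidate being excluded from both
sums symmetrically. The fish with the smaller aggregate is the emitter;
exact ties break to the lower fish id with a review flag. The absolute
difference of the two aggregates (delta error) orders the review queue:
wrong assignments concentrate where delta error is small, so manually
checking the smallest 5 % captures a disproportionate share of errors.

## Pose import and synchronization

Tracking files follow the analysis HDF5 layout of multi-animal pose
estimators (`tracks` (n_tracks, 2, n_nodes, n_frames), `node_names`,
`track_occupancy`); node order is remapped to the canonical six names and
missing detections become invisible nodes. Pixel-to-cm calibration comes
from the known tank width (config value). Camera exposures are timed by
TTL pulses recorded alongside the voltage channels; rising edges must
match the video frame count exactly. Poses at EOD times are linearly
interpolated nodewise between flanking frames (EOD rates can exceed
100 Hz against 30 Hz video, so nearest-frame would be coarse), with a
nearest-frame fallback for nodes invisible on one side. Identity swaps
are assumed proofread upstream; a >15 cm/frame anchor jump triggers a
warning only.

## Fish surface reconstruction

A third-order polynomial is fitted by least squares to the visible
skeleton nodes (≥ 4 required) in a fish-aligned frame whose x-axis is the
head-to-tail chord, keeping the curve single-valued for realistic bends.
49 elliptical cross-sections of 17 nodes each are placed uniformly in arc
length along the curve (the spacing rule is unstated in the source
material; uniform arc length is our choice), each ring lying in the plane
normal to the local tangent. Ring semi-axes come from a relative body
profile table — a mormyrid-like spindle, laterally compressed
(height 0.10 L, width 0.05 L at the deepest section, s^0.7 (1−s)^0.9
taper) — and scale with body length; the table is a shipped default that
users can override per ring. Apex vertices close the nose and tail with
triangle fans: V = 49·17 + 2 = 835 vertices and F = 2V − 4 = 1,666
triangles, a closed orientable surface with V − E + F = 2 for any ring and
node count. The skeleton is 2-D; the third dimension comes entirely from
the profile, and the mesh is centred vertically at half the water depth
(6 cm).

## Boundary element electric images

All media are ohmic (J = σE), charge does not accumulate, and each
discharge is solved electrostatically. Each fish is a homogeneous
conductive volume covered by a thin resistive skin: the normal current
density is continuous across the skin while the potential jumps by
ρ_skin · J_n. The electric organ is modelled as two point-current poles
(±I) on the body midline at 75 % and 90 % of arc length (caudal
peduncle); currents sum to zero, and more poles are supported by the same
assembly path.

Collocating the boundary-integral form of the interior and exterior
Laplace/Poisson problems at the N mesh nodes, with linear interpolation
over triangles, a 7-point symmetric quadrature rule, one-level-refined
quadrature for near-singular entries and a Duffy transform for the
singular single-layer self terms (the flat-triangle double-layer self
term vanishes identically), yields a dense 2N × 2N system in the per-node
surface potential and transepithelial current density. Solid-angle
coefficients are taken from double-layer row sums, which makes constant
potentials exact, and the interior equations are scaled by the body
conductivity so perfectly insulating bodies remain well conditioned.
Internal units are cm, S/cm and µA (potentials in µV, current densities
in µA/cm²).

Default materials: water 120 µS/cm (the measured tank value), body
0.5 S/m, skin 30 kΩ·cm², source amplitude ±1 mA. Skin and body values
are not reported by the source study and are flagged here deliberately:
mormyrid skin is highly resistive, and the skin default is chosen so the
electrotonic length √(ρσ_b A/P) is at least the body length. Below a few
kΩ·cm² the discretized two-domain system becomes severely ill-conditioned
(the physical cable modes of a thin, leaky body) and the collocation
solution develops standing-wave artifacts; parameter choices in that
regime require a finer mesh than the default. The source amplitude sets
only an overall linear scale; ±1 mA puts passive-image maxima in the
0.01–2 µA/cm² range over realistic inter-fish distances so the 0.1 µA
model noise floor is meaningful. Results are expressed relative to these
defaults.

The basal field is the solve with the discharging fish alone; the active
image is the nodewise difference between the two-fish scene and the basal
field at the emitter's own skin; the passive image is the stimulus at the
silent fish's skin in the two-fish scene. Image amplitude for the
detection criterion is the max over nodes of |current density| (RMS is
also reported). First detection is the earliest instant — on the union of
both fish's EOD times, the other fish's amplitude held at its most recent
value — at which one fish's received amplitude exceeds the other's by a
factor of two while also exceeding the 0.1 µA floor.

In this homogeneous-body model the basal self-image peaks near the source
poles in the tail, not at the head; the head-funneling phenomenon
described for real fish appears in the *passive* image, where the
elongated conductive body concentrates an external field at the tip
facing the source. Tank walls are absent (infinite water), capacitive
skin impedance and receptor transduction are out of scope.

## Dyad statistics

Dominance within a pairing is the strict majority of manually annotated
attacks (ties are undetermined, not an error); the size classes split at
a 20 % length difference, with the boundary value assigned to "small"
(the "large" class is strictly greater). All tests are exact one-sided
binomial upper tails P(X ≥ k); this sidedness reproduces every printed
value of the source analysis (5/5 → 0.03125, 9/13 → 0.1334,
4/8 → 0.6367, 10/13 → 0.0461, 5/8 → 0.3633), and full precision is
reported rather than truncation. The approach-predictor summary counts,
per modality and size class, how often the fish that initiated the first
contact is also the fish predicted to have detected its contender first.

## Synthetic test bed

The fixture generator emulates the acquisition chain end to end:
heading-random-walk trajectories (8 cm/s, heading diffusion
1.5 rad/√s, reflected at the 10 cm margin) carrying a six-node skeleton;
gamma-distributed inter-pulse intervals (shape 3, mean 50/60 ms per fish
— within the few-Hz-to->100 Hz range of pulse fish); biphasic
difference-of-Gaussians EOD templates whose second-phase width differs by
10 % between fish (mimicking small individual waveform differences); per
channel injection scaled by the dipole model at the interpolated pose;
Gaussian channel noise calibrated so the weakest event's strongest
channel sits at SNR 10; a TTL pulse per video frame; and ground-truth
tables for every planted EOD. All generators are bit-reproducible under a
fixed seed.

What passing the closed-loop test shows: with ~1,400 single-fish training
EODs and ~1,000 dyad EODs at SNR 10 the detect → train → assign chain
recovers ≥ 96 % of identities, errors concentrate at short inter-fish
distances, and reviewing the smallest-delta 5 % captures far more than
5 % of the errors. What it does not show: robustness to real-world
nuisances absent from the generator — wall boundary effects on the
fields, amplitude changes with fish posture, tracking identity swaps,
electrode drift, or EOD waveform nonstationarity. The synthetic dyad is a
correctness harness, not a substitute for validation on recorded data.

## Problem sizes and numerical choices

Default problem sizes were chosen to keep each analysis step in the
seconds-to-minutes range on a single core: the placement study uses 2,500
samples; BEM meshes default to 49 × 17 nodes per fish (two-fish systems
of 3,340 unknowns solve densely in seconds) with 25 × 13 used in
multi-solve sweeps; the closed-loop harness uses 80 s of single-fish and
28 s of dyad recording at the full 125 kHz rate. Linear systems are
solved by dense LU; a solve reports its relative residual, and scenes are
validated (closed meshes, balanced sources, positive conductivities)
before assembly. Degenerate inputs fail loudly: coincident dipole poles,
all-zero windows, unresolved doublet flags, TTL/frame count mismatches
and out-of-range pose queries all raise typed errors.

## Known limitations

- The dipole mimic ignores tank walls; near-wall channel amplitudes are
  biased relative to a real tank, which is one reason the study trains
  the real-fish assigner on recorded data rather than simulations.
- The BEM assumes piecewise-homogeneous bodies and purely resistive
  skin; low skin resistivities need finer meshes than the default.
- Assignment is limited to dyads by construction (candidate set of two);
  extending to larger groups requires both more electrodes and a
  doublet model for >2 overlapping discharges.
- The electrode layouts are reconstructions; absolute errors for layouts
  other than 1 should not be compared against the original figures.
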