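# Methods

## The coarse-grained mechanism model

The rotary device is reduced to seven degrees of freedom: the camshaft
angle θ (degrees) and the outward radial deflections d₁..d₆ (nm) of the
six stator pawls.  Internal units are k_BT (at 295 K), nm, degrees and
seconds; the one documented unit conversion is the steering stiffness,
0.5 kcal/mol/deg² ≈ 0.853 k_BT/deg² at 295 K.

The potential energy is

```
U = Σⱼ ½ k_pawl dⱼ²                              pawl bending
  + Σⱼ ½ k_steric (cⱼ(θ) − dⱼ)²  for dⱼ < cⱼ      cam–pawl contact
  + Σ_pairs ½ k_pair (dⱼ − dₖ)²                   inter-pawl couplings
  + strut terms (below)
  − stack_depth Σⱼ exp(−(dⱼ/stack_range)²)        blunt-end stacking
```

with required clearance `cⱼ(θ) = h·g(θ−φⱼ; w)` where `g` is a cosine
taper (g(0)=1, g(±w)=0, C¹).  Forces are therefore C⁰-continuous with
bounded curvature everywhere, which keeps plain Euler–Maruyama stable.
Deflections may go slightly negative; the stacking well at d = 0 provides
the inward restoring force, avoiding hard constraints.

**Geometry (calibrated, not predicted).**  Pawls sit at the unit centers
(0°, 120°, 240°) ± 25°; cam half-width w = 30°; cam protrusion h = 5 nm
past a bore radius r₀ = 10 nm; lever radius R = 290 nm (the designed
pointer length).  h and r₀ are calibration choices that reproduce the
~5 nm pawl deflections seen during forced rotation; they are not
independent predictions.  The six circular midpoints between adjacent
pawls are the slots: three "inter-unit" (60°, 180°, 300°) and three
"intra-unit" (0°, 120°, 240°).

**Variant couplings.**  A *rigid* cross-link is a stiff difference spring
(k = 100·k_pawl) — so one integrator covers all variants — **plus** a
steric strut spanning the slot between the linked pawls, because a strand
cross-link physically occupies that gap ("removes the slot").  A strut
between the two pawls of one unit rides on its pawls (its clearance is
relieved by their mean deflection); a strut bridging the inter-unit
interface is backed by the rigid bearing blocks of both units and is
treated as immobile.  This distinction is the model's account of why
intra-unit coupling (variant 3) merely removes three slots while
inter-unit coupling (variants 4 and 6) blocks the slots the shaft
actually uses and stalls the rotor: a plain radial difference coupling
alone cannot distinguish the two cases (they are related by relabeling).
A *spacer* (25-thymidine-like) linkage restores flexibility and pushes
the flanking pawls apart; it is modeled as a soft difference spring
(k_couple) plus a reduction of the effective cam–pawl overlap,
h_eff = h − δ, for its pawls.

**Default mechanical parameters** (one consistent, calibrated set — the
experiments report no stiffness values):

| parameter | default | role |
|---|---|---|
| k_pawl | 0.12 k_BT/nm² | radial pawl stiffness |
| k_steric | 10·k_pawl | contact stiffness (soft steric) |
| k_rigid | 100·k_pawl | "rigid" coupling limit |
| k_couple | 0.05 k_BT/nm² | spacer/spring coupling |
| δ (couple_rest) | 4 nm | spacer overlap reduction |
| stack_depth | 0.7 k_BT | per-pawl stacking well |
| stack_range | 1.5 nm | stacking decay length |
| D_θ | 2×10⁴ deg²/s | bare camshaft rotational diffusion |
| D_pawl | 5×10³ nm²/s | pawl deflection diffusion |

The calibration targets are the *relative* behaviors reported for the
designs: disabling stacking roughly doubles mobility (sets stack_depth),
the spacer variant is fastest (sets δ), intra-unit coupling leaves
mobility within the same order of magnitude as the reference (the higher
two-pawl barrier of variant 3 is largely compensated by its 120° instead
of 60° step length), and the inter-unit-coupled variants stall.  The
diffusion coefficients are effective values chosen so slot hopping occurs
at a few per second — resolvable at 20 frames/s — not molecular-level
predictions.  Absolute rates and D_eff values from this model are
therefore not quantitative predictions; orderings and geometric phases
are.

**Integrator.**  Euler–Maruyama with fixed dt = 2 µs (per-coordinate
update `x ← x − D ∂U/∂x dt + √(2D dt) ξ`, energies already in k_BT), one
seeded RNG stream per trajectory, bit-reproducible.  A precondition check
warns when the worst-case drift per step exceeds 10% of the cam height or
half-width.  States are recorded every 1 ms by default; trajectories
store the unwrapped angle.  Non-finite states abort with the step index.

**Steered rotation** adds `½ k_spring·wrapdiff(θ − θ_rest(t))²` with
θ_rest advancing at 90°/s (default) for three full turns in each
direction; configurations from both runs are pooled, binned every 10° of
wrapped θ, and each subunit's cam-to-subunit distance curve (Euclidean
distance between the cam tip at radius r₀+h and the unit's pawl midpoint
at radius r₀ + mean deflection) is fitted with a first circular harmonic
to extract amplitude and phase; adjacent-subunit phase offsets are
circular differences.

**Effective landscape** U_eff(θ) = min_d U(θ,d) is computed by L-BFGS-B
(analytic gradients, warm-started along the grid, two fresh starts per
point to escape the stacked/open bistability).  Minima are detected with
a 0.1 k_BT prominence filter and placed at the circular midpoint of flat
basin bottoms.

**Mobility** is the slope of the time-lag MSD of the unwrapped angle,
fitted as `MSD = 2 D_eff t + b` over lags 0.05–0.5 s (clipped to
duration/20); the intercept absorbs the intra-well plateau.  A block
bootstrap over angular increments gives the confidence interval.  Slot
hops are counted with hysteresis (within 15° of a new slot center for ≥3
consecutive records); fewer than 5 hops flags the run "stalled", in which
case D_eff is only an upper bound.

## The synthetic movie generator

The generator emulates single-particle TIRF movies of the surface-
anchored mechanism whose camshaft carries a fluorescent lever arm.  What
it reproduces: 20 frames/s acquisition with 5 ms laser-on time; a
diffraction-limited spot (pixel-integrated Gaussian PSF) circling a fixed
anchor at R/pixel_size ≈ 2.9 px; Poisson shot noise, camera gain, read
noise, offset and clipping; optional linear plus random-walk stage drift;
stationary and blinking ("defective") control particles and an optional
stator-fixed reference spot.  Angle traces come either from mechanism
simulations or from a three-state Markov hopping model (Gillespie-
sampled; states 120° apart; mean dwell 1.5 s; an Ornstein–Uhlenbeck
intra-state wiggle of σ = 7°, τ = 0.1 s, emulating the restricted
rotary wiggling of a docked shaft).

Assumed (unreported) imaging parameters: 100 nm pixels, 130 nm PSF σ,
5000 photons/spot/frame, 20 background photons/px/frame, gain 2, read
noise 3 counts.  Motion blur over the 5 ms exposure is available but off
by default (5 ms ≪ 50 ms frame interval).  Not modeled: EMCCD excess
noise, 3D/astigmatic PSFs, evanescent-field depth, dye photophysics
beyond simple two-state blinking.  Passing tests against this generator
demonstrates correctness of the analysis chain under a realistic noise
model — not robustness to every artifact of real microscopy (e.g.
overlapping particles, non-uniform illumination, slow focus drift).

## Tracking

Drift is estimated by upsampled phase cross-correlation against a
reference frame (median-subtracted images; failed registrations are
flagged and carry the previous shift forward) and corrected by bilinear
sub-pixel translation with a border mask.  Registration needs stationary
features in the field; a lone rotating particle biases it.

Screening follows the std-image logic: rotating particles appear as
rings, stationary ones as compact spots.  Candidates are connected
components above a robust threshold (median + 6·MAD); each is scored by
annularity (mean std on the best ring ÷ std at the center), classified
rotary if the score exceeds 1.4 with ring radius in [1.5, 6] px,
otherwise defective if the local intensity on-fraction is below 0.6
(with a noise-contrast gate so steady spots are not misread as
blinkers), else stationary.  All thresholds are configuration.  This
replaces manual picking and visual sorting with an explicit, testable
criterion.

VWCM localization: square window of half-width 5 px applied with
fractional edge weights (the estimate varies smoothly with window
position), background = median of the window perimeter, residual clipped
at zero, centroid update, tolerance 0.01 px, ≤50 iterations.  The
original analysis names the approach but not its parameters; this is one
explicit, tested variant, validated against generator ground truth
(noiseless recovery < 0.02 px; noise-free end-to-end tracking < 0.05 px;
precision within 1.5× of the shot-noise bound) rather than claimed
bit-equivalent to any prior script.  Non-converged frames are flagged and
excluded downstream, never interpolated; tracks truncate after 10
consecutive failures.

## Angular statistics

The center of motion is an algebraic (Kåsa) circle fit refined by
geometric least squares; it requires ≥10 converged points spanning ≥90°
of arc.  Angles use atan2 in image coordinates (+x toward +y, y down) and
unwrap by mapping each increment into (−180°, +180°]; gaps ≤10 frames are
bridged by the same rule, longer gaps split the trace.  Orientation
states are found by circular k-means (circular distances and means, best
of 10 seeded restarts, k = 3 by default and configurable — the data
cannot by themselves exclude six shallower states).  Two RMSD readouts
are provided because the printed formula is single-origin while the
diffusion plot needs time dependence: `rmsd_single` evaluates
√(Σ(θᵢ−θ₀)²/N) exactly, and `rmsd_ensemble` averages squared increments
over traces and sliding origins, fitting `RMSD = A√t`.  Velocities are
computed on unwrapped angles (so wrap crossings cannot inject ±360°/Δt
outliers); ensemble means weight each sample equally, i.e. traces count
by their length — the interpretation adopted for "weighted average",
switchable by the caller.  Dwell analysis run-length-encodes state
labels, absorbing runs shorter than min_dwell into the preceding run and
censoring the first and last runs.  A trace is "rotary" iff its unwrapped
span strictly exceeds 200° and it shows ≥2 inter-state transitions;
these thresholds are explicit configuration standing in for a visual
judgment.

## Problem sizes and determinism

Default study sizes: ensemble statistics use ≥50 tracked particles at
30 s (600 frames) each; three-state recovery uses eight variant-3
trajectories of 45 s rendered and tracked end to end; variant mobility
uses 20–60 s equilibrium runs (hundreds of slot hops for the mobile
variants); steered cycles use three full turns per direction.  Every
stochastic entry point takes a seed; pipelines fan a single global seed
out to named substreams (SeedSequence over a CRC of the stage name), so
full runs reproduce byte-for-byte.

## Known limitations

* The stator's global twist and elastic deformation modes are not
  modeled; only relative cam–pawl geometry enters, which suffices for the
  cycle observables but not for predicting absolute deformation maps.
* The immobile-strut treatment of inter-unit cross-links is the model's
  sharpest simplification; it encodes "the pawls cannot give way" as an
  infinite-stiffness limit rather than deriving it from DNA mechanics.
* Hydrodynamic coupling between coordinates, base-pair-level structure,
  and dye photophysics are out of scope.
* D_θ, D_pawl and all stiffnesses are effective, calibrated quantities;
  only orderings, phases, and recovered geometry should be compared
  against experiments.
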