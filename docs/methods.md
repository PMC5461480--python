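# Methods

## Model overview

`myovasim` simulates a rigid spherical cargo (default 350 nm diameter)
carried by `n_motors` (default 10) myosin Va HMM molecules whose membrane
anchors are free to diffuse on the cargo's fluid surface, walking along
rigid suspended actin filaments. The state is the set of bound heads
(lattice sites) plus the cargo centre; everything else is integrated out:

* **Fluid membrane ⇒ no rotational state.** Because anchors slide freely
  on the sphere, a bound motor's anchor is taken at the sphere point
  nearest its head, and free anchors are uniformly distributed (membrane
  diffusion, 0.92 µm²/s, relaxes in ~R²/2D ≈ 17 ms, shorter than typical
  event intervals). Rotating the sphere then moves no anchors and stores
  no energy, so the cargo pose reduces to its centre position. Explicit
  Brownian sub-stepping of the free anchors (0.1 ms steps) would only
  re-derive this uniform distribution, so it is not simulated.
* **Quasi-static mechanics.** After every discrete event the centre is
  relaxed to a local minimum of the total elastic energy: extension
  ½k_ext(ℓ−ℓ₀)₊² per taut linkage (slack in compression — a 50 nm
  flexible molecule cannot push), torsion ½k_tor·θ² about each bound
  filament's axis, a harmonic trap when configured, and a stiff quadratic
  penalty (100 pN/nm) for sphere–cylinder overlap with any filament
  (radius 4 nm), which leaves sub-0.1 nm residual penetration at
  piconewton forces. Minimization is damped Newton with an analytic 3×3
  Hessian and Armijo backtracking (gradient tolerance 10⁻⁵ pN — forces of
  interest are ≥10⁻³ pN); Newton is required because the torsional mode
  is ~10⁷ times softer than the contact penalty. The relaxed energy never
  exceeds the starting energy, and a warm start means a fully slack pose
  does not drift.
* **Exact-time kinetics.** Between relaxations all propensities are
  frozen and the next event is Gillespie-sampled, so there is no
  time-step bias. A run is bitwise reproducible from its configuration
  and seed.

## The actin lattice and stepping

Filaments carry a discrete helical lattice with 2.75 nm axial rise and
−166.15°/subunit twist (standard F-actin constants; left-handed genetic
helix). A 13-subunit step advances 35.75 nm and is azimuthally neutral
(−2159.95° ≡ +0.05°); an 11-subunit short step advances 30.25 nm and
rotates the bound head by −27.65°. Short steps therefore drag the cargo
azimuthally and are the origin of the left-handed spiral; the expected
spiral rate is 27.65° × p_short × k_step ≈ 70°/s, giving pitch
≈ 360·v/ω ≈ 2.1 µm at the default parameters.

Mechanically, a bound head is attached at the filament-axis point of its
site: the 4 nm radial monomer offset matters for azimuth bookkeeping but
is negligible against the 225 nm tether, and coupling it into the
extension energy injects a spurious sub-thermal azimuthal torque that
biases the spiral.

The torsion reference azimuth is set when a motor binds and advanced by
each step's lattice twist (the new lead head re-anchors on the rotated
site), so the weak torsional spring pulls the cargo azimuth after the
drifting binding sites instead of fighting them.

## Kinetic parameters

All rates are Bell-form, `k(F) = k₀·exp(±F·δ/kBT)` with kBT = 4.1 pN·nm.
The published observables anchoring the calibration are the unloaded cargo velocity
(423 ± 24 nm/s), the left-handed pitch (2,120 ± 200 nm), the ensemble
attachment (~2.4 s⁻¹) and unloaded detachment (~0.35 s⁻¹) rates, the
modal engaged count of 3, and the measured single-motor stall peak
(~1.9 pN). The microscopic constants below are calibrated to reproduce
those observables; they are not transcribed from any table.

| parameter | default | role |
|---|---|---|
| k_ext | 1 pN/nm | linkage extension stiffness |
| k_tor | 0.25 pN·nm/rad | linkage torsion about the filament |
| rest_length | 50 nm | HMM tether length = motor reach |
| k_step0 | 15 s⁻¹ | unloaded forward stepping (head speed ~500 nm/s; ensemble drag yields ~450 nm/s cargo velocity) |
| p_short0 → p_short_stall | 0.17 → 0.50 | short-step fraction, rising linearly to stall |
| step_distance_param | 3.4 nm | forward-step Bell distance |
| k_back0, back_distance | derived, 3.4 nm | back-step channel; k_back0 is solved from the stall condition v(F_stall) = 0 |
| stall_force | 1.55 pN | zero of the net stepping velocity. Measured stall *peaks* overshoot this root by about half a step of trap force (36 nm × 0.019 pN/nm = 0.68 pN per step), so detected single-motor peaks average ~1.9–2.0 pN, the canonical value. |
| k_detach0 | 0.35 s⁻¹ | unloaded detachment |
| detach_distance | 1.0 nm | Bell distance under resistive load |
| detach_distance_assist | 1.8 nm | Bell distance under assisting load — a dragged motor lets go much faster than one resisting backward load (myosin V load asymmetry); this sheds rear "passenger" motors and keeps transport fast |
| k_attach_max | 2.4 s⁻¹ | ensemble attachment ceiling |
| footprint_radius | 40 nm | membrane disc swept by a bound HMM, excluded from new anchoring |
| site_exclusion | 26 subunits (~72 nm) | lattice corridor a *newly arriving* motor must clear around each bound head; established motors tread through each other's sweep |

**Ensemble-size restriction.** Attachment propensity is
`k_attach_max · (n_free/n_motors) · min(f/f_ref, 1)`, where `f` is the
fraction of membrane directions whose anchor point reaches an available
site within the rest length, excluding the membrane and lattice
footprints of bound motors, and `f_ref` is the same fraction for a bare
cargo tethered by a single motor (the calibration state for the ~2.4 s⁻¹
contract). The strip of membrane within reach of a filament is only
~100 nm wide and ~250 nm long, so each bound motor's footprint removes a
large share of it; together with crowding-induced detachment this yields
a modal engaged count of 3 without any hard cap. In this realization the
engaged count still exceeds 3 for ~20% of attached time (transient
quads that assist-shedding removes within ~0.5 s); parameter scans showed
that pushing this below 5% flips the census mode to 2 or drops the
velocity out of its band, so the heavier quad tail is accepted as a known
limitation.

## Intersections

The standard scene places the original filament South→North through the
origin (plus end North) and the intersecting filament East–West at
height d ∈ [50, 250] nm. A transit starts with one motor bound 1.5 µm
upstream (ensemble size equilibrates during the approach) at a uniformly
random azimuth; because the spiral randomizes azimuth anyway, the
*measured* approach angle (circular mean over the ten 100 ms frames
before the crossing, 0° = intersecting side) is uniform. Outcomes:
straight = exit ≥500 nm past the crossing on the original filament;
turn = exit ≥500 nm along the intersecting filament, left/right by the
compass rule (East = right); terminate = all motors released within
interaction range of the crossing, or dwell within ±225 nm of it beyond
10 s. Batch statistics keep transits that reached the crossing with an
interacting measured geometry (d ≤ d_int(α) = (R+L)(1+cos α)), mirroring
the experimental 94/103 filtering. Runs whose ensemble died upstream are
excluded (they never met the intersection); ~20% do at defaults.

Two caveats discovered in simulation. First, roughly a fifth of transits
whose *measured* approach angle predicts no interaction still capture the
intersecting filament, because the spiral (~70°/s) keeps rotating the
cargo between the measurement window and the transit itself; the
experimental non-interacting sample (n = 9) was too small to resolve
such a rate, and the package reports these events as what they are.
Second, in the strong-barrier regime (α < 60°, d < 125 nm) a
quasi-static cargo must rotate ~150° against its own spiral to clear the
obstruction, so deep-barrier transits resolve as turns or terminations
more often than the published model heat map (whose straight-to-turn
ratio stays above 1 everywhere); here that regime's ratio hovers around
0.8–1.2. `SimConfig(azimuth_diffusion=True)` enables an optional
thermal treatment of the cargo's azimuthal soft mode (overdamped
rotational Brownian motion about the bound filament, Metropolis-accepted
on the relaxed energies, free-Stokes drag), which restores that regime's
ratio above 1 by letting blocked cargos reposition — at the cost of
suppressing turning overall (~72/22 instead of ~64/28). The default
keeps the quasi-static treatment; both the option and the trade-off are
deliberate.

## Optical trap

The trap adds ½k_trap|c−c₀|² to the relaxed energy (k_trap = 0.019
pN/nm); the reported force is the axial component. On full detachment the
cargo snaps back to the trap centre and motors re-engage — the saw-tooth.
There is no thermal noise term (quasi-static), so traces are clean;
stall-peak detection uses the 250 ms sliding window with ±50 nm/s
half-window velocity criteria, with two numerical choices: half-window
velocities are least-squares slopes (endpoint differences amplify
sampling noise ~10× on 50 Hz data), and qualifying windows are merged
into one event per saw-tooth (a tooth ends when the force falls below
half its rise over the trace baseline), since plain overlap-merging
counts one stall plateau once per back-step dip. Peak forces are read
from a ~25 ms boxcar-smoothed trace.

At defaults the detected peak-force distribution has a strong
single-motor component at ~1.9 pN and a broad multi-motor cluster at
~4–6 pN; BIC model selection over 1–4 Gaussian components typically
chooses two components, not the three reported for the experimental
data — the simulated 2- and 3-motor stall populations overlap too much
(spacing ~1.5 pN against widths ~0.9 pN). This is a known limitation of
the model's load-sharing fluctuations rather than of the mixture code
(which recovers three components exactly on synthetic samples drawn at
the published component parameters).

## Synthetic data

`synthetic_data` generates every input the analysis consumes, with known
ground truth: helices with per-axis Gaussian localization noise
(17/18/30 nm X/Y/Z at 100 ms frames — the published tracking precision),
binomial photobleaching ensembles (independent exponential bleach times),
saw-tooth trap traces (plateaus kept shorter than the 250 ms detection
window so teeth are detectable), and STORM-like filament clouds (5 nm Z
precision). These emulate the *statistical* structure of the real data,
not its physics: no drift, no vignetting, no intensity blinking, no
filament curvature. Passing the recovery tests therefore demonstrates
estimator correctness, not robustness to every experimental artifact.

## Numerical and procedural choices

* Helix fits share one frequency between X(t) and Z(t), with bounds
  A ∈ [50, 500] nm, f ∈ [0.001, 10] s⁻¹; fits pinned at a bound, or with
  near-aligned phases (|sin Δφ| < 0.2, planar wobble), are non-helical.
  Handedness: under the right-handed axes (x East, y travel, z up),
  φ_z − φ_x = +π/2 is right-handed, −π/2 left-handed. Pitch =
  velocity/frequency.
* Kaplan–Meier run lengths use lifelines; with censoring beyond the
  largest observed event the restricted mean (to the largest recorded
  time) is reported.
* The photobleaching variance relation σ_I²(t) = v·I₀·p(1−p) is fitted
  with weights ∝ the predicted variance, after τ is fitted from the mean
  decay; the count follows the published formula n = 2I₀/v. Note that on
  an N-fluorophore ensemble this formula returns 2N, so its absolute
  normalization is a convention carried from the source method.
* Batch child seeds come from a counter-based `SeedSequence` split of the
  master seed (reproducible, order-independent, all < 2³¹).
* Problem sizes in the reproduction script (300 intersection transits,
  10 spiral runs, 50 velocity runs, ≥500 trap events) are chosen so each
  statistic's sampling error is several times smaller than the tolerance
  band of the quantity it estimates.

## Known limitations

* No thermal fluctuation of the cargo: binding-rate restriction is
  carried entirely by the static footprint geometry, and barrier escape
  by re-centring/corkscrew motion only.
* Rigid filaments and sphere; no membrane deformation (observed
  experimentally only for larger, denser cargos).
* Engaged-count tail (P(n ≤ 3) ≈ 0.8, not ≥0.95) and two- rather than
  three-component stall mixtures, as discussed above.
* Unbound cargo is treated as lost (no rebinding from solution).
* Single filaments or one intersection only; no dense networks.
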