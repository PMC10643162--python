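# Methods

This note records the models implemented in `backdoorflux`, the
parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where the
procedure was genuinely open.

## Bulk release kinetics

The two-channel assay is modeled by the three-state scheme
A →(k_poly) B ⇌(k−Pi / k+Pi) C + P_i: monomeric ATP-actin polymerizes
and hydrolyzes with the single observed first-order rate k_poly;
filamentous ADP-P_i-actin releases P_i at k−Pi; free P_i can rebind at
k+Pi (fixed at 2·10⁻⁶ µM⁻¹s⁻¹).  The pyrene channel is proportional to
the polymerized fraction 1 − e^(−k_poly t); the sensor (MDCC) channel
to released phosphate captured by 30 µM sensor with K_D = 0.1 µM.

Two simulation modes are implemented.  The analytic mode ignores
rebinding and uses the sequential-first-order closed form
C(t) = A₀[1 − (k_r e^(−k_p t) − k_p e^(−k_r t))/(k_r − k_p)], with the
(1 + k t)e^(−kt) limit when the rates coincide.  The ODE mode
integrates A and B with LSODA (rtol 1e-10) and computes C by mass
balance, so A + B + C = A₀ holds to machine precision; free P_i is
total released minus the sensor-bound amount from the quadratic
rapid-equilibrium isotherm.  With the sensor in excess the bound and
released fractions differ by <0.5 %, which is why the analytic mode is
the fitting default.  Fitted k−Pi shifts by <5 % when k+Pi is scaled
1000-fold, so the fixed rebinding constant is immaterial under assay
conditions.

Normalization subtracts the minimum over the first 10 s (robust to a
noisy first sample) and divides by the signal at t = 900 s.  k_poly is
fitted per replicate and averaged; k−Pi is fitted to the averaged
normalized sensor trace with k_poly fixed, the model prediction being
normalized exactly as the data.

**Enhancement lower bound.**  When observed release is
indistinguishable from polymerization, only a lower bound on the rate
can be stated.  The implemented criterion defines the error margin from
the data: the maximal deviation of the observed normalized sensor
signal from the fitted polymerization curve, widened by the k_poly
standard-error band.  The bound is the smallest fold enhancement whose
simulated release-versus-polymerization gap fits inside that margin;
the gap is strictly decreasing in the fold, so the scan is monotone.
This margin definition is this package's own choice — it reproduces the
right limits (data generated at fold f yield a bound ≤ f; wild-type
release at k_poly yields a bound of 1) — and is configurable.

## Single-filament aging kinetics

Length traces (subunits; imaging data convert at 370 subunits/µm) are
truncated at the first depolymerization pause (zero-velocity run of at
least 15 s), averaged across filaments aligned at flow-out, and
differentiated by centered local linear regression over odd window
sizes 17–29 frames.  Velocities are averaged over windows; the spread
across windows provides the per-point uncertainty.  A window-selection
report scores each candidate window by the mean relative standard error
of the (a, b, c) fit parameters and admits windows under 10 %.

Filament age is τ = t + (L₀ − L_t)/v_pol: the subunits exposed at the
barbed end at time t were laid down (L₀ − L_t)/v_pol before flow-out.
The profile 1/v_depol(τ) is fitted with a·e^(−bτ) + c by nonlinear
least squares (bounds a ≥ 0, b ∈ [10⁻⁵, 5] s⁻¹, c > 0).  Parameter
meanings: b is the interior (core) P_i-release rate, 1/c the ADP
depolymerization velocity and 1/(a+c) the observed ADP-P_i velocity.
The barbed-end release rate follows from the printed two-route
formula with the direct ADP-P_i dissociation rate fixed at 0.2 s⁻¹.

A profile is declared *flat* — maturation unresolved — when the fitted
amplitude is small against the plateau (a < 0.05·c), statistically
insignificant (a ≤ 2·SE(a)), or the decay rate pins at its bounds.  For
flat profiles the plateau is re-estimated as the profile mean (the
degenerate exponential term can otherwise soak up part of it), and a
lower bound on the release rate is derived instead: assuming the
ADP-P_i velocity equals (or doubles) the wild-type value, the predicted
excess of 1/v at the first analyzable age point must exceed twice the
empirical SD of the profile; the largest rate still detectable by that
criterion is reported as "k−Pi ≥ bound".  The exact detectability rule
is again a declared choice; it grows with sampling rate and degenerates
to an unbounded value for noiseless, infinitely fast sampling.

## Synthetic filament cohorts

The generator realizes the two-route scheme event by event: growth adds
ADP-P_i subunits as a Poisson process at v_pol for t_growth; each
interior subunit converts to ADP after an exponential waiting time at
k_release_core; during depolymerization the terminal subunit leaves at
v_depol,ADP when ADP, while a terminal ADP-P_i subunit faces competing
risks — direct dissociation at v_depol,ADPPi versus barbed-end release
at k_release_BE followed by ADP dissociation.  The interior-release
clock of the terminal subunit is superseded by the much faster
barbed-end rate.  The observed ADP-P_i depolymerization velocity
implied by the competing risks is 1/[1/(k_BE+v_Pi) + (k_BE/(k_BE+v_Pi))/v_ADP]
(`FilamentSimConfig.observed_v_adppi`), which is the quantity 1/(a+c)
recovers.

Default study conditions: v_pol = 15 subunits/s for 300 s (~4500
subunits, a typical TIRF filament), frame interval 5 s.  Wild-type-like
rates: v_depol,ADP = 6.7 subunits/s, direct ADP-P_i dissociation
0.2 subunits/s, k_release_core = 0.006 s⁻¹, k_release_BE = 2 s⁻¹.  The
fast-release mutant condition uses v_depol,ADP = 14.71 subunits/s
(≈2.2× wild type) and k_release_core = 0.113 s⁻¹, which is invisible at
5-s frames and yields the flat profile the lower-bound path handles.
Optional pauses emulate photo-induced stalling: each filament's pause
onset is drawn from a logistic distribution (so the cohort's cumulative
pause probability is a logistic CDF) with exponential durations;
default off.

What the generator does not emulate: length-measurement noise from
imaging and tracking, filament-to-filament rate heterogeneity,
rescue/catastrophe-like events, and pointed-end dynamics.  Passing
recovery tests therefore shows the estimators are consistent under the
model's own assumptions, not that they are robust to tracking
artifacts.

## Toy escape landscape and biased sampler

The egress sampler stands in for all-atom enhanced-sampling runs.  A
particle (the P_i phosphorus atom in the filament frame) moves by
overdamped Langevin dynamics (dt = 0.01 ps, D = 0.005 nm²/ps,
kT = 2.577 kJ/mol i.e. 310 K) in a landscape with a Gaussian binding
well at the origin (depth 20 kJ/mol, width 0.22 nm) and a barrier shell
at 0.6 nm whose height is 25 kJ/mol (~10 kT) inside narrow angular
gates (half-width 0.35 rad) and 35 kJ/mol higher elsewhere.  The four
default gates sit at tetrahedral directions; one is tagged as the
R177-N111 backdoor.  Well depth, barrier height, radii and the
diffusion constant are calibration knobs of the toy model with no
experimental counterpart; they were chosen once so that unbiased escape
over the gate is negligible within 10 ns while the biased sampler
escapes well inside it, and so that the escape corridor is long enough
for contact features to record the traversed channel.

Three independent one-dimensional metadynamics biases act on the
Cartesian coordinates (hill height W = 1 kJ/mol, width 0.05 nm,
deposition at 0.125 ps⁻¹); the total deposited bias per coordinate
after time T is exactly W·⌊T·rate⌋.  For speed the bias force is
tabulated on a 0.005-nm grid per coordinate, updated at each deposition
and linearly interpolated per step; the landscape force uses central
differences (ε = 10⁻⁴ nm).  These bias parameters capture escape events
but are unsuitable for reconstructing a converged free-energy profile,
which is out of scope.  Trajectories are recorded every 1 ps, truncated
at the first crossing of the 1.4-nm escape cutoff, and labeled with the
gate whose center direction is nearest at the crossing; runs that never
cross within 10 ns are kept with a "no-escape" label and excluded from
clustering and featurization by default.

The 48 anchors (one per residue id of the egress-pathway list, which
expands to exactly 48) are placed deterministically: four per gate
ringing the escape corridor just outside the shell — for the backdoor
gate these carry the R177 and N111 labels — and the rest on a Fibonacci
lattice at 1.3 nm.  Placing gate anchors in the corridors, rather than
on the shell, mirrors the fact that pathway residues line the channels:
contacts then record which channel was traversed instead of the
bias-driven wandering inside the well.

## Path discretization, clustering, pathCV

Escaped trajectories are smoothed per coordinate by cubic B-splines
parameterized by frame index.  The default smoothing factor scales the
FITPACK residual bound to the noise level estimated from second
differences (s = 3·m·σ̂², the factor 3 because the bound covers all
three coordinates); generalized cross-validation is available as an
option but is an order of magnitude slower at typical trajectory
lengths and gives indistinguishable paths.  Trajectories longer than
512 frames are decimated before fitting — the sub-frame jitter carries
no path information.  Discretization evaluates the spline on 10⁴ points
and interpolates at 100 equal arc-length stations (30 for pathCV
reference paths).

Paths are compared by the Euclidean norm of the 300-dimensional
difference of their discretizations and clustered agglomeratively with
average linkage (the linkage is a declared choice), cut at k = 4 by
default.  Centroids are arithmetic means in discretized-path space;
representatives are the members closest to their centroid, ties broken
by lowest index.

The longitudinal pathCV uses Gaussian-weighted node indices,
s = [Σᵢ (i−1) e^(−λ d_i²) / Σᵢ e^(−λ d_i²)]/(N−1) with N = 30 nodes and
λ = 325 nm⁻² multiplying the squared Euclidean distance.  Exponents are
stabilized by subtracting the row maximum, which also realizes the
nearest-node fallback when all weights underflow; λ → 0 gives s = 1/2
exactly, and large λ pins s to the nearest node.  Each trajectory's
reference path is its own spline — s is a rescaled time along that
trajectory, which is what makes trajectories of different durations
comparable.

## Backdoor classifier

Featurization: per frame, contact with each of the 48 anchor residues
is the Boolean distance ≤ 0.75 nm; frames are assigned to four equal
bins of s; the per-bin, per-residue mean contact forms a 48 × 4 map in
[0, 1], flattened residue-major into a 192-vector.  Empty bins
contribute zeros and set a mask flag rather than dropping the
trajectory.  Static anchors are the default; per-frame anchors are
accepted for moving-protein data.

The stratified 75/25 split rounds per-class test counts by largest
remainder, flooring the minority class on ties (300 samples with 70
positives give a 75-sample test set with 17 positives); every class
keeps at least one test member.  The logistic model uses L2
regularization at strength C = 1 — a declared choice needed because
synthetic corpora can be linearly separable — and a 0.5 decision
threshold.

## Structure observables

Structures are read with biotite (first model, altloc 'A' preferred,
insertion codes rejected) and shadowed in float64, because the float32
storage of the parsing container is too coarse for the 10⁻⁹-level
rigid-motion invariants the observables satisfy.  Distances and the
signed χ1 dihedral (N–CA–CB–Cγ, range (−180°, 180°]) are elementary;
superposition RMSD uses least-squares rotation via scipy with the RMSD
recomputed from the aligned coordinates.

ΔRMSD = rmsd(x, core) − rmsd(x, barbed end) is computed over the Cα
atoms of the steered-MD fit ranges after *independent* superposition
onto each reference, and is reported in nm (structure coordinates are
Å; the conversion happens at this interface).  The moving restraint
U(x,t) = ½k(· − v t)² with k = 334 124 kJ mol⁻¹ nm⁻² and
v = 0.0022 nm/ns is implemented in two conventions, because the printed
offset (−rmsd(core, be)) makes the restraint energy ½k(2R)² at the
start structure, which contradicts a restraint that starts at rest: the
default `zero_at_start` flips the offset sign so U(core, 0) = 0, and
`as_printed` evaluates the formula literally.

Helical parameters: for each pair of consecutive subunits the optimal
rigid transform (Kabsch) is decomposed into a screw motion.  The
rotation axis comes from the rotation vector; the axis is oriented so
the translation along it (the rise) is non-negative, and the twist is
the signed rotation angle about that oriented axis — negative for the
right-handed actin genetic helix (≈ −166.5°).  A pure translation
(angle < 10⁻⁹) reports twist 0 and rise |t|.  Means ± SD over the
interfaces are reported; five subunits give four interfaces.  The
estimator is validated on constructed ideal helices at the deposited
symmetry values; applying it to a downloaded atomic model works through
the same `helical_parameters` call (see the CLI `helical` command) but
requires the model file, which the test suite does not fetch.

## Problem sizes and determinism

All generators are bit-reproducible under a fixed seed (the Langevin
integrator derives one child seed per trajectory).  The shipped
analyses use three bulk replicates on a 1-s/900-s grid, filament
cohorts of 45–200, swarms of 50 × 10 ns and a 300-trajectory classifier
corpus — sizes chosen to match the emulated experiments while keeping a
full pipeline run in the minutes range.  Estimator variance at these
sizes is covered by the tolerance-based tests; larger cohorts tighten
the recovered rates roughly as 1/√n.
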