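# Methods

`pathmetad` implements, at desk scale, the combined enhanced-sampling
protocol used to study ligand unbinding from buried protein cavities:
steered dynamics with Jarzynski analysis to rank competing unbinding
channels, a hybrid reference path defining path collective variables
(PCVs), and well-tempered metadynamics in the PCV plane to reconstruct the
free-energy surface (FES), extract the binding free energy, and
characterise the minima along the route.  All physics runs on analytic
model systems so that every estimate can be checked against an exact or
brute-force oracle.

## Units

kcal/mol, Angstrom, ps and Kelvin internally, with
k_B = 0.0019872041 kcal/mol/K.  File I/O follows the conventions of the
PLUMED ecosystem: hill heights and bias energies in kJ/mol
(1 kJ/mol = 0.239 kcal/mol), squared path distances in nm^2
(1 nm^2 = 100 A^2).  Forces are reported in pN where the literature does
(1 kcal/mol/A = 69.4786 pN).

## Model systems

**Double well.**  `make_double_well(barrier, separation, asymmetry)`
constructs the quartic
`U(x) = c (x^4/4 - b x^3/3 - a^2 x^2/2 + a^2 b x)` whose stationary points
are exactly the two minima at ±a and the barrier top at b; b and c are
solved by bisection so the requested barrier (from the deeper well) and
the well-energy difference are met to machine precision.  The well-to-well
free-energy difference at temperature T follows from Boltzmann quadrature
over each basin (split at the barrier top); this is the oracle for all
biased-sampling checks.

**Host–guest bead system.**  A 2D ring of strongly repulsive Gaussian
beads (amplitude 30 kcal/mol, width 1.2 A, radius 6 A) encloses a Gaussian
cavity; two gaps on opposite sides are each blocked by one wide gate bead
(width 2.4 A).  This mimics the key feature of a buried binding site with
two unbinding routes of different difficulty.  Gate amplitudes are
calibrated by bisection on the *wedge saddle* — the minimum over gap
angles of the maximum over radius of the guest energy — so each channel's
lowest saddle sits at the requested energy **relative to bulk** (guest far
away, energy zero); a straight axis scan is not sufficient because the
guest can slip past the gate off-axis.  The cavity amplitude is corrected
self-consistently so the bound minimum sits at exactly −cavity_depth.
The total unbinding barrier through channel *i* is therefore
`barrier_i + cavity_depth`.  Host beads are frozen by default; a
`tether_k` option puts them on harmonic tethers (a stand-in for
mouth-opening flexibility) at the cost of a larger mobile-coordinate
space.

**Integrator.**  Overdamped (Brownian) Euler–Maruyama:
`dx = -∇U/γ dt + sqrt(2 k_B T dt/γ) ξ`, with γ the drag coefficient.
Equilibrium properties (FES, basin occupancies) are independent of γ;
only kinetics depend on it, and no kinetic quantity is reported.  Defaults
dt = 0.005 ps, γ = 1 kcal/mol·ps/A² keep `dt·U''/γ ≲ 0.05` for every
shipped system.  One root seed per run; replica *i* of a stage derives its
seed deterministically from the root, so every result in the package is
bit-reproducible from config + seed.

## Steered stage and Jarzynski analysis

The pulling variable is the distance between the guest and a fixed anchor
placed behind the cavity on the side opposite the channel mouth (the
analogue of the centre of mass of residues at the bottom of the binding
cavity).  The restraint centre moves linearly; external work is
accumulated per step as `W += k (c_t − q_t) Δc` (spring force times centre
displacement; the discretisation is a documented choice).  The spring
constant defaults to 10 kcal/mol/A².

`jarzynski_estimate` evaluates `−k_B T ln⟨exp(−W/k_B T)⟩` with a
log-sum-exp; the finite-sample estimate provably lies between min(W) and
mean(W), and both bounds are enforced as property tests.  Per-pathway
statistics follow the conventions of the field's SMD tables: W_min and
W_max of the final works, the **minimum over replicas of the per-replica
peak |spring force|** (in pN), the Jarzynski estimate, and the sample sd of
final works.  Absolute force is used because the sign convention is not
standardised.  `compare_pathways` ranks by argmin W_min and flags "no
preference" whenever the W_min gap is inside either pathway's work spread;
the peak-force difference is reported alongside as corroborating evidence.
Note that W_min and the peak-force statistic are extreme-value statistics:
with few replicas on shallow systems they are noisy, which is why the
channel-ranking checks use ≥16 replicas.

## Reference path and PCVs

The frame metric is the mean-square deviation (A², matching the inverse-
area units of λ) after optimal rigid superposition (Kabsch, proper
rotations only) on an alignment selection; the deviation is measured over
a separate distance selection (guest beads, the analogue of ligand heavy
atoms).  The path is hybrid: an inner segment of frames taken from the
lowest-work steered replica, greedily emitted whenever the RMSD from the
last emitted frame reaches the spacing target, plus an outer segment that
interpolates the guest linearly to a bulk end frame with the host frozen —
in bulk the host conformation is irrelevant.

Before frame selection the protocol driver filters the steered trajectory
to snapshots that set a new record of the pulling distance, stops just
outside the cavity mouth, and applies a light 5-point moving average to
the guest track.  Without this, thermal transverse wobble (σ ≈ 0.5–0.9 A
in the model, a sizable fraction of the 1–2 A spacing) contaminates the
frame set and the RMSD matrix loses its gull-wing shape; at atomistic
scale the same role is played by the much larger spacing-to-fluctuation
ratio.

PCVs follow the standard softmax form
`s = Σ i e^{−λ d_i} / Σ e^{−λ d_i}`, `z = −(1/λ) ln Σ e^{−λ d_i}`,
evaluated with a max-shift so large λ·d cannot overflow.  Note z is
*negative* wherever several frames are simultaneously close (weight sum
above one, bounded below by −ln N/λ); grids and walls account for this.
Gradients with respect to guest coordinates are analytic and exact because
the guest is excluded from the alignment selection (the superposition then
does not depend on it).  λ defaults to `ln 2 / ⟨d_adj²⟩` so a neighbouring
frame carries weight one half; on uniform 0.021 A² spacings this
reproduces the magnitude (33 A⁻²) used in the atomistic literature, whose
printed unit (nm²) we read as a typo for nm⁻² since the PCV exponent
requires inverse area.

## Well-tempered metadynamics

Gaussians of widths (σ_s, σ_z) are deposited every τ_G steps at the
current (s, z) with height `w = w0 exp(−V/(k_B ΔT))`, ΔT = (γ−1)T.
Defaults follow the atomistic literature: w0 = 1 kJ/mol, γ = 10,
τ_G = 500 steps, σ_s = 0.05, σ_z = 0.007 nm²; the width rule σ = sd/3 from
an unbiased run is available (`sigma_from_unbiased`) and is what the
protocol driver uses by default, since the toy system's CV fluctuations
differ from the atomistic ones.  Walls are one-sided harmonics
κ(x − x_max)² above s_max (default 12) and z_max (default 0.2 nm²); the
functional form and stiffness are conventions, not literature values, and
are configurable.

The running bias and its analytic gradients are accumulated on a grid
(default 200×200) and read back by bilinear interpolation; the
interpolation error is below 10⁻³ kcal/mol at default resolution (tested).
The exact hill list is kept alongside and is what file output and FES
reconstruction use.  `w0 = 0` short-circuits deposition, so the biased
driver reproduces the unbiased trajectory bit-for-bit at equal seed — the
zero-bias reduction test.

The FES estimator is the plain well-tempered relation
`F = −(T+ΔT)/ΔT · V`, min-shifted; no reweighting or time-averaging.  The
1D profile is the Boltzmann projection over z.  The binding free energy is
the deepest minimum of the profile in the bound region (s ∈ [1, 3] by
default) minus the **mean** over the unbound region (s ≥ 7); the plateau
sd is reported so the flat-plateau assumption is auditable (using the mean
rather than a single unbound value is a documented choice).  If the
unbound region was never visited the analysis raises "unconverged" rather
than returning a number.  Convergence is monitored by the running ΔF_bind
at hill checkpoints and by the decay of deposited hill heights.

## Basins and clusters

Grid minima are found in the 8-neighbourhood, basins grown by discrete
steepest descent, and minima with topological persistence (lowest
connecting saddle minus the minimum) below 1.5 kcal/mol — the isoline
spacing at which such surfaces are usually drawn — are merged into the
deeper basin they drain to; the informal notion of a "minimum hole" has no
unique formalisation, and persistence-filtered watershed basins are this
package's choice.  Labels A, B, C… follow increasing free energy.  Strided
trajectory snapshots are assigned to basins through their (s, z); each
basin's members are clustered with the GROMOS algorithm (greedy
neighbour-count clustering, 2 A RMSD cutoff on the guest beads), and the
centroid of the most populated cluster is the representative structure.
All tie-breaks (equal neighbour counts, equal populations) resolve to the
lowest frame index, making the output order-auditable.

## Protocol driver and desk-scale parameter choices

`run_protocol` chains the stages and emits COLVAR/HILLS files, the
reference path (XYZ + PDB), CSV matrices and a JSON/text report; rerunning
the same config and seed reproduces the report byte for byte.

The shipped configuration defaults are sized for minutes on one core
rather than microseconds of atomistic sampling: unbiased run 200k steps
(1 ns), 10 steered replicas of 50 ps per channel, 1.2M biased steps, hill
height 4 kJ/mol.  Two defaults deliberately differ from the atomistic
values, for reasons the bead geometry makes necessary: the initial hill
height (4 kJ/mol rather than 1) because at 1 kJ/mol the 14 kcal/mol
unbinding barrier of the default system fills logarithmically slowly; and
the z wall (0.1 nm², κ = 5000 kcal/mol/nm⁴ rather than 0.2 nm² with soft
κ) because in 2D the unbound guest can otherwise drift around the host and
re-enter the *other* channel, which the path CVs cannot describe.  The
type-level defaults of `WTParams` and `WallSpec` keep the literature
values; only the run configuration overrides them.

## What the model shows — and what it cannot

The bead system reproduces the *structure* of the problem: a buried bound
minimum, two channels with designed saddle energies, work-based channel
ranking, multiple binding/unbinding events under the path-CV bias, a bound
basin at low s, intermediates, and an unbound plateau whose depth orders
with the designed cavity depth.  It does not emulate solvent, protein
flexibility beyond optional harmonic tethers, orientational ligand degrees
of freedom, or force-field realism, so passing tests validate the
*methodology* (estimators, CV machinery, bias dynamics, analysis), not any
atomistic binding free energy.  The published SMD tables enter only as
inputs to the comparison machinery; no attempt is made to reproduce
μs-scale atomistic numbers at desk scale.

## Known limitations

- The finite-sample Jarzynski estimate is bounded below by min(W); one
  printed table cell in the source literature (ΔF_unbind 27.12 < W_min
  27.47) violates this bound, so the plain formula cannot reproduce it and
  no attempt is made to.
- Overdamped dynamics has no momenta; kinetic observables (rates, friction
  dependence) are out of scope.
- The grid-accumulated bias trades exactness for speed; the error bound is
  tested but a very narrow hill (σ below the grid step) would break it.
  Widths from `sigma_from_unbiased` stay well above the default grid step.
- GROMOS clustering is O(n²) in frames; the strided assignment keeps n in
  the hundreds.
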