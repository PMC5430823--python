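# Methods

## Scope and model

`memnano` characterizes lateral heterogeneity in planar lipid-bilayer
trajectories, aimed at the binary DPPC–cholesterol system in which cholesterol
drives the spontaneous formation of ordered nanodomains: a fluid,
cholesterol-rich ordered annulus wrapped around a hexagonally packed,
cholesterol-poor gel-like core, embedded in a disordered background, with the
ordered regions registered across the two leaflets and cholesterol
concentrating — and flip-flopping — at the domain boundary.

The analyses operate on orthorhombic boxes with the membrane normal along z.
Coordinates are nm, times ns (GRO conventions; XYZ input is Å and converted on
read). Topology is an explicit JSON side-car declaring atom roles (chain
carbons and their hydrogens, headgroup phosphorus, sterol ring atoms, a
methyl-side marker on the sterol's rough β-face) rather than inference from
atom names, so the suite is force-field agnostic and every role is testable.

## Order parameters

The deuterium order parameter of a C–H bond is
S_CD = ⟨(3 cos²θ − 1)/2⟩ with θ the angle between the bond and the membrane
normal; results are reported as −S_CD (positive for ordered chains, 0.5 for a
chain standing along the normal). Distributions are built from **per-chain
time averages**: each chain contributes one value per carbon, averaged over
both attached hydrogens and all frames of the window, and the histogram runs
over chains. Subpopulations that keep their identity over the window (gel,
liquid-ordered, liquid-disordered) therefore appear as separate modes.
Defaults: bin width 0.01 over [−0.1, 0.55] (resolves the three modes), sn-2
chain, carbons 2–15 for the chain-mean scalar (the terminal methyl is noisy),
full analysis window. For hydrogen-free (united-atom) input an optional
reconstruction infers ideal C–H directions from the local C(i−1)→C(i+1)
skeleton vector u: with tetrahedral azimuthal symmetry the two C–H bonds'
mean squared z-projection is (1 − u_z²)/2; it is off by default.

## Phase decomposition

A heterogeneous distribution is fitted as a convex mixture of reference
single-phase distributions: minimize ‖target − Σ fᵢ·refᵢ‖² over the
probability simplex (fᵢ ≥ 0, Σ fᵢ = 1), stacking per-carbon histograms with
equal weight per carbon (the appropriate weighting is not obvious; equal
weight is the neutral choice). The constraint is enforced exactly (SLSQP); a
ridge of 1e-10 selects the minimum-norm fraction vector when references are
collinear. The reported error is L1-relative over all carbon–bin cells,
100·Σ|target − fitted| / Σ target, a stated, testable definition of
reconstruction error.

## Spatial maps

All maps are periodic grids over the membrane plane (default cell 0.5 nm,
giving ≥ 20 cells across a ~10 nm domain). Leaflet surfaces are per-cell
time-averaged phosphorus heights with periodic Gaussian smoothing
(default σ = 1.0 nm) applied as occupancy-weighted (normalized) convolution;
cells filled from data further than 3σ away are flagged. Thickness is the
upper minus the lower surface. Leaflets are assigned against the *local*
midplane (per-cell mean of the two phosphorus surfaces, bootstrapped from a
global mean-height split), so ripples do not misassign sterols. Jump maps
average each lipid's in-plane displacement over fixed windows (default 1 ns),
binned at the window's start position, with coordinates unwrapped by
frame-to-frame minimum-image continuation. Interleaflet registration is
quantified on co-located cell pairs of the two leaflets' order maps: a joint
histogram, its Pearson correlation, and the mass of the diagonal band
|Δ| ≤ 0.05.

## Packing, partitioning, tilt, faces

Chain sites are the xy-projected carbon centroids of each acyl chain
(optionally one site per cholesterol ring centroid). Neighbour counting is
cutoff-based under the periodic minimum image, with the cutoff defaulting to
the first minimum of the 2D radial distribution function computed per system
— the standard self-calibrating first-shell definition. Six neighbours
diagnose hexagonal packing. Cholesterol partitioning versus thickness
compares the thickness histogram of all cells with that of cholesterol-
occupied cells (a cell counts as occupied in a frame when it holds ≥ 1 sterol
reference point), with cumulative curves and a two-sample KS statistic.
Chain tilt uses the first principal component of the chain carbons (robust to
gauche defects); collective tilt is the mean resultant of the unit lateral
tilt directions, 0 for azimuthally uncorrelated tilts. Sterol face
orientation compares the lateral direction from ring centroid to methyl
marker with the negative local order-map gradient; the fraction of
observations pointing the rough face toward disorder is tested against 0.5
with a binomial test, and a vanishing gradient (homogeneous membrane) yields
an explicit "no boundary" flag rather than a spurious preference.

## Region classification and tracking

Cells of the smoothed, time-averaged thickness map are labelled
disordered (< t₁), ordered ([t₁, t₂)) or core (≥ t₂). Automatic thresholds
come from the crossing points of a 3-component 1D Gaussian mixture fitted to
the cell values; the fit falls back to an explicit error with guidance when
three modes cannot be resolved. Connected-component analysis uses
4-connectivity with periodic wrap; patches smaller than 4 cells are
reabsorbed into their surrounding class to suppress speckle. Domain-area
tracking classifies per-window maps with shared thresholds and reports the
final/initial ratio of the combined (ordered + core) footprint. Boundary
cells are those with a differently labelled periodic 4-neighbour; distances
to the boundary are minimum-image distances to boundary-cell centres, and
event-shell membership uses the same cell-centre distance map as the area
null so the enrichment ratio is exactly 1 under uniform placement.

## Flip-flop detection

A sterol's leaflet trace is its ring-centroid height relative to the local
midplane. The detector uses hysteresis plus dwell: having last been beyond
+δ, the molecule commits a flip at its first crossing beyond −δ provided it
stays on the new side for ≥ τ_min (and symmetrically). Defaults δ = 0.4 nm,
τ_min = 1 ns. Excursions inside (−δ, +δ) never count; event counts are
monotone non-increasing in both δ and τ_min. Boundary enrichment compares
the fraction of events within a shell of the domain boundary against the
shell's area fraction with a one-sided binomial test.

## Synthetic bilayer generator

The generator builds toy membranes with exactly the statistics the analyses
consume; chains are rigid rods with decorative hydrogens, not physical
lipids. Each region (disc or background) specifies target order, phosphate
height (half-thickness), lattice packing, cholesterol mole fraction and a
random-walk mobility. Key constructions:

- **Order**: a chain is a carbon rod tilted by β from the normal with the two
  hydrogens of each carbon along an orthonormal pair perpendicular to the
  axis. The mean of P2(cos θ) over such a pair is exactly −½·P2(cos β) in
  every frame, so cos²β = (4·S_target + 1)/3 realizes the target exactly for
  any S_target ∈ [0, 0.5]. (Targets below −0.25 would need a two-point β
  mixture; they are outside the physical reporting range and rejected.)
  Tilt azimuths are random per chain, so there is no collective tilt.
- **Packing**: per-region hexagonal or jittered lattices of chain sites, with
  a small static wobble (default σ = 0.02 nm) so radial distribution
  functions have finite-width peaks. Chains are laterally centred on their
  sites; pairs of nearest-neighbour sites form one DPPC (greedy periodic
  matching), with the phosphorus at the periodic pair midpoint. An odd
  leftover site is dropped at the region's rim so interior packing is intact.
- **Registration**: in registered/antiregistered modes the two leaflets share
  one site layout; antiregistration assigns complementary order targets
  (lower = 0.6 − upper) over identical geometry.
- **Dynamics**: per-molecule Gaussian random walks (per-region step size);
  scripted sterol flip-flops move the whole molecule across the midplane over
  two frames at the scripted time, with optional sub-threshold "feints";
  a shrinking disc replays r(t) = r₀√(1 − t/2T) by switching phosphate
  heights of lipids outside the instantaneous radius.
- Reference single-phase order distributions are parametric per-carbon
  Gaussians (gel 0.42 narrow, Lo 0.33 intermediate, Ld 0.18 broad, each with
  a mild decay toward the chain terminus; gel > Lo > Ld at every carbon).

What the generator does **not** emulate: molecular shape and rotameric
disorder, thermal area/volume fluctuations, curvature coupling,
self-assembly or domain energetics (domains are placed, never evolved), and
realistic flip-flop kinetics. Passing tests therefore demonstrate that the
analyses measure what they claim on data with known structure — not that a
particular real membrane is heterogeneous.

## Problem sizes and numerical choices

Preset membranes are desk-scale by design: 8–12 nm boxes (≈ 250–500 lipids),
24–200 frames at 0.1–0.2 ns spacing; the order round-trip uses 4 nm boxes
over 500 frames. These sizes keep every verification in seconds while
preserving the structures the analyses detect. Degenerate inputs raise
explicit errors (empty leaflets, all-zero distributions, empty boundaries,
traces shorter than the dwell time). Ties and edge cases are documented in
place: histogram values are clipped to the outermost bins; cells never
visited are NaN and excluded from histograms; wrapped coordinates that land
exactly on the box edge fold to 0.

## Known limitations

- Orthorhombic boxes only; triclinic input is rejected explicitly.
- The interleaflet histogram is location-based (grid-cell means), not
  lipid-pair based.
- Hexatic bond-orientational order (ψ₆) and 2D crystallography are out of
  scope; hexagonal packing is diagnosed by coordination number only.
- Automatic thresholds assume three thickness modes; membranes with two (or
  four) modes need explicit thresholds.
- Flip-flop analysis counts and localizes events; it does not fit rate
  constants.
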