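# Methods

This note documents the models implemented in `rigidbd`, the numerical
choices behind them, what the synthetic test systems do and do not probe,
and the package's known limitations.  Units throughout: Å, ps, kcal/mol,
elementary charge e, kelvin; k_B = 0.0019872 kcal/(mol·K), electrostatic
constant 332.064 kcal·Å/(mol·e²), Avogadro 6.0221×10²³/mol.

## Rigid-body model and propagator

A solute is a rigid all-atom conformation with three kinds of attached
data: interaction sites (effective charges for electrostatic terms, atoms
for desolvation/soft-core terms), a bundle of body-frame scalar grids, and
its infinite-dilution diffusion coefficients D_T (Å²/ps), D_R (rad²/ps) and
Stokes radius.  The body frame is centred on the geometric mean of the atom
coordinates; centre-to-centre distances use these geometric centres
(mass-weighted centres are deliberately not used).  Orientation is stored
as a unit quaternion, renormalised after every update and converted to a
rotation matrix for transforms; long products of incremental rotations stay
orthonormal to better than 1e-6 over 10⁵ steps.

Translation advances by the overdamped update
Δr = (Δt/k_BT)·D_T·F + R with R isotropic Gaussian, per-component variance
2·D_T·Δt (so ⟨R²⟩ = 6 D_T Δt).  Rotation uses the same form on a rotation
vector (torque in place of force, D_R in place of D_T) realised through the
exponential map.  The discrete rotational update reproduces
⟨u(0)·u(t)⟩ = exp(−2 D_R t) with an O((2 D_R Δt)²) per-step defect —
negligible at the step sizes used here.

The off-diagonal hydrodynamic coupling between solutes is neglected
throughout (dilute-solution assumption); crowding corrections enter only
through the mean-field scaling described below.  The full pairwise
diffusion tensor with its O(N³) Cholesky factorisation is out of scope.

### Time step

The step is fixed by default.  A two-zone extension (off unless configured)
uses a small Δt when the centre separation is below `near_radius` and a
larger `dt_far` beyond it.  For force-free trajectories the splitting
probability between two spheres is a harmonic function of position, and the
mean-value property makes any isotropic Gaussian step exactly
splitting-neutral away from the boundaries; variable step size therefore
biases only the boundary-detection error, which the small near-zone step
controls.  The Smoluchowski-recovery runs use Δt = 0.2 ps within 5 Å of the
contact sphere and 15 ps outside; at these settings the recovered β is
statistically indistinguishable from the analytic first-passage value at
n = 10⁴ (verified over multiple seeds).

### Random numbers

All per-step noise comes from counter-based Philox streams keyed by
(master seed, step); the step lives in the 128-bit key, never in the
counter, so streams at different steps cannot overlap.  Forces are
accumulated in fixed solute-index order regardless of the `n_workers`
chunking, so results are bit-identical for any worker count — the
determinism contract replaces thread-level reproducibility claims.

## Grids and interactions

Grids are node-centred, isotropically spaced scalar lattices.  Energy and
force interpolation is trilinear (C⁰, exact on affine fields); the force is
the analytic gradient of the interpolant.  Queries outside a grid return
zero: the long-range electrostatic tail is carried instead by the analytic
Debye–Hückel term between net effective charges,

    U(r) = 332.064 q_a q_b e^{κ a}/(1+κ a) · e^{−κ r}/(ε r),   a = sum of Stokes radii,

applied only when every electrostatic site evaluation fell outside the
partner grids (no double counting).  κ defaults to 0.32914·√I Å⁻¹ at
298.15 K and is config-overridable.

Term conventions: electrostatic = Σ q_j Φ(r_j); electrostatic desolvation
= Σ q_j² U(r_j); hydrophobic desolvation and soft-core = Σ_atoms U(r).
When both solutes carry the grid for a term the two one-sided evaluations
are averaged.  The average restores action–reaction exactly: each one-sided
evaluation applies ±f at the sampling site positions, so total force is
zero and torques are consistent.  Grid forces match central finite
differences of the pair energy to better than 1e-9 in practice (tested at
1e-4), and the pair energy is invariant under joint rigid transforms to
1e-9.

File formats: UHBD ASCII (header records, per-z-plane blocks, x fastest)
and the OpenDX "regular positions, regular connections" scalar dialect
(z fastest).  Both writers emit full-precision headers so origin, spacing
and dimensions round-trip exactly and values to < 1e-9 relative; the DX
output is readable by the independent `gridData` package.  Only these two
ASCII dialects are supported — Poisson–Boltzmann solving, binary grids and
desolvation-grid construction from first principles are not in scope; such
grids are inputs.

Analytic builders supply synthetic stand-ins for solver output: a
screened-Coulomb (Debye–Hückel) potential grid for point charges (nodes
within half a spacing of a charge are clamped to the value at that
distance), and exclusion/soft-core builders (exclusion node = 1 inside any
probe-inflated atom sphere, probe 1.4 Å; soft-core Σ A/(1+(r/σ)^n) with
A = 1 kcal/mol, σ = atom radius, n = 6 by default — the soft-core functional
form is a package choice, config-exposed).

Effective charges are fitted by linear least squares: over grid nodes whose
distance from the site centroid lies in a spherical shell, minimise the
squared mismatch between the target potential and the screened-Coulomb
basis of the sites.  The spherical shell simplifies the classical
surface-skin construction while keeping the same least-squares principle;
planted single charges are recovered to 1e-3 e and two-charge arrangements
to 1e-2 e, and coincident sites raise an error naming the degenerate pair.

## Bimolecular mode: rates and docking

One solute is fixed at the origin but rotates; the mobile solute translates
with D_rel = D_T(fixed) + D_T(mobile), which accounts for the fixed
partner's diffusion.  Trajectories start uniformly on the b-sphere with
uniform (Shoemake) orientations and end on reaction at the tightest contact
window or at the c-sphere; a trajectory that exhausts the step budget is
counted as escaped (logged).  Batches propagate in lockstep with vectorised
grid evaluation; the single-trajectory API is a batch of one.

Reaction criteria are native-contact pairs: a pair is made when its
inter-site distance is at or below the window threshold (default 6 Å), and
the independent count is a greedy maximal subset (ascending contact
distance) in which selected sites on the same solute are mutually more than
5 Å apart; two independent contacts are required by default.  The greedy
order is a package choice — only the >5 Å rule itself is prescribed by the
method.  β = reacted/total with binomial standard error, and

    k_on = 4π D_rel b · β / (1 − (1−β) b/c),

with 4π D_rel b assuming negligible forces at the start surface (b is meant
to be chosen accordingly); a `b_rate` hook accepts a centrosymmetric
correction but defaults off.  Pushing the analytic absorbing-sphere
first-passage probability through this formula returns 4π D_rel R exactly,
and the simulated pipeline agrees within binomial error.

Docking records the mobile pose and energy breakdown during trajectories
into a bounded archive: a candidate within 1 Å RMSD of an archived
lower-energy record increments that record's multiplicity instead of being
stored, so cluster populations reflect the full sampling; the archive keeps
the `capacity` lowest energies and accounts for evicted multiplicity.
RMSD between poses is computed over a chosen atom subset of the mobile
solute with no re-superposition — the fixed-solute frame is the alignment.
Archived poses are grouped by average-linkage hierarchical clustering
(scipy linkage on the RMSD matrix, cut at n_clusters) with
multiplicity-weighted population percentages; the representative is the
medoid.  The clustering matches a brute-force agglomerative implementation
on small synthetic sets.

## Many-molecule mode

`genbox` realises a target mass concentration: the cubic edge follows from
L³ = Σ n M/(N_A c) (343.5 Å for 256 × 14,300 g/mol at 150 mg/ml), and
solutes are placed by rejection sampling against Stokes-sphere overlap with
minimum-image distances.  The dynamics loop evaluates pair forces within a
cutoff (minimum image), optionally scales each solute's D_T and D_R by the
mean-field hydrodynamic factor, applies the BD move with stochastic-part
redraws on hard overlap (up to `n_retry` = 100, then the solute stays put),
and wraps or reflects at the boundary.  Wrap counters are stored per solute
so MSD analysis uses exact unwrapped displacements.

Local occupancy counts neighbours whose centres fall within r_local
(default 4× the largest Stokes radius) with their full Stokes volumes:
φ = Σ (a_j/r_local)³.  The scaling policy is pluggable; the default is the
Tokuyama–Oppenheim short-time form D/D₀ = 1/(1+H(φ)) with
b = √(9φ/8), c = 11φ/16,
H = 2b²/(1−b) − c/(1+2c) − bc(2+c)/[(1+c)(1−b+c)] — chosen as a standard
closed-form short-time self-diffusion expression; φ ≥ 1 is clamped to
`phi_max` (0.74, the close-packing region) with a logged warning.

RDF uses the standard pair histogram normalised by the ideal-gas
expectation C(N,2)·V_shell/V per frame (bin width 1 Å and r_max = L/2 by
default); per-bin uncertainty comes from the frame-to-frame scatter.
Self-diffusion estimates are least-squares fits of MSD/6 (zero intercept,
time-origin averaged) and of log⟨u(0)·u(t)⟩ = −2 D_R t for a body-fixed
axis; both recover planted inputs within ~1 % at the test sizes.

## Conformational switching

Flexible solutes carry an ordered conformer list; trial moves occur at
fixed intervals or at Normal(mean, sd) intervals floored at one BD step.
Proposals are either nearest-neighbour in the list (endpoints have one
neighbour — a documented sampling bias of adjacency proposals) or uniform
over the other conformers.  Acceptance is one of: always, downhill
(ΔG₁ ≤ ΔG₀), or Metropolis (uphill accepted with exp((ΔG₀−ΔG₁)/k_BT)),
where ΔG₀/ΔG₁ are the solute's interaction energies with its surroundings
in the current/proposed conformation, computed with the same enabled terms
as the dynamics.  An accepted swap changes only the active conformation —
position and orientation persist, so conformers must be pre-aligned in a
common body frame (user requirement).  A rejected move waits a full
interval before the next attempt.  In a static external field with two
states 1 kcal/mol apart at 298.15 K, Metropolis occupancies converge to the
Boltzmann ratio exp(−1/0.59248) ≈ 0.1849 and the downhill rule absorbs
permanently into the ground state — the desk-scale analogue of
charge-state convergence in crowded many-molecule runs.

## Surface PMF

The adsorption free energy along the surface normal is computed on a
regular product grid over the five orthogonal degrees of freedom: equal
subintervals (midpoint rule) in each Euler angle — with sin β quadrature
weights so the orientational average is unbiased — and in the two lateral
offsets of a periodic surface cell.  At each height,

    PMF(z) = −k_BT ln ⟨exp(−E/k_BT)⟩,

computed with the per-height minimum subtracted before exponentiation
(overflow-safe) and anchored so PMF(z_max) = 0.  The exponential
(free-energy) average over the sampled grid is the implemented estimator;
integrating the mean force over z is an alternative reading of the
thermodynamic-integration lineage and is left as a hook, because the two
coincide in closed-form test cases and the exponential form is directly
testable (square well: PMF equals the well depth; two-level mixture:
−k_BT ln((e^{2/k_BT}+1)/2)).  Samples landing outside all surface grids
contribute zero energy and are recorded, not errors.

## Synthetic test systems — what they show and what they do not

All tests run on generated inputs: single-site charged spheres,
analytic screened-Coulomb grids, and random boxes at target concentration.
These exercise every code path (grid I/O, interpolation and forces, the
propagator, rate/docking bookkeeping, crowding machinery, switching,
PMF) against closed forms, but they do not probe realistic molecular
shape: anisotropic solutes, rugged potential surfaces, desolvation grids
from continuum solvers, or real reaction-site geometries.  Passing tests
therefore validate the mechanics and statistics of the method, not the
biophysical accuracy of any particular force field or grid input.

Problem sizes in the test-suite and acceptance runs (10⁴ trajectories,
10⁴ solute-walkers × 100 steps, 10⁵ switch attempts, 256-solute boxes) were
chosen so every stochastic check has ≥3σ headroom at its stated tolerance
while a full run completes in well under a minute; they are package
defaults for verification, not recommendations for production studies.

## Degenerate inputs and tie-breaks

Out-of-grid queries are values (0), not errors.  Grid nodes coincident with
a source charge are clamped at half a spacing.  Coincident effective-charge
sites are an error naming the sites; an empty contact-pair list, zero
atoms, non-finite forces/positions and r ≤ 0 in the DH term are errors.
φ ≥ 1 clamps with a warning.  The greedy contact filter breaks distance
ties by stable sort order.  Dedup compares a candidate only against
archived records with energy ≤ its own.  `np.mod` landing exactly on a box
face is folded back consistently with the wrap counters.

## Known limitations

No hydrodynamic tensor (and hence no near-field lubrication), no
electron-transfer windows, no image-charge metal-surface electrostatics
beyond user-supplied grids, no binary grid or trajectory formats (DCD is
deliberately excluded; the native trajectory is a documented TSV plus
multi-model PDB export), and no internal flexibility beyond discrete
conformer swaps.  The `rate`/`dock`/`manymol` CLI subcommands drive
built-in spherical test systems; structure-derived production set-ups are
assembled through the Python API.
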