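# Methods

## Problem

A current dipole in the myocardium drives potentials on the body surface.
Given the nine physical observation points of the standard 12-lead ECG
(V1–V6, RA, LA, LL), the package estimates where that source is and which way
it points, and corrects a time series of such estimates with a Kalman filter.
The chain is: voxel volume-conductor forward model → lead field matrix →
greedy sparse inverse → state-space smoothing.

## Forward model (SPFD)

Cardiac frequencies are of order 1 Hz, so displacement currents are
negligible and the field problem reduces to quasi-static conduction:

    div(sigma grad phi) = -div J   in the body,
    (sigma grad phi) · n = 0       on the body surface.

The conductor is a 3-D array of cubic voxels (pitch 2 mm at whole-body scale)
with a per-tissue conductivity table (blood 0.70, muscle 0.20, lung 0.20,
heart 0.05, skin pinned to 0.10 S/m; air 0). Unknowns are node potentials;
each grid edge carries the conductance

    S = mean(sigma of the up-to-4 voxels sharing the edge) × pitch,

the standard scalar-potential finite-difference construction (arithmetic mean
over existing neighbors; an edge surrounded by air has S = 0). Kirchhoff's
law at each node gives a symmetric 7-point system with zero row sums. The
1-voxel dipole is a DC injection of ±I at two adjacent nodes.

Numerical choices:

- **Air handling.** Nodes touching no conducting voxel are eliminated from
  the unknown set, which enforces the Neumann condition exactly rather than
  approximating air by a small conductivity.
- **Gauge.** The pure-Neumann system is singular up to a constant per
  connected component; solutions are fixed to zero mean over conducting
  nodes and all comparisons are gauge-aligned.
- **Solver.** Conjugate gradients preconditioned by a geometric multigrid
  V-cycle: Galerkin coarsening with trilinear interpolation on the node
  grid, red-black SOR smoothing on the finest level (the 7-point stencil
  2-colors exactly), damped Jacobi on Galerkin-coarsened levels (whose
  stencils are wider), and a dense pseudoinverse at the coarsest level. Up
  to six levels, relative L2 residual tolerance 1e-6 (both configurable). A
  plain red-black SOR solver (relaxation factor 1.5 by default) is kept as
  an independent slow path and the two are asserted to agree in tests.
- **Residual norm.** "Relative residual" is ||b − A phi||₂ / ||b||₂.

## Lead field matrix

Source points are heart voxels whose six face neighbors are all heart,
subsampled on an axis-aligned 6 mm lattice anchored at the minimal eligible
corner (deterministic ascending z, y, x order). For each point and each base
direction a unit dipole is solved and the column is the electrode potential
vector divided by the anode-point current density — the branch current
through the source edge over the voxel cross-section — so the injected
current magnitude cancels. Columns are blocked [x | y | z]. Persistence is
HDF5 with a model content hash; loading against a different model refuses
unless forced.

## Localization (OMP) and scoring

Single-iteration orthogonal matching pursuit: the column with the largest
|cosine similarity| to the measured potential vector selects the source
point (ties break to the lowest point index); the three columns of that
point form the support, and the Moore–Penrose pseudoinverse recovers the
current-density vector, sign and direction included. The absolute value in
the selection is deliberate — an anti-aligned source must still select its
location — and the sign is restored by the least-squares fit. Scores are
LE = ||r̂ − r_t|| in mm and DE = angle(ĵ, j_t) in degrees with the dot
product clamped to [−1, 1].

Noise is additive white Gaussian at a prescribed SNR: variance = mean signal
power × 10^(−SNR/10), over the grid {0, 10, 20, 30, ∞} dB.

**Test-dipole orientation.** A physical 1-voxel dipole is necessarily
axis-aligned; an oblique orientation is realized as a weighted superposition
of the three grid-edge components, and its true current-density vector is
taken as the per-axis anode current densities weighted by the direction.
Orientation sampling is a mode: `"sphere"` (uniform on the sphere, the
default study protocol) and `"axis"` (random signed base direction). For
noise-free dipoles placed exactly at lead-field grid points, axis-aligned
sources are recovered exactly (the measurement is literally a dictionary
column); oblique sources are frequently assigned to a neighboring point
because the greedy selection correlates against single columns — this, with
the off-grid placement of random test positions (a floor of roughly half the
6 mm lattice diagonal), is why mean noise-free LE is nonzero, here ≈12–13 mm
on the desk phantom.

## Kalman correction

The source moves at a constant ventricular conduction velocity
v = 1.9 m/s along the direction of the estimated current density,
u(t) = v·ĵ/||ĵ||. The filter is scalar per axis (diagonal Q, R — the printed
gain division is scalar-form) with the literal recursion: P⁻ = P + dt²·Q,
K = P⁻/(P⁻+R), P = (1−K)P⁻, x̂ = x̂⁻ + K(r̂ − x̂⁻), initialized at the
AV-node location with P(0) = Q. State is in mm, dt in seconds (default
1 ms — the R-wave sampling interval is a user input), so the dt²·Q
process-noise inflation is small at millisecond steps; that is the unit
convention of the recursion as specified, kept verbatim.

Q defaults to the per-axis variance of signed localization-error components
over a 100-dipole study (a pooled LE-variance mode exists). R is estimated
by localizing a fixed probe set against random lead-field sub-dictionaries
(10 subsets, 500 points at full scale; capped below N on desk phantoms) and
taking the variance of the estimates across subsets — one documented reading
of an ambiguous protocol; both Q and R are directly settable.

## Synthetic phantoms

The block torso emulates the structure the method relies on: an air margin,
a muscle body, two lung slabs flanking a cubic heart with a high-conductivity
blood core, and nine named surface electrodes (six anterior sites spanning
the heart projection, three distal limb surrogates on lateral faces). The
desk-scale default is 40³ voxels at 2 mm (44 source points at 6 mm spacing);
a 24³ variant backs fast unit tests. Generation is pure (same spec →
bit-identical model). What the phantom does *not* emulate: realistic torso
and heart geometry, the 51-tissue inhomogeneity spectrum, and physiologic
ECG waveforms — so passing desk-scale tests validates the machinery and its
physics contracts, not clinical-scale error magnitudes, which require the
externally licensed whole-body anatomical model.

Trajectories advance by exactly v·dt per step along a direction profile
(constant-speed contract to 1e-9 relative) and must remain inside cardiac
tissue when a model is attached.

## Problem sizes used in the shipped checks

Dense-oracle comparison on a 6³ phantom; analytic-limit refinement on a
96 mm uniform body at 4 mm and 2 mm pitch with 8 interior probes; exact
recovery and OMP-vs-exhaustive on the 40³ phantom (N = 44 ≤ 50 supports);
SNR sweep with 1000 noise patterns per level over 100 dipoles; Kalman
recovery over 200 Monte-Carlo runs of 30 steps; end-to-end tracking over 30
noise patterns of an 11-step in-heart trajectory at 20 dB. These sizes keep
every stage reproducible in minutes on one CPU.

## Known limitations

- Single-source (one OMP iteration) only; no minimum-norm baselines.
- Isotropic, frequency-independent conductivities.
- Greedy selection is not the exhaustive best-support minimizer; the
  agreement rate between the two is measured and reported rather than
  assumed.
- The per-axis scalar Kalman filter ignores cross-axis covariance.
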