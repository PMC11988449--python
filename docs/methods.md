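# Methods

## The model and its assumptions

The workflow assumes that a cryptic pocket corresponds to a metastable,
rarely visited region of the receptor's conformational landscape, and
that a pose is pharmacologically plausible only if (i) the conformations
that bind it carry non-negligible equilibrium probability, (ii) the
ligand is kinetically stable there, and (iii) the site is reachable from
bulk solvent.  Each stage operationalises one of these requirements.

### Adaptive sampling (FAST)

Each generation launches `sims_per_generation` unbiased simulations from
conformations chosen among *all* frames discovered so far by the reward

    r_i = φ̃_i + α·ψ̃_i

with φ the directed metric (arithmetic mean of the loop–wall nearest-atom
distances; larger = more open), ψ = 1/(1 + neighbours within an RMSD
radius) the inverse local sampling density, and φ̃, ψ̃ min–max normalised
over the discovered set.  Defaults: α = 1, neighbourhood radius 0.3 (toy
units), candidate pool = every stored frame, ties broken by discovery
index.  The functional form of the reward (sum of normalised terms) and
the default α are our choices; the balance itself — exploitation of
pairwise-distance progress against exploration of undersampled states —
is the method's defining property.  No bias acts within a trajectory, so
archives remain valid MSM input.

### Markov state model

* Discretisation: k-means (k-means++ init, 10 restarts, fixed seed).
* Counting: sliding window at lag τ, never across trajectory
  boundaries.  Sliding (rather than strided) counting maximises data use;
  the estimator choice is ours and is recorded here because published
  workflows often leave it implicit.
* Ergodic trimming to the largest strongly connected component of the
  count graph, required for π to exist.
* Reversible maximum likelihood: the standard self-consistent fixed
  point on the symmetric flux matrix,
  `x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j)`, iterated until
  max|Δx| < 1e-10 (x normalised to unit mass) or 1e6 sweeps.  The
  iteration increases the likelihood monotonically; detailed balance
  holds to 1e-8 by construction and is asserted in tests.  π is read off
  the converged flux row sums.
* Implied timescales t_k = −τ/ln λ_k with the stationary eigenvalue
  excluded; non-positive eigenvalues are flagged as undefined rather than
  propagated as NaN.
* tICA solves the symmetrised generalised eigenproblem
  C(τ)v = λC(0)v on mean-free data (ridge ε = 1e-8 when C(0) is
  singular); VAMP-2 score = 1 + Σλ² (constant function included).
* Presets: toy scale (50 states, lag by timescale plateau) and a
  production preset (1000 states, 5 ns lag, 1 ns tICA lag, 4 tICs)
  matching the scale of real membrane-protein campaigns.

### Boltzmann-reweighted docking

One best-scored pose per conformation.  A microstate's π is split
uniformly across the poses assigned to it (π̂_i), avoiding double
counting; the default effective score is the PopShift-style

    G_i = g_i − kT·ln π̂_i ,   kT = 0.596 kcal/mol (300 K)

with a macroscopic constant K = Σ π̂_i·e^(−g_i/kT).  A second,
`linear-expectation` mode ranks by the population-weighted score
contribution π̂_i·g_i; the exponential form is the default and the mode
used is recorded in output metadata, because the lineage of ensemble-
docking reweighting admits both conventions.  Pose clustering is
quality-threshold: repeatedly promote the pose with most neighbours
within the 2.5 Å ligand-RMSD cutoff (ties to the lowest pose id), remove
its cluster, repeat; poses share a receptor-aligned frame so raw
coordinate RMSD is the pose distance.

### Stability screen

"Remained stable throughout" is read in its strictest form: a replicate
passes only if **every** stored frame has COM-RMSD strictly below the
15 Å threshold, and a pose passes with ≥ 5 of 6 passing replicates.
Traces are used raw (no smoothing); stride and smoothing conventions are
otherwise unspecified in published practice, so the strict reading is
documented here.  Contact profiles pool all stable replicates before
computing per-residue frequencies (any-atom 4.0 Å cutoff, strict > 0.5
threshold for the high-contact set).

### Accessibility

A clearance grid (default 0.5 Å spacing; voxel value = distance to the
nearest atom surface, negative inside atoms) replaces Voronoi-based
tunnel finding: the widest path from the ligand COM to bulk is the
max-min path on the 6-connected voxel graph, computed exactly (over the
discrete field) by binary search on the clearance threshold with
connected-component labelling.  This has the same bottleneck semantics as
Voronoi tunnel software but is verifiable against analytic constructions
and an exhaustive Dijkstra oracle, which the tests do.  "Bulk" is the
padded bounding-box boundary; per-face results give up to six distinct
exit directions.  Bottlenecks carry a ±spacing tolerance, reported with
every result.  Classification: open ≥ 2.0 Å, buried < 1.5 Å,
indeterminate in between — indeterminate is reported, never silently
resolved.  Pocket volume counts probe-admissible voxels not reachable by
a flood fill from the exterior.

### Dose–response analysis

The four-parameter Hill model in log-concentration form,
Y = R_basal + (R_max − R_basal)/(1 + 10^((logEC50 − logX)·nH)), is fitted
by Levenberg–Marquardt least squares with multi-start initialisation
(logEC50 over the observed range × nH ∈ {0.5, 1, 2, 4}); the best
residual sum of squares wins and parameters are canonicalised to
R_max ≥ R_basal.  EC fractions invert the fitted curve analytically;
% modulation = (R_A − R_0)/R_0·100; groups are compared per
concentration by unpaired two-sided t tests with **unadjusted** p-values
(no multiple-comparison correction is applied, and the output says so).

## The synthetic layer: what it emulates and what it does not

* **Toy dynamics**: overdamped Euler–Maruyama on 2D sums of inverted
  Gaussians over a quadratic confinement.  The default three-well
  landscape (depths 10, 6.5, 4.8 kT; widths 0.3 nm; confinement
  2 kT/nm²) encodes a closed → intermediate → open staircase with
  barriers of ≈ 8 and ≈ 5 kT, making the open basin rare on the
  simulation timescale — the regime in which reward-guided reseeding
  demonstrably beats uniform restarts.  The barrier heights were chosen
  once to put a single unbiased swarm's direct-transit probability near
  zero while keeping the FAST ladder feasible within ~20 generations.
  The wall-anchor featurization (distances from the moving bead to three
  fixed beads) makes the mean feature distance maximal in the open basin.
* **Sphere receptors**: Fibonacci-lattice shells of uniform-radius
  spheres.  Open sites get an explicit tube of rings whose clear inner
  radius *is* the stated bottleneck; buried sites get a double, offset
  shell that seals all lattice pores.  For buried sites with a stated
  non-zero bottleneck the annotation is an upper bound on the realized
  pore radius.  The slab-with-channel construct lines its hole with
  rings at exactly channel radius + atom radius, so the analytic
  bottleneck is exact.
* **Surrogate scores**: linear in openness with seeded Gaussian noise —
  the simplest calibrated model in which better scores accompany more
  open conformations.
* **Stability traces**: reflected OU about a ~3 Å converged displacement
  (stable poses) versus drift with no restoring force (escaping poses).

Not emulated: atomic force fields, solvent, ligand chemistry, score
physics, receptor flexibility during the screen.  Passing tests
therefore demonstrate the *pipeline logic* — ranking, clustering,
filtering and classification recover planted truth under calibrated
noise — not the accuracy of any physical model.

## Numerical choices and degenerate inputs

* Reversible MLE: convergence 1e-10 on the flux, 1e6 sweep cap, failure
  raises with the last likelihood gap.  Two-state chains reproduce
  row-normalised counts exactly (automatically reversible).
* tICA eigenvalues are clipped only by assertion (|λ| ≤ 1 + tol); white
  noise yields λ ≈ 0, and the ridge path emits a warning.
* Brownian integration refuses timesteps whose single-step noise SD
  exceeds 0.2× the minimum well separation; non-finite forces abort with
  the offending coordinate.
* Grid origins snap to the spacing lattice so symmetric constructions
  land on voxel centres; empty FES bins are +inf, not zero; degenerate
  (single-bin) surfaces warn.
* All generators are bit-reproducible from their seed; the pipeline
  derives per-stage substreams from one root seed by hashing stage names.

## Problem sizes

Toy defaults (8 generations × 10 sims × 400 steps, 30 microstates,
0.5 Å grids) run the full pipeline in a few seconds on one core; the
acceptance script's benchmarks (1e5-step chains, 2e5-step AR(1) series,
20 paired FAST/random repeats) complete in well under a minute each.
These sizes are the package's chosen desk-scale study conditions; the
production preset records the original campaign's parameters without
attempting to run them.

## Known limitations

* The grid tunnel search is resolution-limited (±spacing) and reports
  per-face alternatives rather than a full tunnel tree.
* ψ (exploration) uses a hard neighbourhood radius; kernel densities
  would be smoother but add a bandwidth parameter.
* The reversible MLE provides no Bayesian error bars; recovery quality
  is assessed against analytic chains instead.
* Macrostate assignment is by free-energy-surface inspection (basin
  counting), not PCCA+.
* The Hill fit treats replicates as independent observations; no
  mixed-effects structure.
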