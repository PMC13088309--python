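# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each analysis stage, and what the synthetic
generators do and do not emulate.

## Coordinate conventions and alignment

Internally all coordinates are Å, times ps, frames 0-based; residue ids
are kept verbatim from the topology. Boxes are orthorhombic edge lengths
per frame; triclinic input is rejected because the z-binning, periodic
re-wrapping and minimum-image arithmetic used throughout assume
rectangular cells (membrane systems built by the usual bilayer builders
are orthorhombic).

`align_to_pore_axis` superposes every frame onto a reference frame by
least squares (Kabsch) over a fit selection — by default the
selectivity-filter (SF) selection, in practice best taken as the SF plus
pore-helix backbone — then rotates the whole series so the principal
pore axis lies on z and translates the SF centroid of the reference to
the origin. The pore axis is estimated as the eigenvector of smallest
eigenvalue of the SF-ring coordinate covariance (the ring is wide
in-plane and thin along the pore), and the final rotation is the minimal
(geodesic) rotation taking that axis onto z, so an already-aligned
series maps to itself exactly. The axis-sign convention is
+z = extracellular; `z_orientation=-1` flips it for structures deposited
the other way up. Which atoms define the axis is a package decision —
the choice is not dictated by any single convention, and is exposed as a
parameter.

## Permeation counting

A traversal is counted by a three-zone state machine per ion: above the
extracellular boundary `z_top`, inside the pore, below the gate-side
boundary `z_bottom`, with the additional requirement that while inside
the ion stays within a lateral cylinder of radius `r_max` (default 8 Å).
Only the full sequence above → inside → below (inward) or the reverse
(outward) emits an event; re-entry without completion emits nothing, so
boundary flicker cannot double count (hysteresis is structural — no
dwell-time constants are needed). An ion leaving the cylinder mid-pore
is reset to whichever bulk zone it next visits.

Periodic boundaries: each frame the ion's z is re-wrapped by minimum
image about the pore centre. A jump through the periodic image then
moves the ion directly between the two bulk zones without visiting the
inside zone, so image re-entry cannot fabricate traversals. This
per-frame zone classification is equivalent to analysing the unwrapped
path as long as the frame spacing is small relative to the pore length —
the randomised-path oracle test covers jump cases explicitly.

Boundary placement defaults (SF-top plane + 3 Å, gate plane − 3 Å,
r_max 8 Å) are configuration, not physics: only "from the filter to the
gate" is physically prescribed, and all three values are exposed.

Conductance: g = |N_net·e/(T·V)| reported in pS from duration in µs and
voltage in mV; net signed charge is used (the physically meaningful
current), with the gross count reported alongside. Replicas aggregate as
mean ± SD with the n−1 denominator, the convention for small sets of
independent runs (typically five).

## Free-energy profiles by Boltzmann inversion

Occupancy is accumulated per z bin (Δz = 0.5 Å default) over all
analysed frames, either laterally integrated within `r_max` (1D) or
resolved in cylindrical shells (2D), where the shell volume
π(r_out²−r_in²)Δz normalises the density ("ions per 0.001 Å³ per frame
interval"). The inversion is

ΔG(z) = −RT ln( C(z) / C_bulk ),

so ion-enriched binding sites are *negative* — the sign under which a
selectivity filter reads as the deepest minima of the profile. C_bulk
comes from a user-defined bulk slab (must be disjoint from the pore and
hold ≥ 100 counts). R = 8.314 J/(mol·K); T defaults to 300 K with
303.15 K selectable for thermophile-channel protocols. Zero-count bins
are set to a finite cap (+8 kcal/mol) and flagged instead of ±∞.
Replicate runs are averaged on the ΔG profiles, not on pooled counts, so
the reported SD is the between-run spread.

`barrier_height` smooths the binned profile with a 3-bin moving average
(edges pinned so padding cannot invent minima), finds local minima,
takes the two deepest inside the window, and returns the maximum of the
profile between them minus the shallower minimum. Monotone or
single-minimum profiles raise a degenerate-profile error. Note the
systematic effects of the estimator itself: extrema sampled at bin
centres and flattened by the moving average bias a sharp barrier low by
a few hundredths of kcal/mol at Δz = 0.5 Å; the recovery tests measure
against the imposed potential evaluated on the same bin centres.

## Hydration census

First-shell coordination counts oxygens within a fixed cutoff of the
ion: 3.4 Å for K⁺ and 3.1 Å for Na⁺, the positions of the first minimum
of the respective ion–oxygen pair-distribution profiles; these are
parameters, not re-derived quantities. Distances are minimum-image under
the frame's box; ties at exactly the cutoff count as inside
(deterministic and testable). The carbonyl class is backbone O atoms of
protein residues by default — scope it to the SF residues via the
selection to reproduce filter-focused profiles; side-chain oxygens are
excluded by default since the coordination chemistry of interest is
backbone-carbonyl substitution for water. Profiles bin the census by the
ion's axial position; bins with fewer than 50 ion visits are masked
(configurable), and replicas aggregate as mean ± SD per bin.

## Pore geometry

The pore-radius profile is the classic largest-inscribed-sphere
construction: at each z, maximise r(c) = min_atoms(|c−atom| − vdW) over
the sphere centre's (x, y), holding z fixed. The optimiser is a seeded
annealed random walk: 500 proposals from a Gaussian step starting at
0.1 Å and decaying geometrically (factor 0.99), accepting improvements,
warm-started from the previous z's optimum (axis start at the first
grid point, which must not be inside an atom). On convex fixtures this
converges well inside 0.05 Å and is seed-independent at that tolerance;
the z step defaults to 0.25 Å. van der Waals radii come from a bundled
element table with atom-name overrides; unresolvable atoms default to
1.5 Å with a logged warning (the profiler's customary fallback).

RMSF is √⟨|x−⟨x⟩|²⟩ per atom in nm over frames already superposed by the
alignment stage (no re-fitting inside the RMSF routine, so the closed
form √3·σ holds exactly for isotropic jitter); per-residue averaging and
replica mean ± SD are options. RMSD is per-frame least-squares-superposed
deviation versus a reference frame, with a `superpose=False` mode for
raw deviations. Cavity water counts waters inside an axial slice and
lateral radius; the region is configuration (gate plane to below the SF,
radius 8 Å by default).

## Transmembrane voltage

Applied-field protocol: V = E·L_z (mV from V/nm and nm), with the
inverse solving E for a target voltage — e.g. −700 mV over a 14 nm box
needs −0.05 V/nm.

Charge-imbalance protocol: the z-binned charge density (from the atom
table's partial charges, averaged over frames, e/Å³) is double-integrated
through the 1D Poisson equation. The piecewise-constant density
integrates exactly (field piecewise linear, potential piecewise
quadratic), so the analytic plate and sinusoid solutions are reproduced
to the binning error (< 0.02 % at 0.5 Å bins). Two gauges are offered:
*periodic* (field and potential periodic, zero-mean potential — the
double-bilayer setting, and the default) and *open* (zero field at the
lower box edge — the isolated-membrane convention, which reproduces the
textbook capacitor formula |ΔV| = σd/ε₀ exactly). Compartment ΔV is the
mean potential contrast between the central 50 % of each compartment's
z range. ε_r = 1 because all charges are explicit. A net-charged cell is
rejected — neither gauge has a solution.

## Single-channel amplitude analysis

The recording-noise scale is estimated from median absolute successive
differences (insensitive to slow gating, which spans many samples at
10 kHz); the default histogram bin width is one third of that scale. The
baseline is the highest-count histogram mode — which presumes the closed
level dominates the recording (open probability below one half);
baseline and open level swap roles otherwise — and is subtracted before
binning. The fit is A_c·N(i_c,σ_c) + A_o·N(i_o,σ_o) by weighted
nonlinear least squares on binned counts (√count weights, Poisson
motivated; unweighted selectable), with i_c constrained to zero within
one bin and a handful of deterministic restarts on the open-level
initial guess. The reported i_o is the open–closed peak separation: the
sub-bin residual of the baseline peak is folded out, which removes the
bin-quantisation bias (up to half a bin, i.e. several percent of a small
unitary current) from the recovered current. Fits whose two means are
closer than the wider σ are flagged single-Gaussian and report no i_o.
Conductance is g = |i_o/V| in pS, and multi-recording aggregation is
mean ± SD.

The optional 4-pole Bessel low-pass at the 1 kHz corner matches the
standard amplifier on-line filter. Filtering attenuates the white
recording noise by roughly half at 10 kHz sampling, so σ-recovery
against the generator's input noise is only meaningful on unfiltered
traces; the parameter-recovery grid therefore runs unfiltered, and a
separate check confirms i_o is robust under filtering (level positions
survive, widths shrink).

## The synthetic generators — what they emulate, and what they do not

`simulate_langevin_pore` is an overdamped (inertialess) Euler–Maruyama
integrator: z ← z + (D/kT)F(z)dt + √(2Ddt)η with F = −dU/dz + qE,
periodic in z; laterally a harmonic spring (1 kcal/mol/Ų) confines ions
to the axis inside the pore half-length and walls reflect outside. Only
steady-state occupancy and flux statistics are consumed downstream, so
inertia is irrelevant. Defaults are the package's study conditions,
chosen once: D = 0.2 Å²/ps (the bulk K⁺ diffusion coefficient), 300 K,
L_z = 40 Å, 20 Å lateral box, dt = 0.2 ps, eight ions — an intentionally
high ion count, for the same reason conduction studies raise the salt
concentration: enough crossing events for stable statistics. A power
consideration fixes the count: well-to-well exchange over a 4 kcal/mol
barrier at these D and T runs at ~6·10⁻⁵/ps, so a 10⁶-step run gives
~12 transitions per ion; with eight ions the ~100 total transitions keep
the well-population error near 0.05 kcal/mol, well under the 0.3 kcal/mol
recovery target. Ions start from the Boltzmann distribution of the
imposed PMF, so equilibrium tests need no burn-in. The stability
contract max|F|·dt·D/kT < 0.2 Å is enforced up front, and any single
step over 5 Å aborts with the step index.

Two deliberate non-physical simplifications: (i) the lateral spring
switches on and off with |z| discontinuously and the axial force does
not depend on (x, y), so the z-marginal of the stationary state is
exactly exp(−U(z)/RT) with no entropic contribution from the lateral
confinement — convenient, because the imposed U(z) is then precisely
what Boltzmann inversion should recover; (ii) pseudo-water is a
non-interacting ideal gas re-sampled per saved frame, sufficient for
cavity-count volume expectations but carrying no solvation structure.
Ion–ion interactions are off by default (no knock-on correlation is
claimed or needed by the downstream statistics).

Because ideal-gas water cannot reproduce the structured first shell
(at 0.0334 Å⁻³ it gives ρ·(4/3)πr³ ≈ 5.5 oxygens within 3.4 Å),
bulk solvation is emulated separately: `make_bulk_solvation` samples
water-oxygen positions from an inhomogeneous Poisson process with
intensity ρ·g(r) around the cation, where g(r) is a parametric
cation–oxygen radial distribution function (excluded core 2.4 Å, first
peak at 2.80 Å of height 2.7 and width 0.30 Å, shallow first minimum
near 3.7 Å — standard K⁺–water magnitudes). The census then measures a
coordination number of ρ∫g(r)4πr²dr ≈ 7.1, consistent with the ~7
oxygens coordinating K⁺ in bulk water. The generator reproduces the
radial statistics of solvation, not its energetics or dynamics — no
water–water correlations, no exchange kinetics.

The two-state trace simulator draws exponential dwell times from a
continuous-time closed/open Markov chain, samples at 10 kHz, sets the
closed level to exactly 0 before noise, and adds white Gaussian noise
(0.05 pA default — a low-noise quartz-pipette recording scale).

What passing tests therefore show about real data: the estimators are
correct on inputs satisfying their stated assumptions (rigid wrapping,
orthorhombic boxes, two well-separated current levels, equilibrated
occupancy). They do not validate force fields, sampling convergence of
microsecond MD, filter conformational heterogeneity, or multi-channel
patches.

## Applying the pipeline to real trajectories

For externally supplied MD (deposited trajectory archives or
regenerated runs), the workflow is: `align` on the SF + pore-helix
backbone; `permeation` with boundaries at the SF top and gate planes and
the protocol voltage (±100 mV physiological-scale, −700 mV
high-voltage, or the charge-imbalance compartment ΔV from
`voltage compel`); `energetics`, `hydration`, `pore-profile`, `rmsf`,
`cavity-water`, `rmsd` per replica; then replica aggregation. These
cluster-scale integration runs are intentionally outside the test
suite — the suite validates every stage on desk-scale synthetic ground
truth instead, and the pipeline end-to-end test runs the identical stage
chain on a generated conduction trajectory.

## Problem sizes used by the test suite and acceptance script

Boltzmann-inversion recovery: 10⁶ steps × 8 ions, occupancy from every
5th step. Drift-conductance: 4×10⁵ steps under 0.1 V/nm (≈ 1200 events).
Permeation oracle: 1000 random paths. Hydration: 200 uniform-background
seeds, 1000 structured-solvation snapshots. Ephys grid: nine 10⁵-sample
traces. These sizes put every stochastic check at ≥ 3σ resolution while
keeping the full suite near a minute of CPU.

## Known limitations

- Orthorhombic boxes only; no velocities/forces; no structure repair.
- Partial charges are not read from PDB/GRO (absent in those formats);
  charge-density analyses need synthetic structures or explicitly
  assigned charges.
- The pore-radius profiler implements only the inscribed-sphere profile
  (no conductance prediction, no surface export).
- Amplitude fitting handles one open level; multi-channel patches and
  drift beyond a constant baseline are out of scope.
- The permeation machine reports no per-binding-site dwell kinetics;
  z-traces can be exported for inspection instead.
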