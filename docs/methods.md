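# Methods

## The model

`latagg` simulates the aggregation kinetics of short amphipathic peptides
on a simple cubic lattice (spacing a = 1). Each peptide is a self-avoiding
chain of M beads over a four-letter alphabet — H (hydrophobic), P (polar),
and the charged types + and − — with the default 8-bead sequence
`+HHPPHH-`. The system holds N such chains in a box that is periodic in x
and y (and in z in bulk); an attached surface turns the z axis into a slab
with the surface plane at z = 0 and a hard, non-interacting wall at the
top.

The total energy is a sum of nearest-neighbour (distance a, minimum
image) contact terms,

    E = Σ_intra e(s_i, s_j) + Σ_inter e(s_i, s_j) + Σ_surf e_ν(s_i),

in units of the hydrogen-bond energy ε_H. Intra-chain pairs count only
beads non-successive in sequence (|i − j| ≥ 2 — note that on the lattice
|i − j| = 2 pairs can never actually sit at distance 1, by parity, so
only odd separations ≥ 3 contribute); inter-chain pairs count every
distance-1 pair from different chains. The bead–bead matrix is the
statistical-potential-derived table hard-coded in `energy.py` (H–H −1.0,
+/− −0.7, P–P −0.2, …). A surface is a frozen layer of beads of a single
chemistry — hydrophilic Ps or hydrophobic Hs — that do not interact with
each other; each (chain bead, surface site) contact adds one entry of the
chemistry's affinity row. The row entry coupling the surface to its
matching polarity (P for Ps, H for Hs) is the tunable adsorption strength
ε^ps or ε^hs, stored as −ε with ε ≥ 0; the remaining entries are fixed
(Ps: H 0.2, ± −0.2; Hs: P 0.2, ± 0.2). A bead touching two surface sites
accrues two terms. Balls on rough surfaces carry the same affinity row as
their plane.

## Rough surfaces and roughness statistics

Rough surfaces place balls (each occupying one lattice site, excluding
chain beads like any other occupied site) on columns sampled uniformly
without replacement: style S puts a single ball at z = 1, style D a rigid
double ball at z = 1 and 2, and DS an equal mix (an odd ball budget gives
the extra column to the S type). Over the Ns = Lx·Ly columns with heights
h ∈ {0, 1, 2}:

    h̄ = Σh_i/Ns,  Θ = sqrt(Σ(h_i − h̄)²/Ns),  Ω = N_b/Ns.

Because Θ depends only on the height counts, it obeys closed forms at
coverage Ω: Θ = sqrt(Ω(1−Ω)) (S), 2·sqrt(Ω(1−Ω)) (D), and
sqrt(2.5Ω − 2.25Ω²) (DS at an exact split). Θ-parameterised scans invert
these on the smaller root (Ω ≤ the peak), so the realised Θ matches the
target up to the round(Ω·Ns) discretisation (≲ 0.01 on a 14×14 base).
No minimum-separation constraint is imposed between ball columns; they
are plain uniform draws.

## Monte Carlo dynamics

Moves follow the standard self-avoiding-walk repertoire. With probability
p_global = 0.1 a whole chain is either rotated 90° about a coordinate
axis through a uniformly chosen pivot bead (axis uniform, sense ±90°
equiprobable) or translated one lattice unit in one of the 6 directions
(each variant with probability 1/2). Otherwise a chain and a bead are
picked uniformly: end beads attempt a tail rotation onto a uniformly
chosen neighbour of their anchor; an interior bead attempts, with
probability 1/2 each, a corner flip (to the fourth corner of its
right-angle plaquette, a deterministic target) or a crankshaft of the
U-segment (i, i+1) about the axis through beads i−1 and i+2, the 90°,
180° and 270° rotations chosen uniformly. The branch probabilities are
fixed, never conditioned on geometry: picks whose geometric precondition
fails (a straight bead for a corner flip, non-adjacent anchors for a
crankshaft, a wall or occupied target) are null moves that still consume
the attempt. This makes every proposal probability exactly symmetric,
P(A→B) = P(B→A), which the test suite verifies by exhaustive enumeration
of proposal probabilities on small systems; combined with Metropolis
acceptance min(1, exp(−ΔE/T)) (k_B = 1, T in ε_H) the chain samples the
Boltzmann distribution, verified against exact enumeration of a 4- and a
5-bead chain in a 4³/5³ periodic box.

A note on the crankshaft bookkeeping: the two middle beads of a U-segment
are themselves corner beads, so "corner beads flip, straight beads
crankshaft" would never fire a crankshaft; splitting the interior-bead
pick 50/50 between the two move types keeps both reachable and symmetric.

One MCS is one attempted elementary move by default. A per-sweep mode
(one MCS = N·M attempts) is available behind `MCConfig.sweep_mode` and
recorded in all metadata; absolute first-passage times shift by a
constant factor between conventions while comparisons across conditions
are unaffected. ΔE for a proposal is computed from the moved beads'
contact shells only (with within-segment pairs counted once); it agrees
with full recomputation to < 10⁻⁹ over randomized stress tests in all
environments. All attainable energies are integer multiples of 0.05 ε_H
with the default tables, so the incrementally accumulated running energy
is exact to round-off over millions of steps.

The hot loop (proposals, incremental energies, acceptance) is compiled
with numba over flat arrays: ~0.7 µs per attempt on one core, which is
what makes the stochastic end-to-end checks feasible at desk scale. The
pure-numpy `total_energy` in `energy.py` is deliberately independent of
the kernels and serves as the oracle in the ΔE tests.

## Reference fibrils and the aggregation time

The aggregation criterion is relative to an environment-specific
reference: the lowest-energy aggregated configuration found for bulk or
for a smooth surface of the relevant chemistry at the scan's ε (surface
morphology differs — on a strongly hydrophobic surface the chains adopt
the compact monomer conformation). References come from best-of-many
simulated annealing (geometric ladder, default 24 temperatures from 1.2
to 0.12, 20 000 attempts each, recorded seeds); for bulk a deterministic
antiparallel in-register stack (near-square checkerboard cross-section,
every seam −5.8 ε_H for the default sequence) competes as a candidate so
the bulk reference is never worse than the constructed stack. For N ≥ 2
only candidates with at least one inter-chain contact are eligible — a
cold search can otherwise end with every chain adsorbed separately,
which is not a fibril. For M = 8 and N ≤ 2 the annealed minimum is
cross-checked against exhaustive enumeration (81 390 conformations for
one chain; all conformation pairs and offsets for 3-bead dimers).

Q_fib is the reference's inter-chain contact count. The fibril fraction
of a state is its inter-chain contact count divided by Q_fib (stored
uncapped); a stricter mode counting only contacts whose bead-type pair
occurs in the reference contact map exists behind a flag, the default
being the plain count ratio for robustness and speed. A trajectory's
first passage is the earliest measured MCS with fraction ≥ 0.8.
τ_agg is the arithmetic mean of uncensored first passages pooled across
profiles, ln τ_agg = ln(mean) (not the mean of logs), the SEM comes from
a bootstrap over trajectories, and censored runs are excluded from the
mean but always reported; a censoring fraction above 20% flags the
estimate as a lower bound.

## Scans, seeds and regime classification

`ScanSpec` fixes system, chemistry, scan axis (ε on smooth surfaces or Θ
with a ball style), replication and budget. Every random draw derives
from a master seed through `numpy.random.SeedSequence` keyed by
(condition, profile, run), so scans are bit-reproducible end to end and
order-independent. Default boxes are 14³ for N = 6 and 18³ for N = 12,
keeping the chain-bead number density near 0.017 per site — the model's
high-concentration working regime; the mapping of lattice units to a
molar concentration is a convention recorded in run metadata, not a
derived quantity. With a surface, chains live in 1 ≤ z ≤ Lz−1.

`classify_regimes` reads the weak/medium/strong absorption boundaries
off a scanned ln τ_agg curve: ε1 is the grid argmax (the slow-down peak),
ε2 the argmin (the catalytic optimum); purely monotonic curves are
labelled as such and fewer than 4 points is "indeterminate". For Θ scans
a U-shape is flagged when an interior point sits at least one pooled SEM
below the Θ = 0 value and is followed by a rise. These are grid
estimates with at best half-a-grid-step resolution, never exact values.

## Desk scale versus production scale

Desk-scale defaults (tests and the acceptance script) use 20
trajectories per condition, MC budgets of 3×10⁷ attempts and the N = 6
system; they resolve the qualitative regime structure — the monotonic
roughness slow-down at strong absorption reproducibly spans ~4 units of
ln τ_agg between Θ = 0 and Θ = 0.4 — but not converged absolute
ln τ_agg values, which require on the order of 10⁷–10⁸ MCS × 100–150
trajectories per point. The full protocol (10–15 profiles × 15–20 runs
per point, the published ε and Θ grids, N = 12) is expressible through
`ScanSpec` unchanged; only the budgets grow.

## Numerical and degenerate-input choices

* Chi-square comparisons against exact Boltzmann weights thin the
  sampled energies (every 150–200 attempts after a 10⁴ burn-in): raw
  per-step occupancies of even a perfect sampler fail independence-based
  tests because successive states are autocorrelated. Levels with
  expected counts < 5 are excluded.
* Bond and contact tests use the minimum-image convention on periodic
  axes; rigid rotations act on minimum-image displacements from the
  pivot, which is exact for chains shorter than half the box edge (the
  default boxes satisfy this with margin).
* N = 0 is a valid state with zero energy; `max_mcs = 0` returns the
  initial measurement only; placement failures raise with a suggestion
  to enlarge the box after a bounded retry budget.
* Annealing convergence is heuristic (agreement of independent
  restarts); a non-converged reference is flagged, not fatal.

## What the generator does and does not emulate

Synthetic inputs are the model itself: random dispersed initial
configurations, uniformly random ball placements, and the fixed
interaction tables. The model has no solvent, no bond angles, no
off-lattice geometry, no distance dependence beyond contact, and no
mapping of MCS to physical time; passing tests therefore validate the
simulator's statistical mechanics and its qualitative regime behaviour,
not quantitative kinetics of any real peptide–surface system.

## Known limitations

* Absolute ln τ_agg values at desk scale depend on the MCS convention,
  the box-density convention and the reference's Q_fib; only
  comparisons across conditions at fixed conventions are meaningful.
* The local-move set is not ergodic for arbitrarily dense packings
  (standard for lattice-polymer move sets); at the working density this
  is immaterial, and the Boltzmann tests cover the dilute regime
  exactly.
* `find_reference_fibril` is a stochastic search for N > 2; its Q_fib
  can differ between runs with different seeds. Scans therefore compute
  the reference once per condition from derived seeds and record it.
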