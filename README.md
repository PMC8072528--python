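# latagg — lattice Monte Carlo of peptide aggregation on rough surfaces

`latagg` is a simulator for studying how foreign surfaces — membranes,
nanoparticles, engineered substrates — change the aggregation kinetics of
amyloid-forming peptides. It implements a coarse-grained cubic-lattice
model: peptides are 8-bead self-avoiding chains over the alphabet
{+, −, H, P} (default sequence `+HHPPHH-`), interacting through a
contact-energy matrix in hydrogen-bond units ε_H, near smooth or rough
chemically uniform surfaces. Aggregation is followed with Metropolis
Monte Carlo dynamics and quantified by the aggregation time τ_agg, the
mean first-passage time (in Monte Carlo steps) to a configuration holding
at least 80% of the inter-chain contacts of a reference fibril.

The total energy of N chains is

    E = Σ_l Σ_{i<j} e(s_i, s_j) δ(r_ij − a)        (intra-chain)
      + Σ_{m<l} Σ_{i,j} e(s_i, s_j) δ(r_ij − a)    (inter-chain)
      + Σ_m Σ_i Σ_k e^νs(s_i) δ(r_ik − a)          (chain–surface)

with a = 1 the lattice spacing and δ the lattice contact indicator. The
surface affinity for the matching polarity (ε^ps for hydrophilic, ε^hs
for hydrophobic surfaces) is tunable; sweeping it reproduces the three
absorption regimes — weak (aggregation slowed), medium (catalysed) and
strong (re-slowed) — and roughness scans show the monotonic slow-down of
fibril formation with roughness Θ at weak/strong absorption and a
U-shaped (catalytic) dip at medium absorption. Rough surfaces are built
from randomly placed single (S), double (D) or mixed (DS) balls; Θ is
the standard deviation of the resulting height field.

Everything a desk machine can check exactly is checked exactly: energy
increments against full recomputation, Boltzmann sampling against exact
enumeration of small chains, annealed ground states against exhaustive
self-avoiding-walk enumeration, and roughness statistics against closed
forms.

## Worked example

```python
import latagg as lg

# strongly absorbing hydrophilic surface
model = lg.InteractionModel(eps_ps=1.4)

# environment-specific reference fibril (annealed, seeded)
ref = lg.find_reference_fibril(6, lg.DEFAULT_SEQUENCE, "Ps", model,
                               seeds=[0, 1, 2])
print(round(ref.e_min, 6), ref.q_fib)  # -55.0 32

# one trajectory on a rough S-surface with roughness Theta = 0.2
box = lg.default_box(6, with_surface=True)
om = lg.solve_coverage_for_roughness("S", 0.2)
prof = lg.generate_profile("S", om, (box.Lx, box.Ly), "Ps", seed=5)
state = lg.place_random_chains(6, lg.DEFAULT_SEQUENCE, box,
                               surface=prof, rng_seed=2)
rec = lg.run_trajectory(state, model,
                        lg.MCConfig(temperature=0.54, max_mcs=20_000_000,
                                    measure_every=2000, seed=1),
                        stop_condition=lg.FibrilStop(ref.q_fib, 0.8))
print(rec.first_passage)               # 54000
```

The reference search finds an aggregate of energy −55.0 ε_H whose 32
inter-chain contacts define Q_fib; the trajectory first reaches 80% of
those contacts (26 of 32) after 54 000 attempted moves. Repeating over
an ensemble of profiles and runs and averaging the first passages gives
τ_agg for that roughness; at ε^ps = 1.4 the ensemble mean grows
monotonically with Θ (ln τ_agg rises by ≈ 4 between Θ = 0 and Θ = 0.4
at desk scale), the roughness-induced slow-down of fibril formation.

The same machinery is scriptable from the shell:

```bash
latagg surface-gen --style S --omega 0.25 --dims 14 14 --out surf.txt
latagg simulate -n 6 --chemistry Ps --eps 1.2 --max-mcs 200000 --out traj.csv
latagg scan -c scan.yaml -o results/ --classify
latagg ground-state -n 1 --environment Hs --eps 2.0
```

where `scan.yaml` mirrors `latagg.ScanSpec` field for field (axis values,
replication, budgets, master seed).

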