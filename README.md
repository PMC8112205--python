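# raftadhesion

Lattice Monte Carlo and mean-field model of cell–substrate adhesion in
which a fluctuating membrane carries lipid-raft patches and adhesion
receptors and binds ligands on an apposing surface that are either
laterally mobile (supported bilayer) or immobilized (uniform grid,
random, or circular clusters).

The configurational energy on an L×L periodic square lattice (patch size
`a = 10 nm`) has four terms: discretized curvature (bending) energy of
the separation field, a square-well receptor–ligand binding potential,
a raft–receptor coupling, and a nearest-neighbor raft–raft contact
energy. A Metropolis sampler with three move types (membrane height
shifts, protein hops, raft hops that leave receptors behind) generates
equilibrium configurations; observables include the heat capacity per
site (whose peak locates the homogeneous → phase-separated transition),
the two-dimensional binding constant `K = [RL]/([R][L])`, and receptor
partitioning into raft domains. A Bragg–Williams mean-field module
reproduces the mobile-ligand phase line via a common-tangent binodal
solver.

## Layout

| module | contents |
| --- | --- |
| `raftadhesion.model_core` | domain types, the four energy terms, incremental single-move energies, snapshots |
| `raftadhesion.mc_engine` | Metropolis engine: pure-Python reference path + numba production kernel |
| `raftadhesion.observables` | sample series, heat capacity, binding constant, raft partitioning, replicate stats |
| `raftadhesion.phase_analysis` | contact-energy sweeps, CV-peak transition location, phase diagrams, K(u) curves |
| `raftadhesion.mean_field` | free energy, critical point, binodal solver, contact probability Pb, MF phase lines |
| `raftadhesion.scenarios` | synthetic initial configurations for all studied systems |
| `raftadhesion.cli` / `validation` | YAML-driven pipeline commands and the fast oracle suite |

## CLI

```sh
raftadhesion example-config > config.yaml   # complete annotated config
raftadhesion describe -c config.yaml        # realized counts/concentrations
raftadhesion simulate -c config.yaml        # one run -> series.csv + observables.csv
raftadhesion sweep -c config.yaml           # CV and K over a u grid
raftadhesion phase-diagram -c config.yaml   # u*(cR) table + figure
raftadhesion k-curve -c config.yaml         # K vs u/u*
raftadhesion mf -c config.yaml              # mean-field phase line (mobile ligands)
raftadhesion validate                       # fast oracle suite
```

Configs accept a `preset: paper | desk | test` key that fills in lattice
size, cycle counts and replicate numbers (the `paper` preset is the full
published fidelity — 5×10⁷ + 5×10⁷ cycles at L = 60 — and is
cluster-scale; `desk` and `test` are scaled-down).

Every output CSV carries a config hash and seed; reruns of the same
config are bit-identical.

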