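# poreflux

Analysis toolkit for ion-channel MD trajectories: permeation-event counting
and single-channel current estimation, selectivity-filter (S0–S4) site
occupancy, axial ion-density / free-energy profiles, HOLE-style pore radius
profiles, gate–filter order parameters, and PLS functional mode analysis
(ewMCM) of the activation-gate → filter coupling. A synthetic-ensemble
generator (`poreflux.synthgen`) plants a known hop-chain / gating structure
with ground-truth logs so every pipeline stage is testable without MD data.

Internal units throughout: nm, ns, pA, mV, kT, degrees.

## Layout

| module | contents |
| --- | --- |
| `poreflux.trajio` | PDB/GRO + XTC/TRR/DCD reading (via MDAnalysis), role annotation (TVGYG motif search or explicit selections), restraint-scheme tables, tidy CSV I/O |
| `poreflux.geometry` | cross-subunit distances (opposite/adjacent), contact distances, helix bend, rigid-body superposition |
| `poreflux.permeation` | crossing state machine (hysteresis, radial check, periodic-wrap suppression), current ± bootstrap CI, cavity census, voltage from applied field |
| `poreflux.filter_state` | site geometry from oxygen-ring planes, ion/water/vacant occupancy, carbonyl-flip detection |
| `poreflux.profiles` | Gaussian-KDE density → free-energy profiles, coverage-factor CIs, pore-radius optimisation |
| `poreflux.fma` | PLS1 (NIPALS) functional mode analysis, MCM/ewMCM, half/half cross-validation, mode interpolation, PCA comparison |
| `poreflux.stats` | replica-level percentile bootstrap (20,000 repeats default), Student-t coverage-factor CIs |
| `poreflux.synthgen` | synthetic tetramer with compartment hop-chain ions, gate-coupled filter spread, water entry/blocking, scripted planted-rate mode, ground-truth logs |
| `poreflux.cli` | `poreflux` command with `synth`, `order-params`, `current`, `occupancy`, `flips`, `density`, `pore`, `fma`, `scan` subcommands |

## CLI quick start

```bash
# generate a synthetic gating preset (structure.pdb + per-replica XTCs + truth log)
poreflux synth --preset gating-curve --seed 1 --out synth_out

# count crossings and estimate the current with a bootstrap CI
poreflux current synth_out/structure.pdb \
    --traj synth_out/replica_00.xtc --traj synth_out/replica_01.xtc \
    --out current_out

# end-to-end opening scan from a config file
cat > scan.ini <<EOF
[scan]
openings = 1.2, 1.5, 1.7, 2.0, 2.4
n_replicas = 3
n_frames = 1000
EOF
poreflux scan scan.ini --out scan_out
```

All commands write tidy CSV tables plus a JSON manifest (seed, parameters,
config hash); reruns with the same config and seed are byte-identical.

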