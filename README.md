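# egresslab

A desk-scale toolkit for studying how a buried ligand leaves its binding
site, built around four pieces of methodology from biased molecular
dynamics:

1. **Memetic egress-path search.** Candidate rigid-body poses of the
   ligand are sampled in a local sphere and scored with an effective
   ligand–environment interaction functional

   Λ = Σ<sub>i∈lig, j∈env</sub> h<sub>ij</sub> e<sup>−r<sub>ij</sub>²/2w²</sup> + γ,  h<sub>ij</sub> = s<sub>i</sub>v<sub>j</sub> + s<sub>j</sub>v<sub>i</sub>,

   where s and v are per-atom partial volumes and solvation coefficients
   and γ is the van der Waals + electrostatic interaction energy.  The
   minimizing pose becomes the target of a constant-magnitude pulling
   force over *m* Langevin steps; the relaxed snapshot is saved as node
   S(k) of the reaction coordinate S(1..N).

2. **Path collective variables.** Progress along and deviation from the
   discretized path:

   s(**R**) = Σ<sub>k</sub> k e<sup>−λm<sub>k</sub></sup> / Σ<sub>k</sub> e<sup>−λm<sub>k</sub></sup>,  z(**R**) = −(1/λ) ln Σ<sub>k</sub> e<sup>−λm<sub>k</sub></sup>,

   with m<sub>k</sub> the mean-square deviation (Å²) from node k after
   Kabsch superposition on a disjoint alignment set.  Analytic gradients
   (exact for displacement atoms) drive the bias forces.

3. **Well-tempered metadynamics** on s with time-domain adaptive Gaussian
   widths, a one-sided harmonic wall keeping z < 6 Å², the
   time-independent estimator F(ξ) = −((T+ΔT)/ΔT) V(ξ), and
   c(t) reweighting,

   c(t) = (1/β) ln [ ∫dξ e<sup>−βF(ξ)</sup> / ∫dξ e<sup>−β(F(ξ)+V(ξ,t))</sup> ],

   which turns biased frames into equilibrium-weighted samples.

4. **Conformational-state decomposition**: pairwise Kabsch RMSD →
   classical (Torgerson) MDS into 2-D → DBSCAN, with basin occupancies,
   medoid representatives and nearest-basin assignment of external
   structures.

Everything runs on built-in fixtures: analytic double-well benchmarks and
a "cage" system — a spherical shell of tethered particles with engineered
tunnel gaps enclosing a rigid 5-atom ligand — so the whole methodology is
exercised end-to-end in minutes on one CPU.  The audience is method
developers and students of enhanced sampling who want a transparent,
fully testable implementation of this pipeline without an MD engine.

## Worked example

```bash
egresslab demo --seed 1 --outdir demo_out
```

runs the full chain on a single-tunnel cage (radius 10 Å, 110-point
shell lattice): unbiased equilibration, memetic path search, path-CV
metadynamics with the z wall, the free-energy estimator, and the planted
open/closed clustering demo.  It prints

```
demo complete: demo_out (path nodes=19, kernels=11)
```

meaning the ligand escaped in an 19-node path and 11 well-tempered
kernels were deposited in the short illustration run.  `demo_out/`
contains `path.xyz` (+ JSON sidecar with λ and the index sets),
`HILLS.tsv`, `COLVAR.tsv` (time, s, σ, z, bias), `fes.tsv` and
`states.json`; the clustering demo reports basin occupancies 0.70/0.30
for the planted 70/30 closed/open mixture.  All outputs are reproduced
byte-identically when the same seed is given.

The library surface mirrors the pipeline; the same demo in Python:

```python
from egresslab import toysim, memetic_path, wt_metad

cage = toysim.make_cage_ligand(n_cage=110, cage_radius=10.0, n_tunnels=1, seed=4)
state = toysim.langevin_step(cage, toysim.initial_state(cage, seed=104), 400)
path = memetic_path.build_path(cage, state,
                               memetic_path.LambdaParams(rng_seed=11),
                               memetic_path.PathSearchConfig())
path = memetic_path.reparameterize_path(path, 10)
run = wt_metad.run_pcv_metad(cage, path, state, n_steps=3000)
print(run["colvar"][:, 3].max())   # z stays below the 6 A^2 wall
```

## Layout

- `src/egresslab/toysim.py` — fixtures, energies, BAOAB Langevin dynamics
- `src/egresslab/memetic_path.py` — Λ functional, pose search, path assembly
- `src/egresslab/path_cv.py` — Kabsch alignment, s/z/σ and gradients
- `src/egresslab/wt_metad.py` — bias, estimator, c(t), diagnostics, drivers
- `src/egresslab/conf_analysis.py` — RMSD/MDS/DBSCAN state analysis
- `src/egresslab/io_interface.py`, `cli.py` — XYZ/PDB/COLVAR/HILLS, CLI
- `docs/methods.md` — model assumptions, parameters and limitations
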