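# ecgloc

Cardiac current-source localization from 12-lead ECG electrode potentials,
built on a physics-based volume-conductor forward model.

Clinicians read the 12-lead ECG from nine physical observation points
(V1–V6 on the chest, RA/LA/LL on the limbs). `ecgloc` inverts that
measurement: given a voxelized conductor model of the body (a tissue-label
grid with per-tissue conductivities), it estimates **where** the equivalent
cardiac current dipole is and **which way it points**, then stabilizes a
time series of such estimates with a Kalman filter.

The pipeline:

1. **SPFD forward solver** — the quasi-static conduction problem
   ∇·(σ∇φ) = −∇·J with an insulating body surface, discretized on the voxel
   node grid (edge conductances from neighboring voxel conductivities) and
   solved by multigrid-preconditioned CG with SOR smoothing to a 1e-6
   relative residual.
2. **Lead field matrix** — L (M×3N) maps unit-direction current densities at
   N myocardial points (6 mm spacing, interior heart voxels only) to the M=9
   electrode potentials, one forward solve per point and direction:
   L·j = Φ.
3. **OMP localization** — the dictionary column most correlated with Φ
   selects the source point î = argmax |Φ·Lᵢ|/(‖Φ‖‖Lᵢ‖); the pseudoinverse
   of the three-column support [L_îx, L_îy, L_îz] recovers ĵ. Errors are
   scored as LE = ‖r̂ − r_t‖ (mm) and DE = ∠(ĵ, j_t) (degrees).
4. **Kalman tracking** — the source is modeled as moving at the ventricular
   conduction velocity (1.9 m/s) along ĵ/‖ĵ‖; a per-axis scalar filter
   (P⁻ = P + dt²Q, K = P⁻/(P⁻+R)) corrects the location series from the
   AV-node onward.

A deterministic block-torso phantom module (muscle body, lung slabs, heart
with blood core, nine surface electrodes) makes every stage testable at desk
scale. Whole-body anatomical voxel models (e.g. 51-tissue, 2 mm-pitch
datasets) can be loaded from NIfTI or raw+JSON files when licensed from
their providers.

## Worked example

```python
import numpy as np
from ecgloc import (PhantomSpec, make_block_torso, default_electrodes,
                    ForwardSolver, select_source_points, build_lfm,
                    run_dipole_study, study_summary)

spec = PhantomSpec()                      # 40^3 voxels at 2 mm
model = make_block_torso(spec)
solver = ForwardSolver(model)             # builds the multigrid hierarchy once
grid = select_source_points(model)        # 44 points at 6 mm spacing
lfm = build_lfm(model, default_electrodes(spec), grid, solver=solver)

table = run_dipole_study(model, lfm, n_dipoles=100,
                         rng=np.random.default_rng(1), solver=solver)
print(study_summary(table))
```

prints (noise-free, random heart-voxel positions, sphere-uniform
orientations; values rounded here):

```
{'n': 100, 'LE_mean_mm': 13.17, 'LE_sd_mm': 7.31,
 'DE_mean_deg': 30.48, 'DE_sd_deg': 22.92}
```

The ~12 mm mean localization error on this desk phantom has two understood
sources: test dipoles sit at arbitrary heart voxels while estimates snap to
the 6 mm source lattice (a floor of about half the lattice diagonal), and
the greedy single-column selection can assign an oblique source to a
neighboring point. Dipoles placed exactly on lattice points along a grid
axis are recovered with LE = 0 and DE = 0 — that identity is what the
acceptance checks pin down.

The same flow is scriptable from the shell:

```sh
ecgloc phantom --out m.raw --electrodes-out el.csv
ecgloc build-lfm --model m.raw --electrodes el.csv --out lfm.h5 --spacing 6
ecgloc study --model m.raw --lfm lfm.h5 --n 100 --snr 20 --seed 1 --out-dir out/
ecgloc track --series series.csv --out track.csv --q 50 --r 20
```

## Layout

- `src/ecgloc/conductor_model.py` — voxel models, tissue tables, I/O,
  homogenization, heart rotation/scaling.
- `src/ecgloc/spfd.py` — SPFD assembly and the multigrid/SOR solver.
- `src/ecgloc/leadfield.py` — source-point selection, LFM build/persistence.
- `src/ecgloc/localization.py` — noise injection, OMP, LE/DE, dipole studies.
- `src/ecgloc/kalman.py` — the tracking filter and Q/R estimation.
- `src/ecgloc/phantom.py` — block torsos, test dipoles, trajectories.
- `src/ecgloc/cli.py`, `src/ecgloc/config.py` — the `ecgloc` command.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
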