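"""Synthetic voxel torsos, test-dipole sets and moving-source trajectories.

The block phantom emulates the essential structure of a whole-body anatomical
voxel model at desk scale: a muscle body with an air margin, two lung slabs
flanking a cardiac block that contains a high-conductivity blood core, and
nine named surface electrode sites (six anterior precordial sites spanning
the heart projection plus three distal limb surrogates).  Conductivities are
the standard quasi-static values (muscle 0.20, lung 0.20, heart 0.05, blood
0.70 S/m).  Phantom generation is pure: the same spec always yields a
bit-identical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .conductor_model import TissueTable, VoxelModel
from .leadfield import ElectrodeSet, STANDARD_ROLES

__all__ = [
    "PhantomSpec",
    "Trajectory",
    "make_block_torso",
    "default_electrodes",
    "make_test_dipoles",
    "make_trajectory",
    "synthesize_observations",
]

AIR, MUSCLE, LUNG, HEART, BLOOD = 0, 1, 2, 3, 4

PHANTOM_TISSUES = TissueTable({
    AIR: ("Air", 0.00),
    MUSCLE: ("Muscle", 0.20),
    LUNG: ("Lung", 0.20),
    HEART: ("Heart", 0.05),
    BLOOD: ("Blood", 0.70),
})


def _block(center, half) -> tuple[slice, slice, slice]:
    c, h = np.asarray(center, int), np.asarray(half, int)
    return tuple(slice(int(c[a] - h[a]), int(c[a] + h[a])) for a in range(3))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a block torso, in voxel indices.

    Defaults describe the desk-scale study phantom: 40^3 voxels at 2 mm pitch
    (an 80 mm cube), body margin 4 voxels, a 14^3-voxel heart with a 6^3
    blood core, and two 7-voxel-thick lung slabs.
    """

    dims: tuple[int, int, int] = (40, 40, 40)
    pitch_mm: float = 2.0
    body_margin: int = 4
    heart_center: tuple[int, int, int] = (20, 20, 20)
    heart_half: int = 7
    blood_half: int = 3
    lung_halfwidth: int = 8     # lung slab extent in y/z around heart center
    lung_thickness: int = 7
    lung_gap: int = 1           # voxels between heart face and lung slab
    seed: int = 0

    def validate(self) -> None:
        d = np.asarray(self.dims)
        if self.blood_half >= self.heart_half:
            raise ValueError("blood core must nest strictly inside the heart block")
        hc = np.asarray(self.heart_center)
        if np.any(hc - self.heart_half < self.body_margin) or \
           np.any(hc + self.heart_half > d - self.body_margin):
            raise ValueError("heart block must nest inside the body")
        if np.any(d < 2 * self.body_margin + 2):
            raise ValueError("body margin leaves no interior")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        data = yaml.safe_load(open(path)) or {}
        for k in ("dims", "heart_center"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as f:
            yaml.safe_dump(data, f)


def make_block_torso(spec: PhantomSpec = PhantomSpec()) -> VoxelModel:
    """Deterministic block torso per the spec (see module docstring)."""
    spec.validate()
    labels = np.zeros(spec.dims, dtype=np.int64)
    m = spec.body_margin
    body = tuple(slice(m, d - m) for d in spec.dims)
    labels[body] = MUSCLE

    hc = np.asarray(spec.heart_center)
    lw, lt = spec.lung_halfwidth, spec.lung_thickness
    for side in (-1, +1):
        x0 = hc[0] + side * (spec.heart_half + spec.lung_gap)
        xs = (x0, x0 + lt) if side > 0 else (x0 - lt, x0)
        xs = (max(xs[0], m), min(xs[1], spec.dims[0] - m))
        sl = (slice(*xs), slice(max(hc[1] - lw, m), min(hc[1] + lw, spec.dims[1] - m)),
              slice(max(hc[2] - lw, m), min(hc[2] + lw, spec.dims[2] - m)))
        labels[sl] = LUNG

    labels[_block(hc, [spec.heart_half] * 3)] = HEART
    labels[_block(hc, [spec.blood_half] * 3)] = BLOOD

    return VoxelModel(
        labels=labels, pitch_mm=spec.pitch_mm, tissues=PHANTOM_TISSUES,
        heart_label=HEART, blood_label=BLOOD, lung_label=LUNG,
    )


def default_electrodes(spec: PhantomSpec = PhantomSpec()) -> ElectrodeSet:
    """Nine-site electrode layout on the block torso surface.

    V1-V6 sit on the anterior face (min-y body surface) spanning the heart
    projection; RA/LA/LL are limb surrogates on distal lateral surfaces.
    """
    m = spec.body_margin
    hc = np.asarray(spec.heart_center)
    h = spec.heart_half
    nx, ny, nz = spec.dims
    # anterior face nodes (node index j = m), arc across the heart projection
    xs = np.linspace(hc[0] - h, hc[0] + h, 6).round().astype(int)
    zs = np.round(hc[2] + h * np.array([0.5, 0.5, 0.25, 0.0, -0.25, -0.5])).astype(int)
    nodes = [(int(x), m, int(z)) for x, z in zip(xs, zs)]
    # limb surrogates: lateral faces near the top (arms) and bottom (left leg)
    nodes += [(m, ny // 2, nz - m - 2),        # RA on min-x face, superior
              (nx - m, ny // 2, nz - m - 2),   # LA on max-x face, superior
              (nx - m, ny // 2, m + 2)]        # LL on max-x face, inferior
    pos = np.asarray(nodes, float) * spec.pitch_mm
    return ElectrodeSet(STANDARD_ROLES, pos)


def make_test_dipoles(model: VoxelModel, n: int,
                      rng: np.random.Generator,
                      replace: bool = True,
                      orientation: str = "sphere"
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random test dipoles at uniformly chosen cardiac voxels.

    ``orientation="sphere"`` draws directions uniformly on the sphere (an
    oblique dipole, realized as a superposition of the three grid-edge
    components).  ``orientation="axis"`` draws a random signed base direction,
    the orientation a single physical 1-voxel-edge dipole can take.
    """
    if n < 1:
        raise ValueError("need n >= 1 dipoles")
    heart_idx = np.argwhere(model.heart_mask)
    if heart_idx.size == 0:
        raise ValueError("model has no heart voxels")
    if not replace and n > len(heart_idx):
        raise ValueError(f"cannot draw {n} distinct voxels from {len(heart_idx)}")
    picks = rng.choice(len(heart_idx), size=n, replace=replace)
    if orientation == "sphere":
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    elif orientation == "axis":
        dirs = np.eye(3)[rng.integers(0, 3, size=n)] \
            * rng.choice([-1.0, 1.0], size=n)[:, None]
    else:
        raise ValueError(f"unknown orientation mode {orientation!r}")
    return [(heart_idx[p], dirs[i]) for i, p in enumerate(picks)]


@dataclass(frozen=True)
class Trajectory:
    """Constant-speed source path: times (s), positions (mm), unit directions."""

    times_s: np.ndarray
    positions_mm: np.ndarray
    directions: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.times_s)


def make_trajectory(
    model: Optional[VoxelModel],
    start_mm,
    direction_profile,
    v_mps: float = 1.9,
    dt_s: float = 1e-3,
    n_steps: int = 10,
) -> Trajectory:
    """Constant-speed trajectory from a direction profile.

    ``n_steps`` counts moves: the result holds ``n_steps + 1`` positions (the
    total path length is ``n_steps * v * dt``); ``n_steps = 0`` yields an
    empty trajectory.  ``direction_profile`` may be a single 3-vector, an
    array of per-position vectors or a callable ``step -> vector``; move t
    advances by v*dt along the normalized direction at position t.  When
    ``model`` is given, every position must stay inside cardiac tissue
    (heart or blood); the first offending step raises.
    """
    start = np.asarray(start_mm, float)
    if n_steps == 0:
        return Trajectory(np.zeros(0), np.zeros((0, 3)), np.zeros((0, 3)))
    if callable(direction_profile):
        dirs = np.asarray([direction_profile(t) for t in range(n_steps + 1)], float)
    else:
        dirs = np.atleast_2d(np.asarray(direction_profile, float))
        if dirs.shape[0] == 1:
            dirs = np.tile(dirs, (n_steps + 1, 1))
        elif dirs.shape[0] == n_steps:     # per-move profile: hold the last
            dirs = np.vstack([dirs, dirs[-1]])
    dirs = dirs[:n_steps + 1] / np.linalg.norm(dirs[:n_steps + 1], axis=1,
                                               keepdims=True)
    step_mm = v_mps * dt_s * 1e3
    pos = start + np.vstack(
        [np.zeros((1, 3)), np.cumsum(dirs[:-1] * step_mm, axis=0)])
    if model is not None:
        cardiac_labels = [l for l in (model.heart_label, model.blood_label)
                          if l is not None]
        vox = np.floor((pos - model.origin_mm) / model.pitch_mm).astype(int)
        inside = np.all((vox >= 0) & (vox < model.shape), axis=1)
        ok = inside.copy()
        ok[inside] = np.isin(
            model.labels[tuple(vox[inside].T)], cardiac_labels)
        if not ok.all():
            raise ValueError(
                f"trajectory exits cardiac tissue at step {int(np.argmin(ok))}")
    times = np.arange(n_steps + 1) * dt_s
    return Trajectory(times_s=times, positions_mm=pos, directions=dirs)


def synthesize_observations(
    trajectory: Trajectory,
    model: VoxelModel,
    lfm,
    snr_db: float = 20.0,
    rng: Optional[np.random.Generator] = None,
    solver=None,
):
    """Forward-solve, add noise and localize each step of a trajectory.

    Returns ``(observations, truth)``: a DataFrame of per-step OMP estimates
    (r_hat, j_hat) ready for Kalman tracking, and a DataFrame with the true
    positions and the synthesized true anode current densities.
    """
    import pandas as pd

    from .leadfield import point_responses
    from .localization import add_noise, omp_localize
    from .spfd import ForwardSolver, SolverConfig

    if rng is None:
        rng = np.random.default_rng()
    if solver is None:
        solver = ForwardSolver(model, SolverConfig(tol=lfm.solver_tol))
    enodes = lfm.electrodes.node_indices(model)
    vox = np.floor((trajectory.positions_mm - model.origin_mm)
                   / model.pitch_mm).astype(int)
    cache: dict[tuple, tuple] = {}
    obs_rows, truth_rows = [], []
    for t in range(trajectory.n_steps):
        key = tuple(vox[t])
        if key not in cache:
            cache[key] = point_responses(solver, enodes, vox[t])
        Phi3, j_an = cache[key]
        w = trajectory.directions[t]
        phi = add_noise(Phi3 @ w, snr_db, rng)
        est = omp_localize(lfm, phi)
        obs_rows.append({"t": t, "rx": est.location_mm[0], "ry": est.location_mm[1],
                         "rz": est.location_mm[2], "jx": est.j_hat[0],
                         "jy": est.j_hat[1], "jz": est.j_hat[2]})
        jt = w * j_an
        truth_rows.append({"t": t, "x": trajectory.positions_mm[t, 0],
                           "y": trajectory.positions_mm[t, 1],
                           "z": trajectory.positions_mm[t, 2],
                           "jx": jt[0], "jy": jt[1], "jz": jt[2]})
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)
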