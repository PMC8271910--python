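"""Lead-field-matrix construction for the 9-electrode 12-lead ECG configuration.

The lead field matrix L (M x 3N) maps the current density of three orthogonal
unit dipoles at each of N myocardial source points to the potentials at the M
body-surface electrodes, L . j = Phi.  Each column is obtained by one forward
solve: a 1-voxel dipole is placed at the source point along a base direction,
the electrode potential vector is read off, and the column is the potential
vector divided by the anode-point current density of that solve (so the
injected current magnitude cancels).  Columns are ordered in three blocks
[x | y | z], each of N columns.

Source points are chosen on the cardiac tissue at a regular spacing (6 mm by
default), keeping only voxels whose six face neighbors are all cardiac, so
that every dipole sits strictly inside the myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .conductor_model import VoxelModel, model_hash
from .spfd import DipoleSource, ForwardSolver, SolverConfig, electrode_potentials

__all__ = [
    "ElectrodeSet",
    "SourceGrid",
    "LeadFieldMatrix",
    "select_source_points",
    "point_responses",
    "build_lfm",
    "save_lfm",
    "load_lfm",
]

#: Role names of the standard 9-point 12-lead ECG observation set.
STANDARD_ROLES = ("V1", "V2", "V3", "V4", "V5", "V6", "RA", "LA", "LL")


@dataclass(frozen=True)
class ElectrodeSet:
    """Named electrode positions (mm) on the body surface."""

    names: tuple[str, ...]
    positions_mm: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_mm",
                           np.atleast_2d(np.asarray(self.positions_mm, float)))
        if len(self.names) != self.positions_mm.shape[0]:
            raise ValueError("one name per electrode position required")

    @property
    def M(self) -> int:
        return len(self.names)

    def node_indices(self, model: VoxelModel) -> np.ndarray:
        """Nearest grid-node index of each electrode on the given model."""
        rel = (self.positions_mm - model.origin_mm) / model.pitch_mm
        nodes = np.rint(rel).astype(int)
        dims = tuple(s + 1 for s in model.shape)
        if np.any(nodes < 0) or np.any(nodes >= dims):
            raise ValueError("electrode position outside the model grid")
        return nodes

    @classmethod
    def from_csv(cls, path) -> "ElectrodeSet":
        df = pd.read_csv(path)
        return cls(tuple(df["role"]), df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"role": self.names,
             "x_mm": self.positions_mm[:, 0],
             "y_mm": self.positions_mm[:, 1],
             "z_mm": self.positions_mm[:, 2]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SourceGrid:
    """Regularly spaced myocardial source points.

    ``voxel_indices`` are (N, 3) voxel indices; ``points_mm`` the voxel
    centers.  Scan order is ascending (z, y, x).
    """

    voxel_indices: np.ndarray
    points_mm: np.ndarray
    spacing_mm: float

    @property
    def N(self) -> int:
        return self.voxel_indices.shape[0]


@dataclass
class LeadFieldMatrix:
    """M x 3N lead field matrix with provenance."""

    L: np.ndarray
    grid: SourceGrid
    electrodes: ElectrodeSet
    model_hash: str
    solver_tol: float = 1e-6

    @property
    def N(self) -> int:
        return self.grid.N

    @property
    def M(self) -> int:
        return self.L.shape[0]

    def column(self, point: int, axis: int) -> np.ndarray:
        return self.L[:, axis * self.N + point]

    def support(self, point: int) -> np.ndarray:
        """The (M, 3) sub-dictionary [L_ix, L_iy, L_iz] for one source point."""
        return self.L[:, [point, self.N + point, 2 * self.N + point]]


def eligible_source_voxels(model: VoxelModel) -> np.ndarray:
    """Boolean mask of heart voxels whose six face neighbors are all heart."""
    heart = model.heart_mask
    ok = heart.copy()
    for ax in range(3):
        p = np.pad(heart, [(1, 1) if a == ax else (0, 0) for a in range(3)],
                   constant_values=False)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, heart.shape[ax])
        hi[ax] = slice(2, heart.shape[ax] + 2)
        ok &= p[tuple(lo)] & p[tuple(hi)]
    return ok


def select_source_points(model: VoxelModel, spacing_mm: float = 6.0) -> SourceGrid:
    """Select myocardial source points on a regular lattice.

    A voxel is eligible iff it and its six face neighbors carry the heart
    label.  Eligible voxels are subsampled on an axis-aligned lattice with the
    given spacing, anchored at the per-axis minimum of the eligible set; the
    result is sorted in ascending (z, y, x) order.
    """
    step = spacing_mm / model.pitch_mm
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            f"spacing {spacing_mm} mm is not a positive multiple of the "
            f"{model.pitch_mm} mm voxel pitch")
    step = int(round(step))
    ok = eligible_source_voxels(model)
    idx = np.argwhere(ok)
    if idx.size == 0:
        raise ValueError("no eligible source voxel (heart too thin for interior points)")
    anchor = idx.min(axis=0)
    on_lattice = np.all((idx - anchor) % step == 0, axis=1)
    pts = idx[on_lattice]
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))  # ascending z, y, x
    pts = pts[order]
    return SourceGrid(voxel_indices=pts,
                      points_mm=model.voxel_centers_mm(pts),
                      spacing_mm=spacing_mm)


def point_responses(solver: ForwardSolver, electrode_nodes: np.ndarray,
                    voxel: Sequence[int], current_A: float = 1.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Electrode responses of the three base-direction dipoles at one voxel.

    Returns ``(Phi, j_anode)`` where ``Phi[:, d]`` is the raw electrode
    potential vector of the unit-current dipole along axis d (cathode at the
    voxel's min-corner node, anode one step along +d) and ``j_anode[d]`` the
    corresponding anode-point current density (A/m^2).
    """
    Phi = np.empty((len(electrode_nodes), 3))
    j_an = np.empty(3)
    for d in range(3):
        src = DipoleSource.along(tuple(voxel), d, current_A=current_A)
        field = solver.solve_dipole(src)
        Phi[:, d] = electrode_potentials(field, electrode_nodes)
        j_an[d] = solver.anode_current_density(field, src)
    return Phi, j_an


def build_lfm(model: VoxelModel, electrodes: ElectrodeSet, grid: SourceGrid,
              solver_cfg: Optional[SolverConfig] = None,
              solver: Optional[ForwardSolver] = None,
              checkpoint: Optional[Path] = None,
              progress: bool = False) -> LeadFieldMatrix:
    """Build the lead field matrix by 3N forward solves.

    Columns are independent work units; any execution order yields identical
    output.  ``checkpoint`` (``.npz``) makes long builds resumable.
    """
    if solver is None:
        solver = ForwardSolver(model, solver_cfg or SolverConfig())
    enodes = electrodes.node_indices(model)
    N = grid.N
    L = np.full((electrodes.M, 3 * N), np.nan)
    start = 0
    if checkpoint is not None and Path(checkpoint).exists():
        saved = np.load(checkpoint)
        if saved["L"].shape == L.shape:
            L, start = saved["L"], int(saved["next_point"])
    for p in range(start, N):
        try:
            Phi, j_an = point_responses(solver, enodes, grid.voxel_indices[p])
        except Exception as exc:
            raise RuntimeError(f"forward solve failed at point {p} "
                               f"(voxel {tuple(grid.voxel_indices[p])})") from exc
        for d in range(3):
            L[:, d * N + p] = Phi[:, d] / j_an[d]
        if checkpoint is not None and (p + 1) % 25 == 0:
            np.savez(checkpoint, L=L, next_point=p + 1)
        if progress and (p + 1) % 10 == 0:
            print(f"  lead field: {p + 1}/{N} points")
    if np.isnan(L).any():
        raise RuntimeError("lead field matrix has unfilled columns")
    return LeadFieldMatrix(
        L=L, grid=grid, electrodes=electrodes, model_hash=model_hash(model),
        solver_tol=solver.config.tol,
    )


def save_lfm(lfm: LeadFieldMatrix, path) -> None:
    """Persist a lead field matrix (HDF5, lossless, with provenance)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("L", data=lfm.L)
        f.create_dataset("voxel_indices", data=lfm.grid.voxel_indices)
        f.create_dataset("points_mm", data=lfm.grid.points_mm)
        f.create_dataset("electrode_positions_mm", data=lfm.electrodes.positions_mm)
        f.attrs["electrode_names"] = list(lfm.electrodes.names)
        f.attrs["spacing_mm"] = lfm.grid.spacing_mm
        f.attrs["model_hash"] = lfm.model_hash
        f.attrs["solver_tol"] = lfm.solver_tol
        f.attrs["column_order"] = "x-block | y-block | z-block"


def load_lfm(path, expected_model: Optional[VoxelModel] = None,
             force: bool = False) -> LeadFieldMatrix:
    """Load a lead field matrix; refuses a model-hash mismatch unless forced."""
    with h5py.File(path, "r") as f:
        lfm = LeadFieldMatrix(
            L=f["L"][()],
            grid=SourceGrid(
                voxel_indices=f["voxel_indices"][()],
                points_mm=f["points_mm"][()],
                spacing_mm=float(f.attrs["spacing_mm"]),
            ),
            electrodes=ElectrodeSet(
                tuple(str(n) for n in f.attrs["electrode_names"]),
                f["electrode_positions_mm"][()],
            ),
            model_hash=str(f.attrs["model_hash"]),
            solver_tol=float(f.attrs["solver_tol"]),
        )
    if lfm.L.ndim != 2 or lfm.L.shape[1] != 3 * lfm.grid.N:
        raise ValueError("corrupt lead field file: dimension mismatch")
    if expected_model is not None and not force:
        h = model_hash(expected_model)
        if h != lfm.model_hash:
            raise ValueError(
                f"lead field was built against model {lfm.model_hash}, "
                f"got {h}; pass force=True to override")
    return lfm
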