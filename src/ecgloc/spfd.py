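"""Scalar-potential finite-difference (SPFD) forward solver.

Solves the quasi-static conduction problem

    div(sigma grad phi) = -div J   in the body,
    (sigma grad phi) . n = 0       on the body surface,

for a point current dipole, on the node grid of a voxel volume conductor.
Unknowns are scalar potentials at voxel-corner nodes; each grid edge carries a
conductance derived from the conductivities of the (up to four) voxels that
share it, and Kirchhoff's current law at every node yields a symmetric
7-point-stencil linear system.  A 1-voxel-long dipole is realized as a static
current injection of +I at the anode node and -I at the adjacent cathode node
(quasi-static DC limit: the cardiac source spectrum is of order 1 Hz, far
below any displacement-current regime).

The system is pure-Neumann, hence singular with a constant null space per
connected conducting component; solutions are gauge-fixed to zero mean over
conducting nodes.  The iterative solver is a conjugate-gradient iteration
preconditioned by a geometric multigrid V-cycle (Galerkin coarsening on the
node grid, red-black SOR smoothing on the finest level, damped Jacobi on
coarse levels), run until the relative residual ||b - A phi|| / ||b|| drops
below the tolerance (default 1e-6, six grid levels).  A plain red-black SOR
solver is provided as an independent slow path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .conductor_model import VoxelModel, assign_conductivity

__all__ = [
    "SolverConfig",
    "EdgeConductanceField",
    "DipoleSource",
    "LinearSystem",
    "PotentialField",
    "ConvergenceError",
    "edge_conductances",
    "conducting_node_mask",
    "assemble_system",
    "solve_spfd",
    "electrode_potentials",
    "MultigridSolver",
    "ForwardSolver",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


class ConvergenceError(RuntimeError):
    """Solver failed to reach the requested residual; carries the final value."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverConfig:
    """Iterative-solver settings.

    tol : target relative L2 residual (default 1e-6).
    levels : maximum multigrid depth (default 6; shallower on small grids).
    omega : SOR relaxation factor for the standalone SOR solver.
    method : "multigrid" (MG-preconditioned CG) or "sor" (plain red-black SOR).
    """

    tol: float = 1e-6
    max_iter: int = 500
    levels: int = 6
    omega: float = 1.5
    method: str = "multigrid"


@dataclass(frozen=True)
class EdgeConductanceField:
    """Edge conductances S (siemens) along each grid axis.

    ``Sx[i, j, k]`` is the conductance of the edge from node (i, j, k) to
    node (i+1, j, k); analogously for Sy, Sz.  S = mean(sigma of the voxels
    sharing the edge) * pitch (cross-section pitch^2 over length pitch);
    edges on the domain boundary average only the voxels that exist.
    """

    Sx: np.ndarray
    Sy: np.ndarray
    Sz: np.ndarray
    pitch_mm: float

    def along(self, axis: int) -> np.ndarray:
        return (self.Sx, self.Sy, self.Sz)[axis]


@dataclass(frozen=True)
class DipoleSource:
    """A 1-voxel-edge current dipole: +I at ``anode_node``, -I at ``cathode_node``.

    The two nodes must be grid-adjacent; the dipole moment points from
    cathode to anode.
    """

    cathode_node: tuple[int, int, int]
    anode_node: tuple[int, int, int]
    current_A: float = 1.0

    def __post_init__(self) -> None:
        d = np.subtract(self.anode_node, self.cathode_node)
        if sorted(np.abs(d)) != [0, 0, 1]:
            raise ValueError("anode and cathode must be grid-adjacent nodes")

    @property
    def axis(self) -> int:
        return int(np.nonzero(np.subtract(self.anode_node, self.cathode_node))[0][0])

    @classmethod
    def along(cls, node: tuple[int, int, int], axis: str | int,
              current_A: float = 1.0) -> "DipoleSource":
        """Dipole with cathode at ``node`` and anode one step along +axis."""
        ax = _AXIS[axis] if isinstance(axis, str) else axis
        anode = tuple(np.add(node, np.eye(3, dtype=int)[ax]))
        return cls(cathode_node=tuple(node), anode_node=anode, current_A=current_A)


@dataclass
class LinearSystem:
    """Reduced SPFD system A phi = b over conducting nodes only."""

    A: sp.csr_matrix
    b: Optional[np.ndarray]
    node_dims: tuple[int, int, int]
    pitch_mm: float
    cond_mask: np.ndarray           # (node_dims,) bool
    reduced_index: np.ndarray       # flat full-grid -> reduced index, -1 at air
    components: np.ndarray = field(default=None)  # per reduced node

    def __post_init__(self) -> None:
        if self.components is None:
            n_comp, comp = connected_components(self.A, directed=False)
            self.components = comp
            self.n_components = n_comp
        else:
            self.n_components = int(self.components.max()) + 1

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def reduced(self, node: tuple[int, int, int]) -> int:
        flat = int(np.ravel_multi_index(node, self.node_dims))
        r = int(self.reduced_index[flat])
        if r < 0:
            raise ValueError(f"node {node} lies in a non-conducting region")
        return r

    def rhs_for(self, sources: DipoleSource | Sequence[DipoleSource],
                weights: Optional[Sequence[float]] = None) -> np.ndarray:
        """Current-injection RHS for one dipole or a weighted superposition."""
        if isinstance(sources, DipoleSource):
            sources = [sources]
        if weights is None:
            weights = [1.0] * len(sources)
        b = np.zeros(self.n)
        for src, w in zip(sources, weights):
            ia, ic = self.reduced(src.anode_node), self.reduced(src.cathode_node)
            b[ia] += w * src.current_A
            b[ic] -= w * src.current_A
        return b


@dataclass
class PotentialField:
    """Node potentials (V), full-grid array with zeros at non-conducting nodes."""

    phi: np.ndarray
    cond_mask: np.ndarray
    residual: float
    iterations: int
    pitch_mm: float

    def at_node(self, node: tuple[int, int, int]) -> float:
        if not self.cond_mask[tuple(node)]:
            raise ValueError(f"node {tuple(node)} is non-conducting (air)")
        return float(self.phi[tuple(node)])


def edge_conductances(sigma_grid, pitch_mm: Optional[float] = None) -> EdgeConductanceField:
    """Edge conductances from a :class:`ConductivityGrid` or raw sigma array."""
    if hasattr(sigma_grid, "sigma"):
        sigma, pitch_mm = sigma_grid.sigma, sigma_grid.pitch_mm
    else:
        sigma = np.asarray(sigma_grid, float)
        if pitch_mm is None:
            raise ValueError("pitch_mm required with a raw sigma array")
    pitch_m = pitch_mm * 1e-3
    S = [_edge_mean_sigma(sigma, ax) * pitch_m for ax in range(3)]
    return EdgeConductanceField(Sx=S[0], Sy=S[1], Sz=S[2], pitch_mm=pitch_mm)


def _edge_mean_sigma(sigma: np.ndarray, axis: int) -> np.ndarray:
    """Mean sigma over the <=4 voxels sharing each edge along ``axis``."""
    t1, t2 = [a for a in range(3) if a != axis]
    pad = [(0, 0)] * 3
    pad[t1] = pad[t2] = (1, 1)
    p = np.pad(sigma.astype(float), pad, constant_values=np.nan)
    views = []
    for d1 in (0, 1):
        for d2 in (0, 1):
            sl = [slice(None)] * 3
            sl[t1] = slice(d1, d1 + sigma.shape[t1] + 1)
            sl[t2] = slice(d2, d2 + sigma.shape[t2] + 1)
            views.append(p[tuple(sl)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(views), axis=0)


def conducting_node_mask(sigma: np.ndarray) -> np.ndarray:
    """Nodes touching at least one voxel with sigma > 0."""
    c = np.pad(sigma > 0, 1, constant_values=False)
    dims = tuple(s + 1 for s in sigma.shape)
    out = np.zeros(dims, dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                out |= c[dx:dx + dims[0], dy:dy + dims[1], dz:dz + dims[2]]
    return out


def assemble_system(
    edges: EdgeConductanceField,
    source: DipoleSource | Sequence[DipoleSource] | None = None,
) -> LinearSystem:
    """Assemble the Kirchhoff node system on conducting nodes.

    Row n reads  (sum_k S_nk) phi_n - sum_k S_nk phi_k = b_n  over the <=6
    edges incident on node n; b is +I at the anode, -I at the cathode.  Rows
    for nodes entirely surrounded by air are eliminated.  A is symmetric with
    zero row sums (pure Neumann).
    """
    # node dims from Sx, which is node-shaped except along x (one shorter)
    dims = (edges.Sx.shape[0] + 1, edges.Sx.shape[1], edges.Sx.shape[2])

    cond = np.zeros(dims, dtype=bool)
    rows, cols, data = [], [], []
    for ax in range(3):
        S = edges.along(ax)
        i, j, k = np.nonzero(S > 0)
        s = S[i, j, k]
        step = np.eye(3, dtype=int)[ax]
        n0 = np.ravel_multi_index((i, j, k), dims)
        n1 = np.ravel_multi_index((i + step[0], j + step[1], k + step[2]), dims)
        rows += [n0, n1, n0, n1]
        cols += [n1, n0, n0, n1]
        data += [-s, -s, s, s]
        cond.ravel()[n0] = True
        cond.ravel()[n1] = True
    if not data:
        raise ValueError("model contains no conducting voxels")
    A_full = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(int(np.prod(dims)),) * 2,
    ).tocsr()

    cond_flat = cond.ravel()
    reduced_index = np.full(cond_flat.size, -1, dtype=np.int64)
    reduced_index[cond_flat] = np.arange(int(cond_flat.sum()))
    keep = np.nonzero(cond_flat)[0]
    A = A_full[keep][:, keep].tocsr()
    A.sum_duplicates()

    system = LinearSystem(
        A=A, b=None, node_dims=dims, pitch_mm=edges.pitch_mm,
        cond_mask=cond, reduced_index=reduced_index,
    )
    if source is not None:
        b = system.rhs_for(source)
        diag = A.diagonal()
        nz = np.nonzero(b)[0]
        if np.any(diag[nz] <= 0):
            raise ValueError("source in non-conducting region")
        system.b = b
    return system


# ---------------------------------------------------------------------------
# Multigrid-preconditioned solver
# ---------------------------------------------------------------------------

def _interp_1d(n_fine: int) -> sp.csr_matrix:
    """1-D linear interpolation from coarse nodes (every other fine node)."""
    n_coarse = (n_fine + 1) // 2
    rows, cols, vals = [], [], []
    for f in range(n_fine):
        if f % 2 == 0:
            rows.append(f); cols.append(f // 2); vals.append(1.0)
        else:
            lo, hi = (f - 1) // 2, (f + 1) // 2
            if hi < n_coarse:
                rows += [f, f]; cols += [lo, hi]; vals += [0.5, 0.5]
            else:
                rows.append(f); cols.append(lo); vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))


@dataclass
class _Level:
    A: sp.csr_matrix
    diag: np.ndarray
    P: Optional[sp.csr_matrix]          # prolongation to this level's fine parent
    # red-black structure (finest level only)
    red: Optional[np.ndarray] = None
    black: Optional[np.ndarray] = None
    A_rb: Optional[sp.csr_matrix] = None
    A_br: Optional[sp.csr_matrix] = None


class MultigridSolver:
    """Geometric-multigrid-preconditioned CG for the singular SPFD system.

    The hierarchy is built once per model and reused across right-hand sides,
    which is what makes repeated forward solves (lead-field construction,
    dipole studies) cheap.
    """

    def __init__(self, system: LinearSystem, levels: int = 6,
                 omega: float = 1.5, coarse_limit: int = 300):
        self.system = system
        self.omega = omega
        self._levels: list[_Level] = []

        A = system.A
        dims = system.node_dims
        mask_flat = system.cond_mask.ravel().copy()

        # red-black coloring of the finest level (7-point stencil: neighbors
        # always have opposite (i+j+k) parity, so each color decouples)
        ii, jj, kk = np.unravel_index(np.nonzero(mask_flat)[0], dims)
        parity = (ii + jj + kk) % 2
        red = np.nonzero(parity == 0)[0]
        black = np.nonzero(parity == 1)[0]
        lv0 = _Level(A=A, diag=A.diagonal().copy(), P=None, red=red, black=black,
                     A_rb=A[red][:, black].tocsr(), A_br=A[black][:, red].tocsr())
        np.maximum(lv0.diag, 1e-300, out=lv0.diag)
        self._levels.append(lv0)

        for _ in range(levels - 1):
            if A.shape[0] <= coarse_limit or min(dims) <= 3:
                break
            P1 = [_interp_1d(d) for d in dims]
            P_full = sp.kron(P1[0], sp.kron(P1[1], P1[2])).tocsr()
            P_fine = P_full[np.nonzero(mask_flat)[0]]
            col_nnz = np.diff(P_fine.tocsc().indptr)
            keep = np.nonzero(col_nnz > 0)[0]
            P = P_fine[:, keep].tocsr()
            Ac = (P.T @ A @ P).tocsr()
            Ac.sum_duplicates()
            diag = Ac.diagonal().copy()
            np.maximum(diag, 1e-300, out=diag)
            self._levels.append(_Level(A=Ac, diag=diag, P=P))
            A = Ac
            cdims = tuple((d + 1) // 2 for d in dims)
            m = np.zeros(int(np.prod(cdims)), dtype=bool)
            m[keep] = True
            mask_flat, dims = m, cdims

        # dense (pseudo-)inverse at the coarsest level; pinv handles the
        # constant null space of the pure-Neumann operator
        self._coarse_pinv = np.linalg.pinv(
            self._levels[-1].A.toarray(), rcond=1e-12
        )

        comp = system.components
        self._comp = comp
        self._comp_counts = np.bincount(comp).astype(float)

    # -- smoothers -----------------------------------------------------------

    def _rb_half(self, lv: _Level, x, b, idx, other, A_io, omega):
        x[idx] = (1.0 - omega) * x[idx] + omega * (b[idx] - A_io @ x[other]) / lv.diag[idx]

    def _smooth_finest(self, x, b, omega, order):
        lv = self._levels[0]
        if order == "rb":
            self._rb_half(lv, x, b, lv.red, lv.black, lv.A_rb, omega)
            self._rb_half(lv, x, b, lv.black, lv.red, lv.A_br, omega)
        else:
            self._rb_half(lv, x, b, lv.black, lv.red, lv.A_br, omega)
            self._rb_half(lv, x, b, lv.red, lv.black, lv.A_rb, omega)

    def _smooth_jacobi(self, lv: _Level, x, b, sweeps=2, damp=0.8):
        for _ in range(sweeps):
            x += damp * (b - lv.A @ x) / lv.diag

    # -- V-cycle -------------------------------------------------------------

    def _vcycle(self, i: int, b: np.ndarray) -> np.ndarray:
        if i == len(self._levels) - 1:
            return self._coarse_pinv @ b
        lv = self._levels[i]
        x = np.zeros_like(b)
        if i == 0:
            self._smooth_finest(x, b, 1.0, "rb")
        else:
            self._smooth_jacobi(lv, x, b)
        r = b - lv.A @ x
        P = self._levels[i + 1].P
        x += P @ self._vcycle(i + 1, P.T @ r)
        if i == 0:
            self._smooth_finest(x, b, 1.0, "br")
        else:
            self._smooth_jacobi(lv, x, b)
        return x

    def _project(self, x: np.ndarray) -> np.ndarray:
        """Remove the per-component constant (null-space) content."""
        means = np.bincount(self._comp, weights=x) / self._comp_counts
        return x - means[self._comp]

    # -- outer iterations ----------------------------------------------------

    def solve(self, b: np.ndarray, tol: float = 1e-6, max_iter: int = 500,
              x0: Optional[np.ndarray] = None) -> tuple[np.ndarray, float, int]:
        """MG-preconditioned CG; returns (phi, relative residual, iterations)."""
        A = self.system.A
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            return np.zeros_like(b), 0.0, 0
        sums = np.bincount(self._comp, weights=b, minlength=self._comp_counts.size)
        if np.any(np.abs(sums) > 1e-9 * bnorm):
            warnings.warn(
                "RHS is not balanced within each conducting component "
                "(source and sink in disconnected regions?)"
            )
        x = self._project(x0.copy()) if x0 is not None else np.zeros_like(b)
        r = b - A @ x
        p = np.zeros_like(b)
        rz_old = 0.0
        res = float(np.linalg.norm(r)) / bnorm
        it = 0
        while res >= tol:
            if it >= max_iter:
                raise ConvergenceError(
                    f"no convergence in {max_iter} iterations "
                    f"(relative residual {res:.3e})", res)
            z = self._project(self._vcycle(0, r))
            rz = float(r @ z)
            p = z if it == 0 else z + (rz / rz_old) * p
            q = A @ p
            alpha = rz / float(p @ q)
            x += alpha * p
            r -= alpha * q
            rz_old = rz
            it += 1
            res = float(np.linalg.norm(r)) / bnorm
        return self._project(x), res, it

    def solve_sor(self, b: np.ndarray, tol: float = 1e-6, max_iter: int = 50000,
                  omega: Optional[float] = None) -> tuple[np.ndarray, float, int]:
        """Plain red-black SOR (no multigrid); the independent slow path."""
        omega = self.omega if omega is None else omega
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            return np.zeros_like(b), 0.0, 0
        x = np.zeros_like(b)
        res = np.inf
        for it in range(1, max_iter + 1):
            self._smooth_finest(x, b, omega, "rb")
            if it % 10 == 0:
                res = float(np.linalg.norm(b - self.system.A @ x)) / bnorm
                if res < tol:
                    return self._project(x), res, it
        res = float(np.linalg.norm(b - self.system.A @ x)) / bnorm
        if res < tol:
            return self._project(x), res, max_iter
        raise ConvergenceError(
            f"SOR did not converge in {max_iter} sweeps (residual {res:.3e})", res)


def _field_from_reduced(system: LinearSystem, x: np.ndarray,
                        res: float, it: int) -> PotentialField:
    phi = np.zeros(int(np.prod(system.node_dims)))
    phi[system.cond_mask.ravel()] = x
    return PotentialField(
        phi=phi.reshape(system.node_dims), cond_mask=system.cond_mask,
        residual=res, iterations=it, pitch_mm=system.pitch_mm,
    )


def solve_spfd(system: LinearSystem, tol: float = 1e-6, max_iter: int = 500,
               levels: int = 6, omega: float = 1.5,
               method: str = "multigrid") -> PotentialField:
    """One-shot solve of an assembled system (builds the hierarchy afresh).

    For repeated solves against the same conductor use :class:`ForwardSolver`,
    which caches the multigrid hierarchy.
    """
    if system.b is None:
        raise ValueError("system has no right-hand side (no source assigned)")
    mg = MultigridSolver(system, levels=levels, omega=omega)
    if method == "multigrid":
        x, res, it = mg.solve(system.b, tol=tol, max_iter=max_iter)
    elif method == "sor":
        x, res, it = mg.solve_sor(system.b, tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _field_from_reduced(system, x, res, it)


def electrode_potentials(field: PotentialField, electrode_nodes) -> np.ndarray:
    """Potentials (V) at the M electrode nodes of a solved field."""
    return np.array([field.at_node(tuple(n)) for n in np.asarray(electrode_nodes, int)])


class ForwardSolver:
    """Cached forward-problem context for one volume conductor.

    Builds conductivities, edge conductances, the reduced linear system and
    the multigrid hierarchy once; then solves arbitrarily many dipole or raw
    right-hand sides against it.
    """

    def __init__(self, model: VoxelModel, config: SolverConfig = SolverConfig()):
        self.model = model
        self.config = config
        self.sigma = assign_conductivity(model)
        self.edges = edge_conductances(self.sigma)
        self.system = assemble_system(self.edges)
        self.mg = MultigridSolver(self.system, levels=config.levels,
                                  omega=config.omega)

    def solve_rhs(self, b: np.ndarray) -> PotentialField:
        cfg = self.config
        if cfg.method == "sor":
            x, res, it = self.mg.solve_sor(b, tol=cfg.tol, max_iter=cfg.max_iter)
        else:
            x, res, it = self.mg.solve(b, tol=cfg.tol, max_iter=cfg.max_iter)
        return _field_from_reduced(self.system, x, res, it)

    def solve_dipole(self, source: DipoleSource | Sequence[DipoleSource],
                     weights=None) -> PotentialField:
        b = self.system.rhs_for(source, weights)
        diag = self.system.A.diagonal()
        if np.any(diag[np.nonzero(b)[0]] <= 0):
            raise ValueError("source in non-conducting region")
        return self.solve_rhs(b)

    def anode_current_density(self, field: PotentialField,
                              source: DipoleSource) -> float:
        """Branch current through the source edge divided by the voxel
        cross-section (A/m^2): the normalization of lead-field columns."""
        ax = source.axis
        lo = np.minimum(source.cathode_node, source.anode_node)
        S = self.edges.along(ax)[tuple(lo)]
        dphi = field.at_node(source.anode_node) - field.at_node(source.cathode_node)
        pitch_m = self.system.pitch_mm * 1e-3
        return float(S * dphi / pitch_m**2)
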