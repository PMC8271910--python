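"""Kalman-filter correction of time-series source-location estimates.

The activation source is modeled as moving at the constant ventricular
conduction velocity (1.9 m/s) along the direction of the estimated current
density:

    x(t)     = x(t-1) + dt * u(t) + W,      u(t) = v * j_hat(t) / ||j_hat(t)||
    r_hat(t) = x(t) + V,

with zero-mean Gaussian process noise W (variance Q) and observation noise V
(variance R).  The filter is scalar per axis (diagonal covariances), applied
as the recursion

    predict:  x-(t) = x-(t-1) + dt * u(t),   P-(t) = P(t-1) + dt^2 * Q
    update:   K(t)  = P-(t) / (P-(t) + R)
              P(t)  = (1 - K(t)) P-(t)
              x(t)  = x-(t) + K(t) (r_hat(t) - x-(t)),

initialized at the AV-node location with P(0) = Q.  Q is estimated as the
variance of the localization error over a test-dipole study; R as the
variance of location estimates across random sub-dictionaries of the lead
field (one documented reading of an ambiguous protocol; both are directly
settable).

State is in mm, velocity in m/s, dt in s; unit conversion happens only in
:func:`direction_input`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "V_VENTRICULAR_MPS",
    "TrackConfig",
    "TrackState",
    "direction_input",
    "kalman_step",
    "track",
    "estimate_Q",
    "estimate_R",
    "steady_state_gain",
]

#: Ventricular conduction velocity, m/s.
V_VENTRICULAR_MPS = 1.9


@dataclass(frozen=True)
class TrackConfig:
    """Tracking parameters.

    v_mps : conduction speed driving the prediction step (m/s).
    dt_s : sampling interval of the estimate series (s).
    q_mm2, r_mm2 : per-axis process / observation noise variances (mm^2);
        scalars broadcast to all three axes.
    x0_mm : initial state (anatomically, the AV-node location).
    """

    x0_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v_mps: float = V_VENTRICULAR_MPS
    dt_s: float = 1e-3
    q_mm2: np.ndarray | float = 1.0
    r_mm2: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0_mm", np.asarray(self.x0_mm, float))
        for name in ("q_mm2", "r_mm2"):
            v = np.broadcast_to(np.asarray(getattr(self, name), float), (3,)).copy()
            if np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")
            object.__setattr__(self, name, v)
        if self.v_mps <= 0 or self.dt_s <= 0:
            raise ValueError("v_mps and dt_s must be > 0")


@dataclass
class TrackState:
    """Per-axis Kalman state: position x (mm), variance P (mm^2), step index."""

    x_mm: np.ndarray
    P_mm2: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, float).copy()
        self.P_mm2 = np.broadcast_to(np.asarray(self.P_mm2, float), (3,)).copy()
        if np.any(self.P_mm2 < 0):
            raise ValueError("P must be >= 0")


def direction_input(j_hat, v_mps: float = V_VENTRICULAR_MPS,
                    dt_s: float = 1e-3) -> np.ndarray:
    """Predicted displacement over one step, mm: unit(j_hat) * v * dt."""
    j = np.asarray(j_hat, float)
    n = np.linalg.norm(j)
    if n == 0.0:
        raise ValueError("direction input undefined for zero current density")
    return j / n * v_mps * dt_s * 1e3


def kalman_step(state: TrackState, u_disp_mm, observation_mm,
                q_mm2, r_mm2, dt_s: float = 1e-3) -> tuple[TrackState, np.ndarray]:
    """One predict/update step of the per-axis recursion.

    Returns the new state and the per-axis gain K (each in [0, 1]).
    """
    q = np.broadcast_to(np.asarray(q_mm2, float), (3,))
    r = np.broadcast_to(np.asarray(r_mm2, float), (3,))
    x_pred = state.x_mm + np.asarray(u_disp_mm, float)
    P_pred = state.P_mm2 + dt_s**2 * q
    denom = P_pred + r
    if np.any(denom == 0.0):
        raise ZeroDivisionError(
            "Kalman gain indeterminate: P- + R = 0 on some axis "
            "(Q and R both zero with vanished covariance)")
    K = P_pred / denom
    P = (1.0 - K) * P_pred
    x = x_pred + K * (np.asarray(observation_mm, float) - x_pred)
    return TrackState(x_mm=x, P_mm2=P, t=state.t + 1), K


def track(r_hat_mm: np.ndarray, j_hat: np.ndarray,
          config: TrackConfig) -> pd.DataFrame:
    """Filter a series of OMP estimates into a corrected trajectory.

    Parameters
    ----------
    r_hat_mm : (T, 3) observed locations per time step.
    j_hat : (T, 3) estimated current-density vectors (direction input).

    Returns a per-step table with the corrected location, gains and variances.
    """
    r_hat_mm = np.atleast_2d(np.asarray(r_hat_mm, float))
    j_hat = np.atleast_2d(np.asarray(j_hat, float))
    if len(r_hat_mm) != len(j_hat) or len(r_hat_mm) == 0:
        raise ValueError("r_hat and j_hat must be equal-length, nonempty series")
    state = TrackState(x_mm=config.x0_mm, P_mm2=config.q_mm2)
    rows = []
    for t in range(len(r_hat_mm)):
        u = direction_input(j_hat[t], config.v_mps, config.dt_s)
        try:
            state, K = kalman_step(state, u, r_hat_mm[t],
                                   config.q_mm2, config.r_mm2, config.dt_s)
        except Exception as exc:
            raise RuntimeError(f"Kalman step failed at t={t}") from exc
        rows.append({
            "t": t + 1,
            "x_mm": state.x_mm[0], "y_mm": state.x_mm[1], "z_mm": state.x_mm[2],
            "Kx": K[0], "Ky": K[1], "Kz": K[2],
            "Px": state.P_mm2[0], "Py": state.P_mm2[1], "Pz": state.P_mm2[2],
        })
    return pd.DataFrame(rows)


def estimate_Q(study_table: pd.DataFrame, per_axis: bool = True) -> np.ndarray:
    """Process-noise variance from a test-dipole study (default 100 dipoles).

    Per-axis: sample variance of the signed localization-error components
    (ex, ey, ez).  Pooled: the scalar variance of LE, broadcast to all axes.
    """
    if len(study_table) < 2:
        raise ValueError("need at least 2 study trials to estimate a variance")
    if per_axis:
        return study_table[["ex", "ey", "ez"]].var(ddof=1).to_numpy()
    return np.full(3, float(study_table["LE_mm"].var(ddof=1)))


def estimate_R(lfm, n_subsets: int = 10, subset_size: int = 500,
               rng: Optional[np.random.Generator] = None,
               probe_points: Optional[Sequence[int]] = None,
               n_probes: int = 10) -> np.ndarray:
    """Observation-noise variance from lead-field sub-dictionary resampling.

    Draws ``n_subsets`` random sub-dictionaries of ``subset_size`` source
    points, localizes a fixed probe set (noise-free fields of sources at
    known grid points) against each, and returns the per-axis variance of the
    resulting location estimates across sub-dictionaries, averaged over
    probes.  Defaults follow the 10-subsets-of-500-points protocol.
    """
    from .leadfield import LeadFieldMatrix, SourceGrid
    from .localization import omp_localize

    if rng is None:
        rng = np.random.default_rng()
    N = lfm.N
    if subset_size > N:
        raise ValueError(f"subset_size {subset_size} exceeds the {N} grid points")
    if probe_points is None:
        probe_points = rng.choice(N, size=min(n_probes, N), replace=False)
    probe_dirs = rng.standard_normal((len(probe_points), 3))
    probe_dirs /= np.linalg.norm(probe_dirs, axis=1, keepdims=True)
    probes = [lfm.support(int(p)) @ d for p, d in zip(probe_points, probe_dirs)]

    est = np.empty((n_subsets, len(probes), 3))
    for s in range(n_subsets):
        pts = np.sort(rng.choice(N, size=subset_size, replace=False))
        cols = np.concatenate([pts, N + pts, 2 * N + pts])
        sub = LeadFieldMatrix(
            L=lfm.L[:, cols],
            grid=SourceGrid(voxel_indices=lfm.grid.voxel_indices[pts],
                            points_mm=lfm.grid.points_mm[pts],
                            spacing_mm=lfm.grid.spacing_mm),
            electrodes=lfm.electrodes, model_hash=lfm.model_hash,
            solver_tol=lfm.solver_tol)
        for k, phi in enumerate(probes):
            est[s, k] = omp_localize(sub, phi).location_mm
    return est.var(axis=0, ddof=1).mean(axis=0)


def steady_state_gain(q_mm2: float, r_mm2: float, dt_s: float = 1e-3) -> float:
    """Fixed-point gain of the scalar recursion (algebraic Riccati solution).

    With qe = dt^2 q the per-step prediction-variance inflation, the
    stationary predicted variance solves P- = (1-K)P- + qe with
    K = P-/(P- + r), giving P- = (qe + sqrt(qe^2 + 4 qe r)) / 2.
    """
    qe = dt_s**2 * q_mm2
    if qe == 0.0 and r_mm2 == 0.0:
        raise ValueError("gain undefined with Q = R = 0")
    P_pred = 0.5 * (qe + np.sqrt(qe**2 + 4.0 * qe * r_mm2))
    return float(P_pred / (P_pred + r_mm2)) if P_pred + r_mm2 > 0 else 0.0
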