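"""Two-layer stochastic Generalized Lotka–Volterra dynamics.

The elementary layer carries competitive rate dynamics

    τ_x dx_i = x_i (Σ_k P_ki s_k + b_x − Σ_i' V_i'i x_i' − Σ_j R_ji y_j) dt
               + σ_x dW,

the chunking layer grows with a synaptic drive variable z,

    τ_y dy_j = y_j (z_j + b_y) dt + σ_y dW,
    τ_z dz_j = (−z_j + Σ_i Q_ij x_i − Σ_j' W_j'j y_j' + b_z(t)) dt,

integrated with Euler–Maruyama (additive noise, multiplicative drift).
Activities are clipped at a configurable nonnegative floor after every step:
additive noise can push a mode slightly negative, which lies outside the
Lotka–Volterra domain.  ``τ_z = 0`` removes the synaptic dynamics (z is
slaved to its instantaneous drive).

A single-layer reduction (one competition matrix, no chunking feedback) is
provided for analysis and as the unit-test oracle for winner-take-all and
heteroclinic-cycle behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .metrics import extract_sequence
from .plasticity import (
    PlasticityParams,
    TraceState,
    WeightSet,
    update_competition,
    update_P,
    update_Q,
    update_R,
    update_traces,
)

__all__ = ["ModelParams", "NetworkState", "Trajectory", "step", "run",
           "run_single_layer"]


@dataclass
class ModelParams:
    """Network constants of the two-layer system.

    Time constants are in model time units; ``tau_z`` may be 0 (synaptic
    dynamics removed).  ``v_diag`` / ``w_diag`` are the fixed self-inhibition
    strengths excluded from learning; an active mode alone rests at
    ``b_x / v_diag``.
    """

    N_X: int = 30
    N_Y: int = 30
    M: int = 144
    tau_x: float = 1.0
    tau_y: float = 1.0
    tau_z: float = 1.5
    b_x: float = 2.0
    b_y: float = 0.1
    b_z: float = 0.0
    b_z_fn: object = None  # optional callable t -> bias, overrides b_z
    sigma_x: float = 0.005
    sigma_y: float = 0.01
    dt: float = 0.02
    floor: float = 0.0
    v_diag: float = 1.0
    w_diag: float = 0.8

    def __post_init__(self):
        for name in ("tau_x", "tau_y", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_z < 0:
            raise ValueError("tau_z must be >= 0 (0 removes the synaptic dynamics)")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.N_Y <= 3 or self.N_X <= 3:
            warnings.warn(
                "a stable heteroclinic cycle needs more than three units per "
                f"layer (N_X={self.N_X}, N_Y={self.N_Y}); a 3-unit chunking "
                "layer is only adequate for closed-loop demonstrations",
                stacklevel=2,
            )
        if 0 < self.tau_z <= self.tau_x:
            warnings.warn(
                "tau_z <= tau_x breaks the hierarchy of time scales; the "
                "chunking layer will not integrate over items", stacklevel=2
            )

    def bz_at(self, t: float) -> float:
        return float(self.b_z_fn(t)) if self.b_z_fn is not None else self.b_z


@dataclass
class NetworkState:
    """Instantaneous activities, synaptic variables and plasticity traces."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t: float = 0.0
    traces: TraceState = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.traces is None:
            self.traces = TraceState.zeros(len(self.x), len(self.y))
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("activities must be nonnegative")

    @classmethod
    def zeros(cls, params: ModelParams) -> "NetworkState":
        return cls(np.zeros(params.N_X), np.zeros(params.N_Y), np.zeros(params.N_Y))

    @classmethod
    def small_random(cls, params: ModelParams, rng, scale: float = 0.02) -> "NetworkState":
        return cls(
            scale * rng.random(params.N_X),
            scale * rng.random(params.N_Y),
            np.zeros(params.N_Y),
        )

    def copy(self) -> "NetworkState":
        return NetworkState(self.x.copy(), self.y.copy(), self.z.copy(),
                            self.t, self.traces.copy())


@dataclass
class Trajectory:
    """Sampled states on a strictly increasing time grid."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray = None
    z: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def events(self, layer: str = "x", active_threshold: float = 0.9,
               min_dwell: int = 3):
        """Mode on/offset log: the dominant-mode symbol sequence."""
        arr = self.x if layer == "x" else self.y
        return extract_sequence(self.t, arr, active_threshold, min_dwell)

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("t", "x", "y", "z"):
                arr = getattr(self, name)
                if arr is not None:
                    fh.create_dataset(name, data=arr)

    def to_csv(self, path, stride: int = 1):
        import pandas as pd

        cols = {"t": self.t[::stride]}
        for name in ("x", "y", "z"):
            arr = getattr(self, name)
            if arr is not None:
                for k in range(arr.shape[1]):
                    cols[f"{name}{k}"] = arr[::stride, k]
        pd.DataFrame(cols).to_csv(path, index=False)


def _check_dims(state, weights, params, s):
    if len(state.x) != params.N_X or len(state.y) != params.N_Y:
        raise ValueError("state dimensions inconsistent with params")
    if weights.P.shape != (params.M, params.N_X):
        raise ValueError("weight dimensions inconsistent with params")
    if s is not None and len(s) != params.M:
        raise ValueError(f"input vector must have length M={params.M}")


def step(
    state: NetworkState,
    weights: WeightSet,
    params: ModelParams,
    plast: PlasticityParams,
    s: np.ndarray = None,
    rng=None,
) -> NetworkState:
    """One Euler–Maruyama step (reference numpy implementation).

    Advances x, y, z; applies the plasticity rules enabled in ``plast`` using
    the pre-step state; updates the learning-window traces; clips activities
    at the floor.  ``s = None`` means zero input.  Weights are modified in
    place when learning is enabled.
    """
    _check_dims(state, weights, params, s)
    if not (np.all(np.isfinite(state.x)) and np.all(np.isfinite(state.y))
            and np.all(np.isfinite(state.z))):
        raise FloatingPointError(
            f"non-finite state at t={state.t}: "
            f"x={state.x}, y={state.y}, z={state.z}"
        )
    dt = params.dt
    x, y, z = state.x, state.y, state.z
    sv = np.zeros(params.M) if s is None else np.asarray(s, dtype=float)

    inp = weights.P.T @ sv
    drift_x = x * (inp + params.b_x - weights.V.T @ x - weights.R.T @ y)
    drift_y = y * (z + params.b_y)
    if rng is not None and (params.sigma_x > 0 or params.sigma_y > 0):
        noise_x = params.sigma_x * np.sqrt(dt) * rng.standard_normal(params.N_X)
        noise_y = params.sigma_y * np.sqrt(dt) * rng.standard_normal(params.N_Y)
    else:
        noise_x = noise_y = 0.0
    new_x = np.maximum(x + (dt * drift_x + noise_x) / params.tau_x, params.floor)
    new_y = np.maximum(y + (dt * drift_y + noise_y) / params.tau_y, params.floor)

    drive = weights.Q.T @ x - weights.W.T @ y + params.bz_at(state.t)
    if params.tau_z > 0:
        new_z = z + (dt / params.tau_z) * (-z + drive)
    else:
        new_z = drive

    # plasticity reads the pre-step state
    if plast.learn_P and s is not None:
        weights.P = update_P(weights.P, x, sv, dt, plast.tau_P)
    if plast.learn_V:
        weights.V = update_competition(weights.V, state.traces, x, dt, plast, "x")
    if plast.learn_W:
        weights.W = update_competition(weights.W, state.traces, y, dt, plast, "y")
    if plast.learn_Q:
        weights.Q = update_Q(weights.Q, x, y, dt, plast)
    if plast.learn_R:
        weights.R = update_R(weights.R, x, y, dt, plast)
    traces = update_traces(state.traces, x, y, dt, plast)

    return NetworkState(new_x, new_y, new_z, state.t + dt, traces)


def run(
    state: NetworkState,
    weights: WeightSet,
    params: ModelParams,
    plast: PlasticityParams,
    schedule=None,
    T: float = None,
    record_stride: int = 5,
    seed: int = 0,
) -> Trajectory:
    """Integrate for duration ``T`` (jitted loop), mutating state and weights.

    ``schedule`` is a :class:`~heterochunk.stimulus.StimulusSequence` or
    ``None`` for a free run (recall: the layers are driven only by the growth
    terms b_x and b_y).  ``T`` defaults to the schedule duration.  Returns the
    sampled trajectory.
    """
    if schedule is not None:
        if T is None:
            T = schedule.total_duration
        items = np.ascontiguousarray(schedule.items)
        item_steps = max(int(round(schedule.item_duration / params.dt)), 1)
    else:
        if T is None or T <= 0:
            raise ValueError("a free run needs T > 0")
        items = np.zeros((0, params.M))
        item_steps = 1
    _check_dims(state, weights, params, None)
    n_steps = int(round(T / params.dt))
    bz = np.empty(n_steps)
    if params.b_z_fn is None:
        bz.fill(params.b_z)
    else:
        bz[:] = [params.b_z_fn(state.t + k * params.dt) for k in range(n_steps)]
    n_rec = (n_steps + record_stride - 1) // record_stride
    out_x = np.empty((n_rec, params.N_X))
    out_y = np.empty((n_rec, params.N_Y))
    out_z = np.empty((n_rec, params.N_Y))
    pv = _kernels.pack_params(params, plast)
    flags = _kernels.pack_flags(plast)
    status = _kernels.simulate(
        state.x, state.y, state.z, state.traces.a_x, state.traces.a_y,
        weights.P, weights.V, weights.W, weights.Q, weights.R,
        items, item_steps, bz, n_steps,
        pv, flags, int(seed) & 0x7FFFFFFF,
        record_stride, out_x, out_y, out_z,
    )
    t0 = state.t
    state.t += n_steps * params.dt
    if status != 0:
        raise FloatingPointError(
            f"non-finite state near t={t0 + status * params.dt:.3f} "
            f"(step {status - 1}); x={state.x}, y={state.y}"
        )
    t_grid = t0 + (np.arange(n_rec) * record_stride + 1) * params.dt
    return Trajectory(t_grid, out_x, out_y, out_z)


def run_single_layer(x0, V, s=None, b: float = 0.0, sigma: float = 0.0,
                     T: float = 100.0, dt: float = 0.01, seed: int = 0,
                     record_stride: int = 5) -> Trajectory:
    """Single-layer GLV: ``dx_i = x_i (s_i + b − Σ V_i'i x_i') dt + σ dW``.

    The canonical substrate for a stable heteroclinic channel; with symmetric
    strong couplings it behaves as winner-take-all.  Used as the reduced
    oracle for unit tests.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    x = np.array(x0, dtype=float)
    n = len(x)
    sv = np.zeros(n) if s is None else np.asarray(s, dtype=float)
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    rec_t, rec_x = [], []
    for k in range(n_steps):
        drift = x * (sv + b - V.T @ x)
        if sigma > 0:
            x = x + dt * drift + sigma * np.sqrt(dt) * rng.standard_normal(n)
        else:
            x = x + dt * drift
        x = np.maximum(x, 0.0)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at step {k}")
        if k % record_stride == 0:
            rec_t.append((k + 1) * dt)
            rec_x.append(x.copy())
    return Trajectory(np.array(rec_t), np.array(rec_x))
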