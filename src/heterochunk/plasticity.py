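"""The five coupled synaptic-plasticity rules and their activity traces.

* ``P`` (perceptual → elementary): correlation rule with synaptic scaling —
  competitive learning that associates one elementary mode with each input
  pattern.  With inputs normalized to sum C, each column of P converges to
  the pattern its mode responds to, so column sums tend to C.
* ``V`` / ``W`` (within-layer inhibition): bistable asymmetric Hebb rule.  A
  cubic drift gives every off-diagonal weight two stable resting values
  (low/high) separated by an unstable one; thresholded products of current
  activity with exponentially filtered traces detect transitions between
  modes and push the weight along the transition direction to the low state
  (depression) and the reverse weight to the high state (potentiation).  The
  growing asymmetry converts winner-take-all into winnerless competition.
* ``Q`` (elementary → chunking excitation): bistable rule with soft bounds;
  potentiates on EM/CM co-activity, depotentiates whenever the CM is active
  alone, and carries a heterosynaptic penalty capping each EM's total
  outgoing weight.
* ``R`` (chunking → elementary inhibition): same structure with swapped
  bounds — co-activity disinhibits (toward the low state), lone CM activity
  potentiates the inhibition.

All rules are continuous-time ODEs integrated online with the network
dynamics; during recall the weights are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlasticityParams",
    "WeightSet",
    "TraceState",
    "update_P",
    "update_traces",
    "update_competition",
    "update_Q",
    "update_Q_reduced",
    "update_R",
    "freeze",
    "thaw",
    "cubic_drift",
]


def _check_triple(name, lo, mid, hi):
    if not (0 <= lo < mid < hi):
        raise ValueError(
            f"{name} bistable triple must satisfy 0 <= low < unstable < high, "
            f"got ({lo}, {mid}, {hi})"
        )


@dataclass
class PlasticityParams:
    """All constants of the learning model.

    Times are in model time units.  Each learned matrix has a bistable triple
    ``(low, unstable, high)``: low and high are the stable resting weights,
    the middle value is the basin boundary.  See ``docs/methods.md`` for the
    rationale behind the defaults (the printed source of the model gives the
    orderings, not the magnitudes).
    """

    # P: competitive associative rule
    tau_P: float = 40.0
    C: float = 6.0  # input normalization total; column sums of P tend to C

    # V (elementary-layer inhibition): bistable asymmetric Hebb
    tau_V: float = 30.0
    alpha_V: float = 0.05
    V_low: float = 0.3
    V_mid: float = 0.7
    V_high: float = 1.15
    theta_p: float = 4.5
    theta_d: float = 4.5

    # W (chunking-layer inhibition): same rule, own constants
    tau_W: float = 60.0
    alpha_W: float = 0.05
    W_low: float = 0.3
    W_mid: float = 0.7
    W_high: float = 1.15
    theta_p_W: float = 2.0
    theta_d_W: float = 2.0

    # learning-window traces (one-sided exponential kernels)
    tau_A: float = 2.0
    A_plus: float = 1.0
    A_minus: float = 1.0
    tau_A_y: float = 2.0

    # Q (EM -> CM excitation)
    tau_Q: float = 60.0
    alpha_Q: float = 4.0
    Q_low: float = 0.0
    Q_mid: float = 0.12
    Q_high: float = 0.4
    gamma_p_Q: float = 8.0
    gamma_d_Q: float = 0.8
    theta_p_Q: float = 0.5
    theta_d_Q: float = 0.5
    eps_H: float = 0.01
    m_H: float = 1.0

    # R (CM -> EM inhibition), swapped bounds
    tau_R: float = 80.0
    alpha_R: float = 0.3
    R_low: float = 0.1
    R_mid: float = 1.0
    R_high: float = 2.8
    gamma_p_R: float = 8.0
    gamma_d_R: float = 0.12
    theta_p_R: float = 1.0
    theta_d_R: float = 0.5

    # per-matrix learning switches (all frozen during recall)
    learn_P: bool = True
    learn_V: bool = True
    learn_W: bool = True
    learn_Q: bool = True
    learn_R: bool = True

    def __post_init__(self):
        _check_triple("V", self.V_low, self.V_mid, self.V_high)
        _check_triple("W", self.W_low, self.W_mid, self.W_high)
        _check_triple("Q", self.Q_low, self.Q_mid, self.Q_high)
        _check_triple("R", self.R_low, self.R_mid, self.R_high)
        for name in ("tau_P", "tau_V", "tau_W", "tau_Q", "tau_R", "tau_A", "tau_A_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma_p_Q", "gamma_d_Q", "gamma_p_R", "gamma_d_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WeightSet:
    """The five coupling matrices.

    ``P`` is (M, N_X); ``V`` is (N_X, N_X) with ``V[i, j]`` the inhibition
    exerted by EM ``i`` on EM ``j``; ``W`` is (N_Y, N_Y) likewise for CMs;
    ``Q`` is (N_X, N_Y) excitation from EMs onto CMs; ``R`` is (N_Y, N_X)
    inhibition from CMs onto EMs.  Diagonals of V and W are fixed
    self-inhibition constants excluded from learning.
    """

    P: np.ndarray
    V: np.ndarray
    W: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        for name in ("P", "V", "W", "Q", "R"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        M, N_X = self.P.shape
        N_Y = self.W.shape[0]
        if self.V.shape != (N_X, N_X) or self.W.shape != (N_Y, N_Y):
            raise ValueError("V / W must be square and consistent with P")
        if self.Q.shape != (N_X, N_Y) or self.R.shape != (N_Y, N_X):
            raise ValueError("Q must be (N_X, N_Y) and R (N_Y, N_X)")
        for name in ("P", "V", "W", "Q", "R"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} has negative entries")

    @property
    def shapes(self):
        return {k: getattr(self, k).shape for k in ("P", "V", "W", "Q", "R")}

    def copy(self) -> "WeightSet":
        return WeightSet(*(getattr(self, k).copy() for k in ("P", "V", "W", "Q", "R")))


@dataclass
class TraceState:
    """Exponentially filtered activities used by the learning windows.

    ``a_x[i]`` integrates EM activity with kernel ``exp(-Δ/τ_A)`` (steady
    state ``τ_A · x``); ``a_y`` likewise for CMs with ``τ_A_y``.  The
    potentiation and depression windows scale the same filtered trace by the
    gains ``A_plus`` / ``A_minus``.
    """

    a_x: np.ndarray
    a_y: np.ndarray

    @classmethod
    def zeros(cls, N_X: int, N_Y: int) -> "TraceState":
        return cls(np.zeros(N_X), np.zeros(N_Y))

    def copy(self) -> "TraceState":
        return TraceState(self.a_x.copy(), self.a_y.copy())


def cubic_drift(w, low, mid, high, alpha):
    """Bistable drift ``alpha (high - w)(low - w)(mid - w)``.

    Its zeros are exactly {low, mid, high}; low and high are attracting and
    mid is the basin boundary.
    """
    return alpha * (high - w) * (low - w) * (mid - w)


def update_P(P, x, s, dt, tau_P):
    """Correlation rule with synaptic scaling:
    ``P_ki += (dt/τ_P) · x_i · (s_k − P_ki)``."""
    P = np.asarray(P, float)
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    return P + (dt / tau_P) * x[None, :] * (s[:, None] - P)


def update_traces(traces: TraceState, x, y, dt, params: PlasticityParams) -> TraceState:
    """Advance the exponential learning-window filters by one step:
    ``τ_A da/dt = -a + τ_A · activity`` (steady state τ_A · activity)."""
    a_x = traces.a_x + (dt / params.tau_A) * (-traces.a_x + params.tau_A * np.asarray(x))
    a_y = traces.a_y + (dt / params.tau_A_y) * (
        -traces.a_y + params.tau_A_y * np.asarray(y)
    )
    return TraceState(a_x, a_y)


def _competition_delta(V, act, trace, dt, tau, alpha, lo, mid, hi, th_p, th_d, A_plus, A_minus):
    act = np.asarray(act, float)
    trace = np.asarray(trace, float)
    ltp = (np.outer(act, A_plus * trace) - th_p) > 0  # w_ij: i active now, j recently
    ltd = (np.outer(A_minus * trace, act) - th_d) > 0  # w_ij: j active now, i recently
    dV = (
        cubic_drift(V, lo, mid, hi, alpha)
        + (hi - V) * ltp
        + (lo - V) * ltd
    ) * (dt / tau)
    np.fill_diagonal(dV, 0.0)  # self-inhibition is fixed
    return dV


def update_competition(V, traces_or_trace, act, dt, params: PlasticityParams, layer="x"):
    """Bistable asymmetric Hebb rule for within-layer inhibition (V or W).

    For weight ``V[i, j]`` (inhibition of j by i): LTP fires when mode i is
    active while the trace of mode j is still high (the network just
    transitioned j → i), driving ``V[i, j]`` toward the high state; LTD fires
    for the transition i → j, driving it toward the low state.  The weight
    along the direction of a transition therefore ends low (the successor is
    released) and the reverse weight high (the predecessor is shut off).
    Diagonal entries are untouched.

    ``layer`` selects the elementary ("x") or chunking ("y") constants.
    """
    trace = traces_or_trace.a_x if layer == "x" else traces_or_trace.a_y
    if layer == "x":
        args = (params.tau_V, params.alpha_V, params.V_low, params.V_mid,
                params.V_high, params.theta_p, params.theta_d)
    else:
        args = (params.tau_W, params.alpha_W, params.W_low, params.W_mid,
                params.W_high, params.theta_p_W, params.theta_d_W)
    V = np.asarray(V, float)
    dV = _competition_delta(V, act, trace, dt, *args,
                            A_plus=params.A_plus, A_minus=params.A_minus)
    return np.maximum(V + dV, 0.0)


def update_Q(Q, x, y, dt, params: PlasticityParams, gate="step"):
    """Bistable excitatory rule with soft bounds and heterosynaptic competition.

    ``τ_Q dQ_ij ∝ cubic + γ_p (Q⁺−Q) Θ(x_i y_j − θ_p) + γ_d (Q⁻−Q) Θ(y_j −
    θ_d) − ε_H max(Σ_j' Q_ij' − m_H, 0)``.  Co-activity potentiates, lone CM
    activity depotentiates, and the last term caps each EM's total outgoing
    weight at ``m_H``.

    ``gate="linear"`` replaces the Heaviside by identity (the small-signal
    form used for analysis).
    """
    Q = np.asarray(Q, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if gate == "linear":
        co = np.outer(x, y)
        lone = y[None, :] * np.ones((Q.shape[0], 1))
    elif gate == "step":
        co = ((np.outer(x, y) - params.theta_p_Q) > 0).astype(float)
        lone = ((y - params.theta_d_Q) > 0).astype(float)[None, :] * np.ones((Q.shape[0], 1))
    else:
        raise ValueError(f"unknown gate mode {gate!r}")
    hetero = params.eps_H * np.maximum(Q.sum(axis=1) - params.m_H, 0.0)
    dQ = (
        cubic_drift(Q, params.Q_low, params.Q_mid, params.Q_high, params.alpha_Q)
        + params.gamma_p_Q * (params.Q_high - Q) * co
        + params.gamma_d_Q * (params.Q_low - Q) * lone
        - hetero[:, None]
    ) * (dt / params.tau_Q)
    return np.maximum(Q + dQ, 0.0)


def update_Q_reduced(Q, x, y, dt, params: PlasticityParams):
    """Small-signal reduction of the excitatory rule:
    ``dQ_ij = y_j (r x_i (Q⁺ − Q_ij) − Q_ij) dt / γ_d``, with ``r = γ_p/γ_d``.

    Exactly equals :func:`update_Q` with ``gate="linear"`` under the
    degeneracies θ = 0, ε_H = 0, Q⁻ = 0, α_Q = 0, τ_Q = γ_d.
    """
    Q = np.asarray(Q, float)
    r = params.gamma_p_Q / params.gamma_d_Q
    dQ = np.asarray(y, float)[None, :] * (
        r * np.asarray(x, float)[:, None] * (params.Q_high - Q) - Q
    )
    return np.maximum(Q + dt * dQ, 0.0)


def update_R(R, x, y, dt, params: PlasticityParams):
    """Inhibitory feedback rule with swapped bounds.

    ``τ_R dR_ji ∝ cubic + γ_p (R⁻−R) Θ(x_i y_j − θ_p) + γ_d (R⁺−R) Θ(y_j −
    θ_d)``: EM/CM co-activity disinhibits the member EM (drives toward the
    low state); lone CM activity strengthens the inhibition of every other EM
    toward the high state.
    """
    R = np.asarray(R, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    co = ((np.outer(y, x) - params.theta_p_R) > 0).astype(float)
    lone = ((y - params.theta_d_R) > 0).astype(float)[:, None] * np.ones((1, R.shape[1]))
    dR = (
        cubic_drift(R, params.R_low, params.R_mid, params.R_high, params.alpha_R)
        + params.gamma_p_R * (params.R_low - R) * co
        + params.gamma_d_R * (params.R_high - R) * lone
    ) * (dt / params.tau_R)
    return np.maximum(R + dR, 0.0)


def freeze(params: PlasticityParams, matrices=("P", "V", "W", "Q", "R")) -> PlasticityParams:
    """Return a copy with learning disabled for the named matrices."""
    return replace(params, **{f"learn_{m}": False for m in matrices})


def thaw(params: PlasticityParams, matrices=("P", "V", "W", "Q", "R")) -> PlasticityParams:
    """Return a copy with learning re-enabled for the named matrices."""
    return replace(params, **{f"learn_{m}": True for m in matrices})
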