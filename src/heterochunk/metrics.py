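"""Observables: symbol sequences, recall distance, chunking rate, pauses.

A simulated trajectory is discretized into a symbol sequence by tracking the
most active mode; sequences are compared with an insertion/deletion-only
Levenshtein distance normalized by the longer length.  Chunk structure is read
either from activity (which chunking mode is up at each elementary-mode onset)
or from the learned excitatory weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SymbolSequence",
    "extract_sequence",
    "levenshtein_indel",
    "normalized_distance",
    "chunking_rate",
    "chunk_partition",
    "pause_durations",
    "asymmetry_index",
    "project_phase_portrait",
]


@dataclass
class SymbolSequence:
    """Ordered mode activations with onset/offset times.

    Consecutive duplicates are merged; onsets are strictly increasing.
    """

    symbols: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=int)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.symbols) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.symbols) > 1 and np.any(self.symbols[1:] == self.symbols[:-1]):
            raise ValueError("consecutive duplicate symbols must be merged")

    def __len__(self):
        return len(self.symbols)

    @property
    def dwells(self) -> np.ndarray:
        return self.offsets - self.onsets

    def to_text(self, path):
        """Plain text: symbol, onset, offset — one activation per line."""
        with open(path, "w") as fh:
            fh.write("symbol\tonset\toffset\n")
            for s, a, b in zip(self.symbols, self.onsets, self.offsets):
                fh.write(f"{s}\t{a:.6g}\t{b:.6g}\n")


def extract_sequence(
    t: np.ndarray,
    activity: np.ndarray,
    active_threshold: float = 0.9,
    min_dwell: int = 3,
) -> SymbolSequence:
    """Discretize a trajectory into the sequence of dominant modes.

    At each sample the argmax mode is a candidate; an activation is emitted
    when a mode is both the argmax and above ``active_threshold`` for at least
    ``min_dwell`` consecutive samples (debounce).  Consecutive duplicates are
    merged.

    Parameters
    ----------
    t : (n,) time grid.
    activity : (n, n_modes) mode activities.
    """
    t = np.asarray(t, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2 or activity.shape[0] != t.shape[0] or t.shape[0] == 0:
        raise ValueError("trajectory must be non-empty with matching time grid")
    winner = np.argmax(activity, axis=1)
    above = activity[np.arange(len(t)), winner] > active_threshold
    lab = np.where(above, winner, -1)

    # run-length encode, drop sub-min_dwell runs and gaps, merge duplicates
    change = np.flatnonzero(np.diff(lab) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(lab)]))
    syms, ons, offs = [], [], []
    for s0, e0 in zip(starts, ends):
        sym = lab[s0]
        if sym < 0 or (e0 - s0) < min_dwell:
            continue
        if syms and syms[-1] == sym:
            offs[-1] = t[e0 - 1]
            continue
        syms.append(int(sym))
        ons.append(t[s0])
        offs.append(t[e0 - 1])
    return SymbolSequence(np.array(syms, int), np.array(ons), np.array(offs))


def _lcs_length(a, b) -> int:
    """Longest-common-subsequence length, O(len(a)·len(b)) DP."""
    la, lb = len(a), len(b)
    prev = np.zeros(lb + 1, dtype=np.int64)
    for i in range(la):
        cur = np.zeros(lb + 1, dtype=np.int64)
        ai = a[i]
        for j in range(lb):
            if ai == b[j]:
                cur[j + 1] = prev[j] + 1
            else:
                cur[j + 1] = max(prev[j + 1], cur[j])
        prev = cur
    return int(prev[lb])


def _as_symbols(seq):
    if isinstance(seq, SymbolSequence):
        return list(seq.symbols)
    return list(seq)


def levenshtein_indel(a, b) -> int:
    """Minimum number of insertions plus deletions transforming ``a`` into
    ``b`` (no substitutions); equals ``len(a) + len(b) - 2·LCS(a, b)``."""
    a, b = _as_symbols(a), _as_symbols(b)
    return len(a) + len(b) - 2 * _lcs_length(a, b)


def normalized_distance(a, b, clip: bool = False) -> float:
    """Indel Levenshtein distance normalized by the longer sequence length.

    The raw normalization can exceed 1 (disjoint alphabets of equal length
    give 2); pass ``clip=True`` to clip to [0, 1] for reporting.
    """
    a, b = _as_symbols(a), _as_symbols(b)
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("both sequences are empty")
    d = levenshtein_indel(a, b) / m
    return min(d, 1.0) if clip else d


def chunking_rate(chunk_sequence: SymbolSequence, n_patterns_presented: int) -> float:
    """Chunking-layer transitions per presented pattern.

    ``chunk_sequence`` must be extracted from the presentation-phase window.
    A rate of 1 means one chunking-mode transition per pattern (no chunking);
    values well below 1 indicate chunk formation.
    """
    if n_patterns_presented <= 0:
        raise ValueError("presentation phase is empty")
    n_trans = max(len(chunk_sequence) - 1, 0)
    return n_trans / n_patterns_presented


def chunk_partition(
    em_sequence: SymbolSequence = None,
    cm_trajectory=None,
    Q: np.ndarray = None,
    active_floor: float = 0.15,
    q_floor: float = 0.05,
):
    """Assign elementary modes to chunking modes.

    Activity-based partition: each recalled EM activation is assigned to the
    CM with the largest mean activity over the activation's dwell window
    (tagged unassigned, -1, when even that mean stays below ``active_floor``
    — no CM was active while the EM was up); requires ``em_sequence`` and
    ``cm_trajectory`` as a ``(t, y)`` tuple.  Weight-based partition:
    ``argmax_j Q_ij`` per EM (unassigned where the row maximum is below
    ``q_floor``); requires ``Q``.  Either or both may be requested.

    Returns
    -------
    dict with keys (present when computable):
      ``activity`` : (n_em_activations,) CM index per recalled EM activation;
      ``weights`` : (N_X,) CM index per EM from Q;
      ``chunk_sizes`` : EM count per CM among CMs used in the activity
          partition (or the weight partition if no activity given).
    """
    out = {}
    assign = None
    if em_sequence is not None and cm_trajectory is not None:
        t_y, y = cm_trajectory
        t_y = np.asarray(t_y, float)
        y = np.asarray(y, float)
        a = np.empty(len(em_sequence), dtype=int)
        for n, (onset, offset) in enumerate(
            zip(em_sequence.onsets, em_sequence.offsets)
        ):
            k0 = int(np.searchsorted(t_y, onset))
            k1 = max(int(np.searchsorted(t_y, offset)) + 1, k0 + 1)
            ybar = y[k0:k1].mean(axis=0)
            j = int(np.argmax(ybar))
            a[n] = j if ybar[j] > active_floor else -1
        out["activity"] = a
        assign = a[a >= 0]
    if Q is not None:
        Q = np.asarray(Q, float)
        wa = np.argmax(Q, axis=1)
        wa = np.where(Q.max(axis=1) > q_floor, wa, -1)
        out["weights"] = wa
        if assign is None:
            assign = wa[wa >= 0]
    if assign is not None and len(assign):
        used, counts = np.unique(assign, return_counts=True)
        out["chunk_sizes"] = dict(zip(used.tolist(), counts.tolist()))
    return out


def pause_durations(em_sequence: SymbolSequence, boundary_positions) -> dict:
    """Excess dwell of the elementary modes at chunk boundaries.

    ``boundary_positions`` are indices into ``em_sequence`` marking the EM
    active at each chunk transition.  The pause at a boundary is its dwell
    minus the median dwell of the non-boundary (within-chunk) activations.

    Returns a dict with ``dwells`` (all activations), ``within_median``, and
    ``pauses`` (one per boundary).
    """
    dwells = em_sequence.dwells
    boundary_positions = np.asarray(list(boundary_positions), dtype=int)
    mask = np.ones(len(dwells), dtype=bool)
    mask[boundary_positions] = False
    within = dwells[mask]
    med = float(np.median(within)) if len(within) else 0.0
    pauses = dwells[boundary_positions] - med
    return {"dwells": dwells, "within_median": med, "pauses": pauses}


def boundary_positions(em_sequence: SymbolSequence, cm_sequence: SymbolSequence):
    """Indices of EM activations during which a CM transition begins.

    The EM at a chunk boundary stays active while the next chunk loads, so we
    mark the EM activation whose [onset, offset) window contains a CM onset
    (excluding the first CM onset).
    """
    pos = []
    for cm_on in cm_sequence.onsets[1:]:
        k = np.searchsorted(em_sequence.onsets, cm_on, side="right") - 1
        if 0 <= k < len(em_sequence):
            pos.append(int(k))
    return sorted(set(pos))


def asymmetry_index(V: np.ndarray) -> float:
    """Norm of the antisymmetric part of the off-diagonal couplings, relative
    to the norm of the off-diagonal part.  0 for symmetric matrices."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    off = V - np.diag(np.diag(V))
    denom = np.linalg.norm(off)
    if denom == 0:
        return 0.0
    anti = 0.5 * (off - off.T)
    return float(np.linalg.norm(anti) / denom)


def project_phase_portrait(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    partition: np.ndarray,
    active_threshold: float = 0.9,
    n_members: int = 3,
):
    """Low-dimensional projection of the two-layer trajectory, per chunk.

    For chunk ``i`` with member EMs ``m1, m2, m3`` (the first ``n_members``
    members), the projected coordinate is ``J_i = 0.5 y_i + 0.5 (x_m1 + x_m2 +
    x_m3)``.  Also returns an activity flag per sample (any ``y_i`` above
    ``active_threshold``).

    ``partition`` maps each EM index to its CM index (-1 = unassigned).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    partition = np.asarray(partition, int)
    chunks = [j for j in np.unique(partition) if j >= 0]
    J = np.zeros((x.shape[0], len(chunks)))
    for c, j in enumerate(chunks):
        members = np.flatnonzero(partition == j)[:n_members]
        J[:, c] = 0.5 * y[:, j] + 0.5 * x[:, members].sum(axis=1)
    active = (y > active_threshold).any(axis=1)
    return {"t": np.asarray(t, float), "J": J, "chunks": chunks, "active": active}
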