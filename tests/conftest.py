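import itertools
import warnings

import numpy as np
import pytest

import heterochunk as hc
from heterochunk.plasticity import WeightSet
from heterochunk.stimulus import generate_bar_patterns, normalize_input

warnings.filterwarnings("ignore", message=".*heteroclinic.*")
warnings.filterwarnings("ignore", message=".*hierarchy of time scales.*")


@pytest.fixture(scope="session")
def small_config():
    """A tiny network for fast structural tests (not a learning demo)."""
    cfg = hc.RunConfig(n_epochs=2, recall_duration=40.0, cue_duration=4.0,
                       consolidation_time=2.0)
    cfg.model = hc.ModelParams(N_X=6, N_Y=4, M=12)
    cfg.stimulus = hc.StimulusSpec(n_patterns=4, pixels_high=3, item_duration=4.0)
    return cfg


def build_template_weights(cfg, chunk_size=8, q_member=0.35, q_boundary=0.3):
    """Hand-built trained-state weights: a closed elementary chain tiled into
    chunks, the corresponding chunk-layer chain, and block-structured Q / R.

    Synthetic stand-in for a learned weight set; used to test the recall-side
    dynamics and the observables independently of the learning rules.
    """
    m, pl = cfg.model, cfg.plasticity
    NX, NY = m.N_X, m.N_Y
    n = cfg.stimulus.n_patterns
    pats = generate_bar_patterns(m.M, n, cfg.stimulus.pixels_high)
    P = np.full((m.M, NX), 1e-3)
    for k in range(n):
        P[:, k] = normalize_input(pats.patterns[k], pl.C)
    V = np.full((NX, NX), pl.V_high)
    np.fill_diagonal(V, m.v_diag)
    for k in range(n):
        V[k, (k + 1) % n] = pl.V_low
    n_chunks = int(np.ceil(n / chunk_size))
    assign = np.repeat(np.arange(n_chunks), chunk_size)[:n]
    W = np.full((NY, NY), pl.W_high)
    np.fill_diagonal(W, m.w_diag)
    for c in range(n_chunks):
        W[c, (c + 1) % n_chunks] = pl.W_low
    Q = np.full((NX, NY), 0.01)
    R = np.full((NY, NX), pl.R_high)
    for k in range(n):
        c = assign[k]
        Q[k, c] = q_member
        R[c, k] = pl.R_low
        nxt = assign[(k + 1) % n]
        if nxt != c:
            Q[k, nxt] = q_boundary
            R[nxt, k] = pl.R_low
    return WeightSet(P, V, W, Q, R), assign, pats


@pytest.fixture(scope="session")
def template_setup():
    """Default-size network with hand-built trained weights (see above)."""
    cfg = hc.RunConfig()
    w, assign, pats = build_template_weights(cfg)
    return cfg, w, assign, pats


@pytest.fixture(scope="session")
def template_recall(template_setup):
    """A frozen-weight recall run on the hand-built weights."""
    from heterochunk.plasticity import freeze
    from heterochunk.stimulus import RawSchedule

    cfg, w, assign, pats = template_setup
    m, pl = cfg.model, cfg.plasticity
    frozen = freeze(pl)
    rng = np.random.default_rng(7)
    st = hc.NetworkState.small_random(m, rng)
    cue = RawSchedule(normalize_input(pats.patterns[0], pl.C)[None, :], 10.0)
    w2 = w.copy()
    t1 = hc.run(st, w2, m, frozen, cue, T=10.0, record_stride=5, seed=11)
    t2 = hc.run(st, w2, m, frozen, None, T=260.0, record_stride=5, seed=12)
    traj = hc.Trajectory(
        np.concatenate([t1.t, t2.t]),
        np.vstack([t1.x, t2.x]),
        np.vstack([t1.y, t2.y]),
        np.vstack([t1.z, t2.z]),
    )
    return cfg, w, assign, traj


# ------------------------- independent edit-distance oracles (tests) ------
def _indel_brute_force(a, b):
    """Independent oracle: enumerate all subsequences of the shorter string
    and find the longest that is also a subsequence of the other."""
    if len(a) > len(b):
        a, b = b, a

    def is_subseq(s, t):
        it = iter(t)
        return all(c in it for c in s)

    best = 0
    for r in range(len(a), -1, -1):
        if r <= best:
            break
        for comb in itertools.combinations(a, r):
            if is_subseq(comb, b):
                best = r
                break
    return len(a) + len(b) - 2 * best


def _indel_dp_recurrence(a, b):
    """Second oracle: direct DP of the insertion/deletion recurrence."""
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=int)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            opts = [d[i - 1, j] + 1, d[i, j - 1] + 1]
            if a[i - 1] == b[j - 1]:
                opts.append(d[i - 1, j - 1])
            d[i, j] = min(opts)
    return int(d[la, lb])


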