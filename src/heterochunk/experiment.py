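"""Training protocol: epochs, recall, batteries, parameter sweeps.

An epoch is one full presentation of the stimulus sequence with plasticity
on, an input-free consolidation interval (plasticity still on, so the
bistable weights settle toward their resting values), and a recall phase
with all learning frozen: the network is cued with the first sequence
element for one item duration and then runs freely, driven only by its
growth terms.  Recall quality is the normalized indel Levenshtein distance D
between the dominant-mode sequences of the presentation and recall phases;
chunking is monitored through the chunking rate CR and the chunk partition.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as mx
from .dynamics import ModelParams, NetworkState, Trajectory, run
from .plasticity import PlasticityParams, TraceState, WeightSet, freeze
from .stimulus import RawSchedule, generate_bar_patterns, make_schedule, normalize_input

__all__ = [
    "StimulusSpec", "InitSpec", "RunConfig", "TrialRecord", "ExperimentResult",
    "init_weights", "run_epoch", "run_battery", "sweep", "classify_failure",
]


@dataclass
class StimulusSpec:
    """Declarative description of the training stimulus."""

    n_patterns: int = 24
    pixels_high: int = 6
    item_duration: float = 8.0
    noise_sigma: float = 0.0
    low_value: float = 0.0
    high_value: float = 1.0
    order: list = None  # None -> identity order
    noise_before_normalize: bool = False


@dataclass
class InitSpec:
    """Baseline weights + jitter amplitude for :func:`init_weights`.

    Within-layer couplings start symmetric and above the self-inhibition
    (winner-take-all regime, inside the upper basin of the bistable rule);
    the between-layer matrices start at mid-range baselines.
    """

    v_baseline: float = 1.05
    w_baseline: float = 0.9
    q_baseline: float = 0.2
    r_baseline: float = 0.45
    jitter: float = 0.03
    q_col_jitter: float = 0.3  # per-CM multiplicative spread of the Q baseline
    p_alpha: float = 0.015  # sparseness of the random normalized P columns

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.p_alpha <= 0:
            raise ValueError("p_alpha must be > 0")


@dataclass
class RunConfig:
    """Everything that determines a training run (with the seed)."""

    model: ModelParams = field(default_factory=ModelParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    init: InitSpec = field(default_factory=InitSpec)
    n_epochs: int = 120
    n_runs: int = 1
    consolidation_time: float = 5.0
    cue_duration: float = 16.0
    recall_duration: float = 300.0
    recall_every: int = 1  # run the recall phase every k-th epoch (and last)
    record_stride: int = 5
    x_active_threshold: float = 0.5
    y_active_threshold: float = 0.5
    cr_threshold: float = 0.5  # CM counts as active above this level
    min_dwell: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs < 1 or self.n_runs < 1:
            raise ValueError("n_epochs and n_runs must be >= 1")
        if self.model.N_X < self.stimulus.n_patterns:
            raise ValueError(
                "the elementary layer must have at least one mode per pattern"
            )

    def copy(self) -> "RunConfig":
        return copy.deepcopy(self)


@dataclass
class TrialRecord:
    """Per-epoch outputs of one run."""

    epoch: int
    presented: list
    recalled: list
    D_raw: float
    D: float
    CR: float
    partition: np.ndarray = None  # CM per recalled EM activation (-1 unassigned)
    chunk_sizes: dict = None
    mean_chunk_size: float = np.nan
    n_cm_distinct: int = 0
    pauses: np.ndarray = None
    dwell_median: float = np.nan
    failure: str = "none"


@dataclass
class ExperimentResult:
    """Per-run record series plus per-epoch aggregate curves."""

    records: list  # list (runs) of lists (epochs) of TrialRecord
    config: RunConfig = None

    def curves(self) -> pd.DataFrame:
        """Mean ± sd of D and CR per epoch over runs (recall epochs only)."""
        rows = []
        for r, recs in enumerate(self.records):
            for rec in recs:
                rows.append({"run": r, "epoch": rec.epoch, "D": rec.D,
                             "CR": rec.CR, "failure": rec.failure,
                             "mean_chunk_size": rec.mean_chunk_size})
        df = pd.DataFrame(rows)
        agg = df.groupby("epoch").agg(
            D_mean=("D", "mean"), D_sd=("D", "std"),
            CR_mean=("CR", "mean"), CR_sd=("CR", "std"),
        ).reset_index()
        return agg

    def table(self) -> pd.DataFrame:
        rows = []
        for r, recs in enumerate(self.records):
            for rec in recs:
                rows.append({
                    "run": r, "epoch": rec.epoch, "D": rec.D, "D_raw": rec.D_raw,
                    "CR": rec.CR, "mean_chunk_size": rec.mean_chunk_size,
                    "n_cm_distinct": rec.n_cm_distinct, "failure": rec.failure,
                })
        return pd.DataFrame(rows)


def _seed_for(config_seed, run_idx, epoch, phase) -> int:
    """Counter-based seed split: independent of execution order."""
    ss = np.random.SeedSequence([int(config_seed), int(run_idx), int(epoch), int(phase)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def init_weights(config: RunConfig, rng) -> WeightSet:
    """Initial coupling matrices: symmetric-up-to-jitter all-to-all
    inhibition within layers (winner-take-all), mid-range baselines between
    layers, fixed diagonals."""
    m, ini = config.model, config.init
    j = ini.jitter

    def jit(shape, base):
        return np.maximum(base + j * (2 * rng.random(shape) - 1), 0.0)

    # sparse random normalized columns: each mode starts tuned to a few
    # random pixels, so the input itself can break the competition tie
    g = rng.gamma(ini.p_alpha, 1.0, size=(m.M, m.N_X)) + 1e-12
    P = config.plasticity.C * g / g.sum(axis=0, keepdims=True)
    V = jit((m.N_X, m.N_X), ini.v_baseline)
    np.fill_diagonal(V, m.v_diag)
    W = jit((m.N_Y, m.N_Y), ini.w_baseline)
    np.fill_diagonal(W, m.w_diag)
    # per-CM column scaling gives each chunking mode a persistent identity
    # in the initial lottery (a per-entry jitter averages out over a column)
    col = 1 + ini.q_col_jitter * (2 * rng.random(m.N_Y) - 1)
    Q = jit((m.N_X, m.N_Y), ini.q_baseline) * col[None, :]
    R = jit((m.N_Y, m.N_X), ini.r_baseline)
    return WeightSet(P, V, W, Q, R)


def _build_schedule(config: RunConfig, noise_seed: int):
    st = config.stimulus
    pats = generate_bar_patterns(
        config.model.M, st.n_patterns, st.pixels_high,
        st.low_value, st.high_value, seed=config.seed,
    )
    order = np.arange(st.n_patterns) if st.order is None else np.asarray(st.order)
    return make_schedule(
        pats, order, 1, st.item_duration, st.noise_sigma,
        C=config.plasticity.C, seed=noise_seed,
        noise_before_normalize=st.noise_before_normalize,
    )


def classify_failure(record: TrialRecord, recall_traj: Trajectory,
                     expected_len: int, config: RunConfig) -> str:
    """Tag the two characteristic failure modes of recall.

    ``stuck``: the elementary itinerancy halts before the sequence completes
    (no transition within five median dwell times of the end of the last
    onset).  ``no_chunks``: the elementary order is essentially correct but
    the chunking layer shows no transition.  Healthy runs return ``none``.
    """
    recalled = record.recalled
    if len(recalled) < expected_len:
        em = mx.extract_sequence(
            recall_traj.t, recall_traj.x,
            config.x_active_threshold, config.min_dwell,
        )
        if len(em):
            med = float(np.median(em.dwells))
            tail = recall_traj.t[-1] - em.onsets[-1]
            if med > 0 and tail > 5 * med:
                return "stuck"
        else:
            return "stuck"
    if record.n_cm_distinct < 2 and record.D_raw <= 0.2:
        return "no_chunks"
    return "none"


def run_epoch(
    state: NetworkState,
    weights: WeightSet,
    config: RunConfig,
    epoch: int = 0,
    run_idx: int = 0,
    do_recall: bool = True,
    return_trajectories: bool = False,
):
    """One epoch: presentation (learning on) → consolidation → frozen recall.

    Mutates ``state`` and ``weights``; returns ``(weights, TrialRecord)`` (and
    the phase trajectories when requested).
    """
    m, pl = config.model, config.plasticity
    sched = _build_schedule(config, _seed_for(config.seed, run_idx, epoch, 0))

    traj_pres = run(state, weights, m, pl, sched,
                    record_stride=config.record_stride,
                    seed=_seed_for(config.seed, run_idx, epoch, 1))
    if config.consolidation_time > 0:
        run(state, weights, m, pl, None, T=config.consolidation_time,
            record_stride=max(config.record_stride, 1),
            seed=_seed_for(config.seed, run_idx, epoch, 2))

    em_pres = mx.extract_sequence(traj_pres.t, traj_pres.x,
                                  config.x_active_threshold, config.min_dwell)
    cm_pres = mx.extract_sequence(traj_pres.t, traj_pres.y,
                                  config.cr_threshold, config.min_dwell)
    CR = mx.chunking_rate(cm_pres, sched.n_items)

    if not do_recall:
        rec = TrialRecord(epoch, list(em_pres.symbols), [], np.nan, np.nan, CR)
        return (weights, rec, traj_pres, None) if return_trajectories else (weights, rec)

    # recall: frozen weights, cue with the first element, then free run
    frozen = freeze(pl)
    cue = RawSchedule(normalize_input(
        sched.pattern_set.patterns[sched.order[0]], pl.C
    )[None, :], config.cue_duration)
    w_before = weights.copy()
    traj_cue = run(state, weights, m, frozen, cue, T=config.cue_duration,
                   record_stride=config.record_stride,
                   seed=_seed_for(config.seed, run_idx, epoch, 3))
    traj_free = run(state, weights, m, frozen, None, T=config.recall_duration,
                    record_stride=config.record_stride,
                    seed=_seed_for(config.seed, run_idx, epoch, 4))
    assert np.array_equal(w_before.V, weights.V), "weights changed during recall"
    traj_rec = Trajectory(
        np.concatenate([traj_cue.t, traj_free.t]),
        np.vstack([traj_cue.x, traj_free.x]),
        np.vstack([traj_cue.y, traj_free.y]),
        np.vstack([traj_cue.z, traj_free.z]),
    )

    em_rec = mx.extract_sequence(traj_rec.t, traj_rec.x,
                                 config.x_active_threshold, config.min_dwell)
    cm_rec = mx.extract_sequence(traj_rec.t, traj_rec.y,
                                 config.y_active_threshold, config.min_dwell)
    # recall is cued with the first element and cyclic: score one pass,
    # starting from the first appearance of the cued element (activity
    # carried over from the presentation phase may precede it) and
    # truncating the reproduced stream at the presented length
    start = 0
    if len(em_pres) and em_pres.symbols[0] in em_rec.symbols:
        start = int(np.flatnonzero(em_rec.symbols == em_pres.symbols[0])[0])
    stop = start + max(len(em_pres), 1)
    em_pass = mx.SymbolSequence(
        em_rec.symbols[start:stop], em_rec.onsets[start:stop],
        em_rec.offsets[start:stop],
    )
    rec_syms = list(em_pass.symbols)
    D_raw = (mx.normalized_distance(list(em_pres.symbols), rec_syms)
             if max(len(em_pres), len(rec_syms)) else np.nan)
    first = np.sort(np.unique(em_pass.symbols, return_index=True)[1])
    em_uniq = mx.SymbolSequence(em_pass.symbols[first], em_pass.onsets[first],
                                em_pass.offsets[first])
    part = mx.chunk_partition(em_uniq, (traj_rec.t, traj_rec.y))
    sizes = part.get("chunk_sizes", {})
    mean_size = float(np.mean(list(sizes.values()))) if sizes else np.nan
    bpos = mx.boundary_positions(em_pass, cm_rec)
    pause = mx.pause_durations(em_pass, bpos) if len(em_pass) else None

    rec = TrialRecord(
        epoch=epoch,
        presented=list(em_pres.symbols),
        recalled=list(em_rec.symbols),
        D_raw=D_raw,
        D=min(D_raw, 1.0) if np.isfinite(D_raw) else np.nan,
        CR=CR,
        partition=part.get("activity"),
        chunk_sizes=sizes,
        mean_chunk_size=mean_size,
        n_cm_distinct=len(set(cm_rec.symbols)),
        pauses=pause["pauses"] if pause else None,
        dwell_median=pause["within_median"] if pause else np.nan,
    )
    rec.failure = classify_failure(rec, traj_rec, len(em_pres), config)
    if return_trajectories:
        return weights, rec, traj_pres, traj_rec
    return weights, rec


def train_run(config: RunConfig, run_idx: int = 0, keep_weights: bool = False,
              progress=None):
    """Train one network for ``config.n_epochs`` epochs.

    Returns the list of TrialRecords (recall epochs carry full metrics) and,
    when requested, the final weights and state.
    """
    rng = np.random.default_rng(_seed_for(config.seed, run_idx, 0, 9))
    weights = init_weights(config, rng)
    state = NetworkState.small_random(config.model, rng)
    records = []
    prev_recalled = False
    for epoch in range(config.n_epochs):
        # each epoch is a fresh trial: restart from a small random state so
        # the arbitrary end state of the previous epoch (in particular a
        # recall phase) cannot imprint a spurious transition into the first
        # sequence element
        if epoch > 0:
            state = NetworkState.small_random(
                config.model,
                np.random.default_rng(_seed_for(config.seed, run_idx, epoch, 8)),
            )
        do_recall = ((epoch + 1) % config.recall_every == 0
                     or epoch == config.n_epochs - 1)
        prev_recalled = do_recall
        try:
            _, rec = run_epoch(state, weights, config, epoch, run_idx, do_recall)
        except FloatingPointError as exc:
            rec = TrialRecord(epoch, [], [], np.nan, np.nan, np.nan,
                              failure=f"diverged: {exc}")
            records.append(rec)
            if progress is not None:
                progress(run_idx, rec)
            break
        records.append(rec)
        if progress is not None:
            progress(run_idx, rec)
    if keep_weights:
        return records, weights, state
    return records


def run_battery(config: RunConfig, progress=None) -> ExperimentResult:
    """Independent seeded runs of the full training protocol.

    Seeds are split per (run, epoch, phase) with a counter scheme, so the
    results do not depend on execution order.  Failed runs are kept as tagged
    records; the battery never aborts.
    """
    records = [train_run(config, r, progress=progress)
               for r in range(config.n_runs)]
    return ExperimentResult(records, config)


def _set_by_path(config: RunConfig, path: str, value):
    obj = config
    parts = path.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise AttributeError(f"no config entry {path!r}")
    old = getattr(obj, parts[-1])
    if not isinstance(old, (int, float, np.floating, np.integer)):
        raise AttributeError(f"{path!r} is not numeric")
    setattr(obj, parts[-1], value)


def sweep(config: RunConfig, parameter_path: str, values, n_reps: int = 10
          ) -> pd.DataFrame:
    """Sweep one numeric config entry; ``n_reps`` trained runs per value.

    Records mean ± sd of the final-epoch chunk size and the fraction of runs
    whose chunking layer shows sequential activity (≥ 2 distinct chunking
    modes during recall).  ``model.tau_z = 0`` is supported (synaptic
    dynamics removed).
    """
    n_items = config.stimulus.n_patterns
    rows = []
    for v in values:
        cfg = config.copy()
        _set_by_path(cfg, parameter_path, v)
        cfg.n_runs = n_reps
        result = run_battery(cfg)
        finals = [recs[-1] for recs in result.records if recs]
        sizes = [r.mean_chunk_size for r in finals if np.isfinite(r.mean_chunk_size)]
        # robust companion estimate from the presentation phase: items per
        # chunk-layer transition (immune to recall glitches)
        cr_sizes = [n_items / max(r.CR * n_items, 1.0) for r in finals
                    if np.isfinite(r.CR)]
        seq = [r.n_cm_distinct >= 2 for r in finals]
        rows.append({
            "param": parameter_path, "value": v, "n_reps": n_reps,
            "chunk_size_mean": float(np.mean(sizes)) if sizes else np.nan,
            "chunk_size_sd": float(np.std(sizes)) if sizes else np.nan,
            "chunk_size_cr": float(np.mean(cr_sizes)) if cr_sizes else np.nan,
            "frac_sequential": float(np.mean(seq)) if seq else np.nan,
            "D_mean": float(np.nanmean([r.D for r in finals])) if finals else np.nan,
        })
    return pd.DataFrame(rows)
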