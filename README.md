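# heterochunk

A simulator for studying how long sequences are learned and recalled as
*chunks* — the way a phone number is remembered as a few groups of digits —
in a hierarchical neural network with winnerless-competition dynamics.

## The model

Three populations of modes interact: perceptual modes `s_k` carry the
stimulus, elementary modes `x_i` come to represent individual sequence
items, and slower chunking modes `y_j` come to represent groups of
consecutive items.  The rate dynamics are a two-layer stochastic
Generalized Lotka–Volterra (GLV) system

    τ_x ẋ_i = x_i ( Σ_k P_ki s_k + b_x − Σ_i' V_i'i x_i' − Σ_j R_ji y_j ) + σ_x η_i
    τ_y ẏ_j = y_j ( z_j + b_y ) + σ_y ξ_j
    τ_z ż_j = −z_j + Σ_i Q_ij x_i − Σ_j' W_j'j y_j' + b_z(t)

with five coupled synaptic-plasticity rules, all unsupervised and running
online with the dynamics:

* `P` — competitive associative learning (one elementary mode per item),
* `V`, `W` — bistable asymmetric Hebbian rules on the within-layer
  inhibition: each observed transition depresses the coupling along its
  direction and potentiates the reverse one, converting winner-take-all
  into winnerless competition along a stable heteroclinic channel,
* `Q`, `R` — bistable rules on the between-layer couplings that associate
  each chunking mode with a group of consecutive elementary modes
  (excitation up, inhibition of members released), with heterosynaptic
  competition capping each elementary mode's total outgoing weight.

After training, cueing the network with the first item and freezing the
weights makes the activity travel the learned chain: items are recalled in
order, grouped into chunks, with a characteristic *pause* at every chunk
boundary while the next chunking mode loads.  Recall quality is measured
with an insertion/deletion-only Levenshtein distance `D` normalized by the
longer sequence; chunking is monitored by the chunking rate `CR`
(chunk-layer transitions per presented item) and the chunk partition.
`docs/methods.md` derives the default constants and documents every design
choice.

## Worked example

`examples/03_train_and_recall.py` trains the demonstration network — 24
elementary modes, 3 chunking modes, a sequence of 24 non-overlapping bar
patterns presented 120 times — and recalls it from a single cue:

```
presented : [6, 16, 14, 18, 5, 15, 2, 1, 12, 21, 19, 0, 23, 20, 13, 10]
recalled  : [10, 6, 16, 14, 18, 15, 2, 1, 12, 21, 19, 0, 23, 20, 13, 15]
D = 0.250  (normalized indel Levenshtein distance; 0 = perfect order)
chunking rate during the last presentation: 0.25 (chunk-mode transitions per item; well below 1 = chunks formed)
chunk sizes (elementary modes per chunking mode): {0: 3, 1: 3, 2: 8}
pauses at chunk boundaries: [ 0.3  0.5  0.5 -2.8] time units beyond the median dwell of 7.0
failure tag: none
```

The recalled stream reproduces the presented order (the leading `10` is
activity carried over from the presentation phase; scoring starts at the
cued element), the chunk layer has segmented the sequence into three
groups, and the boundary items dwell longer than their within-chunk peers.
The other examples cover the stimulus generator, the winner-take-all /
winnerless-competition regimes of the single-layer model, a multi-run
learning curve, and the per-chunk phase-portrait projection.

A thin command line mirrors the library:

```bash
heterochunk train   --config cfg.yaml --seed 1 --out runs/demo
heterochunk battery --config cfg.yaml --seed 1 --out runs/battery
heterochunk sweep   --param plasticity.gamma_p_Q --values 3,5,8,12 --out runs/sweep
```

Configs are YAML; omitted keys take the defaults recorded in
`src/heterochunk/defaults.yaml`.  Every run writes a JSON manifest (config
snapshot, seed, file checksums) from which it can be re-executed
bit-identically.

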