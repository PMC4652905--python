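"""Winner-take-all versus winnerless competition in the single-layer model.

The same Generalized Lotka-Volterra equation produces a stable winner under
symmetric inhibition and a perpetual cyclic itinerancy once the couplings
are asymmetric - the two regimes that learning connects in the full model.
"""

import numpy as np

from heterochunk import run_single_layer

# symmetric strong inhibition: one winner, resting at b / V_ii
V_sym = np.full((4, 4), 1.5)
np.fill_diagonal(V_sym, 1.0)
traj = run_single_layer(np.array([0.3, 0.1, 0.1, 0.1]), V_sym, b=2.0, T=200.0)
print(f"winner-take-all: final activities {np.round(traj.x[-1], 4)} "
      f"(closed form b/V_ii = {2.0 / 1.0})")

# asymmetric couplings: a stable heteroclinic cycle 0 -> 1 -> 2 -> 0
V_asym = np.array([[1.0, 0.5, 1.5],
                   [1.5, 1.0, 0.5],
                   [0.5, 1.5, 1.0]])
traj = run_single_layer(np.array([1.0, 0.02, 0.01]), V_asym, b=1.0,
                        sigma=0.005, T=300.0, seed=4)
seq = traj.events(active_threshold=0.6)
print(f"winnerless competition: visits {list(seq.symbols[:9])} ... "
      f"(mean dwell {seq.dwells.mean():.1f} time units)")
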