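"""Train the demonstration network and recall the learned sequence.

24 elementary modes and 3 chunking modes learn a 24-bar sequence over 120
loop presentations, then reproduce it from a single cue with all learning
frozen.  Prints the recall distance D, the recalled order, the chunk
partition and the pauses at chunk boundaries.  Takes a couple of minutes on
one CPU.
"""

import numpy as np

import heterochunk as hc

cfg = hc.RunConfig(seed=0, recall_every=10**9)  # recall once, after training
cfg.model.N_X = 24
cfg.model.N_Y = 3

records = hc.train_run(cfg)
final = records[-1]

print(f"presented : {[int(s) for s in final.presented]}")
print(f"recalled  : {[int(s) for s in final.recalled[:len(final.presented)]]}")
print(f"D = {final.D:.3f}  (normalized indel Levenshtein distance; "
      "0 = perfect order)")
print(f"chunking rate during the last presentation: {final.CR:.2f} "
      "(chunk-mode transitions per item; well below 1 = chunks formed)")
print(f"chunk sizes (elementary modes per chunking mode): {final.chunk_sizes}")
if final.pauses is not None and len(final.pauses):
    print(f"pauses at chunk boundaries: {np.round(final.pauses, 1)} "
          f"time units beyond the median dwell of {final.dwell_median:.1f}")
print(f"failure tag: {final.failure}")
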