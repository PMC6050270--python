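"""Detect bursts in a hand-built spike train with the Max-Interval algorithm.

Builds a 40-spike train containing two dense runs (ISI 0.05 s) separated
by a 0.3 s pause, plus sparse tonic spikes, and prints the detected
bursts.  The 0.3 s pause is longer than the 0.2 s end-ISI threshold, so
the runs split into two candidates, but shorter than the 0.5 s minimum
inter-burst interval, so they merge back into a single 20-spike burst.
"""

import numpy as np

from meaburst import BurstParams, SpikeTrain, detect_bursts

run1 = np.arange(10) * 0.05                  # 10 spikes, ISI 50 ms
run2 = run1[-1] + 0.30 + np.arange(10) * 0.05
tonic = 5.0 + np.arange(20) * 1.0            # 20 tonic spikes, 1 s apart
train = SpikeTrain(unit_id="demo", electrode_id="e0", epoch="baseline",
                   spike_times=np.concatenate([run1, run2, tonic]),
                   epoch_duration=30.0)

bursts = detect_bursts(train, BurstParams())
print(f"{train.n_spikes} spikes -> {len(bursts)} burst(s)")
for b in bursts:
    print(f"  spikes {b.first_spike_index}-{b.last_spike_index} "
          f"({b.n_spikes} spikes), {b.start_time:.2f}-{b.end_time:.2f} s, "
          f"duration {b.duration:.2f} s")
# One burst of 20 spikes: the tonic spikes (ISI 1 s) never open a
# candidate, and the two dense runs merged across the 0.3 s pause.
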