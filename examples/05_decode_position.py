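"""Bayesian position decoding and the spike-efficiency exponent.

Decodes the simulated animal's position from population spike counts
in 500-ms windows (independent-Poisson likelihood over 5x5-cm rate-map
pixels) and fits how the median error falls with the number of spikes
used: median_error = A exp(-c n_spikes).
"""

import numpy as np

from hypergeo import synth
from hypergeo.decode import bayes_decode, efficiency_exponent
from hypergeo.fields import compute_rate_map

traj = synth.simulate_trajectory(100.0, 480.0, speed_mean=15.0, seed=21)
pop = synth.generate_population(30, zeta=0.06, field_count_mean=2.0,
                                field_count_sd=0.5, arena_cm=100.0,
                                amplitude_range=(8.0, 20.0), seed=22)
spikes = synth.simulate_spikes(pop, traj, seed=23)
maps = [compute_rate_map(t, traj, bin_cm=5.0) for t in spikes.spike_times]

run = bayes_decode(spikes, maps, traj, window_s=0.5)
rng = np.random.default_rng(0)
chance = np.linalg.norm(rng.uniform(0, 100, (20000, 2))
                        - rng.uniform(0, 100, (20000, 2)), axis=1).mean()
print(f"decoded windows         : {run.errors.size}")
print(f"median decoding error   : {run.median_error:.1f} cm "
      f"(chance {chance:.1f} cm)")

fit = efficiency_exponent(spikes, traj, subsample_range=(10, 20),
                          rate_maps=maps, seed=24)
print(f"efficiency exponent c   : {fit.c:.4f} +- {fit.c_stderr:.4f} "
      "per spike")
# c measures how much one extra spike shrinks the median error; it
# tracks the size (radius) of the latent hyperbolic representation.
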