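"""Synthesise a short multi-channel EMG record for one muscle.

Constant drive -> spike trains -> convolution with (static) MUAP templates
-> 320-channel interference EMG with additive noise at 20 dB SNR.
"""

import numpy as np

from emgforge import (MuscleModel, PoolConfig, SimConfig, init_pool,
                      fuglevand_spikes, morph_sequence, sample_latent,
                      len2params, synthesize, add_noise, select_channels)
from emgforge.augment import _base_condition

cfg = SimConfig()
cfg.grid.fs_muap = 2048.0
muscle = MuscleModel("FCR", 0.063, 0.244, 74.0, {"wrist_flexion": 0.015},
                     territory_centre_depth=7.0, ml_angle=275.0,
                     n_units=10, total_fibres=2500)

fs, duration = 2048.0, 3.0
pool = init_pool(muscle, "classical", cfg.pool, seed=5)
drive = np.full(int(duration * fs) + 1, 0.5)
spikes = fuglevand_spikes(pool, drive, fs, seed=5)
print(f"{sum(t.size > 0 for t in spikes.trains)} of {pool.n_units} units "
      f"recruited, {spikes.total_spikes} spikes in {duration:.0f} s")

static = len2params(np.ones(10), 1.0)          # no movement: static templates
size_max = max(u.size for u in pool.units)
muaps = {u.rank: morph_sequence(_base_condition(u, muscle, cfg, size_max),
                                static, n_keyframes=2,
                                latent=sample_latent(u.rank, u.latent_seed),
                                grid=cfg.grid, ranges=cfg.cond_ranges)
         for u in pool.units}

emg = synthesize(spikes, muaps, fs, duration)
emg = add_noise(emg, snr_db=20.0, seed=5)
rms = np.sqrt((emg.values ** 2).mean(axis=1))
hottest = int(np.argmax(rms))
row, col = emg.channel_map[hottest]
print(f"EMG: {emg.n_channels} channels x {emg.n_samples} samples")
print(f"hottest channel (row {row}, column {col}) RMS {rms[hottest]:.4f} — "
      f"the column sits over the muscle at {muscle.ml_angle:.0f} deg")
six = select_channels(emg, [(4, c) for c in range(0, 32, 6)][:6])
print(f"selected subset: {six.n_channels} channels")
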