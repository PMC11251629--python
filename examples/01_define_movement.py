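"""Define a wrist flexion/extension movement and track fibre lengths.

Builds a 4-s movement by interpolating between named poses, checks joint
ranges, writes a .mot motion file, and prints how the flexor/extensor fibre
lengths respond.
"""

import numpy as np

from emgforge import (SimConfig, define_movement, check_joint_ranges,
                      write_mot, fibre_length)

cfg = SimConfig()
traj = define_movement(["default", "flex", "default", "ext", "default"],
                       [1.0, 1.0, 1.0, 1.0], fs_motion=50)
print(f"trajectory: {traj.time.size} samples, {len(traj.dof_names)} DoFs, "
      f"{traj.duration:.1f} s")
print(f"range violations: {len(check_joint_ranges(traj))}")
write_mot(traj, "scratch_movement.mot")

for name in ("FCR", "ECRB"):
    mt = fibre_length(cfg.muscles[name], traj)
    print(f"{name}: normalised fibre length "
          f"min={mt.fibre_length_norm.min():.3f} "
          f"max={mt.fibre_length_norm.max():.3f}")
# The flexor (FCR) shortens below 1.0 during flexion and the extensor (ECRB)
# stretches above 1.0 — the basic geometry every downstream module relies on.
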