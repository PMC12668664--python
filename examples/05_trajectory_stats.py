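"""RMSD distribution and per-residue RMSF from a synthetic trajectory.

A 2000-frame Gaussian-jitter trajectory is generated around an ideal helix
with a known per-residue amplitude profile (σ rising along the chain). The
per-frame backbone RMSD series is summarized as a normalized distribution
P(d) with mean ± SD, and the per-residue RMSF — computed about the mean
structure with two-pass alignment — recovers each residue's σ·√3.
"""

import numpy as np

from abepitope.synthetic import HelixSpec, JitterSpec, build_ideal_helix, gen_jitter_trajectory
from abepitope.traj import distribution, rmsd_series, rmsf

n_res = 20
ref = build_ideal_helix(HelixSpec("A" * n_res, with_backbone=True))
sigmas = {("A", i + 1, ""): 0.1 + 0.02 * i for i in range(n_res)}
traj = gen_jitter_trajectory(
    JitterSpec(ref, sigma_per_residue=sigmas, n_frames=2000, seed=5)
)

series = rmsd_series(traj, reference=0)
summary = distribution(series, bins=50)
print(f"RMSD over {traj.n_frames} frames: "
      f"{summary.mean:.2f} ± {summary.sd:.2f} Å "
      f"(P(d) normalization = {summary.normalization():.6f})")

profile = rmsf(traj)
print("residue   σ·√3 (expected)   RMSF (measured)")
for rid, value in list(zip(profile.residues, profile.values))[::5]:
    expected = sigmas[rid] * np.sqrt(3)
    print(f"  {rid[1]:3d}       {expected:.3f}            {value:.3f}")
# Measured RMSF tracks the generating amplitudes: fluctuation statistics
# are recovered from coordinates alone, as for a real MD trajectory.
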