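"""Reference-free maximum-likelihood averaging of noisy subtomograms.

Fifty particles at SNR 0.5 in random orientations are aligned by EM over a
discrete orientation grid, starting from a subset mean of the raw particles
(no external model).  The script reports the angular recovery after removing
the global gauge rotation and the solvent-masked FSC resolution of the
half-set averages.
"""
import numpy as np
from scipy.spatial.transform import Rotation

from polytomo import (AlignmentConfig, GeneratorConfig, ParticleSet, Pose,
                      build_reference, extract_subtomograms, fsc_resolution,
                      ml_align, render_tomogram, soft_spherical_mask)
from polytomo.so3 import gauge_fix

ref = build_reference(2.0, 24)
cfg = GeneratorConfig(box_edge=24, snr=0.5)
rng = np.random.default_rng(8)
true = Rotation.random(50, rng=rng)
center = np.full(3, 23.0)
subs = []
for k, rot in enumerate(true):
    tomo = render_tomogram([Pose(f"p{k}", center, rot)], ref, cfg, rng,
                           box_edge=24)
    subs.append(extract_subtomograms(tomo, [center], 24).subvolumes[0])

particles = ParticleSet(np.stack(subs), 2.0)
result = ml_align(particles, AlignmentConfig(rotation_grid_deg=20.0,
                                             refine_grid_deg=10.0,
                                             n_iterations=6,
                                             refine_iterations=3, seed=0))
gauge, err = gauge_fix(true, result.rotations)
mask = soft_spherical_mask(result.average.shape, 2.0, ref.diameter / 2 + 1)
curve, resolution = fsc_resolution(result.half_averages[0] * mask,
                                   result.half_averages[1] * mask, 2.0)

print(f"particles: {len(particles)}, SNR 0.5, grid 20 deg refined to 10 deg")
print(f"median angular error after gauge fixing: {np.median(err):.1f} deg "
      "(how well each ribosome's orientation was recovered)")
print(f"estimated noise sd {result.sigma:.3f}")
print(f"FSC(0.5) resolution of the average: {resolution:.1f} nm "
      "(half-set agreement; the study's regime is 4-5 nm)")
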