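"""Synthetic TIRF movie -> VWCM tracking -> angular statistics.

Generates a three-state hopping trace (orientations 120 degrees apart,
mean dwell 1.5 s, 7-degree wiggle), renders it as a noisy movie of a
290 nm lever-arm pointer (20 frames/s, 100 nm pixels), screens the
temporal-standard-deviation image, tracks the spot with the virtual-window
center-of-mass localizer, and recovers the center of motion, radius,
orientation clusters and angular velocities.
"""

import numpy as np

from camrotor import angular as ang
from camrotor import movie as mv
from camrotor import tracking as tk

trace, labels = mv.make_hopping_trace(mv.HopModel(), duration=60.0,
                                      dt=0.05, seed=3)
scene = mv.SceneSpec(field_size=(32, 32),
                     particles=[mv.ParticleSpec((15.5, 15.5))])
stack = mv.render_movie([trace], scene, seed=4)

std = tk.std_image(stack)
candidates = tk.detect_and_classify(std, stack)
print("detected:", [(c.kind, f"score {c.score:.1f}") for c in candidates])

track = tk.track_particle(stack, candidates[0])
gt = stack.ground_truth
err = np.hypot(track.x - gt.x_px.values, track.y - gt.y_px.values)
print(f"tracked {len(track)} frames, median error "
      f"{np.median(err[track.converged]):.3f} px vs ground truth")

fit = ang.fit_center(track)
seg = ang.to_angle_trace(track, fit, stack.frame_interval)[0]
_, mean_nm = ang.radius_distribution(track, fit, stack.pixel_size)
sa = ang.cluster_states(seg, k=3)
vel = ang.angular_velocities(seg)
print(f"center of motion ({fit.cx:.2f}, {fit.cy:.2f}) px, "
      f"mean radius {mean_nm:.0f} nm (designed 290 nm)")
print("orientation clusters (deg):", np.round(sa.centers, 1),
      "occupancies:", np.round(sa.occupancies, 2))
print(f"mean angular velocity {vel.weighted_mean:+.1f} deg/s "
      f"(SE {vel.weighted_sem:.1f}) -> no directional bias")
print(f"single-origin RMSD {ang.rmsd_single(seg):.0f} deg; "
      f"classification: {ang.classify_motion(seg)}")
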