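"""Rectify an image-plane track to floor coordinates and fill gaps.

A side-view camera sees the floor under a projective distortion; the
homography fitted from four floor landmarks maps pixel tracks to
centimetres.  Missing samples (occlusions) are filled by linear
interpolation during resampling to the 0.5-s grid.
"""

import numpy as np

import homebase as hb
from homebase.geometry import Homography
from homebase.tracking import RawTrack

# four floor landmarks: image pixels -> known cm positions
src = [(100.0, 80.0), (540.0, 95.0), (600.0, 400.0), (60.0, 380.0)]
dst = [(0.0, 0.0), (365.0, 0.0), (365.0, 545.0), (0.0, 545.0)]
H = hb.fit_homography(src, dst)
print("fitted homography (pixels -> cm):")
print(np.round(H.matrix, 4))

# a short raw track sampled every 15 frames at 30 fps, one occlusion
frames = np.arange(0, 8 * 15, 15)
u = np.array([150, 200, np.nan, 300, 350, 400, 430, 460], dtype=float)
v = np.array([120, 150, np.nan, 210, 240, 260, 280, 300], dtype=float)
track = RawTrack(frames, u, v)

pixel_traj = hb.interpolate_gaps(track, fps=30, step_frames=15)
floor = hb.apply_homography(H, np.column_stack([pixel_traj.x, pixel_traj.y]))
print(f"\nresampled {len(pixel_traj)} samples at dt = {pixel_traj.dt} s; "
      "first three floor positions (cm):")
print(np.round(floor[:3], 1))
# The occluded sample now lies on the straight segment between its
# tracked neighbours, and all positions are in room coordinates.
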