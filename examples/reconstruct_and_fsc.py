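"""Closed-loop reconstruction of a filament phantom with FSC resolution.

Renders 60 noisy side views of the extended-state phantom, reconstructs the
map at the known helical parameters (projection matching + r-weighted
back-projection + helical symmetrisation), and assesses the half-set
resolution at the FSC 0.5 threshold.  Runs in ~1 minute.
"""

import numpy as np

import helifil as hf
from helifil import _project
from helifil.helix_search import HelicalParams, helical_self_correlation
from helifil.reconstruct import reconstruct_filament, compute_fsc, resolution_at_threshold

BOX, PIXEL = 64, 4.0
phantom = hf.build_helical_volume(hf.extended_state(n_turns=3.0), BOX, PIXEL)
rng = np.random.default_rng(9)
segments = []
for _ in range(60):
    img = _project.project_volume(phantom.voxels.astype(float),
                                  rng.uniform(0, 360), 90.0, 0.0)
    segments.append(img + rng.normal(0, np.sqrt(img.var() / 0.2), img.shape))

hp = HelicalParams(pitch=110.0, twist=40.5)
vol = reconstruct_filament(segments, hp, PIXEL)

c = (BOX - 1) / 2
zz, yy, xx = np.mgrid[0:BOX, 0:BOX, 0:BOX]
mask = (np.hypot(yy - c, xx - c) <= 16) & (np.abs(zz - c) <= 19)
a = vol.voxels[mask] - vol.voxels[mask].mean()
b = phantom.voxels[mask] - phantom.voxels[mask].mean()
corr = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
print(f"map vs phantom correlation (central cylinder): {corr:.3f}")
print(f"helical self-consistency of the map:           "
      f"{helical_self_correlation(vol, hp):.3f}")

half1 = reconstruct_filament(segments[0::2], hp, PIXEL, align_rounds=1)
half2 = reconstruct_filament(segments[1::2], hp, PIXEL, align_rounds=1)
curve = compute_fsc(half1, half2)
res = resolution_at_threshold(curve, 0.5, voxel_size=PIXEL)
print(f"half-set FSC 0.5 resolution:                   {res:.1f} A"
      + ("  (no crossing: Nyquist-limited)" if curve.no_crossing else ""))
print("\nA correlation >= 0.9 means the closed loop (render -> corrupt -> "
      "reconstruct) recovers the phantom; self-consistency ~1 confirms the "
      "imposed helical symmetry.")
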