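"""Small helpers shared across test modules."""

from __future__ import annotations

import numpy as np

from helifil.imagio import RunConfig

WORK_BOX = 64
WORK_PIXEL = 4.0


def make_config(seed: int, **options) -> RunConfig:
    base = {
        "n_segments": 100, "box_size": WORK_BOX, "pixel_size": WORK_PIXEL,
        "snr": 0.1, "states": [{"name": "extended", "fraction": 1.0}],
        "tilt_sd": 5.0, "inplane_jitter": 5.0, "defocus": None,
    }
    base.update(options)
    return RunConfig(seed=seed, options=base)


def masked_volume_correlation(a: np.ndarray, b: np.ndarray,
                              radius_vox: float, half_z_vox: float) -> float:
    """Correlation of two cubic maps over a central cylindrical mask."""
    box = a.shape[0]
    c = (box - 1) / 2.0
    zz, yy, xx = np.mgrid[0:box, 0:box, 0:box]
    mask = (np.hypot(yy - c, xx - c) <= radius_vox) & (np.abs(zz - c) <= half_z_vox)
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    return float(av @ bv / (np.linalg.norm(av) * np.linalg.norm(bv)))
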