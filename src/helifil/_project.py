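"""Shared low-level geometry: projections, back-projection, screw resampling.

Conventions (package-wide):
  * volumes are (z, y, x) arrays; axis 0 (z) is the helical axis;
  * images are (row, col) with row = axial (z-like) coordinate;
  * Euler angles (phi, theta, psi) in degrees: the viewing direction is
    d = (sin t cos p, sin t sin p, cos t) in (x, y, z); theta = 90 is a side
    view, theta = 0 an end view; psi rotates the camera in its own plane;
  * all resampling is tri-/bi-linear (one interpolation rule, one tolerance
    source for the symmetry tests);
  * geometric centre of an n-box is (n - 1) / 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "euler_frame", "project_volume", "backproject_image", "screw_resample",
    "rotate_image", "shift_image", "ramp_filter_image", "max_ncc", "ncc",
]


def euler_frame(phi: float, theta: float, psi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Viewing direction and in-plane image axes for Euler angles (degrees).

    Returns ``(d, e_col, e_row)`` as (x, y, z) unit vectors: ``d`` is the ray
    direction, ``e_col`` spans image columns, ``e_row`` image rows.  For a
    side view (theta=90, psi=0) rows align with the helical (z) axis.
    """
    p, t, s = np.deg2rad([phi, theta, psi])
    d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    z = np.array([0.0, 0.0, 1.0])
    e_row = z - np.dot(z, d) * d
    if np.linalg.norm(e_row) < 1e-8:          # end view: rows along +y
        e_row = np.array([0.0, 1.0, 0.0])
    e_row /= np.linalg.norm(e_row)
    e_col = np.cross(e_row, d)
    # in-plane rotation by psi
    c, sn = np.cos(s), np.sin(s)
    e_col, e_row = c * e_col + sn * e_row, -sn * e_col + c * e_row
    return d, e_col, e_row


def _sample_coords(box: int, frame: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """(3, box, box, box) volume-index coordinates of the camera-aligned grid."""
    d, e_col, e_row = frame
    centre = (box - 1) / 2.0
    ax = np.arange(box) - centre
    # camera coords: (ray t, row i, col j) -> world xyz -> volume (z, y, x)
    tt, ii, jj = np.meshgrid(ax, ax, ax, indexing="ij")
    x = tt * d[0] + ii * e_row[0] + jj * e_col[0] + centre
    y = tt * d[1] + ii * e_row[1] + jj * e_col[1] + centre
    z = tt * d[2] + ii * e_row[2] + jj * e_col[2] + centre
    return np.stack([z, y, x])


def project_volume(voxels: np.ndarray, phi: float, theta: float, psi: float) -> np.ndarray:
    """Line-integral projection of a cubic volume along Euler direction.

    The integral is a sum over box tri-linear samples per ray (step = one
    voxel), so the projection sum equals the volume sum up to interpolation
    and edge clipping.
    """
    box = voxels.shape[0]
    coords = _sample_coords(box, euler_frame(phi, theta, psi))
    samples = ndimage.map_coordinates(voxels, coords.reshape(3, -1), order=1,
                                      mode="constant", cval=0.0, prefilter=False)
    return samples.reshape(box, box, box).sum(axis=0)


def backproject_image(img: np.ndarray, phi: float, theta: float, psi: float,
                      accum: np.ndarray, weight: np.ndarray | None = None) -> None:
    """Smear one image back along its viewing direction into ``accum``.

    Each voxel receives the bilinear image sample at its camera-plane
    position.  ``weight`` (same shape as accum) counts in-bounds hits so the
    caller can normalise.
    """
    box = accum.shape[0]
    _, e_col, e_row = euler_frame(phi, theta, psi)
    centre = (box - 1) / 2.0
    ax = np.arange(box) - centre
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    # world position -> camera plane (row, col); world (x,y,z) = (xx, yy, zz)
    rows = xx * e_row[0] + yy * e_row[1] + zz * e_row[2] + centre
    cols = xx * e_col[0] + yy * e_col[1] + zz * e_col[2] + centre
    vals = ndimage.map_coordinates(img, np.stack([rows.ravel(), cols.ravel()]),
                                   order=1, mode="constant", cval=0.0, prefilter=False)
    accum += vals.reshape(accum.shape)
    if weight is not None:
        inside = ((rows >= 0) & (rows <= box - 1) & (cols >= 0) & (cols <= box - 1))
        weight += inside.astype(weight.dtype)


def screw_resample(voxels: np.ndarray, angle_deg: float, shift_vox: float) -> np.ndarray:
    """Apply the helical screw operator: rotate about z by ``angle_deg`` and
    translate along z by ``shift_vox`` voxels (tri-linear resampling).

    Out-of-box samples are NaN so callers can mask them out of averages.
    """
    box = voxels.shape[0]
    centre = (box - 1) / 2.0
    ax = np.arange(box) - centre
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # source position of each output voxel under the inverse screw
    xs = c * xx + s * yy
    ys = -s * xx + c * yy
    zs = zz - shift_vox
    coords = np.stack([(zs + centre).ravel(), (ys + centre).ravel(), (xs + centre).ravel()])
    out = ndimage.map_coordinates(voxels, coords, order=1, mode="constant",
                                  cval=np.nan, prefilter=False)
    return out.reshape(voxels.shape)


def rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation (bilinear, fixed frame)."""
    if angle_deg == 0.0:
        return img
    return ndimage.rotate(img, angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def shift_image(img: np.ndarray, shift_rows: float, shift_cols: float) -> np.ndarray:
    """Subpixel translation (bilinear)."""
    return ndimage.shift(img, (shift_rows, shift_cols), order=1,
                         mode="constant", cval=0.0, prefilter=False)


def ramp_filter_image(img: np.ndarray, axis: int = 1) -> np.ndarray:
    """|f| ramp filter along one image axis (the r-weighting of single-axis
    filtered back-projection)."""
    n = img.shape[axis]
    f = np.abs(np.fft.fftfreq(n))
    spec = np.fft.fft(img, axis=axis)
    shape = [1, 1]
    shape[axis] = n
    return np.real(np.fft.ifft(spec * f.reshape(shape), axis=axis))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Plain normalised cross-correlation of two equally shaped images."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def max_ncc(a: np.ndarray, b: np.ndarray,
            max_shift_rows: int | None = None,
            max_shift_cols: int | None = None,
            return_shift: bool = False):
    """Maximum circular normalised cross-correlation over translations.

    Shifts are of ``b`` relative to ``a`` and can be restricted to
    ``|rows| <= max_shift_rows`` and ``|cols| <= max_shift_cols``.  Circular
    wrap-around is acceptable for filament boxes: the axial direction is
    (near-)periodic with the pitch and transverse shifts are kept small.
    """
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.linalg.norm(a0) * np.linalg.norm(b0)
    if denom == 0:
        return (0.0, (0, 0)) if return_shift else 0.0
    cc = np.fft.irfft2(np.fft.rfft2(a0) * np.conj(np.fft.rfft2(b0)), s=a.shape)
    n_r, n_c = a.shape
    mask = np.zeros(a.shape, dtype=bool)
    mr = n_r // 2 if max_shift_rows is None else int(max_shift_rows)
    mc = n_c // 2 if max_shift_cols is None else int(max_shift_cols)
    rows = (np.arange(n_r) + n_r // 2) % n_r - n_r // 2
    cols = (np.arange(n_c) + n_c // 2) % n_c - n_c // 2
    mask[np.ix_(np.abs(rows) <= mr, np.abs(cols) <= mc)] = True
    cc_masked = np.where(mask, cc, -np.inf)
    idx = np.unravel_index(np.argmax(cc_masked), cc.shape)
    best = float(cc[idx] / denom)
    if return_shift:
        shift = (rows[idx[0]], cols[idx[1]])
        return best, shift
    return best
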