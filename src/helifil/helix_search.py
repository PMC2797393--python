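"""Helical-parameter inference: two-stage (pitch, twist) grid search.

The search scores every candidate (pitch, twist) node by error minimisation
between the class averages and side-view reprojections of a helically
symmetric reference carrying the node's symmetry.  The reference is a
*parametric helical lattice*: one generic Gaussian protomer repeated by the
node's screw operator at the filament radius estimated from the data's own
transverse profile, plus an axial DNA-like thread.  Because the reference is
rebuilt from the node parameters alone (never from aligned images), the
error surface carries no alignment-reference bias — a data-derived reference
locks the apparent twist to whatever symmetry seeded its alignment.

The error per class average is 1 - max normalised cross-correlation over the
reprojection azimuths (one asymmetric unit), axial shifts up to half a
pitch (with sub-pixel parabolic peak refinement), a small transverse shift,
and in-plane rotation.  The search runs on a coarse grid first (increments
3.2 A and 2 degrees, twist 35-48 by default) and then on a fine grid
(0.5 A / 0.5 degrees) around the coarse minimum.

Class averages mix segments with small out-of-plane tilts and residual
in-plane rotations, which foreshortens the apparent axial periodicity by
E[cos theta] within each average; the reported pitch can be corrected for
this known bias via :func:`foreshortening_factor`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _project
from .imagio import VolumeGrid

__all__ = [
    "HelicalParams", "SearchGrid", "ErrorSurface", "RefinedParams",
    "symmetrize", "reproject_model", "match_error", "grid_search",
    "refine_minimum", "search_helical_params", "estimate_filament_radius",
    "ParametricReferenceBuilder", "foreshortening_factor",
    "helical_self_correlation",
    "COARSE_GRID_DEFAULT", "COARSE_GRID_RECA", "COARSE_GRID_DSDNA",
]


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry of one filament state."""

    pitch: float                 # A per turn
    twist: float                 # degrees per protomer
    diameter: float | None = None

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not 0 < self.twist < 360:
            raise ValueError(f"twist must be in (0, 360), got {self.twist}")

    @property
    def rise(self) -> float:
        """Axial rise per protomer, pitch * twist / 360 (A)."""
        return self.pitch * self.twist / 360.0


def _axis_values(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class SearchGrid:
    """Rectangular (pitch, twist) search grid."""

    pitch_range: tuple[float, float]
    pitch_step: float
    twist_range: tuple[float, float]
    twist_step: float

    def __post_init__(self):
        if self.pitch_step <= 0 or self.twist_step <= 0:
            raise ValueError("grid steps must be positive")
        if not (self.pitch_range[1] >= self.pitch_range[0]
                and self.twist_range[1] >= self.twist_range[0]):
            raise ValueError("grid ranges must be non-degenerate")

    @property
    def pitches(self) -> np.ndarray:
        return _axis_values(*self.pitch_range, self.pitch_step)

    @property
    def twists(self) -> np.ndarray:
        return _axis_values(*self.twist_range, self.twist_step)


# Coarse increments 3.2 A / 2 deg; twist searched over 35-48 deg; the pitch
# range brackets both filament states.  RecA-like and dsDNA-like presets use
# 3-degree twist steps over their wider ranges.
COARSE_GRID_DEFAULT = SearchGrid((80.0, 130.0), 3.2, (35.0, 48.0), 2.0)
COARSE_GRID_RECA = SearchGrid((60.0, 110.0), 3.2, (40.0, 70.0), 3.0)
COARSE_GRID_DSDNA = SearchGrid((80.0, 130.0), 3.2, (30.0, 70.0), 3.0)


@dataclass
class ErrorSurface:
    """Matching error over a (pitch, twist) grid with its ranked minima."""

    grid: SearchGrid
    error: np.ndarray                       # (n_pitch, n_twist)
    minima: list[tuple[float, float, float]] = field(default_factory=list)
    # each minimum is (pitch, twist, error), ranked by error

    def global_minimum(self) -> tuple[float, float, float]:
        return self.minima[0]


@dataclass
class RefinedParams:
    params: HelicalParams
    error: float
    at_boundary: bool
    surface: ErrorSurface


# ---------------------------------------------------------------------------
# symmetrisation and reprojection

def symmetrize(vol: VolumeGrid, hp: HelicalParams, z_fraction: float = 0.6,
               max_copies: int | None = None) -> VolumeGrid:
    """Average the map over its helical screw operator.

    Every voxel is replaced by the mean over all in-box copies under
    k * (twist, rise); only source samples whose z lies inside the central
    ``z_fraction`` of the box are trusted.  Output voxels with no trusted
    source keep their input value.
    """
    if not 0 < z_fraction <= 1:
        raise ValueError("z_fraction must be in (0, 1]")
    rise_vox = hp.rise / vol.voxel_size
    if rise_vox < 1.0:
        raise ValueError(f"rise {hp.rise:.2f} A is below one voxel "
                         f"({vol.voxel_size} A): symmetry undersampled")
    box = vol.box_size
    centre = (box - 1) / 2.0
    half_trust = z_fraction * box / 2.0
    k_lim = int(math.floor((box / 2.0 + half_trust) / rise_vox))
    if max_copies is not None:
        k_lim = min(k_lim, max_copies)
    vox = vol.voxels.astype(np.float64)
    acc = np.zeros_like(vox)
    cnt = np.zeros_like(vox)
    z_idx = np.arange(box)
    ax = z_idx - centre
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    from scipy import ndimage
    for k in range(-k_lim, k_lim + 1):
        src_z = z_idx - k * rise_vox
        valid_z = np.abs(src_z - centre) <= half_trust
        if not valid_z.any():
            continue
        zs = np.nonzero(valid_z)[0]
        if k == 0:
            acc[zs] += vox[zs]
            cnt[zs] += 1.0
            continue
        a = math.radians(k * hp.twist)
        c, s = math.cos(a), math.sin(a)
        xsrc = c * xx + s * yy + centre
        ysrc = -s * xx + c * yy + centre
        # only the output slab whose source z sits in the trusted region
        zsrc = zs - k * rise_vox
        coords = np.stack([
            np.repeat(zsrc, box * box),
            np.tile(ysrc.ravel(), len(zs)),
            np.tile(xsrc.ravel(), len(zs)),
        ])
        samples = ndimage.map_coordinates(vox, coords, order=1, mode="constant",
                                          cval=np.nan, prefilter=False)
        slab = samples.reshape(len(zs), box, box)
        good = np.isfinite(slab)
        acc[zs] += np.where(good, slab, 0.0)
        cnt[zs] += good
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), vox)
    return VolumeGrid(voxels=out.astype(np.float32), voxel_size=vol.voxel_size)


def helical_self_correlation(vol: VolumeGrid, hp: HelicalParams) -> float:
    """Correlation of a map with itself under its own (twist, rise) operator,
    over the voxels the resampling keeps in-box."""
    rise_vox = hp.rise / vol.voxel_size
    moved = _project.screw_resample(vol.voxels.astype(np.float64), hp.twist, rise_vox)
    good = np.isfinite(moved)
    a = vol.voxels.astype(np.float64)[good]
    b = moved[good]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def reproject_model(vol: VolumeGrid, hp: HelicalParams, n_azimuths: int) -> list[np.ndarray]:
    """Side-view projections at azimuths spanning one asymmetric unit [0, twist)."""
    if n_azimuths < 1:
        raise ValueError("n_azimuths must be >= 1")
    vox = vol.voxels.astype(np.float64)
    return [_project.project_volume(vox, i * hp.twist / n_azimuths, 90.0, 0.0)
            for i in range(n_azimuths)]


# ---------------------------------------------------------------------------
# the parametric reference

def estimate_filament_radius(class_avgs: list[np.ndarray], pixel_size: float,
                             exclude_radius: float = 30.0) -> float:
    """Filament (protomer centre-of-mass) radius from the transverse profile.

    Side-view projections of a helical shell show density rails near +-R;
    the estimator averages the outer-peak positions of the mean transverse
    profile, ignoring the central DNA/axis region (``exclude_radius``, A).
    """
    box = class_avgs[0].shape[0]
    centre = (box - 1) / 2.0
    x = (np.arange(box) - centre) * pixel_size
    profile = np.mean([img.mean(axis=0) for img in class_avgs], axis=0)
    peaks = []
    for side in (x < -exclude_radius, x > exclude_radius):
        if side.any():
            idx = np.nonzero(side)[0]
            peaks.append(abs(x[idx[np.argmax(profile[idx])]]))
    if not peaks:
        raise ValueError("box too small to estimate a filament radius")
    r = float(np.mean(peaks))
    return float(np.clip(r, exclude_radius, box * pixel_size / 2 - 15.0))


class ParametricReferenceBuilder:
    """Builds the per-node reference: a generic helical lattice.

    One isotropic Gaussian protomer (``blob_sigma``) is repeated by the
    node's screw operator at the filament radius estimated once from the
    class averages, with an axial thread standing in for the DNA.  The
    reference encodes only the candidate symmetry plus the data's gross
    radial geometry — deliberately nothing that had to be aligned, so the
    error surface cannot inherit a twist from a starting model.
    """

    def __init__(self, blob_sigma: float = 6.0, dna_sigma: float = 5.0,
                 dna_weight: float = 0.3, radius: float | None = None):
        self.blob_sigma = blob_sigma
        self.dna_sigma = dna_sigma
        self.dna_weight = dna_weight
        self.radius = radius

    def __call__(self, class_avgs: list[np.ndarray], hp: HelicalParams,
                 pixel_size: float) -> VolumeGrid:
        from .synthfil import (GaussianBlob, DnaThread, HelicalModel,
                               build_helical_volume)
        if self.radius is None:
            self.radius = estimate_filament_radius(class_avgs, pixel_size)
        box = class_avgs[0].shape[0]
        model = HelicalModel(
            pitch=hp.pitch, twist=hp.twist, filament_radius=self.radius,
            protomer=(GaussianBlob((0.0, 0.0, 0.0), self.blob_sigma, 1.0),),
            axial_dna=DnaThread(radius=self.dna_sigma, weight=self.dna_weight),
            n_turns=box * pixel_size / hp.pitch + 1.0)
        return build_helical_volume(model, box, pixel_size)


def foreshortening_factor(tilt_sd: float = 0.0, psi_halfwidth: float = 0.0) -> float:
    """Expected axial foreshortening of class averages, E[cos tilt]E[cos psi].

    Out-of-plane tilts ~ N(0, tilt_sd) and residual in-plane rotations
    ~ U(-psi_halfwidth, +psi_halfwidth) (degrees) compress the apparent
    axial periodicity of every segment by cos(angle); class averages mix
    segments, so the bias cannot be searched away and is instead divided
    out of the reported pitch.
    """
    t = math.radians(tilt_sd)
    p = math.radians(psi_halfwidth)
    e_tilt = math.exp(-t * t / 2.0)
    e_psi = math.sin(p) / p if p > 0 else 1.0
    return e_tilt * e_psi


# ---------------------------------------------------------------------------
# matching

def _column_mask(box: int, half_width_px: int) -> np.ndarray:
    mask = np.zeros((box, box))
    centre = (box - 1) / 2.0
    mask[:, np.abs(np.arange(box) - centre) <= half_width_px] = 1.0
    return mask


def _prepare(img: np.ndarray, mask: np.ndarray | None):
    x = img * mask if mask is not None else np.asarray(img, dtype=float)
    x = x - x.mean()
    norm = np.linalg.norm(x)
    return np.fft.rfft2(x), norm


def _best_ncc(f_a, norm_a, f_b, norm_b, shape, max_rows: int, max_cols: int,
              subpixel: bool = True) -> float:
    """Max windowed circular NCC with parabolic sub-pixel refinement along
    the (axial) row direction."""
    if norm_a == 0 or norm_b == 0:
        return 0.0
    cc = np.fft.irfft2(f_a * np.conj(f_b), s=shape)
    n_r, n_c = shape
    rows = (np.arange(n_r) + n_r // 2) % n_r - n_r // 2
    cols = (np.arange(n_c) + n_c // 2) % n_c - n_c // 2
    window = np.ix_(np.abs(rows) <= max_rows, np.abs(cols) <= max_cols)
    masked = np.full(shape, -np.inf)
    masked[window] = cc[window]
    i, j = np.unravel_index(np.argmax(masked), shape)
    val = cc[i, j]
    if subpixel:
        ym, yp = cc[(i - 1) % n_r, j], cc[(i + 1) % n_r, j]
        denom = ym - 2 * val + yp
        if denom < -1e-12:
            d = float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
            val = max(val, val + 0.5 * (yp - ym) * d + 0.5 * denom * d * d)
    return float(val / (norm_a * norm_b))


def match_error(class_avg: np.ndarray, reprojections: list[np.ndarray],
                pixel_size: float, pitch: float,
                rot_range: float = 10.0, rot_step: float = 5.0,
                max_transverse_px: int = 3,
                mask: np.ndarray | None = None) -> float:
    """1 - max normalised cross-correlation between a class average and the
    reprojections, maximised over axial shift (+- pitch/2, sub-pixel),
    a small transverse shift, and in-plane rotation (+- rot_range degrees).

    Lies in [0, 2]; 0 iff some reprojection equals the class average up to
    the searched alignment.
    """
    if class_avg.shape != reprojections[0].shape:
        raise ValueError(f"box mismatch: {class_avg.shape} vs {reprojections[0].shape}")
    max_axial = max(1, int(round(pitch / 2.0 / pixel_size)))
    angles = (np.arange(-rot_range, rot_range + rot_step / 2, rot_step)
              if rot_range > 0 else np.array([0.0]))
    projs = [_prepare(p, mask) for p in reprojections]
    best = -1.0
    for ang in angles:
        f_img, n_img = _prepare(_project.rotate_image(class_avg, float(ang)), mask)
        for f_p, n_p in projs:
            c = _best_ncc(f_p, n_p, f_img, n_img, class_avg.shape,
                          max_axial, max_transverse_px)
            if c > best:
                best = c
    return 1.0 - best


# ---------------------------------------------------------------------------
# the grid search

def _node_filter(pixel_size: float):
    from .preprocess import FilterParams, band_pass
    fp = FilterParams(high_cutoff=max(7.0, 2.25 * pixel_size))
    return lambda img: band_pass(img, fp, pixel_size)


def grid_search(class_avgs: list[np.ndarray], grid: SearchGrid, pixel_size: float,
                n_azimuths: int = 12, rot_range: float = 10.0,
                rot_step: float = 5.0, max_transverse_px: int = 3,
                reference_builder=None, band_limit: bool = True) -> ErrorSurface:
    """Error surface over a (pitch, twist) grid.

    For each node, the reference builder produces a helically symmetric
    volume with the node's parameters; its side-view reprojections over one
    asymmetric unit are band-passed like the data and scored by the mean
    :func:`match_error` over the class averages, inside a transverse mask
    around the filament.  Deterministic: a pure function of (class averages,
    grid, settings).
    """
    if len(class_avgs) < 1:
        raise ValueError("need at least one class average")
    box = class_avgs[0].shape[0]
    builder = reference_builder or ParametricReferenceBuilder()
    radius = getattr(builder, "radius", None)
    if radius is None and isinstance(builder, ParametricReferenceBuilder):
        builder(class_avgs, HelicalParams(100.0, 40.0), pixel_size)  # fix radius
        radius = builder.radius
    half_width_px = int(math.ceil(((radius or box * pixel_size / 4) + 15.0) / pixel_size))
    mask = _column_mask(box, min(half_width_px, box // 2 - 1))
    filt = _node_filter(pixel_size) if band_limit else (lambda x: x)

    angles = (np.arange(-rot_range, rot_range + rot_step / 2, rot_step)
              if rot_range > 0 else np.array([0.0]))
    prepared_avgs = [[_prepare(_project.rotate_image(img, float(a)), mask)
                      for a in angles] for img in class_avgs]

    pitches, twists = grid.pitches, grid.twists
    error = np.full((len(pitches), len(twists)), np.nan)
    for ip, pitch in enumerate(pitches):
        max_axial = max(1, int(round(pitch / 2.0 / pixel_size)))
        for it, twist in enumerate(twists):
            hp = HelicalParams(pitch=float(pitch), twist=float(twist))
            ref = builder(class_avgs, hp, pixel_size)
            projs = [_prepare(filt(p), mask)
                     for p in reproject_model(ref, hp, n_azimuths)]
            total = 0.0
            for rotations in prepared_avgs:
                best = -1.0
                for f_img, n_img in rotations:
                    for f_p, n_p in projs:
                        c = _best_ncc(f_p, n_p, f_img, n_img, (box, box),
                                      max_axial, max_transverse_px)
                        if c > best:
                            best = c
                total += 1.0 - best
            error[ip, it] = total / len(class_avgs)
    if np.isnan(error).all():
        raise RuntimeError("grid search produced an all-NaN error surface")
    surface = ErrorSurface(grid=grid, error=error)
    surface.minima = _ranked_minima(pitches, twists, error)
    return surface


def _ranked_minima(pitches, twists, error) -> list[tuple[float, float, float]]:
    """Local minima of the surface (4-neighbourhood, <=), ranked by error;
    ties broken by (pitch, twist) lexicographic order, which the row-major
    scan provides."""
    minima = []
    np_, nt = error.shape
    for i in range(np_):
        for j in range(nt):
            e = error[i, j]
            neighbours = []
            if i > 0:
                neighbours.append(error[i - 1, j])
            if i < np_ - 1:
                neighbours.append(error[i + 1, j])
            if j > 0:
                neighbours.append(error[i, j - 1])
            if j < nt - 1:
                neighbours.append(error[i, j + 1])
            if all(e <= nb for nb in neighbours):
                minima.append((float(pitches[i]), float(twists[j]), float(e)))
    minima.sort(key=lambda m: (m[2], m[0], m[1]))
    return minima


def refine_minimum(class_avgs: list[np.ndarray], seed_params: HelicalParams,
                   fine: SearchGrid, pixel_size: float, **search_kw) -> RefinedParams:
    """Fine-grid refinement around an established coarse minimum.

    A minimum landing on the fine-grid boundary sets ``at_boundary`` (range
    too small) with a warning.
    """
    surface = grid_search(class_avgs, fine, pixel_size, **search_kw)
    pitch, twist, err = surface.global_minimum()
    pitches, twists = fine.pitches, fine.twists
    on_edge = (pitch in (pitches[0], pitches[-1])) or (twist in (twists[0], twists[-1]))
    if on_edge:
        warnings.warn(f"fine-grid minimum at boundary (pitch {pitch}, twist {twist}): "
                      "consider widening the range")
    return RefinedParams(params=HelicalParams(pitch=pitch, twist=twist),
                         error=err, at_boundary=on_edge, surface=surface)


def search_helical_params(class_avgs: list[np.ndarray], pixel_size: float,
                          coarse: SearchGrid = COARSE_GRID_DEFAULT,
                          fine_step_pitch: float = 0.5,
                          fine_step_twist: float = 0.5,
                          fine_half_extent: tuple[float, float] | None = None,
                          jitter: tuple[float, float] | None = None,
                          **search_kw) -> tuple[RefinedParams, ErrorSurface]:
    """The full two-stage search: coarse grid, then fine grid at the minimum.

    ``jitter = (tilt_sd, psi_halfwidth)`` in degrees enables the
    foreshortening correction of the reported pitch (see
    :func:`foreshortening_factor`).  Returns (refined result, coarse
    surface); the fine grid spans one coarse step around the coarse minimum
    unless ``fine_half_extent`` overrides it.
    """
    coarse_surface = grid_search(class_avgs, coarse, pixel_size, **search_kw)
    p0, t0, _ = coarse_surface.global_minimum()
    half = fine_half_extent or (coarse.pitch_step, coarse.twist_step)
    fine = SearchGrid(
        pitch_range=(max(p0 - half[0], 1e-3), p0 + half[0]),
        pitch_step=fine_step_pitch,
        twist_range=(max(t0 - half[1], 1e-3), t0 + half[1]),
        twist_step=fine_step_twist,
    )
    refined = refine_minimum(class_avgs, HelicalParams(pitch=p0, twist=t0),
                             fine, pixel_size, **search_kw)
    if jitter is not None:
        factor = foreshortening_factor(*jitter)
        corrected = HelicalParams(pitch=refined.params.pitch / factor,
                                  twist=refined.params.twist)
        refined = RefinedParams(params=corrected, error=refined.error,
                                at_boundary=refined.at_boundary,
                                surface=refined.surface)
    return refined, coarse_surface
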