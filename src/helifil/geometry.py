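"""Helical-geometry algebra and map measurements.

A helical filament is described by its pitch P (axial distance per 360-degree
turn, in Angstrom) and its twist (azimuthal rotation between successive
protomers, in degrees).  Everything else follows:

    protomers per turn   n = 360 / twist
    axial rise/protomer  d = P / n = P * twist / 360

The stoichiometry helpers report at the one-decimal precision customary for
negative-stain work (raw doubles are always returned alongside); the map
measurements (radial density profile, sigma-threshold diameters) reproduce the
way filament and inner-channel diameters are read off an isosurface of a 3D
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StoichiometryReport",
    "RadialProfile",
    "protomers_per_turn",
    "rise_per_protomer",
    "nucleotides_per_protomer",
    "nucleotides_per_turn",
    "radial_density_profile",
    "measure_diameters",
]


@dataclass(frozen=True)
class StoichiometryReport:
    """Stoichiometric description of one helical filament state."""

    protomers_per_turn: float
    protomers_per_turn_raw: float
    rise_per_protomer: float | None = None
    nt_per_protomer: float | None = None
    nt_per_turn: float | None = None


@dataclass
class RadialProfile:
    """Rotationally averaged density versus radius about the helical axis.

    ``sigma`` is the standard deviation of the full map (solvent included),
    the unit in which isosurface thresholds are quoted.
    """

    radii: np.ndarray  # bin centres, Angstrom
    density: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.radii.ndim != 1 or self.radii.shape != self.density.shape:
            raise ValueError("radii and density must be matching 1-D arrays")
        if len(self.radii) > 1 and not np.all(np.diff(self.radii) > 0):
            raise ValueError("radius bins must be strictly increasing")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("profile contains non-finite density")


def protomers_per_turn(twist: float) -> tuple[float, float]:
    """Number of protomers per helical turn, 360/twist.

    Parameters
    ----------
    twist : float
        Rotation between successive protomers, degrees, in (0, 360].

    Returns
    -------
    (reported, raw) : tuple of float
        ``reported`` is rounded to one decimal; ``raw`` is the exact quotient.
    """
    if not 0 < twist <= 360:
        raise ValueError(f"twist must be in (0, 360] degrees, got {twist}")
    raw = 360.0 / twist
    return round(raw, 1), raw


def rise_per_protomer(pitch: float, twist: float) -> float:
    """Axial rise per protomer, pitch * twist / 360 (Angstrom)."""
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    if not 0 < twist <= 360:
        raise ValueError(f"twist must be in (0, 360] degrees, got {twist}")
    return pitch * twist / 360.0


def nucleotides_per_protomer(n_nucleotides: float, n_protomers_spanned: float) -> tuple[float, float]:
    """Nucleotides covered by one protomer: nt count / protomers spanned.

    Returns (one-decimal report, raw quotient).
    """
    if n_nucleotides <= 0:
        raise ValueError("n_nucleotides must be positive")
    if n_protomers_spanned <= 0:
        raise ValueError("n_protomers_spanned must be positive")
    raw = n_nucleotides / n_protomers_spanned
    return round(raw, 1), raw


def nucleotides_per_turn(protomers_per_turn_: float, nt_per_protomer: float) -> tuple[int, float]:
    """Nucleotides per helical turn: protomers/turn x nt/protomer.

    Returns (nearest-integer report, raw product).
    """
    if protomers_per_turn_ <= 0 or nt_per_protomer <= 0:
        raise ValueError("both factors must be positive")
    raw = protomers_per_turn_ * nt_per_protomer
    return int(round(raw)), raw


def stoichiometry(pitch: float, twist: float,
                  n_nucleotides: float | None = None,
                  n_protomers_spanned: float | None = None) -> StoichiometryReport:
    """Full stoichiometry report for one filament state."""
    ppt_rep, ppt_raw = protomers_per_turn(twist)
    nt_pp = nt_pt = None
    if n_nucleotides is not None and n_protomers_spanned is not None:
        nt_pp, _ = nucleotides_per_protomer(n_nucleotides, n_protomers_spanned)
        nt_pt = nucleotides_per_turn(ppt_rep, nt_pp)[0]
    return StoichiometryReport(
        protomers_per_turn=ppt_rep,
        protomers_per_turn_raw=ppt_raw,
        rise_per_protomer=rise_per_protomer(pitch, twist),
        nt_per_protomer=nt_pp,
        nt_per_turn=nt_pt,
    )


def radial_density_profile(vol, axis: str = "z") -> RadialProfile:
    """Rotationally averaged density versus radius about the helical axis.

    ``vol`` is a VolumeGrid (cubic array, z = axis 0 = helical axis).  Bin
    width is one voxel.
    """
    if axis != "z":
        raise ValueError("only the z helical axis is supported")
    voxels = np.asarray(vol.voxels, dtype=float)
    if voxels.max() == voxels.min():
        raise ValueError("constant map has no radial profile")
    n = voxels.shape[1]
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_px = np.hypot(yy - centre, xx - centre)
    bins = np.arange(0, n // 2 + 1)  # voxel-width bins
    idx = np.clip(r_px.astype(int), 0, len(bins) - 1)
    # accumulate over all z slices at once
    flat = idx.ravel()
    counts = np.bincount(flat, minlength=len(bins)) * voxels.shape[0]
    sums = np.zeros(len(bins))
    plane_sum = voxels.sum(axis=0).ravel()
    np.add.at(sums, flat, plane_sum)
    density = sums / np.maximum(counts, 1)
    radii = (bins + 0.5) * vol.voxel_size
    keep = bins < n // 2
    return RadialProfile(radii=radii[keep], density=density[keep],
                         sigma=float(voxels.std()))


def measure_diameters(profile: RadialProfile, sigma_threshold: float = 1.0) -> tuple[float, float]:
    """Outer and inner-channel diameters at a sigma isosurface threshold.

    The outer diameter is twice the largest radius at which the rotationally
    averaged density still reaches ``sigma_threshold`` map standard deviations;
    the inner channel is twice the largest radius *below the main density
    peak* at which the profile falls under the threshold (0 if the density
    extends to the axis).
    """
    thr = sigma_threshold * profile.sigma
    above = profile.density >= thr
    if not above.any():
        raise ValueError("threshold above profile maximum: nothing to measure")
    outer_idx = np.nonzero(above)[0][-1]
    outer_d = 2.0 * profile.radii[outer_idx]
    peak_idx = int(np.argmax(profile.density))
    below_peak = np.nonzero(~above[:peak_idx])[0]
    inner_d = 2.0 * profile.radii[below_peak[-1]] if len(below_peak) else 0.0
    return float(outer_d), float(inner_d)
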