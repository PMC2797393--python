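"""Synthetic helical-filament data generator.

Builds 3-D density models of protein--DNA helical filaments from Gaussian
blobs, renders noisy projection images (side-view segments, end views,
C8 rings) through an optional contrast-transfer function, and assembles
whole datasets with ground-truth metadata — so every downstream stage of the
pipeline can be exercised against known helical parameters.

The default study conditions emulate negative-stain data of recombinase
filaments on ssDNA: 160 x 160 px segments at 1.59 A/px, a ~70/25/5 mixture of
an extended state (pitch 110 A, twist 40.5 deg), a compressed state (96 A,
42.5 deg) and a heavily noised junk class, side views with small out-of-plane
tilt, 100 kV optics at 1.2 um underfocus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _project
from .imagio import ImageStack, VolumeGrid, RunConfig, ConfigError

__all__ = [
    "GaussianBlob", "DnaThread", "HelicalModel", "CTFParams", "ImagingParams",
    "extended_state", "compressed_state", "reca_state", "dsdna_state", "c8_ring",
    "build_helical_volume", "render_projection", "apply_ctf", "ctf_2d",
    "add_noise", "generate_dataset", "electron_wavelength",
]


@dataclass(frozen=True)
class GaussianBlob:
    """One Gaussian density lobe in the protomer frame.

    The protomer frame places the protomer centre of mass at (x=R, y=0, z=0)
    with x radial, y azimuthal and z axial; ``offset`` is the (x, y, z)
    displacement from that centre, Angstrom.
    """
    offset: tuple[float, float, float]
    sigma: float
    weight: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0 or self.weight <= 0:
            raise ValueError("blob sigma and weight must be positive")


@dataclass(frozen=True)
class DnaThread:
    """On-axis density thread standing in for the bound DNA."""
    radius: float          # Gaussian sigma of the tube cross-section, A
    weight: float = 0.3    # peak density relative to protomer blob peak


@dataclass(frozen=True)
class HelicalModel:
    """Helical filament: protomer blobs repeated by the screw operator."""

    pitch: float                       # A per 360-degree turn
    twist: float                       # degrees per protomer
    filament_radius: float             # protomer centre-of-mass radius, A
    protomer: tuple[GaussianBlob, ...]
    axial_dna: DnaThread | None = None
    n_turns: float = 4.0               # helical turns of protomers to build
    name: str = "model"

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not 0 < self.twist <= 360:
            raise ValueError(f"twist must be in (0, 360], got {self.twist}")
        if len(self.protomer) < 1:
            raise ValueError("protomer needs at least one blob")

    @property
    def rise(self) -> float:
        return self.pitch * self.twist / 360.0

    @property
    def max_sigma(self) -> float:
        return max(b.sigma for b in self.protomer)


@dataclass(frozen=True)
class CTFParams:
    """Contrast transfer function of the microscope (underfocus positive)."""

    defocus: float                    # A
    wavelength: float                 # A
    spherical_aberration: float = 2.0 # mm
    amplitude_contrast: float = 0.10  # fraction

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 <= self.amplitude_contrast <= 1:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass(frozen=True)
class ImagingParams:
    """Image formation settings for one rendered dataset."""

    box_size: int = 160
    pixel_size: float = 1.59          # A / px
    snr: float = 0.1                  # signal variance / noise variance
    seed: int = 0

    def __post_init__(self):
        if self.box_size < 16 or self.box_size % 2:
            raise ValueError("box_size must be even and >= 16")
        if not (self.snr > 0 or math.isinf(self.snr)):
            raise ValueError("snr must be positive (or inf)")


def electron_wavelength(kv: float = 100.0) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    v = kv * 1e3
    return 12.2639 / math.sqrt(v * (1 + 0.97845e-6 * v))


# ---------------------------------------------------------------------------
# model presets (two-lobed protomer: large core lobe L + smaller lobe S)

def _two_lobe_protomer(r_s: float = 12.0) -> tuple[GaussianBlob, ...]:
    # Large core lobe L: a ~20 A domain modelled as four compact sub-blobs
    # (sigma 4.5 A) about the protomer centre of mass; small lobe S: two
    # sub-blobs (sigma 4 A) further out, axially offset toward the
    # neighbouring protomer.  Compact sub-blobs give the protomer genuine
    # density contrast at the inter-protomer lattice spacing (~12 A axial),
    # without which the twist would be invisible to side-view projections;
    # the envelope of each lobe still spans the L (~20 A) / S (~12 A) scale.
    return (
        GaussianBlob(offset=(0.0, 0.0, 0.0), sigma=4.5, weight=1.0),
        GaussianBlob(offset=(6.0, 4.0, -4.0), sigma=4.5, weight=0.9),
        GaussianBlob(offset=(-5.0, 6.0, 3.0), sigma=4.5, weight=0.9),
        GaussianBlob(offset=(1.0, -6.0, 4.0), sigma=4.5, weight=0.8),
        GaussianBlob(offset=(r_s, 6.0, 6.0), sigma=4.0, weight=0.5),
        GaussianBlob(offset=(r_s - 2.0, 9.0, 9.0), sigma=4.0, weight=0.4),
    )


def extended_state(**kw) -> HelicalModel:
    """Extended (active, ATP-like) filament: pitch 110 A, twist 40.5 deg."""
    defaults = dict(pitch=110.0, twist=40.5, filament_radius=54.0,
                    protomer=_two_lobe_protomer(),
                    axial_dna=DnaThread(radius=4.5), name="extended")
    defaults.update(kw)
    return HelicalModel(**defaults)


def compressed_state(**kw) -> HelicalModel:
    """Compressed (inactive, ADP-like) filament: pitch 96 A, twist 42.5 deg."""
    defaults = dict(pitch=96.0, twist=42.5, filament_radius=65.0,
                    protomer=_two_lobe_protomer(),
                    axial_dna=DnaThread(radius=7.5), name="compressed")
    defaults.update(kw)
    return HelicalModel(**defaults)


def reca_state(**kw) -> HelicalModel:
    """RecA-ssDNA-like filament: pitch 82 A, twist 59 deg."""
    defaults = dict(pitch=82.0, twist=59.0, filament_radius=53.0,
                    protomer=_two_lobe_protomer(),
                    axial_dna=DnaThread(radius=4.5), name="reca")
    defaults.update(kw)
    return HelicalModel(**defaults)


def dsdna_state(**kw) -> HelicalModel:
    """dsDNA-bound filament: pitch 106 A, twist 56.5 deg, thinner."""
    defaults = dict(pitch=106.0, twist=56.5, filament_radius=49.0,
                    protomer=_two_lobe_protomer(),
                    axial_dna=DnaThread(radius=7.0), name="dsdna")
    defaults.update(kw)
    return HelicalModel(**defaults)


def c8_ring(ring_radius: float = 48.0) -> HelicalModel:
    """Planar 8-fold ring (the DNA-free octamer): twist 45 deg, no rise.

    Uses the same two-lobed protomer as the filaments — the ring is the same
    protein, so its angular contrast is comparable to an end view.
    """
    return HelicalModel(pitch=1e-6, twist=45.0, filament_radius=ring_radius,
                        protomer=_two_lobe_protomer(),
                        axial_dna=None, n_turns=1.0, name="ring_c8")


# ---------------------------------------------------------------------------
# forward model

def build_helical_volume(model: HelicalModel, box: int, voxel: float) -> VolumeGrid:
    """Render a helical model as a cubic density map (z = helical axis).

    Protomer copy ``k`` sits at azimuth ``k * twist`` and height ``k * rise``;
    copies are laid down for ``n_turns`` helical turns (clipped to the box).
    Density is a sum of Gaussians, hence non-negative.
    """
    extent = 2.0 * (model.filament_radius + max(abs(b.offset[0]) for b in model.protomer)
                    + 3.0 * model.max_sigma)
    if extent >= box * voxel:
        raise ValueError(f"filament (extent {extent:.0f} A) exceeds the "
                         f"{box * voxel:.0f} A box")
    vol = np.zeros((box, box, box), dtype=np.float64)
    centre = (box - 1) / 2.0
    z_half = min(model.n_turns * model.pitch / 2.0, box * voxel / 2.0 + 3 * model.max_sigma)
    planar = model.rise < 1e-2   # effectively a flat ring: one full turn, no stacking
    if planar:
        ks = range(int(round(360.0 / model.twist)))
    else:
        k_max = int(math.floor(z_half / model.rise))
        ks = range(-k_max, k_max + 1)
    ax = np.arange(box) * voxel - centre * voxel   # physical coords, A
    for k in ks:
        ang = math.radians(k * model.twist)
        c, s = math.cos(ang), math.sin(ang)
        zk = 0.0 if planar else k * model.rise
        for blob in model.protomer:
            bx = model.filament_radius + blob.offset[0]
            by, bz = blob.offset[1], blob.offset[2]
            # rotate protomer-frame position into the lab frame
            px = c * bx - s * by
            py = s * bx + c * by
            pz = zk + bz
            _add_gaussian(vol, ax, (px, py, pz), blob.sigma, blob.weight)
    if model.axial_dna is not None:
        r2 = np.add.outer(ax ** 2, ax ** 2)          # (y, x)
        tube = model.axial_dna.weight * np.exp(-r2 / (2 * model.axial_dna.radius ** 2))
        vol += tube[None, :, :]
    return VolumeGrid(voxels=vol.astype(np.float32), voxel_size=voxel)


def _add_gaussian(vol: np.ndarray, ax: np.ndarray, centre_xyz, sigma: float,
                  weight: float) -> None:
    """Add one isotropic Gaussian, evaluated only on its local 4-sigma box."""
    cx, cy, cz = centre_xyz
    voxel = ax[1] - ax[0]
    half = 4.0 * sigma

    def _window(c):
        lo = np.searchsorted(ax, c - half)
        hi = np.searchsorted(ax, c + half)
        return lo, hi

    zlo, zhi = _window(cz)
    ylo, yhi = _window(cy)
    xlo, xhi = _window(cx)
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return
    gz = np.exp(-((ax[zlo:zhi] - cz) ** 2) / (2 * sigma ** 2))
    gy = np.exp(-((ax[ylo:yhi] - cy) ** 2) / (2 * sigma ** 2))
    gx = np.exp(-((ax[xlo:xhi] - cx) ** 2) / (2 * sigma ** 2))
    vol[zlo:zhi, ylo:yhi, xlo:xhi] += weight * np.einsum("i,j,k->ijk", gz, gy, gx)


def render_projection(vol: VolumeGrid, orientation: tuple[float, float, float],
                      imaging: ImagingParams) -> np.ndarray:
    """Line-integral projection of the volume at Euler angles (phi, theta, psi).

    The projection sum equals the volume sum up to interpolation/clipping.
    """
    phi, theta, psi = orientation
    if not all(np.isfinite([phi, theta, psi])):
        raise ValueError("orientation angles must be finite")
    if vol.box_size != imaging.box_size:
        raise ValueError(f"volume box {vol.box_size} != imaging box {imaging.box_size}")
    return _project.project_volume(vol.voxels.astype(np.float64), phi, theta, psi)


def ctf_2d(box: int, pixel_size: float, ctf: CTFParams) -> np.ndarray:
    """2-D CTF sampled on the (unshifted) FFT frequency grid of a box.

    CTF(f) = -[w cos g(f) + sqrt(1-w^2) sin g(f)],
    g(f)  = pi * lambda * dz * f^2 - (pi/2) * Cs * lambda^3 * f^4.
    """
    f = np.fft.fftfreq(box, d=pixel_size)
    f2 = np.add.outer(f ** 2, f ** 2)
    lam = ctf.wavelength
    cs_a = ctf.spherical_aberration * 1e7          # mm -> A
    gamma = math.pi * lam * ctf.defocus * f2 - 0.5 * math.pi * cs_a * lam ** 3 * f2 ** 2
    w = ctf.amplitude_contrast
    return -(w * np.cos(gamma) + math.sqrt(1 - w ** 2) * np.sin(gamma))


def apply_ctf(img: np.ndarray, ctf: CTFParams, pixel_size: float) -> np.ndarray:
    """Multiply the image by the CTF in Fourier space (forward corruption)."""
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"image must be square, got {img.shape}")
    h = ctf_2d(img.shape[0], pixel_size, ctf)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * h))


def add_noise(img: np.ndarray, snr: float, seed) -> np.ndarray:
    """Additive white Gaussian noise at variance = signal variance / snr."""
    if not (snr > 0 or math.isinf(snr)):
        raise ValueError(f"snr must be positive, got {snr}")
    if math.isinf(snr):
        return img.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(img.var() / snr)
    return img + rng.normal(0.0, sigma, img.shape)


# ---------------------------------------------------------------------------
# dataset generation

_PRESETS = {
    "extended": extended_state,
    "compressed": compressed_state,
    "reca": reca_state,
    "dsdna": dsdna_state,
}


def _state_counts(fractions: list[float], n: int) -> list[int]:
    """Deterministic largest-remainder allocation; remainder is the junk class."""
    total = sum(fractions)
    if total > 1 + 1e-9:
        raise ConfigError(f"state fractions sum to {total:.3f} > 1")
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    target = int(round(total * n))
    for i in sorted(range(len(raw)), key=lambda i: -remainders[i]):
        if sum(counts) >= target:
            break
        counts[i] += 1
    return counts


def generate_dataset(config: RunConfig,
                     models: dict[str, HelicalModel] | None = None
                     ) -> tuple[ImageStack, pd.DataFrame]:
    """Generate a side-view segment dataset with ground-truth metadata.

    ``config`` supplies n_segments, box/pixel size, snr, CTF defocus, tilt
    and in-plane jitter, and the list of states (name + fraction, with pitch
    and twist overriding a named preset).  Fractions may sum to < 1: the
    remainder becomes a junk class (extended-like images at snr/10, standing
    in for distorted filaments that real processing would discard).

    The dataset is a pure function of the config: one master seed drives the
    azimuth, tilt, jitter, noise draws and the final shuffle.
    """
    n = int(config["n_segments"])
    box = int(config["box_size"])
    pixel = float(config["pixel_size"])
    snr = float(config["snr"])
    states_cfg = config["states"] or [
        {"name": "extended", "fraction": 0.70},
        {"name": "compressed", "fraction": 0.25},
    ]
    fractions = [float(s["fraction"]) for s in states_cfg]
    counts = _state_counts(fractions, n)
    n_junk = n - sum(counts)

    rng = np.random.default_rng(config.seed)
    tilt_sd = float(config.get("tilt_sd", 5.0))
    jitter = float(config.get("inplane_jitter", 5.0))
    defocus = config.get("defocus", None)
    ctf = None
    if defocus:
        ctf = CTFParams(defocus=float(defocus), wavelength=electron_wavelength(100.0))

    # state models and their volumes, built once
    resolved: list[HelicalModel] = []
    for s in states_cfg:
        name = s.get("name", "extended")
        if models and name in models:
            model = models[name]
        elif name in _PRESETS:
            over = {k: float(s[k]) for k in ("pitch", "twist") if k in s}
            model = _PRESETS[name](**over)
        else:
            raise ConfigError(f"unknown state preset: {name}")
        resolved.append(model)
    n_turns_needed = (box * pixel) / min(m.pitch for m in resolved) + 1.0
    resolved = [HelicalModel(pitch=m.pitch, twist=m.twist,
                             filament_radius=m.filament_radius, protomer=m.protomer,
                             axial_dna=m.axial_dna, n_turns=n_turns_needed,
                             name=m.name) for m in resolved]
    volumes = [build_helical_volume(m, box, pixel).voxels.astype(np.float64)
               for m in resolved]
    junk_model_idx = 0  # junk = first (extended-like) state at snr/10

    images = np.empty((n, box, box), dtype=np.float32)
    rows = []
    order = rng.permutation(n)
    plan: list[tuple[int, bool]] = []
    for i, c in enumerate(counts):
        plan += [(i, False)] * c
    plan += [(junk_model_idx, True)] * n_junk

    for slot, (state_idx, is_junk) in zip(order, plan):
        model = resolved[state_idx]
        phi = rng.uniform(0.0, 360.0)
        theta = 90.0 + rng.normal(0.0, tilt_sd)
        psi = rng.uniform(-jitter, jitter)
        img = _project.project_volume(volumes[state_idx], phi, theta, psi)
        if ctf is not None:
            img = apply_ctf(img, ctf, pixel)
        img = add_noise(img, snr / 10.0 if is_junk else snr, rng)
        images[slot] = img.astype(np.float32)
        rows.append({
            "id": int(slot),
            "state": "junk" if is_junk else model.name,
            "pitch_true": np.nan if is_junk else model.pitch,
            "twist_true": np.nan if is_junk else model.twist,
            "phi": phi, "theta": theta, "psi": psi,
            "defocus": ctf.defocus if ctf else 0.0,
            "class": -1,
        })
    meta = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    stack = ImageStack(images=images, pixel_size=pixel, metadata=meta)
    return stack, meta


def render_end_views(model: HelicalModel, n_images: int, imaging: ImagingParams,
                     seed: int | None = None) -> ImageStack:
    """End-view images (down the helical axis) at random in-plane rotations."""
    rng = np.random.default_rng(imaging.seed if seed is None else seed)
    vol = build_helical_volume(model, imaging.box_size, imaging.pixel_size)
    images = np.empty((n_images, imaging.box_size, imaging.box_size), dtype=np.float32)
    for i in range(n_images):
        psi = rng.uniform(0.0, 360.0)
        img = _project.project_volume(vol.voxels.astype(np.float64), 0.0, 0.0, psi)
        images[i] = add_noise(img, imaging.snr, rng).astype(np.float32)
    return ImageStack(images=images, pixel_size=imaging.pixel_size)
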