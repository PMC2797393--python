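"""Image normalisation, band-pass filtering and CTF handling.

The preprocessing chain for stain EM segments: normalise every image to zero
mean / unit standard deviation, band-pass away the uneven stain background
(low-resolution cut-off ~100 A with 10% remaining amplitude transmission,
high-resolution cut-off ~7 A) and correct the contrast transfer function by
phase flipping — sign correction only, amplitudes untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imagio import ImageStack
from .synthfil import CTFParams, ctf_2d

__all__ = [
    "FilterParams", "DefocusEstimate",
    "normalize", "band_pass", "estimate_defocus", "phase_flip",
    "preprocess_stack",
]


@dataclass(frozen=True)
class FilterParams:
    """Radial band-pass filter settings (cut-offs in Angstrom)."""

    low_cutoff: float = 100.0       # long-period cut-off
    low_transmission: float = 0.10  # amplitude gain left below it
    high_cutoff: float = 7.0        # short-period cut-off
    edge_width: int = 5             # raised-cosine edge, Fourier px

    def validate(self, pixel_size: float) -> None:
        if not (self.low_cutoff > self.high_cutoff):
            raise ValueError(f"low_cutoff ({self.low_cutoff} A) must exceed "
                             f"high_cutoff ({self.high_cutoff} A)")
        if self.high_cutoff < 2 * pixel_size:
            raise ValueError(f"high_cutoff {self.high_cutoff} A is beyond Nyquist "
                             f"({2 * pixel_size} A at {pixel_size} A/px)")
        if not 0 <= self.low_transmission <= 1:
            raise ValueError("low_transmission must be in [0, 1]")


@dataclass(frozen=True)
class DefocusEstimate:
    defocus: float              # A
    at_boundary: bool           # search range did not bracket the minimum
    residual: float             # fit residual at the estimate


def normalize(img: np.ndarray) -> np.ndarray:
    """Zero mean, unit standard deviation."""
    sd = img.std()
    if sd == 0:
        raise ValueError("constant image cannot be normalised")
    return (img - img.mean()) / sd


def _bandpass_gain(box: int, pixel_size: float, fp: FilterParams) -> np.ndarray:
    """Radial amplitude gain on the unshifted FFT grid.

    gain = low_transmission below 1/low_cutoff, raised-cosine ramp to 1 over
    ``edge_width`` Fourier pixels, 1 in the pass band, cosine roll-off to 0
    reaching zero at 1/high_cutoff.
    """
    f = np.fft.fftfreq(box, d=pixel_size)
    r = np.sqrt(np.add.outer(f ** 2, f ** 2))   # 1/A
    df = 1.0 / (box * pixel_size)               # one Fourier px
    f_lo = 1.0 / fp.low_cutoff
    f_hi = 1.0 / fp.high_cutoff
    edge = max(fp.edge_width, 1) * df
    gain = np.ones_like(r)
    t = fp.low_transmission
    # low-frequency shelf and ramp
    ramp = (r - f_lo) / edge
    low_zone = r < f_lo + edge
    gain[low_zone] = t + (1 - t) * 0.5 * (1 - np.cos(np.pi * np.clip(ramp[low_zone], 0, 1)))
    gain[r < f_lo] = t
    # high-frequency roll-off, zero at and beyond f_hi
    roll = (f_hi - r) / edge
    high_zone = r > f_hi - edge
    gain_high = 0.5 * (1 - np.cos(np.pi * np.clip(roll, 0, 1)))
    gain[high_zone] = np.minimum(gain[high_zone], gain_high[high_zone])
    gain[r >= f_hi] = 0.0
    return gain


def band_pass(img: np.ndarray, fp: FilterParams, pixel_size: float) -> np.ndarray:
    """Radial Fourier band-pass filter (amplitude gain; linear operator)."""
    fp.validate(pixel_size)
    gain = _bandpass_gain(img.shape[0], pixel_size, fp)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * gain))


def _radial_average(power: np.ndarray, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    box = power.shape[0]
    f = np.fft.fftfreq(box, d=pixel_size)
    r = np.sqrt(np.add.outer(f ** 2, f ** 2))
    df = 1.0 / (box * pixel_size)
    idx = np.minimum((r / df).astype(int), box // 2)
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=box // 2 + 1)
    counts = np.bincount(idx.ravel(), minlength=box // 2 + 1)
    r_sums = np.bincount(idx.ravel(), weights=r.ravel(), minlength=box // 2 + 1)
    prof = sums / np.maximum(counts, 1)
    # label each shell with its actual mean frequency, not the bin edge
    freqs = r_sums / np.maximum(counts, 1)
    keep = slice(0, box // 2)
    return freqs[keep], prof[keep]


def estimate_defocus(stack: ImageStack, ctf_template: CTFParams,
                     search: tuple[float, float], step: float = 100.0) -> DefocusEstimate:
    """Estimate defocus from the incoherently averaged power spectrum.

    The rotationally averaged power spectrum of the stack, with a low-order
    polynomial background (3rd order in f^2) removed, is compared against
    |CTF|^2 over a defocus grid; the squared distance minimiser wins.
    Astigmatism is ignored.
    """
    if len(stack) < 10:
        raise ValueError(f"need >= 10 images for defocus estimation, got {len(stack)}")
    lo, hi = search
    if not hi > lo:
        raise ValueError("empty defocus search range")
    power = np.zeros((stack.box_size, stack.box_size))
    for img in stack.images:
        power += np.abs(np.fft.fft2(img - img.mean())) ** 2
    power /= len(stack)
    freqs, prof = _radial_average(power, stack.pixel_size)
    # fit band: skip the DC / low-resolution ramp; stop where the structural
    # signal (which alone carries the CTF modulation here) has decayed —
    # around twice the first zero of the shallowest defocus in the range
    lam = ctf_template.wavelength
    f_stop = min(2.0 * math.sqrt(1.0 / (lam * max(lo, 1e3))), freqs[-1])
    band = (freqs > freqs[3]) & (freqs <= f_stop)
    if band.sum() < 8:
        band = freqs > freqs[3]
    f_band, p_band = freqs[band], prof[band]
    # background: polynomial in f^2; the oscillatory residual holds the rings
    bg_coef = np.polyfit(f_band ** 2, np.log(np.maximum(p_band, 1e-300)), 3)
    resid = p_band - np.exp(np.polyval(bg_coef, f_band ** 2))
    if np.allclose(resid, 0, atol=1e-12) or resid.std() == 0:
        raise ValueError("flat power spectrum: no Thon rings to fit")
    resid = resid / np.linalg.norm(resid)

    cs_a = ctf_template.spherical_aberration * 1e7
    w = ctf_template.amplitude_contrast
    f2 = f_band ** 2

    def model_resid(dz: float) -> np.ndarray:
        gamma = np.pi * lam * dz * f2 - 0.5 * np.pi * cs_a * lam ** 3 * f2 ** 2
        c2 = (w * np.cos(gamma) + np.sqrt(1 - w ** 2) * np.sin(gamma)) ** 2
        mc = np.polyfit(f2, c2, 3)
        m = c2 - np.polyval(mc, f2)
        nrm = np.linalg.norm(m)
        return m / nrm if nrm > 0 else m

    grid = np.arange(lo, hi + step / 2, step)
    # maximise the normalised correlation between measured and model ring
    # patterns == minimise the squared distance of unit vectors
    errors = np.array([np.sum((resid - model_resid(dz)) ** 2) for dz in grid])
    best = int(np.argmin(errors))
    return DefocusEstimate(defocus=float(grid[best]),
                           at_boundary=best in (0, len(grid) - 1),
                           residual=float(errors[best]))


def phase_flip(img: np.ndarray, ctf: CTFParams, pixel_size: float) -> np.ndarray:
    """Multiply Fourier components by sign(CTF); amplitudes unchanged."""
    h = ctf_2d(img.shape[0], pixel_size, ctf)
    sign = np.where(h >= 0, 1.0, -1.0)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * sign))


def preprocess_stack(stack: ImageStack, fp: FilterParams | None = None,
                     flip_ctf: bool = False,
                     ctf_template: CTFParams | None = None) -> ImageStack:
    """Normalise (+ optionally phase-flip) and band-pass a whole stack.

    Per-image defocus for phase flipping is taken from the stack metadata
    (synthetic ground truth); images with defocus 0 are left unflipped.

    When no filter is given, the default 7 A high cut-off is relaxed to just
    inside Nyquist for coarser pixel sizes (down-sampled working boxes).
    """
    if fp is None:
        fp = FilterParams(high_cutoff=max(7.0, 2.25 * stack.pixel_size))
    out = np.empty_like(stack.images)
    defoci = None
    if flip_ctf and stack.metadata is not None and "defocus" in stack.metadata:
        defoci = stack.metadata["defocus"].to_numpy()
    for i, img in enumerate(stack.images):
        x = img.astype(np.float64)
        if defoci is not None and defoci[i] > 0:
            if ctf_template is None:
                from .synthfil import electron_wavelength
                ctf_template = CTFParams(defocus=defoci[i],
                                         wavelength=electron_wavelength(100.0))
            ctf = CTFParams(defocus=float(defoci[i]), wavelength=ctf_template.wavelength,
                            spherical_aberration=ctf_template.spherical_aberration,
                            amplitude_contrast=ctf_template.amplitude_contrast)
            x = phase_flip(x, ctf, stack.pixel_size)
        x = band_pass(x, fp, stack.pixel_size)
        out[i] = normalize(x).astype(np.float32)
    return ImageStack(images=out, pixel_size=stack.pixel_size, metadata=stack.metadata)
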