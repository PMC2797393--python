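# Methods

This note documents the models and estimators in `helifil`: what each one
assumes, the parameters that matter, the numerical choices, and what the
synthetic-data validation does and does not demonstrate.

## The helical model

A filament is a screw-symmetric arrangement of protein subunits
(protomers): protomer *k* sits at azimuth *k·Δφ* and height *k·Δz*, where
Δφ is the twist (degrees per protomer) and Δz = P·Δφ/360 the rise, with P
the pitch (Å per 360° turn).  All stoichiometric quantities derive from
(P, Δφ): protomers per turn n = 360/Δφ; nucleotides per turn = n × nt per
protomer.  Conventions: z is the helical axis; angles in degrees; a
right-handed helix has positive twist.  Handedness itself is *not*
determined by this pipeline — projections of mirror-handed filaments are
indistinguishable without tilt or docking information; the sign convention
is an assumption, not an inference.

## The synthetic generator (`synthfil`)

The generator emulates negative-stain segment data of recombinase–ssDNA
filaments: square side-view boxes (defaults 160 px at 1.59 Å/px; the test
and example harness works at 64 px / 4.0 Å), a mixture of an extended state
(P = 110 Å, Δφ = 40.5°, outer diameter tuned to ≈116 Å at the 1σ
isosurface) and a compressed state (96 Å, 42.5°, ≈133 Å), an optional junk
class (extended images at snr/10, standing in for distorted filaments),
C8 rings and end views, additive white Gaussian noise at a configured
signal-to-noise variance ratio, and an optional CTF (100 kV, default
1.2 µm underfocus) applied before the noise.

**Protomer density.**  Each protomer is two lobes — a large core lobe L
(~20 Å envelope) and a smaller lobe S at larger radius, leaning toward the
neighbouring subunit — each built from compact Gaussian sub-blobs
(σ = 4.5 Å and 4.0 Å).  The sub-blob structure is essential, not
cosmetic: a single Gaussian of σ ≈ 10 Å has amplitude exp(−2π²σ²f²) ≈ 3·10⁻⁶
at the inter-protomer lattice frequency (1/12.4 Å⁻¹), i.e. *no* measurable
power at the spacing that encodes twist — side views of such a model are
mathematically indistinguishable across twist values.  Real protein
domains have internal density contrast; the sub-blob cluster restores it
while keeping the two-lobe architecture and the target diameters.

**Orientations.**  Side views are rendered at uniform random azimuth,
out-of-plane tilt ~ N(90°, 5°) (manually selected segments are nearly
equatorial), and in-plane rotation jitter uniform in ±5°.  Segments are
treated as independent (no overlap model along a filament).

**What the generator does not emulate:** stain granularity and unevenness
beyond the band-passed background, filament curvature and stretch
disorder, carbon-film structured noise (so Thon rings live only in the
signal term), electron-optical effects beyond the CTF, and inter-segment
correlation.  Passing tests on this data therefore demonstrate estimator
correctness under the stated noise model, not performance on micrographs.

## Preprocessing (`preprocess`)

Images are normalised to zero mean / unit variance; band-passed with a
radial amplitude filter (gain = 0.10 below 1/100 Å⁻¹, raised-cosine edge of
5 Fourier px, cosine roll-off to zero at the high cut-off, default 7 Å but
relaxed to just inside Nyquist for coarse working pixels); CTF-corrected by
phase flipping only (sign of the CTF; amplitudes untouched).  The "10 %
remaining transmission" is implemented as an *amplitude* gain of 0.10 (the
power interpretation would be √0.10 ≈ 0.32).

Defocus is estimated from the incoherently averaged power spectrum:
rotationally averaged with each shell labelled by its true mean frequency
(bin-edge labelling biases the fit by half a Fourier pixel, ≈1000 Å of
defocus at these settings), a 3rd-order polynomial in f² removed in
log-space, and the residual ring pattern matched against |CTF|² (detrended
the same way) over a defocus grid.  The fit band stops near twice the
first CTF zero of the shallowest defocus searched, because in this
noise model only the structural signal carries CTF modulation and it
decays steeply.  Astigmatism is ignored.

## Eigen-image analysis and classification (`msa`)

Eigen images are the SVD modes of the centred image matrix over a circular
support mask (radius 0.45·box).  Classification is seeded k-means in the
leading 10 eigen coordinates; class size defaults to ~15 members per
class.

**Sorting conformational states** needs care: the raw-image covariance is
dominated by helical phase and azimuth variation, which buries the
diameter mode — k-means on raw eigen coordinates separates the two states
no better than chance at snr 0.1.  `split_states` therefore runs the same
eigen/k-means machinery on each image's *2-D autocorrelation* (central
crop, zero-lag spike blanked, normalised): autocorrelation is invariant to
the nuisance translations while retaining diameter and pitch structure.
This yields ≈94–96 % label purity on the two-state mixture at snr 0.1.

**Symmetry orders** are read from rotational power spectra (angular DFT on
polar rings, circumference-weighted so Parseval holds).  A C8 ring stack
at random rotations produces a quadrature eigen pair peaking at order 8;
end views of a filament with a non-integer protomer count per turn show no
exact n-fold rotational symmetry (the ring is invariant under 45° rotation
at corr ≈ 1, the 8.89-per-turn end view is below 0.95 for every integer
fold).

## The helical grid search (`helix_search`)

Each (pitch, twist) node is scored by **error minimisation between class
averages and reprojections of a node reference**: the error per class
average is 1 − max normalised cross-correlation over reprojection azimuths
spanning one asymmetric unit [0, Δφ), axial shifts up to ±P/2 (circular,
with parabolic sub-pixel peak refinement), a small transverse shift
(±3 px) and in-plane rotations (±10° in 5° steps), computed inside a
transverse mask around the filament and with reprojections band-passed
like the data.  The search is coarse (3.2 Å / 2°; twist 35–48° by
default, with wider 3°-step presets for RecA-like and dsDNA-like
filaments) then fine (0.5 Å / 0.5°) around the coarse minimum.  Ties break
lexicographically (smallest pitch, then twist); a fine minimum on the grid
boundary raises a warning and is flagged.

**The node reference is a parametric helical lattice**, not a
reconstruction from the data: one generic Gaussian protomer (σ = 6 Å)
repeated by the node's screw operator at the filament radius estimated
from the data's own mean transverse profile (the density rails of a
side-view sit at ± the protomer radius), plus a generic axial DNA thread.
This was a deliberate design decision after measuring two failure modes of
data-derived references: an *unaligned* back-projection reference washes
out twist discrimination entirely, and an *aligned* one locks the error
minimum to whatever twist seeded the alignment (classic reference bias —
in measurements the recovered minimum tracked the alignment seed, not the
truth).  The parametric reference encodes only the candidate symmetry plus
the data's gross radial geometry, so the surface cannot inherit a twist.
Its blob width matters little (the twist minimum is stable for radius
errors of ±4 Å and for σ between 4 and 8 Å); what matters is that the
lattice positions are the node's.

**Known bias.**  Class averages mix segments with small out-of-plane tilts
and residual in-plane rotations; every tilted segment's lattice is
foreshortened by cos(tilt), so the *apparent* pitch of an average is
E[cos θ]·E[cos ψ] ≈ 0.995 of the true pitch at the default jitters
(≈0.55 Å at P = 110 Å).  The in-plane part is largely compensated by the
rotation search in the matcher; the residual is below the fine grid step
and the reported pitch is left uncorrected by default.
`foreshortening_factor(tilt_sd, psi_halfwidth)` computes the correction
for callers who want it (`search_helical_params(..., jitter=(5, 5))`).

## Reconstruction (`reconstruct`)

Orientation assignment is projection matching: a library of reference
projections over one asymmetric unit of azimuth and out-of-plane tilt
90 ± 15° (grid centred on 90° so exact side views are present), scored by
windowed normalised cross-correlation with axial shifts up to ±P/2 and
small transverse shifts.  Reconstruction is r-weighted (ramp-filtered)
back-projection with tri-linear gridding — a standard substitution for
exact-filter weighting; equivalence is claimed only at the level of the
phantom-recovery tests, not algorithmic identity.  The map is then
helically symmetrised: every voxel is replaced by its average over all
in-box screw copies whose source z lies in the central trusted fraction
(default 0.6) of the box; voxels with no trusted source keep their input
value.  A final isotropic Gaussian low-pass at the voxel scale
band-limits the map (an isotropic filter commutes with the screw
operator, so helical self-consistency is preserved); noise beyond the
reconstruction's resolution otherwise dominates the invariance measure.

Bootstrapping matters: back-projecting class averages at arbitrary
azimuths and symmetrising produces a self-consistent *wrong* attractor
(alignment scores rise while the map diverges from the phantom).  The
initial reference is therefore the same parametric lattice used by the
grid search, which assigns azimuths from the protomer lattice phase; two
alignment/reconstruction rounds against the data then converge (phantom
correlation ≈0.93 from raw snr-0.2 segments, ≈0.98 noiseless).

FSC uses 1-voxel shells of the full 3-D transforms, no masking by
default; resolution is the reciprocal of the first threshold crossing
(linear interpolation), or Nyquist with a `no_crossing` flag.  Half-sets
split by even/odd index.

## Geometry and measurements (`geometry`)

Per-turn protomer counts and nucleotide coverages are reported at one
decimal (raw doubles retained).  Radial profiles are rotational averages
about z in 1-voxel bins; the σ of a map is the standard deviation over the
*full* box, solvent included — isosurface thresholds quoted in σ units use
that convention.  Outer diameter = 2× the largest radius where the profile
still reaches the threshold; inner channel = 2× the largest radius below
the main peak where it falls under the threshold (0 if density reaches the
axis).  Note the generator's DNA thread fills the axis, so synthetic maps
report an inner channel of 0 by construction unless the thread is
omitted.

One published relation is deliberately not derived here: "a 5.1 Å axial
rise per base giving ~19 nucleotides per turn" is a cited-literature
convention that is numerically inconsistent with the extended pitch
(110/5.1 ≈ 21.6); the package reproduces the ~19 nt/turn figure only via
protomers-per-turn × nt-per-protomer (8.9 × 2.1 ≈ 18.7).

## Problem sizes and determinism

The validation harness works at a 64-px box and 4.0 Å/px — every helical
feature (pitch ~100 Å, rise ~12 Å, protomer lobes ~10–20 Å) stays well
inside Nyquist while whole-pipeline runs take minutes: the end-to-end
two-state study uses 750 segments (500 extended, 250 compressed, snr 0.1),
the reconstruction loop 60 segments, symmetry detection 300 ring images.
Every stochastic stage consumes an explicit seed (NumPy `default_rng`,
seeded k-means); identical configurations produce bit-identical datasets
and error surfaces.

## Limitations

- Handedness is assumed, not determined.
- No astigmatism, amplitude CTF correction, or Wiener filtering.
- The grid search reports the global minimum of a sampled surface; closely
  spaced filament states (Δφ differing by ≲0.5°, i.e. below the fine step)
  are not resolvable at the desk scale.
- Out-of-plane tilt beyond the ±15° matching library and strongly curved
  segments are outside the model.
- Resolution numbers from synthetic half-sets characterise the noise
  model, not any experimental map.
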