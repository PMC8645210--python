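# Methods

## Generative model

The simulator renders what a camera sees when an HCR-stained section is
imaged, stage by stage, with the hidden truth retained for validation.

**Truth.** `n_cells` axis-aligned elliptical cells are placed uniformly on
the field (overlaps allowed; later cells overwrite). Semi-axes are drawn
uniformly from `cell_axes_um` (default 2–6 µm, a typical cell radius
range). Each cell draws a molecule density per target from the abundance
law — by default lognormal with linear-scale mean 5 molecules/pixel and
log-SD 0.6, giving the right-skewed, spatially clustered abundance typical
of tissue — and per-pixel counts are Poisson around that density. A
`deterministic` law assigns exact counts for closed-form tests. A cell
whose diameter exceeds the field raises an error naming the offending
dimension. Two channels may reference the same target (redundant
detection); they then share one truth field.

**Detection.** Each molecule presents `initiators_per_probe` potential
initiators; the number triggered is Binomial(molecules × initiators,
p_eff). For antibody probes p_eff = binding_efficiency × (1 −
interference); for split-initiator pairs both half-probes must bind, so
the efficiency enters squared. Interference models two antibodies
competing for epitopes on the same target in redundant detection; default
0 (the paired channels in the shipped scenarios are independent draws).

**Amplification.** Each triggered initiator grows a polymer whose length
in hairpins follows a geometric law with support ≥ 1 and mean
`mean_polymer_length` (default 180, the scale observed for HCR IHC).
The geometric law is the natural memoryless model for sequential hairpin
addition; only the mean is empirically constrained, so the distributional
shape is an explicit modeling assumption, and a `deterministic` law is
provided for exact arithmetic in tests. Sums of k geometric lengths are
sampled exactly as k + NegativeBinomial(k, 1/mean). In `h1_only` mode
polymerisation cannot proceed and every initiator carries exactly one
hairpin — the basis of the gain measurement. Fluorophores = hairpins ×
`fluors_per_hairpin`.

**Background.** Three components, in fluorophore-equivalent units:

* *AF* — autofluorescence: Gaussian-filtered white noise (periodic
  boundary) rescaled to mean `af_mean` with a fixed 30% coefficient of
  variation and clipped nonnegative. The correlation length (default
  2–3 µm) is a free parameter; real AF statistics are tissue-specific.
* *NSD* — nonspecifically bound probes, Poisson `nsd_rate`/pixel. On
  antibody channels each such probe carries a full initiator and is
  amplified through the channel's amplifier (hence drops to single-hairpin
  scale in the h1-only control); on split-initiator channels a lone probe
  cannot trigger HCR and contributes one hairpin's worth of signal. This
  asymmetry is the *automatic background suppression* property of
  split-initiator chemistry, and the simulator reproduces its expected
  magnitude: antibody NSD / split NSD = mean polymer length.
* *NSA* — nonspecifically bound single hairpins, Poisson `nsa_rate`/pixel,
  never amplified.

**Optics.** Gaussian PSF of width `psf_sigma` (µm; converted to pixels),
convolved with reflective boundaries so total intensity is conserved;
multiplication by `photon_scale` (counts per fluorophore); Poisson shot
noise on the expected photon count; additive Gaussian read noise; then a
constant instrument dark offset (added after shot noise — it models a
camera offset, not a photon flux; the choice of noise model is the
package's own, as none is empirically constrained). Output is clipped at
zero.

**Determinism.** One master seed; every (channel, stage) pair gets an
independent `SeedSequence` substream, so identical configs reproduce
bit-identical experiments *and* controls. Controls share the experiment's
truth, detection draws and background fields; only the render-stage noise
streams differ per image, which is what the estimators assume (an
unstained control images the same AF field).

## Quantitation

**Voxels.** Non-overlapping pixel blocks; the voxel size must be an
integer multiple of the pixel size, and `snap_voxel_size` realizes a
non-commensurate request as the largest commensurate size not exceeding it
(2 µm on 0.16 µm pixels → 1.92 µm, 12×12 pixels), with the realized size
reported. Trailing partial blocks are discarded. Aggregator defaults to
`mean` (normalization removes the mean/sum distinction; the mean keeps
units interpretable).

**Normalization.** Subtract dark offset and background level, clip at 0,
divide by the 0.995 quantile of the remaining voxel values (quantile
rather than maximum to resist single-voxel outliers), clip at 1.

**Masking.** Correlation is computed on expressing voxels only — raw
intensity above background mean + k·SD (k = 2) in at least one channel —
because empty extracellular voxels otherwise cluster at the origin and
inflate r.

**Scatter fit.** Total least squares: the line direction is the leading
eigenvector of the 2×2 voxel covariance; the orthogonal RMS is the square
root of the trailing eigenvalue. TLS is used because both channels carry
comparable noise under redundant detection; OLS is available for
comparison. Degenerate inputs (constant channel, < 2 voxels, vertical
line) raise. |intercept| ≤ 0.05 on the normalized scale is adopted as the
working definition of "approximately zero".

**Read-out / read-in.** Read-out returns the (x₁, x₂) pairs of voxels
whose pixel footprint intersects an anatomical region; read-in rasterises
the footprint of voxels whose pair lies inside (or on the boundary of) a
simple polygon gate in expression space. Self-intersecting gates are
rejected.

## Signal, background, gain

Components are estimated by sequential subtraction of region means:
AF from the unstained control, NSA from the hairpins-only control, NSD
from a non-expressing region of the experiment; estimates clip at zero
with a warning and a missing control yields an *unresolved* component,
never a silent zero. Signal is the dark-subtracted mean over the signal
region minus the background total; S/B = signal / background.

Gain divides background-subtracted paired signal by h1-only signal, with
background measured per arm; it assumes equal fluorophores per hairpin in
both arms. Because autofluorescence varies regionally, the worked
example's gain estimator measures AF+NSA over the *same* expressing region
from the hairpins-only control and adds the (small) NSD excess measured in
the non-expressing region — region-matched backgrounds rather than
region-difference ones, which matters when the h1-only signal is of the
same order as regional AF variation. Where the PSF spills signal across
cell boundaries, region means are taken over eroded interiors with a
dilated guard band excluded from the background region.

The crowding diagnostic bins masked voxels into quantiles (default 4) of
x₁ + x₂, fits a TLS slope per stratum, and flags when any stratum's slope
deviates from the global slope by more than 20% relative — a
package-defined threshold; zero-variance strata are dropped and reported.
Median gain over scenarios uses the standard even-count convention
(mean of the middle two).

## What the simulator does and does not capture

It reproduces the statistical structure the analysis relies on: linear
signal scaling with abundance, geometric amplification, the three
background components with the antibody/split-initiator NSD asymmetry,
PSF blur and camera noise, and control images consistent with the
experiment. It does not attempt real anatomy (cells are ellipses),
probe-kinetics or depletion effects, spectral bleed-through, per-channel
registration error, photobleaching, or 3D optical sectioning (z-planes
would be independent). Passing tests therefore certify the estimators
under the stated model, not performance on any particular tissue; the
published S/B ranges for real FFPE and embryo samples depend on the
original microscope data and are out of scope.

## Problem sizes and numerical choices

The shipped scenarios use a 384×384 field (0.16 µm pixels, ≈61 µm of
tissue, ~1000 voxels at 1.92 µm) for scatter analyses and 512×512 fields
for background-component and S/B recovery — large enough that Monte-Carlo
error sits well inside the stated tolerances while a full test run stays
in seconds. Gain recovery uses 96×96 fields with ~10⁴ molecules per
scenario. Tolerances follow the estimators' sampling error (3 SE over 20
seeds for stochastic recoveries; 10⁻⁶–10⁻⁹ relative for deterministic
identities). TIFF output is float32 multi-page with a JSON description
block (pixel size, channel names) and deterministic bytes; 16-bit input is
promoted to float on read.
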