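# qhcr

Quantitative analysis of HCR-amplified fluorescence images, with a
physics-based synthetic image generator for validating every stage of the
pipeline without microscope data.

## The problem

Hybridization chain reaction (HCR) signal amplification detects proteins
(via initiator-labeled antibody probes) and RNAs (via split-initiator DNA
probe pairs) in situ: each target molecule that colocalises a full HCR
initiator i1 triggers self-assembly of fluorophore-labeled hairpins h1/h2
into a tethered amplification polymer. Because the amplified signal scales
approximately linearly with target abundance, fluorescence intensities can
be read quantitatively — *qHCR imaging*: relative quantitation of targets
at subcellular voxel resolution in an anatomical context.

This package implements the analysis side of that workflow for people
developing or validating such assays:

* **Voxel quantitation** (`qhcr.quant`): bin a two-channel image of a
  redundantly detected target into subcellular voxels (e.g. ~2 µm blocks
  of 0.16 µm pixels), normalize intensities to [0, 1], and fit the
  two-channel scatter by total least squares (orthogonal regression).
  Writing voxel intensities as x₁, x₂ and the fitted line x₂ = a·x₁ + b,
  *accuracy* is linearity with b ≈ 0, *precision* is the RMS orthogonal
  scatter around the line, summarised with the Pearson correlation r.
  Read-out/read-in gating maps between anatomical space and (x₁, x₂)
  expression space.
* **Signal and background** (`qhcr.sbgain`): decompose background into
  autofluorescence (AF), nonspecific detection (NSD) and nonspecific
  amplification (NSA) using unstained and hairpins-only controls,
  compute signal-to-background ratios, and estimate the HCR amplification
  gain g (mean polymer length in hairpins) as the ratio of background-
  subtracted signal with h1+h2 (polymerisation proceeds) to signal with
  h1 only (each initiator binds exactly one hairpin):
  g = SIG_paired / SIG_h1. A density-stratified slope-consistency
  diagnostic guards against crowding/saturation artifacts that could let
  voxel pairs slide undetected along the fitted line.
* **Simulator** (`qhcr.sim`): per-pixel molecule counts on elliptical
  cells → binomial probe detection (squared efficiency for split-initiator
  pairs) → geometric polymer growth → the three background components
  (NSD amplifies only on antibody channels, the automatic background
  suppression asymmetry of split-initiator chemistry) → Gaussian PSF,
  Poisson shot noise, Gaussian read noise, constant dark offset. Fully
  deterministic given one master seed, including control images.

## Worked example

```sh
qhcr demo --seed 1 --out-dir demo_out
```

simulates a redundant two-channel antibody detection of one target at
epifluorescence settings (384×384 field of 0.16 µm pixels, amplification
gain 180, AF + NSD + NSA background, shot and read noise), then runs the
full analysis. It prints:

```
scatter: r=0.9951 slope=1.0412 intercept=0.0046 (n=457 voxels, 1.92 µm)
S/B ratio: 10.1 (AF=40.1, NSD=19.1, NSA=0.1)
amplification gain: 179.6 hairpins/polymer
crowding: max dev 0.024 (ok)
```

Reading: the 2 µm voxel request is realized as 1.92 µm (12×12 pixel
blocks); 457 expressing voxels form a tight line through the origin
(r = 0.995, intercept 0.005 on the normalized scale) — the linear-signal
property that justifies relative quantitation; the paired vs h1-only
comparison recovers the simulator's true polymer length of 180 hairpins
to 0.2%; and no stratum's slope deviates enough from the global slope to
suggest crowding. `demo_out/` contains the experiment and control TIFFs,
the voxel mask, and JSON reports. Library use mirrors the CLI:

```python
from qhcr import demo, sim
report = demo.run_demo(seed=1)
report["scatter"]["pearson_r"]   # 0.9951
```

Other commands: `qhcr simulate --config cfg.yaml --out-dir run/`,
`qhcr quantify --in stack.tif --ch 1 2 --voxel 2.0 --out scatter.json`,
`qhcr sb`, `qhcr gain`, `qhcr crowding` (see `--help`).

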