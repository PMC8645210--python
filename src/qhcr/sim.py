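"""Forward simulation of HCR-stained multichannel fluorescence images.

The generative model mirrors the physics of HCR signal amplification:

1. *Truth*: elliptical cells on an empty field, each with a molecule
   density drawn from an abundance law; integer molecules per pixel.
2. *Detection*: each target molecule independently colocalises a
   functional HCR initiator with probability ``p_eff`` (squared efficiency
   for split-initiator pairs, where both half-probes must bind).
3. *Amplification*: each triggered initiator grows a polymer whose length
   is geometric (support >= 1) or deterministic; fluorophores scale with
   hairpins.  In h1-only mode polymerisation cannot proceed and every
   initiator carries exactly one hairpin.
4. *Background*: smooth autofluorescence (AF), nonspecific detection
   probes (NSD; amplified on antibody channels only) and nonspecific
   single hairpins (NSA).
5. *Optics*: Gaussian PSF blur, photon scaling, Poisson shot noise,
   Gaussian read noise and a constant dark offset.

Everything is deterministic given the master seed; control images
(unstained, hairpins-only, h1-only) share the experiment's truth and
background fields so downstream estimators see consistent data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import (AmplifierParams, BackgroundParams, ChannelSpec,
                     OpticsParams, ParameterError, SimulationConfig)
from .io import ImageStack

# Stage keys for deterministic per-channel, per-stage RNG substreams.
_STAGE = {"truth": 0, "abundance": 1, "detection": 2, "amplification": 3,
          "background": 4, "render_exp": 5, "render_h1": 6,
          "render_unstained": 7, "render_hairpins_only": 8}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_rng(master_seed: int, channel: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for one (channel, stage) pair."""
    ss = np.random.SeedSequence([int(master_seed), int(channel), _STAGE[stage]])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class GroundTruthMap:
    """The simulator's hidden truth: molecules per pixel, per target."""

    molecule_counts: Mapping[str, np.ndarray]  # target_id -> int field
    cell_labels: np.ndarray                    # int field, 0 = extracellular
    target_ids: tuple[str, ...]

    def counts_for(self, channel: ChannelSpec) -> np.ndarray:
        return self.molecule_counts[channel.target_id]


@dataclass(frozen=True)
class BackgroundFields:
    """Per-pixel background in fluorophore-equivalent units, by component."""

    af: np.ndarray
    nsd: np.ndarray
    nsa: np.ndarray
    nsd_probes: np.ndarray  # raw probe counts, before amplification

    @property
    def total(self) -> np.ndarray:
        return self.af + self.nsd + self.nsa


@dataclass(frozen=True)
class ExperimentResult:
    stack: ImageStack
    truth: GroundTruthMap
    controls: Mapping[str, ImageStack]   # unstained, hairpins_only, h1_only
    backgrounds: tuple[BackgroundFields, ...]  # per channel, pre-optics


def generate_truth(config: SimulationConfig) -> GroundTruthMap:
    """Place elliptical cells and assign integer molecule counts per target.

    Cells are axis-aligned ellipses with semi-axes drawn uniformly from
    ``config.cell_axes_um``; overlaps are allowed (later cells overwrite).
    A cell whose diameter exceeds the field raises, naming the offending
    dimension.
    """
    rows, cols = config.image_shape
    geom = stage_rng(config.seed, 0, "truth")
    labels = np.zeros((rows, cols), dtype=np.int32)
    rr, cc = np.mgrid[0:rows, 0:cols]
    lo, hi = config.cell_axes_um
    for i in range(int(config.n_cells)):
        a_r = geom.uniform(lo, hi) / config.pixel_size
        a_c = geom.uniform(lo, hi) / config.pixel_size
        if 2 * a_r + 1 > rows:
            raise ValueError(
                f"cell semi-axis {a_r * config.pixel_size:.3g} µm does not fit "
                f"the field along dimension 'rows' ({rows} px)")
        if 2 * a_c + 1 > cols:
            raise ValueError(
                f"cell semi-axis {a_c * config.pixel_size:.3g} µm does not fit "
                f"the field along dimension 'cols' ({cols} px)")
        cr = geom.uniform(a_r, rows - 1 - a_r)
        ccen = geom.uniform(a_c, cols - 1 - a_c)
        inside = ((rr - cr) / a_r) ** 2 + ((cc - ccen) / a_c) ** 2 <= 1.0
        labels[inside] = i + 1

    law = config.abundance_law
    counts: dict[str, np.ndarray] = {}
    for t_idx, target in enumerate(config.target_ids):
        arng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), _STAGE["abundance"], t_idx]))
        field = np.zeros((rows, cols), dtype=np.int64)
        for i in range(int(config.n_cells)):
            pix = labels == i + 1
            if not pix.any():
                continue
            if law["name"] == "deterministic":
                field[pix] = int(round(law["density"]))
            else:  # lognormal cell density, Poisson pixel counts
                sigma = float(law.get("sigma", 0.6))
                mu = np.log(float(law["mean_density"])) - 0.5 * sigma**2
                density = float(np.exp(arng.normal(mu, sigma)))
                field[pix] = arng.poisson(density, size=int(pix.sum()))
        counts[target] = field
    if not counts:  # no channels configured: still expose the label field
        counts = {}
    return GroundTruthMap(molecule_counts=counts, cell_labels=labels,
                          target_ids=config.target_ids)


def simulate_detection(molecules: np.ndarray, channel: ChannelSpec,
                       seed) -> np.ndarray:
    """Number of triggered initiators per pixel.

    Binomial(molecules x initiators_per_probe, p_eff) where p_eff folds in
    binding efficiency (squared for split-initiator pairs) and interference.
    """
    rng = _rng(seed)
    p = channel.effective_trigger_probability
    n = np.asarray(molecules, dtype=np.int64) * int(channel.initiators_per_probe)
    if n.min() < 0:
        raise ValueError("molecule counts must be nonnegative")
    return rng.binomial(n, p)


def simulate_amplification(initiators: np.ndarray, amp: AmplifierParams,
                           seed) -> np.ndarray:
    """Fluorophores per pixel after polymer growth.

    The sum of k iid geometric lengths (support >= 1, mean m) is sampled
    exactly as k + NegativeBinomial(k, 1/m).
    """
    rng = _rng(seed)
    k = np.asarray(initiators, dtype=np.int64)
    if k.min() < 0:
        raise ValueError("initiator counts must be nonnegative")
    f = int(amp.fluors_per_hairpin)
    if amp.hairpin_mode == "h1_only":
        return (k * f).astype(np.float64)
    if amp.length_law == "deterministic":
        return k.astype(np.float64) * float(amp.mean_polymer_length) * f
    p = 1.0 / float(amp.mean_polymer_length)
    total = k.astype(np.float64).copy()
    pos = k > 0
    if pos.any():
        total[pos] += rng.negative_binomial(k[pos], p)
    return total * f


def simulate_background(shape: tuple[int, int], channel: ChannelSpec,
                        pixel_size: float, seed) -> BackgroundFields:
    """Draw the three background components, in fluorophore equivalents.

    AF is Gaussian-filtered white noise rescaled to mean ``af_mean`` with a
    30% coefficient of variation, clipped nonnegative; NSD probes are
    Poisson and amplified only when the probe carries a full initiator
    (antibody channels); NSA single hairpins are Poisson and never amplify.
    """
    bp = channel.background
    rng = _rng(seed)
    if bp.af_mean > 0:
        raw = rng.standard_normal(shape)
        sigma_px = bp.af_corr_length / pixel_size
        if sigma_px > 0:
            raw = gaussian_filter(raw, sigma_px, mode="wrap")
            sd = raw.std()
            if sd > 0:
                raw = raw / sd
        af = np.clip(bp.af_mean * (1.0 + 0.3 * raw), 0.0, None)
    else:
        af = np.zeros(shape, dtype=np.float64)

    probes = rng.poisson(bp.nsd_rate, size=shape).astype(np.int64)
    f = int(channel.amplifier.fluors_per_hairpin)
    if channel.probe_kind == "antibody_full_initiator":
        initiators = probes * int(channel.initiators_per_probe)
        nsd = simulate_amplification(initiators, channel.amplifier, rng)
    else:  # lone split-initiator probes cannot trigger HCR
        nsd = (probes * f).astype(np.float64)

    nsa = (rng.poisson(bp.nsa_rate, size=shape) * f).astype(np.float64)
    return BackgroundFields(af=af, nsd=nsd, nsa=nsa, nsd_probes=probes)


def render(fluorophores: np.ndarray, optics: OpticsParams, pixel_size: float,
           seed, background: np.ndarray | None = None) -> np.ndarray:
    """Microscope forward model: PSF blur, photons, noise, dark offset.

    Reflective boundary handling makes the Gaussian convolution conserve
    total intensity.  With shot noise off and zero read noise the output is
    a deterministic function of the input fields.
    """
    rng = _rng(seed)
    field = np.asarray(fluorophores, dtype=np.float64)
    if background is not None:
        if background.shape != field.shape:
            raise ValueError(
                f"background shape {background.shape} != field shape {field.shape}")
        field = field + background
    sigma_px = optics.psf_sigma / pixel_size
    if sigma_px > 0:
        field = gaussian_filter(field, sigma_px, mode="reflect")
    expected = field * optics.photon_scale
    img = rng.poisson(expected).astype(np.float64) if optics.shot_noise else expected
    if optics.read_noise_sd > 0:
        img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    img = img + optics.dark_offset
    return np.clip(img, 0.0, None)


def simulate_experiment(config: SimulationConfig) -> ExperimentResult:
    """Run the full pipeline and render the experiment plus control images.

    Controls reuse the experiment's truth, detection draws and background
    fields: ``unstained`` shows AF only; ``hairpins_only`` AF + NSA;
    ``h1_only`` re-runs the experiment with polymerisation disabled
    (every triggered initiator binds exactly one hairpin, and antibody NSD
    drops to single-hairpin scale).  Only the render-stage noise streams
    differ between images.
    """
    if not config.channels:
        raise ParameterError("config must define at least one channel")
    truth = generate_truth(config)
    shape = config.image_shape
    px = config.pixel_size
    names = tuple(f"{ch.target_id}:{i}" for i, ch in enumerate(config.channels))

    exp, h1, unst, hp = [], [], [], []
    bgs = []
    for i, ch in enumerate(config.channels):
        molecules = truth.counts_for(ch)
        det = simulate_detection(molecules, ch,
                                 stage_rng(config.seed, i, "detection"))
        sig = simulate_amplification(det, ch.amplifier,
                                     stage_rng(config.seed, i, "amplification"))
        bg = simulate_background(shape, ch, px,
                                 stage_rng(config.seed, i, "background"))
        bgs.append(bg)

        h1_amp = replace(ch.amplifier, hairpin_mode="h1_only")
        sig_h1 = simulate_amplification(det, h1_amp, np.random.default_rng(0))
        f = int(ch.amplifier.fluors_per_hairpin)
        if ch.probe_kind == "antibody_full_initiator":
            nsd_h1 = (bg.nsd_probes * int(ch.initiators_per_probe) * f).astype(float)
        else:
            nsd_h1 = bg.nsd
        bg_h1_total = bg.af + nsd_h1 + bg.nsa

        exp.append(render(sig, config.optics, px,
                          stage_rng(config.seed, i, "render_exp"),
                          background=bg.total))
        h1.append(render(sig_h1, config.optics, px,
                         stage_rng(config.seed, i, "render_h1"),
                         background=bg_h1_total))
        unst.append(render(bg.af, config.optics, px,
                           stage_rng(config.seed, i, "render_unstained")))
        hp.append(render(bg.af + bg.nsa, config.optics, px,
                         stage_rng(config.seed, i, "render_hairpins_only")))

    def _stack(frames):
        return ImageStack(data=np.stack(frames), pixel_size_um=px,
                          channel_names=names)

    return ExperimentResult(
        stack=_stack(exp), truth=truth,
        controls={"unstained": _stack(unst), "hairpins_only": _stack(hp),
                  "h1_only": _stack(h1)},
        backgrounds=tuple(bgs))


__all__ = [
    "GroundTruthMap", "BackgroundFields", "ExperimentResult", "stage_rng",
    "generate_truth", "simulate_detection", "simulate_amplification",
    "simulate_background", "render", "simulate_experiment",
]
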