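"""Parameter containers for the HCR imaging simulator.

All physical sizes are in micrometres (µm); intensities are in camera
counts; molecular quantities are integer counts per pixel. Every container
validates its invariants at construction time, so downstream code can
assume well-formed parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

PROBE_KINDS = ("antibody_full_initiator", "split_initiator_pair")
LENGTH_LAWS = ("geometric", "deterministic")
HAIRPIN_MODES = ("paired", "h1_only")
ABUNDANCE_LAWS = ("lognormal", "deterministic")


class ParameterError(ValueError):
    """A parameter violates its documented range or type."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class AmplifierParams:
    """HCR amplifier: how many hairpins a triggered initiator accrues.

    ``mean_polymer_length`` is the amplification gain in hairpins per
    polymer.  ``length_law='geometric'`` draws each polymer length from a
    geometric distribution with support >= 1 (memoryless sequential hairpin
    addition); ``'deterministic'`` uses the mean exactly, for closed-form
    tests.  In ``h1_only`` mode each initiator binds a single h1 hairpin and
    polymerisation cannot proceed, so realised length is 1 regardless of law.
    """

    mean_polymer_length: float = 180.0
    length_law: str = "geometric"
    fluors_per_hairpin: int = 1
    hairpin_mode: str = "paired"

    def __post_init__(self) -> None:
        _check(self.mean_polymer_length >= 1,
               f"mean_polymer_length must be >= 1, got {self.mean_polymer_length}")
        _check(self.length_law in LENGTH_LAWS,
               f"length_law must be one of {LENGTH_LAWS}, got {self.length_law!r}")
        _check(int(self.fluors_per_hairpin) >= 1,
               f"fluors_per_hairpin must be >= 1, got {self.fluors_per_hairpin}")
        _check(self.hairpin_mode in HAIRPIN_MODES,
               f"hairpin_mode must be one of {HAIRPIN_MODES}, got {self.hairpin_mode!r}")


@dataclass(frozen=True)
class BackgroundParams:
    """The three background components of an HCR channel.

    AF: smooth autofluorescence field with mean ``af_mean`` (fluorophore
    equivalents per pixel) and correlation length ``af_corr_length`` (µm).
    NSD: nonspecifically bound detection probes, Poisson ``nsd_rate`` per
    pixel.  NSA: nonspecifically bound single hairpins, Poisson ``nsa_rate``
    per pixel.  NSD is amplified on antibody channels (a nonspecific probe
    still carries a full initiator) but stays at single-hairpin scale on
    split-initiator channels, where a lone probe cannot trigger HCR.
    """

    af_mean: float = 0.0
    af_corr_length: float = 2.0
    nsd_rate: float = 0.0
    nsa_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("af_mean", "af_corr_length", "nsd_rate", "nsa_rate"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel: probe chemistry, amplifier, background."""

    target_id: str
    probe_kind: str = "antibody_full_initiator"
    initiators_per_probe: int = 1
    binding_efficiency: float = 1.0
    interference: float = 0.0
    amplifier: AmplifierParams = field(default_factory=AmplifierParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)

    def __post_init__(self) -> None:
        _check(self.probe_kind in PROBE_KINDS,
               f"probe_kind must be one of {PROBE_KINDS}, got {self.probe_kind!r}")
        _check(int(self.initiators_per_probe) >= 1,
               f"initiators_per_probe must be >= 1, got {self.initiators_per_probe}")
        _check(0.0 <= self.binding_efficiency <= 1.0,
               f"binding_efficiency must be in [0, 1], got {self.binding_efficiency}")
        _check(0.0 <= self.interference <= 1.0,
               f"interference must be in [0, 1], got {self.interference}")

    @property
    def effective_trigger_probability(self) -> float:
        """Per-molecule probability that a functional initiator is colocalised.

        Split-initiator pairs require both half-probes to bind, hence the
        squared efficiency; interference multiplicatively blocks binding.
        """
        p = self.binding_efficiency
        if self.probe_kind == "split_initiator_pair":
            p = p * p
        return p * (1.0 - self.interference)


@dataclass(frozen=True)
class OpticsParams:
    """Microscope forward model: Gaussian PSF, photon statistics, camera."""

    psf_sigma: float = 0.3
    photon_scale: float = 1.0
    read_noise_sd: float = 0.0
    dark_offset: float = 0.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        _check(self.psf_sigma >= 0, f"psf_sigma must be >= 0, got {self.psf_sigma}")
        _check(self.photon_scale > 0, f"photon_scale must be > 0, got {self.photon_scale}")
        _check(self.read_noise_sd >= 0, f"read_noise_sd must be >= 0, got {self.read_noise_sd}")
        _check(self.dark_offset >= 0, f"dark_offset must be >= 0, got {self.dark_offset}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic multichannel experiment.

    ``abundance_law`` sets the per-cell molecule density (molecules/pixel):
    ``{"name": "lognormal", "mean_density": m, "sigma": s}`` draws each
    cell's density from a lognormal with linear-scale mean ``m``, then
    per-pixel counts are Poisson; ``{"name": "deterministic", "density": d}``
    assigns every cell pixel round(d) molecules.  ``cell_axes_um`` bounds the
    uniform draw of elliptical cell semi-axes.  ``seed`` fixes all downstream
    randomness, including control images.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.16
    n_cells: int = 20
    abundance_law: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "lognormal", "mean_density": 5.0, "sigma": 0.6})
    channels: tuple[ChannelSpec, ...] = ()
    seed: int = 0
    cell_axes_um: tuple[float, float] = (2.0, 6.0)
    optics: OpticsParams = field(default_factory=OpticsParams)

    def __post_init__(self) -> None:
        shape = tuple(int(d) for d in self.image_shape)
        object.__setattr__(self, "image_shape", shape)
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "abundance_law", dict(self.abundance_law))
        object.__setattr__(self, "cell_axes_um",
                           tuple(float(a) for a in self.cell_axes_um))
        _check(len(shape) == 2 and all(d >= 1 for d in shape),
               f"image_shape must be two dims >= 1, got {shape}")
        _check(self.pixel_size > 0, f"pixel_size must be > 0, got {self.pixel_size}")
        _check(int(self.n_cells) >= 0, f"n_cells must be >= 0, got {self.n_cells}")
        law = self.abundance_law.get("name")
        _check(law in ABUNDANCE_LAWS,
               f"abundance_law name must be one of {ABUNDANCE_LAWS}, got {law!r}")
        lo, hi = self.cell_axes_um
        _check(0 < lo <= hi, f"cell_axes_um must satisfy 0 < lo <= hi, got {self.cell_axes_um}")
        counts: dict[str, int] = {}
        for ch in self.channels:
            counts[ch.target_id] = counts.get(ch.target_id, 0) + 1
        for tid, n in counts.items():
            _check(n <= 2, f"target {tid!r} appears on {n} channels; "
                           "redundant detection uses exactly two")

    @property
    def target_ids(self) -> tuple[str, ...]:
        """Unique targets in first-channel order."""
        seen: list[str] = []
        for ch in self.channels:
            if ch.target_id not in seen:
                seen.append(ch.target_id)
        return tuple(seen)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


# ---------------------------------------------------------------------------
# Strict (unknown-key-rejecting) config (de)serialisation


def _from_mapping(cls, data: Mapping[str, Any], path: str):
    import dataclasses

    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {path}")
    return data


def channel_from_dict(data: Mapping[str, Any]) -> ChannelSpec:
    data = dict(_from_mapping(ChannelSpec, data, "channel"))
    if isinstance(data.get("amplifier"), Mapping):
        data["amplifier"] = AmplifierParams(
            **_from_mapping(AmplifierParams, data["amplifier"], "channel.amplifier"))
    if isinstance(data.get("background"), Mapping):
        data["background"] = BackgroundParams(
            **_from_mapping(BackgroundParams, data["background"], "channel.background"))
    return ChannelSpec(**data)


def simulation_config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    if "config" in data and isinstance(data["config"], Mapping):
        data = data["config"]  # accept a resolved-parameter sidecar directly
    data = dict(_from_mapping(SimulationConfig, data, "config"))
    if "channels" in data:
        data["channels"] = tuple(
            ch if isinstance(ch, ChannelSpec) else channel_from_dict(ch)
            for ch in data["channels"])
    if isinstance(data.get("optics"), Mapping):
        data["optics"] = OpticsParams(
            **_from_mapping(OpticsParams, data["optics"], "optics"))
    return SimulationConfig(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from YAML or JSON (YAML is a superset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterError(f"config file {path} does not contain a mapping")
    return simulation_config_from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__ = [
    "AmplifierParams", "BackgroundParams", "ChannelSpec", "OpticsParams",
    "SimulationConfig", "ParameterError", "channel_from_dict",
    "simulation_config_from_dict", "load_config", "dump_config", "replace",
]
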