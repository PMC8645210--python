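"""Signal, background and amplification-gain estimation.

Background decomposes into three components measured from control images
by sequential subtraction:

* AF  — autofluorescence, from an unstained control;
* NSA — nonspecifically bound single hairpins, from a hairpins-only
  control (after removing AF);
* NSD — nonspecifically bound detection probes, from a non-expressing
  region of the experiment image (after removing AF and NSA).

Amplification gain (mean hairpins per polymer) is estimated by comparing
background-subtracted signal with both hairpins present (polymerisation
proceeds) against signal with h1 only (each initiator binds a single
hairpin), assuming equal fluorophores per hairpin in both arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .quant import VoxelGrid, _tls_line

_REL_TOL = 1e-6


@dataclass(frozen=True)
class BackgroundComponents:
    """AF/NSD/NSA estimates; a component without its control is
    ``None`` and listed in ``unresolved`` rather than silently zero."""

    af: float | None
    nsd: float | None
    nsa: float | None
    unresolved: tuple[str, ...] = ()

    @property
    def total(self) -> float | None:
        if self.unresolved:
            return None
        return self.af + self.nsd + self.nsa

    def to_dict(self) -> dict:
        return {"AF": self.af, "NSD": self.nsd, "NSA": self.nsa,
                "total": self.total, "unresolved": list(self.unresolved)}


@dataclass(frozen=True)
class SBEstimate:
    signal_mean: float
    background_total: float
    components: BackgroundComponents
    ratio: float
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"signal_mean": self.signal_mean,
                "background_total": self.background_total,
                "components": self.components.to_dict(),
                "ratio": self.ratio, "warnings": list(self.warnings)}


@dataclass(frozen=True)
class GainEntry:
    signal_paired: float
    signal_h1_only: float

    @property
    def gain(self) -> float:
        return self.signal_paired / self.signal_h1_only

    def to_dict(self) -> dict:
        return {"signal_paired": self.signal_paired,
                "signal_h1_only": self.signal_h1_only, "gain": self.gain}


@dataclass(frozen=True)
class StratumFit:
    lo: float
    hi: float
    slope: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "slope": self.slope,
                "n_voxels": self.n_voxels}


@dataclass(frozen=True)
class CrowdingReport:
    """Slope consistency across intensity strata.

    A saturating (crowded) channel bends the voxel scatter, so stratum
    slopes drift from the global slope; ``flagged`` marks a maximum
    relative deviation above threshold.
    """

    strata: tuple[StratumFit, ...]
    slope_all: float
    max_rel_slope_dev: float
    threshold: float
    flagged: bool
    dropped: tuple[int, ...] = ()  # zero-variance strata, by index

    def to_dict(self) -> dict:
        return {"strata": [s.to_dict() for s in self.strata],
                "slope_all": self.slope_all,
                "max_rel_slope_dev": self.max_rel_slope_dev,
                "threshold": self.threshold, "flagged": self.flagged,
                "dropped": list(self.dropped)}


def estimate_signal(image: np.ndarray, signal_mask: np.ndarray,
                    dark_offset: float = 0.0) -> float:
    """Mean dark-subtracted intensity over the mask (signal + background).

    Pixels below the dark offset clip to zero before averaging.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(signal_mask, bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ValueError("signal mask is empty")
    return float(np.clip(image[mask] - dark_offset, 0.0, None).mean())


def estimate_background_components(
        experiment: np.ndarray | None = None,
        unstained_ctrl: np.ndarray | None = None,
        hairpins_only_ctrl: np.ndarray | None = None,
        nonexpressing_mask: np.ndarray | None = None,
        dark_offset: float = 0.0) -> BackgroundComponents:
    """Decompose background into AF, NSA and NSD by sequential subtraction.

    AF  = mean(unstained) - dark
    NSA = mean(hairpins_only) - dark - AF          (clipped at 0)
    NSD = mean(experiment | nonexpressing) - dark - AF - NSA  (clipped at 0)

    Any component whose control (or prerequisite component) is missing is
    reported as unresolved, never as zero.
    """
    unresolved: list[str] = []
    af = nsa = nsd = None
    if unstained_ctrl is not None:
        af = max(float(np.mean(unstained_ctrl)) - dark_offset, 0.0)
    else:
        unresolved.append("AF")
    if hairpins_only_ctrl is not None and af is not None:
        nsa = max(float(np.mean(hairpins_only_ctrl)) - dark_offset - af, 0.0)
    else:
        unresolved.append("NSA")
    if (experiment is not None and nonexpressing_mask is not None
            and af is not None and nsa is not None):
        mask = np.asarray(nonexpressing_mask, bool)
        if not mask.any():
            raise ValueError("non-expressing mask is empty")
        mean_bg = float(np.mean(np.asarray(experiment, float)[mask]))
        nsd = max(mean_bg - dark_offset - af - nsa, 0.0)
    else:
        unresolved.append("NSD")
    return BackgroundComponents(af=af, nsd=nsd, nsa=nsa,
                                unresolved=tuple(unresolved))


def signal_to_background(experiment: np.ndarray, signal_mask: np.ndarray,
                         components: BackgroundComponents,
                         dark_offset: float = 0.0) -> SBEstimate:
    """Background-subtracted signal and S/B ratio.

    Negative signal after subtraction clips to zero with a warning in the
    report; a zero background total leaves the ratio undefined and raises.
    """
    total = components.total
    if total is None:
        raise ValueError(
            f"background components unresolved: {components.unresolved}")
    if total <= 0.0:
        raise ValueError("background total is zero; S/B ratio undefined")
    raw = estimate_signal(experiment, signal_mask, dark_offset)
    notes: tuple[str, ...] = ()
    signal = raw - total
    if signal < 0.0:
        msg = (f"background-subtracted signal is negative "
               f"({signal:.4g}); clipped to 0")
        warnings.warn(msg, stacklevel=2)
        notes = (msg,)
        signal = 0.0
    return SBEstimate(signal_mean=signal, background_total=total,
                      components=components, ratio=signal / total,
                      warnings=notes)


def estimate_gain(paired_img: np.ndarray, h1_only_img: np.ndarray,
                  signal_mask: np.ndarray,
                  background_paired: float = 0.0,
                  background_h1_only: float = 0.0,
                  dark_offset: float = 0.0) -> GainEntry:
    """Amplification gain = paired signal / h1-only signal.

    Both signals are background-subtracted per arm.  Equal to the mean
    polymer length in hairpins when both arms use the same fluorophores
    per hairpin.  A nonpositive h1-only signal leaves the gain
    unidentifiable and raises.
    """
    sig_p = estimate_signal(paired_img, signal_mask, dark_offset) - background_paired
    sig_h = estimate_signal(h1_only_img, signal_mask, dark_offset) - background_h1_only
    if sig_h <= 0.0:
        raise ValueError(
            f"h1-only signal is nonpositive ({sig_h:.4g}); gain unidentifiable")
    return GainEntry(signal_paired=float(sig_p), signal_h1_only=float(sig_h))


def median_gain(entries) -> float:
    """Median gain over scenarios; an even count averages the middle two."""
    gains = [e.gain if isinstance(e, GainEntry) else float(e) for e in entries]
    if not gains:
        raise ValueError("no gain entries")
    return float(np.median(gains))


def crowding_diagnostic(ch1: VoxelGrid, ch2: VoxelGrid,
                        mask: np.ndarray | None = None,
                        n_strata: int = 4,
                        threshold: float = 0.2) -> CrowdingReport:
    """Slope-consistency check across total-intensity strata.

    Masked voxels are split into ``n_strata`` quantile bins of x1 + x2 and
    an orthogonal-regression slope is fitted per bin.  Systematic crowding
    (e.g. saturation) makes stratum slopes deviate from the global slope;
    a maximum relative deviation above ``threshold`` flags the comparison.
    Zero-variance strata are dropped and reported.
    """
    if n_strata < 2:
        raise ValueError(f"n_strata must be >= 2, got {n_strata}")
    sel = np.ones(ch1.values.shape, bool) if mask is None else np.asarray(mask, bool)
    x = ch1.values[sel].ravel()
    y = ch2.values[sel].ravel()
    if x.size < n_strata * 10:
        raise ValueError(
            f"need >= {n_strata * 10} masked voxels for {n_strata} strata, "
            f"got {x.size}")
    slope_all, _, _ = _tls_line(x, y)
    s = x + y
    edges = np.quantile(s, np.linspace(0.0, 1.0, n_strata + 1))
    strata: list[StratumFit] = []
    dropped: list[int] = []
    for i in range(n_strata):
        lo, hi = edges[i], edges[i + 1]
        inb = (s >= lo) & (s <= hi if i == n_strata - 1 else s < hi)
        xs, ys = x[inb], y[inb]
        if xs.size < 2 or np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
            dropped.append(i)
            continue
        try:
            sl, _, _ = _tls_line(xs, ys)
        except ValueError:
            dropped.append(i)
            continue
        strata.append(StratumFit(lo=float(lo), hi=float(hi), slope=float(sl),
                                 n_voxels=int(xs.size)))
    if not strata:
        raise ValueError("all strata degenerate; crowding diagnostic undefined")
    max_dev = max(abs(st.slope - slope_all) / abs(slope_all) for st in strata)
    return CrowdingReport(strata=tuple(strata), slope_all=float(slope_all),
                          max_rel_slope_dev=float(max_dev),
                          threshold=float(threshold),
                          flagged=bool(max_dev > threshold),
                          dropped=tuple(dropped))


__all__ = [
    "BackgroundComponents", "SBEstimate", "GainEntry", "StratumFit",
    "CrowdingReport", "estimate_signal", "estimate_background_components",
    "signal_to_background", "estimate_gain", "median_gain",
    "crowding_diagnostic",
]
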