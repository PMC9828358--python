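"""Synthetic-data generators for every input class the pipeline consumes.

The study's raw inputs (TCSPC photon histograms, polarized intensities,
Wilhelmy tension titrations, MD dihedral/SASA series) are not deposited, so
all analyses are exercised on synthetic data generated here with explicit
noise models and seeds:

* TCSPC decays are the discrete causal convolution of an area-normalized IRF
  (Gaussian, FWHM 600 ps by default, or an exact delta for analytic tests)
  with a multi-exponential, scaled to a target peak count, with optional
  per-channel Poisson noise.  The default time base is 2048 channels over a
  200 ns window (5 MHz excitation repetition period).
* Anisotropy titrations follow the hyperbolic one-to-one binding model with
  optional Gaussian noise.
* Tension titrations are continuous two-segment piecewise-linear curves in
  log10(concentration) with optional Gaussian noise.
* Dihedral series place exact per-state frame counts (largest-remainder
  rounding) around the canonical chi1 rotamer centers with a truncated
  Gaussian spread, so classified occupancies equal the requested fractions
  by construction.
* SASA samples are truncated (non-negative) Gaussian mixtures.

Every generator is a pure function of its spec and integer seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .anisotropy import AnisotropyTitration
from .exceptions import ValidationError
from .rotamers import ROTAMER_STATES, STATE_CENTERS, DihedralSeries, SASASamples
from .tcspc import DecayHistogram, _causal_convolve
from .tension import TensionTitration

__all__ = [
    "IRFModel",
    "DecaySimSpec",
    "gen_tcspc_decay",
    "gen_anisotropy_titration",
    "gen_tension_titration",
    "gen_dihedral_series",
    "gen_sasa_samples",
    "largest_remainder_counts",
]

#: default TCSPC time base: 2048 channels spanning the 200 ns repetition period
DEFAULT_N_CHANNELS = 2048
DEFAULT_CHANNEL_WIDTH_NS = 200.0 / 2048
DEFAULT_IRF_FWHM_NS = 0.6


@dataclasses.dataclass(frozen=True)
class IRFModel:
    """Instrument response function model.

    ``gaussian`` uses the given FWHM; ``delta`` puts all weight in the
    channel nearest ``center`` (useful for analytic tests, where convolution
    reduces to a shift).  The default center, 5 x FWHM from the window start,
    keeps the rising edge fully inside the window.
    """

    shape: str = "gaussian"
    fwhm: float = DEFAULT_IRF_FWHM_NS  # ns
    center: float | None = None  # ns; default 5*fwhm for gaussian, 0 for delta

    def __post_init__(self):
        if self.shape not in ("gaussian", "delta"):
            raise ValidationError("IRF shape must be 'gaussian' or 'delta'")
        if self.shape == "gaussian" and not self.fwhm > 0:
            raise ValidationError("gaussian IRF needs fwhm > 0")
        if self.center is None:
            center = 5.0 * self.fwhm if self.shape == "gaussian" else 0.0
            object.__setattr__(self, "center", center)
        elif self.center < 0:
            raise ValidationError("IRF center must be non-negative")

    def weights(self, n_channels: int, channel_width: float) -> np.ndarray:
        """Area-normalized per-channel weights (sum exactly 1)."""
        if self.shape == "delta":
            w = np.zeros(n_channels)
            idx = int(round(self.center / channel_width))
            if not 0 <= idx < n_channels:
                raise ValidationError("delta IRF center outside the window")
            w[idx] = 1.0
            return w
        t = np.arange(n_channels) * channel_width
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * ((t - self.center) / sigma) ** 2)
        total = w.sum()
        if total <= 0:
            raise ValidationError("gaussian IRF has no weight inside the window")
        return w / total

    def to_dict(self) -> dict:
        return {"shape": self.shape, "fwhm_ns": self.fwhm, "center_ns": self.center}


@dataclasses.dataclass(frozen=True)
class DecaySimSpec:
    """Specification of a simulated TCSPC acquisition.

    ``components`` are (lifetime ns, amplitude) pairs; amplitudes may also be
    derived from target fractional intensities via
    :meth:`from_fractional_intensities` (A_i proportional to f_i / tau_i).
    """

    components: tuple
    irf: IRFModel = IRFModel()
    n_channels: int = DEFAULT_N_CHANNELS
    channel_width: float = DEFAULT_CHANNEL_WIDTH_NS
    peak_counts: float = 1e4
    noise: str = "none"
    seed: int = 0

    def __post_init__(self):
        comps = tuple((float(tau), float(amp)) for tau, amp in self.components)
        if not comps:
            raise ValidationError("at least one decay component is required")
        taus = np.array([c[0] for c in comps])
        amps = np.array([c[1] for c in comps])
        if np.any(taus <= 0):
            raise ValidationError("lifetimes must be strictly positive")
        if np.any(amps < 0):
            raise ValidationError("amplitudes must be non-negative")
        srt = np.sort(taus)
        if np.any(srt[1:] / srt[:-1] < 1.0 + 1e-9):
            raise ValidationError("lifetimes must be distinct")
        if self.n_channels < 64:
            raise ValidationError("n_channels must be at least 64")
        if not self.channel_width > 0:
            raise ValidationError("channel_width must be positive")
        if not self.peak_counts > 0:
            raise ValidationError("peak_counts must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValidationError("noise must be 'none' or 'poisson'")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_fractional_intensities(
        cls,
        lifetimes: Sequence[float],
        fractions: Sequence[float],
        **kwargs,
    ) -> "DecaySimSpec":
        """Build a spec from target intensity fractions (A_i ~ f_i / tau_i)."""
        taus = np.asarray(lifetimes, dtype=float)
        f = np.asarray(fractions, dtype=float)
        if taus.shape != f.shape:
            raise ValidationError("lifetimes and fractions must match")
        if np.any(f < 0) or f.sum() <= 0:
            raise ValidationError("fractions must be non-negative with positive sum")
        amps = f / taus
        amps = amps / amps.sum()
        return cls(components=tuple(zip(taus, amps)), **kwargs)

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "irf": self.irf.to_dict(),
            "n_channels": self.n_channels,
            "channel_width_ns": self.channel_width,
            "peak_counts": self.peak_counts,
            "noise": self.noise,
            "seed": self.seed,
        }


def gen_tcspc_decay(spec: DecaySimSpec) -> tuple[DecayHistogram, DecayHistogram]:
    """Simulate a TCSPC decay and its recorded IRF.

    The noiseless curve is the discrete convolution of the unit-area IRF
    with ``sum_i A_i exp(-t/tau_i)``, scaled so the maximum channel equals
    ``peak_counts``.  With ``noise='poisson'`` each channel is replaced by a
    Poisson draw with that expectation.  The recorded IRF is returned
    noiseless, scaled to the same peak.  Identical spec + seed gives
    bit-identical output.
    """
    t = np.arange(spec.n_channels) * spec.channel_width
    curve = np.zeros(spec.n_channels)
    for tau, amp in spec.components:
        curve += amp * np.exp(-t / tau)
    irf_w = spec.irf.weights(spec.n_channels, spec.channel_width)
    model = _causal_convolve(irf_w, curve)
    peak = model.max()
    if peak <= 0:
        raise ValidationError("simulated decay has no signal")
    model = model * (spec.peak_counts / peak)

    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(model).astype(float)
    else:
        counts = model

    origin = int(np.argmax(model))
    decay = DecayHistogram(counts, spec.channel_width, origin_channel=origin)
    irf_counts = irf_w * (spec.peak_counts / irf_w.max())
    irf_hist = DecayHistogram(
        irf_counts, spec.channel_width, origin_channel=int(np.argmax(irf_w))
    )
    return decay, irf_hist


def gen_anisotropy_titration(
    kd: float,
    r_free: float,
    r_bound: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AnisotropyTitration:
    """Anisotropy titration from the one-to-one binding model,
    r(C) = r_free + (r_bound - r_free) * C / (kd + C), with optional
    Gaussian noise of standard deviation ``noise_sd``."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValidationError("concentration list must not be empty")
    if not kd > 0:
        raise ValidationError("kd must be positive")
    if r_bound == r_free:
        raise ValidationError("r_bound must differ from r_free")
    r = r_free + (r_bound - r_free) * conc / (kd + conc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=conc.size)
    sd = np.full(conc.size, noise_sd) if noise_sd > 0 else None
    return AnisotropyTitration(concentration=conc, anisotropy=r, anisotropy_sd=sd)


def gen_tension_titration(
    cac: float,
    gamma_high: float,
    gamma_low: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TensionTitration:
    """Two-segment surface-tension titration: gamma falls linearly in
    log10(C) from ``gamma_high`` at the lowest concentration to ``gamma_low``
    at the breakpoint ``cac`` and stays flat above it (continuous at the
    breakpoint)."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValidationError("concentration list must not be empty")
    if not gamma_high > gamma_low:
        raise ValidationError("gamma_high must exceed gamma_low")
    if not (conc.min() <= cac <= conc.max()):
        raise ValidationError("cac must lie inside the concentration range")
    logc = np.log10(conc)
    log_cac = np.log10(cac)
    denom = log_cac - logc.min()
    slope = (gamma_high - gamma_low) / denom if denom > 0 else 0.0
    gamma = np.where(logc < log_cac, gamma_low + slope * (log_cac - logc), gamma_low)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gamma = gamma + rng.normal(0.0, noise_sd, size=conc.size)
        gamma = np.clip(gamma, 1e-6, 100.0)
    sd = np.full(conc.size, noise_sd) if noise_sd > 0 else None
    return TensionTitration(concentration=conc, gamma=gamma, gamma_sd=sd)


def largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to fractions, by the
    largest-remainder rule (ties broken by position)."""
    exact = fractions * n
    base = np.floor(exact + 1e-9).astype(int)
    short = n - base.sum()
    if short > 0:
        remainders = exact - base
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def gen_dihedral_series(
    occupancies: dict,
    n_frames: int,
    within_state_sd: float = 15.0,
    seed: int = 0,
) -> DihedralSeries:
    """Chi1 series with exact per-state frame counts.

    Counts per state are largest-remainder rounded so they sum to
    ``n_frames`` exactly; angles are drawn around the canonical state centers
    (60/180/300 degrees) with a Gaussian spread truncated to +/-60 degrees of
    the center, so every frame classifies into its generating state.  Frames
    are shuffled (seeded) before return.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be at least 1")
    if not set(occupancies) <= set(ROTAMER_STATES):
        raise ValidationError(f"unknown rotamer state in {sorted(occupancies)}")
    fracs = np.array([float(occupancies.get(s, 0.0)) for s in ROTAMER_STATES])
    if np.any(fracs < 0):
        raise ValidationError("occupancy fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError("occupancy fractions must sum to 1")
    counts = largest_remainder_counts(fracs, n_frames)

    rng = np.random.default_rng(seed)
    angles = []
    for state, count in zip(ROTAMER_STATES, counts):
        if count == 0:
            continue
        center = STATE_CENTERS[state]
        if within_state_sd <= 0:
            dev = np.zeros(count)
        else:
            dev = rng.normal(0.0, within_state_sd, size=count)
            bad = np.abs(dev) >= 60.0
            while np.any(bad):  # truncate: redraw outliers
                dev[bad] = rng.normal(0.0, within_state_sd, size=int(bad.sum()))
                bad = np.abs(dev) >= 60.0
        angles.append(np.mod(center + dev, 360.0))
    chi1 = np.concatenate(angles)
    rng.shuffle(chi1)
    return DihedralSeries(chi1=chi1)


def gen_sasa_samples(
    modes: Sequence[tuple[float, float, float]],
    n: int,
    seed: int = 0,
) -> SASASamples:
    """Truncated Gaussian-mixture SASA samples.

    ``modes`` is a list of (mean nm^2, weight, sd nm^2); weights must sum to
    1 and draws are redrawn until non-negative (SASA cannot be negative).
    """
    if not modes:
        raise ValidationError("need at least one mixture mode")
    means = np.array([m[0] for m in modes], dtype=float)
    weights = np.array([m[1] for m in modes], dtype=float)
    sds = np.array([m[2] for m in modes], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("mode weights must be non-negative and sum to 1")
    if np.any(sds <= 0):
        raise ValidationError("mode standard deviations must be positive")
    if n < 1:
        raise ValidationError("n must be at least 1")

    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=weights)
    values = rng.normal(means[comp], sds[comp])
    bad = values < 0.0
    while np.any(bad):  # truncate at zero by redrawing
        values[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = values < 0.0
    return SASASamples(values=values)
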