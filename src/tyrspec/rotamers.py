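"""Side-chain chi1 rotamer states and SASA multimodality analysis.

Tyrosine side chains populate three canonical chi1 rotamers: g+ around 60
degrees, t around 180 degrees and g- around 300 degrees.  Working on the
[0, 360) circle, frames are classified by thirds of the circle (half-open
intervals, boundary angles assigned upward) and occupancies are reported as
percentages over all pooled frames.  Solvent-accessible surface area (SASA)
samples are characterized by kernel-density mode analysis: burial of a
residue in an oligomer core shows up as extra low-SASA modes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ROTAMER_STATES",
    "STATE_CENTERS",
    "DihedralSeries",
    "RotamerOccupancy",
    "SASASamples",
    "SASAModes",
    "classify_chi1",
    "rotamer_occupancy",
    "sasa_modes",
]

ROTAMER_STATES = ("g+", "t", "g-")
#: canonical chi1 of each rotamer state, degrees
STATE_CENTERS = {"g+": 60.0, "t": 180.0, "g-": 300.0}


@dataclasses.dataclass(frozen=True)
class DihedralSeries:
    """Per-frame chi1 (and optionally chi2) dihedral angles, degrees.

    Angles are wrapped into [0, 360) on construction; chi2 is stored but not
    used for state classification (the informative coordinate is chi1)."""

    chi1: np.ndarray
    chi2: np.ndarray | None = None
    frames: np.ndarray | None = None
    residues: Sequence[str] | None = None

    def __post_init__(self):
        chi1 = np.asarray(self.chi1, dtype=float)
        if chi1.ndim != 1 or chi1.size == 0:
            raise ValidationError("chi1 must be a non-empty 1-D array")
        if np.any(~np.isfinite(chi1)):
            raise ValidationError("chi1 angles must be finite")
        object.__setattr__(self, "chi1", np.mod(chi1, 360.0))
        if self.chi2 is not None:
            chi2 = np.asarray(self.chi2, dtype=float)
            if chi2.shape != chi1.shape or np.any(~np.isfinite(chi2)):
                raise ValidationError("chi2 must be finite and match chi1")
            object.__setattr__(self, "chi2", np.mod(chi2, 360.0))
        if self.frames is None:
            object.__setattr__(self, "frames", np.arange(chi1.size))

    @property
    def n_frames(self) -> int:
        return self.chi1.size


@dataclasses.dataclass(frozen=True)
class RotamerOccupancy:
    """Percent of frames in each chi1 state; sums to 100."""

    percent: dict
    n_frames: int

    def to_dict(self) -> dict:
        return {"percent": dict(self.percent), "n_frames": self.n_frames}


@dataclasses.dataclass(frozen=True)
class SASASamples:
    """Per-frame (or frame-residue) SASA values in nm^2."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("values must be a non-empty 1-D array")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("SASA values must be finite and non-negative")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size


@dataclasses.dataclass(frozen=True)
class SASAModes:
    """Modes of the kernel-smoothed SASA density.

    Heights are normalized to the global maximum (the highest mode has height
    1 and relative difference 0); ``relative_difference`` of mode i is
    100 * (h_max - h_i) / h_max."""

    locations: np.ndarray  # nm^2
    heights: np.ndarray  # normalized to max 1
    relative_differences: np.ndarray  # percent below the highest mode

    def to_dict(self) -> dict:
        return {
            "locations_nm2": self.locations.tolist(),
            "heights": self.heights.tolist(),
            "relative_differences_percent": self.relative_differences.tolist(),
        }


def classify_chi1(angle):
    """Classify chi1 angles (degrees) into rotamer states.

    Angles are wrapped mod 360 first; states are the half-open thirds
    [0, 120) -> g+, [120, 240) -> t, [240, 360) -> g-, so the map is total on
    the reals and periodic with period 360.  Accepts scalars or arrays.
    """
    arr = np.asarray(angle, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValidationError("angles must be finite")
    wrapped = np.mod(arr, 360.0)
    # np.mod can round up to exactly 360.0 for tiny negative angles
    wrapped = np.where(wrapped >= 360.0, 0.0, wrapped)
    idx = np.minimum((wrapped // 120.0).astype(int), 2)
    if arr.ndim == 0:
        return ROTAMER_STATES[int(idx)]
    return np.asarray(ROTAMER_STATES, dtype=object)[idx]


def rotamer_occupancy(series: DihedralSeries) -> RotamerOccupancy:
    """Percent of frames per rotamer state, pooled over all residues."""
    if series.n_frames == 0:
        raise ValidationError("empty dihedral series")
    states = classify_chi1(series.chi1)
    n = series.n_frames
    percent = {
        state: 100.0 * float(np.count_nonzero(states == state)) / n
        for state in ROTAMER_STATES
    }
    return RotamerOccupancy(percent=percent, n_frames=n)


def sasa_modes(
    samples: SASASamples,
    bandwidth: float = 0.05,
    *,
    min_height_frac: float = 0.05,
    n_grid: int = 2048,
) -> SASAModes:
    """Modes of a Gaussian-kernel density estimate of the SASA samples.

    The density is evaluated on a fixed grid from 0 to max(sample) + 3
    bandwidths; modes are local maxima whose height exceeds
    ``min_height_frac`` of the global maximum.  ``bandwidth`` is the kernel
    standard deviation in nm^2.  Scale-equivariant: scaling samples and
    bandwidth by k scales mode locations by k.
    """
    if not bandwidth > 0:
        raise ValidationError("bandwidth must be positive")
    values = samples.values
    if np.ptp(values) == 0.0:
        loc = float(values[0])
        return SASAModes(
            locations=np.array([loc]),
            heights=np.array([1.0]),
            relative_differences=np.array([0.0]),
        )
    if values.size < 100:
        raise ValidationError("need at least 100 SASA samples")

    grid = np.linspace(0.0, values.max() + 3.0 * bandwidth, n_grid)
    # direct Gaussian KDE, chunked over the grid to bound memory
    density = np.empty(n_grid)
    chunk = max(1, int(4_000_000 // max(values.size, 1)))
    for start in range(0, n_grid, chunk):
        z = (grid[start : start + chunk, None] - values[None, :]) / bandwidth
        density[start : start + chunk] = np.exp(-0.5 * z * z).sum(axis=1)
    density /= density.max()

    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    peaks = list(interior)
    if density[0] > density[1]:
        peaks.insert(0, 0)
    if density[-1] > density[-2]:
        peaks.append(n_grid - 1)
    peaks = [p for p in peaks if density[p] >= min_height_frac]
    if not peaks:  # pragma: no cover - density always has a global max
        peaks = [int(np.argmax(density))]

    locations = grid[peaks]
    heights = density[peaks]
    rel = 100.0 * (1.0 - heights)
    return SASAModes(
        locations=locations,
        heights=heights,
        relative_differences=rel,
    )
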