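"""Maximum-entropy recovery of fluorescence lifetime distributions.

Instead of a fixed number of exponentials, the decay is modelled as a
quasi-continuous distribution g over a log-spaced lifetime grid,

    I(t) = D0 * IRF(t) * sum_j g_j exp(-t / tau_j),

and g is chosen to maximize Q = S - lambda*C, where C is the Poisson-weighted
chi-square of the re-convolved model and S is the Shannon-Jaynes entropy
relative to a prior F,

    S(g, F) = sum_j [ g_j - F_j - g_j ln(g_j / F_j) ].

S <= 0 with equality iff g = F, so the entropy term pulls the solution toward
the (flat, by default) prior and lambda controls how closely the data are
fit.  lambda is set by the discrepancy principle: it is bracketed and then
bisected until the reduced chi-square falls in a narrow band around 1.  The
stationarity condition g_j = F_j exp(-lambda * dC/dg_j) keeps g positive by
construction and is iterated as a damped multiplicative fixed point.  The
overall scale D0 is re-estimated analytically each iteration (equivalent to
the normalization Lagrange term at its stationary point).

Micro-heterogeneity is summarized by the fuzzy entropy of the normalized
weights w' = g / sum(g),

    H = -(1 / log N) * sum_i w'_i log w'_i,

which is 0 for a single lifetime and 1 for a uniform distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import MemFitError, NoBandsError, ValidationError
from .tcspc import DecayHistogram, _causal_convolve, _check_grids, fit_window

__all__ = [
    "LifetimeGrid",
    "Band",
    "LifetimeDistribution",
    "mem_fit",
    "extract_bands",
    "fuzzy_entropy",
    "shannon_jaynes_entropy",
]


@dataclasses.dataclass(frozen=True)
class LifetimeGrid:
    """Strictly increasing lifetime grid (ns), normally log-spaced."""

    tau: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or tau.size < 2:
            raise ValidationError("grid needs at least two lifetimes")
        if tau[0] <= 0 or np.any(np.diff(tau) <= 0):
            raise ValidationError("grid must be strictly increasing and positive")
        object.__setattr__(self, "tau", tau)

    @classmethod
    def log_spaced(cls, n_points: int = 150, tau_min: float = 0.01, tau_max: float = 20.0):
        if not (tau_min > 0 and tau_max > tau_min and n_points >= 2):
            raise ValidationError("invalid log grid parameters")
        return cls(np.geomspace(tau_min, tau_max, n_points))

    @property
    def n_points(self) -> int:
        return self.tau.size

    @property
    def log_spacing(self) -> float:
        """Grid spacing in log10(tau) units (uniform for log-spaced grids)."""
        return float(np.median(np.diff(np.log10(self.tau))))


@dataclasses.dataclass(frozen=True)
class Band:
    """Contiguous region of the lifetime distribution around one peak."""

    peak_tau: float  # ns
    weight_percent: float  # 100 * band mass / total mass
    tau_lo: float
    tau_hi: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class LifetimeDistribution:
    """Maximum-entropy lifetime distribution and its summaries."""

    grid: LifetimeGrid
    g: np.ndarray
    scale: float  # D0
    prior: np.ndarray
    lam: float
    chi2_red: float
    fuzzy_entropy: float
    bands: tuple[Band, ...] = ()
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tau_ns": self.grid.tau.tolist(),
            "g": self.g.tolist(),
            "scale": self.scale,
            "lambda": self.lam,
            "chi2_red": self.chi2_red,
            "fuzzy_entropy": self.fuzzy_entropy,
            "bands": [b.to_dict() for b in self.bands],
            "warnings": list(self.warnings),
        }


def shannon_jaynes_entropy(g, prior) -> float:
    """S(g, F) = sum_j [g_j - F_j - g_j ln(g_j/F_j)]; S <= 0, 0 iff g == F."""
    g = np.asarray(g, dtype=float)
    f = np.asarray(prior, dtype=float)
    if np.any(g < 0) or np.any(f <= 0):
        raise ValidationError("g must be non-negative and the prior positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(g > 0, g * np.log(g / f), 0.0)
    return float(np.sum(g - f - term))


def fuzzy_entropy(dist_or_weights) -> float:
    """Normalized Shannon entropy H of the distribution weights, in [0, 1].

    Accepts a :class:`LifetimeDistribution` or a raw weight vector.  Weights
    are normalized internally (w' = g / sum g); the 1/log N prefactor makes H
    independent of the logarithm base.
    """
    if isinstance(dist_or_weights, LifetimeDistribution):
        w = dist_or_weights.g
    else:
        w = np.asarray(dist_or_weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValidationError("need at least two weights")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("total weight must be positive")
    wp = w / total
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(wp > 0, wp * np.log(wp), 0.0)
    h = -float(np.sum(term)) / np.log(w.size)
    return float(min(max(h, 0.0), 1.0))


def extract_bands(dist: "LifetimeDistribution | tuple", threshold_frac: float = 0.01):
    """Segment the distribution into contiguous bands above a threshold.

    Bands are maximal runs of grid points with g >= threshold_frac * max(g)
    (runs are naturally split wherever g dips below the threshold, local
    minima included).  Each band reports the lifetime at its maximum, its
    bounds, and its mass as a percent of the total mass.
    """
    if isinstance(dist, LifetimeDistribution):
        tau, g = dist.grid.tau, dist.g
    else:
        tau, g = dist
        tau = np.asarray(tau, dtype=float)
        g = np.asarray(g, dtype=float)
    if not np.any(g > 0):
        raise NoBandsError("cannot extract bands from an all-zero distribution")
    if not 0 < threshold_frac <= 1:
        raise ValidationError("threshold_frac must be in (0, 1]")

    mask = g >= threshold_frac * g.max()
    total = g.sum()
    bands = []
    i = 0
    n = g.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        run = slice(i, j + 1)
        peak = i + int(np.argmax(g[run]))
        bands.append(
            Band(
                peak_tau=float(tau[peak]),
                weight_percent=float(100.0 * g[run].sum() / total),
                tau_lo=float(tau[i]),
                tau_hi=float(tau[j]),
            )
        )
        i = j + 1
    return bands


def _chi2_solver(b_win, y_win, w_win, ln_prior, dof):
    """Return a function solving the damped multiplicative MEM fixed point at
    a given lambda, warm-started from the previous solution.

    The update g <- F * exp(-lambda * dC/dg) (the stationarity condition of
    Q = S - lambda*C) is applied in log space with a backtracking step size:
    a candidate step is only accepted if it does not decrease Q, which keeps
    the iteration stable at large lambda where the raw fixed point
    oscillates.  D0 is re-estimated analytically at every evaluation."""

    prior = np.exp(ln_prior)

    def stats(ln_g, w):
        """Scale, residuals, chi2 and entropy at fixed Poisson weights."""
        g = np.exp(ln_g)
        m = b_win @ g
        denom = float((w * m) @ m)
        d0 = float((w * y_win) @ m) / denom if denom > 0 else 1.0
        d0 = max(d0, 1e-300)
        resid = d0 * m - y_win
        chi2 = float((w * resid) @ resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(g > 0, g * (ln_g - ln_prior), 0.0)
        entropy = float(np.sum(g - prior - term))
        return g, m, d0, resid, chi2, entropy

    def solve(lam, ln_g0, damping=0.5, tol=1e-6, max_iter=2000):
        ln_g = np.clip(ln_g0, -700.0, 60.0)
        w = w_win  # data-based weights to start, then model-based (IRLS)
        g, m, d0, resid, chi2, entropy = stats(ln_g, w)
        for _ in range(max_iter):
            # refresh the Poisson variances from the current model
            w = 1.0 / np.maximum(d0 * m, 1.0)
            g, m, d0, resid, chi2, entropy = stats(ln_g, w)
            q = entropy - lam * chi2
            grad = 2.0 * d0 * (b_win.T @ (w * resid))
            delta = (ln_prior - lam * grad) - ln_g
            biggest = np.max(np.abs(delta))
            if biggest < tol:
                break
            # cap the log-space step so a huge lambda*grad cannot overshoot
            step = damping * min(1.0, 4.0 / biggest)
            accepted = False
            for _ in range(25):
                ln_new = np.clip(ln_g + step * delta, -700.0, 60.0)
                new = stats(ln_new, w)
                q_new = new[5] - lam * new[4]
                if q_new >= q - 1e-12 * max(abs(q), 1.0):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break  # no uphill step left at these weights: converged
            ln_g = ln_new
            g, m, d0, resid, chi2, entropy = new
        # final chi2 at self-consistent model weights
        w = 1.0 / np.maximum(d0 * m, 1.0)
        chi2 = float((w * resid) @ resid)
        return ln_g, d0, chi2 / dof

    return solve


def mem_fit(
    decay: DecayHistogram,
    irf: DecayHistogram,
    grid: LifetimeGrid | None = None,
    prior: np.ndarray | None = None,
    *,
    chi2_band: tuple[float, float] = (0.98, 1.05),
    band_threshold: float = 0.01,
    damping: float = 0.25,
    inner_tol: float = 1e-6,
    max_inner: int = 4000,
) -> LifetimeDistribution:
    """Maximum-entropy fit of a lifetime distribution to a TCSPC decay.

    Parameters
    ----------
    decay, irf
        Measured (or simulated) decay and instrument response on a common
        channel grid.
    grid
        Lifetime grid; defaults to 150 log-spaced points over 0.01-20 ns.
    prior
        Prior weights F (flat by default); normalized internally.
    chi2_band
        Discrepancy-principle acceptance band for the reduced chi-square.

    Raises
    ------
    MemFitError
        If even the best-fitting lambda cannot bring the reduced chi-square
        down to the acceptance band (the model cannot fit the data).
    """
    grid = grid or LifetimeGrid.log_spaced()
    _check_grids(decay, irf)

    y = decay.counts
    sl = fit_window(y)
    y_win = y[sl]
    w_win = 1.0 / np.maximum(y_win, 1.0)
    dof = y_win.size
    if dof <= grid.n_points // 2:
        raise ValidationError("fit window too small for the lifetime grid")

    t = decay.times
    irf_w = irf.unit_area()
    b_win = np.column_stack(
        [_causal_convolve(irf_w, np.exp(-t / tau))[sl] for tau in grid.tau]
    )

    m = grid.n_points
    if prior is None:
        f = np.full(m, 1.0 / m)
    else:
        f = np.asarray(prior, dtype=float)
        if f.shape != (m,) or np.any(f <= 0):
            raise ValidationError("prior must be positive and match the grid")
        f = f / f.sum()
    ln_prior = np.log(f)

    solve = _chi2_solver(b_win, y_win, w_win, ln_prior, dof)
    lo_band, hi_band = chi2_band

    # Bracket lambda geometrically: chi2(lambda) is non-increasing, chi2(0)
    # is the prior's misfit, large lambda fits as closely as the grid allows.
    lam = 1e-12
    ln_g = ln_prior.copy()
    evaluated = []  # (lam, ln_g, d0, chi2)
    lam_low = None  # chi2 above band
    lam_high = None  # chi2 below band
    best_in_band = None
    for _ in range(40):
        ln_g, d0, chi2 = solve(lam, ln_g, damping=damping, tol=inner_tol, max_iter=max_inner)
        evaluated.append((lam, ln_g.copy(), d0, chi2))
        if lo_band <= chi2 <= hi_band:
            best_in_band = evaluated[-1]
            break
        if chi2 > hi_band:
            lam_low = evaluated[-1]
            lam *= 10.0
        else:
            lam_high = evaluated[-1]
            break
    if best_in_band is None and lam_high is not None and lam_low is not None:
        # bisect in log-lambda between the bracketing pair
        lam_a, ln_a = lam_low[0], lam_low[1]
        lam_b = lam_high[0]
        ln_g = ln_a.copy()
        for _ in range(40):
            lam_mid = np.sqrt(lam_a * lam_b)
            ln_g, d0, chi2 = solve(lam_mid, ln_g, damping=damping, tol=inner_tol, max_iter=max_inner)
            evaluated.append((lam_mid, ln_g.copy(), d0, chi2))
            if lo_band <= chi2 <= hi_band:
                best_in_band = evaluated[-1]
                break
            if chi2 > hi_band:
                lam_a = lam_mid
            else:
                lam_b = lam_mid

    warnings = []
    if best_in_band is None:
        # closest to the discrepancy target among everything evaluated
        evaluated.sort(key=lambda item: abs(item[3] - 1.0))
        lam, ln_g, d0, chi2 = evaluated[0]
        if chi2 > hi_band:
            raise MemFitError(
                f"discrepancy target unreachable: best reduced chi2 {chi2:.4g}",
                chi2_red=chi2,
            )
        warnings.append("lambda bracket exhausted without landing in the chi2 band")
    else:
        lam, ln_g, d0, chi2 = best_in_band

    g = np.exp(ln_g)
    g[g < 1e-290] = 0.0
    total = g.sum()
    if total > 0 and max(g[0], g[-1]) >= 0.05 * total:
        warnings.append("edge saturation: >=5% of total weight on a grid edge point")

    bands = tuple(extract_bands((grid.tau, g), threshold_frac=band_threshold))
    h = fuzzy_entropy(g)
    return LifetimeDistribution(
        grid=grid,
        g=g,
        scale=d0,
        prior=f,
        lam=float(lam),
        chi2_red=float(chi2),
        fuzzy_entropy=h,
        bands=bands,
        warnings=tuple(warnings),
    )
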