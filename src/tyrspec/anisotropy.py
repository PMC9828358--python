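"""Steady-state fluorescence anisotropy and one-to-one binding isotherms.

The anisotropy of the emitted light,

    r = (Ivv - G*Ivh) / (Ivv + 2*G*Ivh),

reports the rotational freedom of the fluorophore; ``G = Ihv/Ihh`` corrects
for the polarization bias of the detection arm.  When a peptide assembles
into larger species its tyrosine anisotropy rises, and the concentration
dependence r(C) is described here by the hyperbolic one-to-one binding model

    r(C) = r_free + (r_bound - r_free) * C / (KD + C),

whose midpoint is the apparent dissociation constant KD.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailureError, UndefinedAnisotropyError, ValidationError

__all__ = [
    "PolarizedIntensities",
    "AnisotropyTitration",
    "BindingFit",
    "compute_anisotropy",
    "compute_g_factor",
    "fit_binding_isotherm",
]


@dataclasses.dataclass(frozen=True)
class PolarizedIntensities:
    """One polarizer configuration set: Ivv (parallel), Ivh (crossed), and
    the horizontal-excitation pair Ihv/Ihh used to derive G."""

    ivv: float
    ivh: float
    ihh: float | None = None
    ihv: float | None = None
    g: float = 1.0

    def __post_init__(self):
        for name in ("ivv", "ivh", "ihh", "ihv"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not self.g > 0:
            raise ValidationError("G factor must be positive")


@dataclasses.dataclass(frozen=True)
class AnisotropyTitration:
    """Anisotropy measured over a strictly increasing concentration series."""

    concentration: np.ndarray  # uM
    anisotropy: np.ndarray
    anisotropy_sd: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentration, dtype=float)
        r = np.asarray(self.anisotropy, dtype=float)
        if conc.ndim != 1 or conc.shape != r.shape or conc.size == 0:
            raise ValidationError("concentration and anisotropy must be matching 1-D arrays")
        if np.any(conc <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentration", conc)
        object.__setattr__(self, "anisotropy", r)
        if self.anisotropy_sd is not None:
            sd = np.asarray(self.anisotropy_sd, dtype=float)
            if sd.shape != conc.shape or np.any(sd <= 0):
                raise ValidationError("anisotropy_sd must be positive and match the series")
            object.__setattr__(self, "anisotropy_sd", sd)


@dataclasses.dataclass(frozen=True)
class BindingFit:
    """Result of a one-to-one binding isotherm fit."""

    kd: float  # uM
    r_free: float
    r_bound: float
    kd_se: float
    r_free_se: float
    r_bound_se: float
    rss: float
    kd_identifiable: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_g_factor(ihv: float, ihh: float) -> float:
    """Instrument G factor from the horizontal-excitation intensity pair.

    With horizontally polarized excitation both emission polarizer settings
    view the same photoselected population, so their ratio isolates the
    relative sensitivity of the two detection channels.
    """
    if ihh == 0:
        raise ZeroDivisionError("Ihh must be nonzero to compute G")
    if ihv < 0 or ihh < 0:
        raise ValidationError("intensities must be non-negative")
    return ihv / ihh


def compute_anisotropy(p: PolarizedIntensities) -> float:
    """Steady-state anisotropy r = (Ivv - G*Ivh) / (Ivv + 2*G*Ivh).

    The G factor multiplies Ivh in both numerator and denominator (the
    standard instrument correction, equal to the uncorrected ratio at G=1).
    Scale-invariant: multiplying all intensities by k > 0 leaves r unchanged.
    """
    g = p.g
    if p.ihh is not None and p.ihv is not None:
        g = compute_g_factor(p.ihv, p.ihh)
    denom = p.ivv + 2.0 * g * p.ivh
    if denom <= 0:
        raise UndefinedAnisotropyError("anisotropy undefined: Ivv + 2*G*Ivh <= 0")
    r = (p.ivv - g * p.ivh) / denom
    return float(r)


def _model(conc: np.ndarray, kd: float, r_free: float, r_bound: float) -> np.ndarray:
    return r_free + (r_bound - r_free) * conc / (kd + conc)


def _linear_solve(conc, r, weights, kd):
    """For fixed KD the model is linear in (r_free, r_bound)."""
    x = conc / (kd + conc)
    a = np.column_stack([1.0 - x, x]) * np.sqrt(weights)[:, None]
    b = r * np.sqrt(weights)
    params, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = a @ params - b
    return params, float(resid @ resid)


def fit_binding_isotherm(
    t: AnisotropyTitration,
    init: BindingFit | None = None,
    *,
    weighted: bool | None = None,
    n_starts: int = 25,
) -> BindingFit:
    """Least-squares fit of the hyperbolic one-to-one binding model.

    KD is multi-started on a log grid spanning [min(C)/10, max(C)*10] (plus
    ``init.kd`` if supplied), with (r_free, r_bound) profiled out linearly at
    each start, so the result does not depend on the initial guess.  Standard
    errors come from the Gauss-Newton covariance at the optimum.  If the
    titration carries per-point standard deviations the fit is weighted by
    1/sd^2 (unless ``weighted=False``).

    A flat titration leaves KD unidentifiable; the returned fit is flagged
    with ``kd_identifiable=False`` rather than raising.
    """
    conc = t.concentration
    r = t.anisotropy
    if np.unique(conc).size < 4:
        raise ValidationError("need at least 4 distinct concentrations")

    use_weights = weighted if weighted is not None else t.anisotropy_sd is not None
    if use_weights and t.anisotropy_sd is None:
        raise ValidationError("weighted fit requested but no anisotropy_sd supplied")
    weights = 1.0 / t.anisotropy_sd**2 if use_weights else np.ones_like(r)

    kd_grid = list(np.geomspace(conc.min() / 10.0, conc.max() * 10.0, n_starts))
    if init is not None and init.kd > 0:
        kd_grid.append(init.kd)

    best = None
    for kd0 in kd_grid:
        (rf, rb), rss = _linear_solve(conc, r, weights, kd0)

        def residual(params):
            kd, r_free, r_bound = params
            return (_model(conc, kd, r_free, r_bound) - r) * np.sqrt(weights)

        try:
            sol = least_squares(
                residual,
                x0=[kd0, rf, rb],
                bounds=([1e-12, -0.5, -0.5], [np.inf, 1.0, 1.0]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=500,
            )
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0] - 1e-15 * max(best[0], 1.0):
            best = (rss, sol)
    if best is None:
        raise FitFailureError("binding isotherm fit did not converge from any start")

    rss, sol = best
    kd, r_free, r_bound = sol.x

    dof = max(conc.size - 3, 1)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.inf)

    span = abs(r_bound - r_free)
    scale = max(np.ptp(r), abs(r).max(), 1e-12)
    identifiable = bool(span > 1e-6 * scale and np.isfinite(ses[0]))
    return BindingFit(
        kd=float(kd),
        r_free=float(r_free),
        r_bound=float(r_bound),
        kd_se=float(ses[0]),
        r_free_se=float(ses[1]),
        r_bound_se=float(ses[2]),
        rss=rss,
        kd_identifiable=identifiable,
    )
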