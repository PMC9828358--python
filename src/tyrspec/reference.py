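"""Literature-reported parameters for the 33-mer gliadin peptide system.

These values, reported for the self-assembly of the immunodominant 33-mer
gliadin peptide (tyrosine fluorescence, surface tension, and MD rotamer/SASA
analysis), parameterize the synthetic fixtures used throughout the test
suite and the acceptance script.  Raw measurements for this system are not
deposited anywhere, so analysis routines are validated by parameter recovery
on data generated from these printed values.
"""

from __future__ import annotations

# --- anisotropy binding isotherm (micromolar range) ---
BINDING_KD_UM = 165.0
R_FREE = 0.028
R_BOUND = 0.16

# --- surface tension / critical aggregation concentration (nanomolar) ---
CAC_NM = 75.0
GAMMA_HIGH_MN_M = 72.1
GAMMA_LOW_MN_M = 63.8

# --- TCSPC instrument ---
IRF_FWHM_NS = 0.6  # 600 ps excitation pulse
REPETITION_PERIOD_NS = 200.0  # 5 MHz repetition rate

#: NLLS results by peptide concentration (uM):
#: (lifetimes tau1..tau3 in ns, fractional intensities f1..f3)
NLLS_TABLE = {
    100: ((4.80, 1.08, 0.02), (0.21, 0.27, 0.52)),
    200: ((4.48, 1.48, 0.13), (0.19, 0.33, 0.50)),
    300: ((5.50, 1.48, 0.26), (0.29, 0.51, 0.47)),
    400: ((6.13, 1.85, 0.54), (0.24, 0.64, 0.13)),
    500: ((5.95, 1.78, 0.49), (0.25, 0.64, 0.11)),
    600: ((6.65, 1.85, 0.51), (0.24, 0.65, 0.11)),
}

#: MEM band results by concentration (uM): (peak lifetimes ns, weights w%).
#: The w% scale is instrument-software specific and is used here only to set
#: the *relative* intensity fractions of simulation fixtures.
MEM_TABLE = {
    100: ((3.38, 0.90, 0.02), (0.54, 3.53, 0.11)),
    200: ((6.06, 2.19, 1.50), (0.96, 6.70, 1.83)),
    300: ((7.07, 2.12, 1.05), (0.81, 9.24, 1.15)),
    400: ((7.76, 2.06, 1.50), (0.58, 11.40, 1.37)),
    500: ((6.25, 1.94, 1.61), (1.15, 15.00, 3.54)),
    600: ((6.25, 1.94, 1.50), (1.14, 14.05, 1.17)),
}

#: Reported chi1 rotamer occupancies (percent, as printed; sums exceed 100).
DIMER_ROTAMER_PERCENT = {"t": 49.0, "g-": 46.0, "g+": 7.0}
DECAMER_ROTAMER_PERCENT = {"g-": 53.0, "t": 43.0, "g+": 7.0}

#: Reported SASA density modes (nm^2) and their height deficits relative to
#: the highest mode (percent).
DIMER_SASA_MODES_NM2 = (0.525, 1.175)
DIMER_SASA_RELDIFF_PERCENT = 37.0
DECAMER_SASA_MODES_NM2 = (0.15, 0.525, 0.975)
DECAMER_SASA_RELDIFF_PERCENT = (48.0, 43.0)


def _renormalize_keep(percent: dict, keep: str) -> dict:
    """Renormalize printed occupancies (which sum to >100) to exactly 100
    while preserving the headline ``keep`` state; the remaining states share
    the leftover proportionally."""
    rest = {s: p for s, p in percent.items() if s != keep}
    rest_total = sum(rest.values())
    leftover = 100.0 - percent[keep]
    out = {keep: percent[keep] / 100.0}
    out.update({s: leftover * p / rest_total / 100.0 for s, p in rest.items()})
    return out


def dimer_rotamer_occupancies() -> dict:
    """Dimer chi1 state fractions renormalized to 1, preserving t exactly."""
    return _renormalize_keep(DIMER_ROTAMER_PERCENT, "t")


def decamer_rotamer_occupancies() -> dict:
    """Decamer chi1 state fractions renormalized to 1, preserving g- exactly."""
    return _renormalize_keep(DECAMER_ROTAMER_PERCENT, "g-")
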