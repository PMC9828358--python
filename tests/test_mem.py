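"""Maximum-entropy lifetime distributions, band extraction, fuzzy entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tyrspec.exceptions import NoBandsError, ValidationError
from tyrspec.mem import (
    LifetimeGrid,
    extract_bands,
    fuzzy_entropy,
    mem_fit,
    shannon_jaynes_entropy,
)
from tyrspec.simulate import DecaySimSpec, gen_tcspc_decay
from tyrspec.tcspc import fit_nlls


def _small_decay(components, noise="none", seed=0):
    spec = DecaySimSpec(
        components=components,
        n_channels=1024,
        channel_width=100.0 / 1024,
        noise=noise,
        seed=seed,
    )
    return gen_tcspc_decay(spec)


SMALL_GRID = LifetimeGrid.log_spaced(80, 0.05, 20.0)


class TestFuzzyEntropy:
    def test_uniform_weights_give_one(self):
        assert fuzzy_entropy(np.full(150, 0.31)) == pytest.approx(1.0)

    def test_single_point_gives_zero(self):
        w = np.zeros(150)
        w[42] = 7.0
        assert fuzzy_entropy(w) == pytest.approx(0.0)

    def test_three_weight_reference_value(self):
        # direct evaluation of the normalized-entropy formula
        assert fuzzy_entropy(np.array([0.1292, 0.8445, 0.0263])) == pytest.approx(
            0.4577, abs=5e-4
        )

    def test_concentrating_mass_decreases_entropy(self):
        # majorization: same total weight on fewer points has lower H
        spread = np.array([0.25, 0.25, 0.25, 0.25, 0.0, 0.0])
        tight = np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0])
        assert fuzzy_entropy(tight) < fuzzy_entropy(spread)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValidationError):
            fuzzy_entropy(np.zeros(10))

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=30).filter(lambda w: sum(w) > 0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, w):
        h = fuzzy_entropy(np.asarray(w))
        assert 0.0 <= h <= 1.0


class TestShannonJaynesEntropy:
    def test_zero_iff_equal_to_prior(self):
        f = np.full(50, 0.02)
        assert shannon_jaynes_entropy(f, f) == pytest.approx(0.0, abs=1e-15)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_positive(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.01, 1.0, 30)
        g = rng.uniform(0.0, 2.0, 30)
        assert shannon_jaynes_entropy(g, f) <= 1e-12


class TestExtractBands:
    def test_single_bump_gives_one_band_at_mode(self):
        tau = np.geomspace(0.1, 10, 100)
        g = np.exp(-0.5 * ((np.log(tau) - np.log(2.0)) / 0.2) ** 2)
        bands = extract_bands((tau, g))
        assert len(bands) == 1
        assert bands[0].peak_tau == pytest.approx(2.0, rel=0.05)
        assert bands[0].weight_percent == pytest.approx(100.0, abs=0.5)

    def test_two_equal_bumps_split_fifty_fifty(self):
        tau = np.geomspace(0.1, 10, 200)
        g = np.exp(-0.5 * ((np.log(tau) - np.log(0.5)) / 0.1) ** 2)
        g += np.exp(-0.5 * ((np.log(tau) - np.log(5.0)) / 0.1) ** 2)
        bands = extract_bands((tau, g))
        assert len(bands) == 2
        assert bands[0].weight_percent == pytest.approx(50.0, abs=1.0)
        assert bands[1].weight_percent == pytest.approx(50.0, abs=1.0)

    def test_all_zero_distribution_rejected(self):
        with pytest.raises(NoBandsError):
            extract_bands((np.geomspace(0.1, 10, 50), np.zeros(50)))

    def test_bands_are_disjoint_and_ordered(self):
        tau = np.geomspace(0.1, 10, 200)
        g = np.exp(-0.5 * ((np.log(tau) - np.log(0.5)) / 0.1) ** 2)
        g += 0.5 * np.exp(-0.5 * ((np.log(tau) - np.log(5.0)) / 0.1) ** 2)
        bands = extract_bands((tau, g))
        for first, second in zip(bands, bands[1:]):
            assert first.tau_hi < second.tau_lo


class TestMemFit:
    def test_noiseless_single_exponential_peaks_at_truth(self):
        decay, irf = _small_decay(((2.0, 1.0),))
        dist = mem_fit(decay, irf, grid=SMALL_GRID)
        peak_tau = dist.grid.tau[np.argmax(dist.g)]
        step = SMALL_GRID.tau[1] / SMALL_GRID.tau[0]
        assert abs(np.log(peak_tau / 2.0)) <= np.log(step)
        # the discrepancy stopping rule smears mass around the true lifetime,
        # but the dominant band still holds the bulk of it at the right peak
        dominant = max(dist.bands, key=lambda b: b.weight_percent)
        assert abs(np.log(dominant.peak_tau / 2.0)) <= np.log(step)
        assert dominant.weight_percent > 50.0

    def test_solution_is_non_negative_with_entropy_at_most_zero(self):
        decay, irf = _small_decay(((2.0, 1.0),), noise="poisson", seed=4)
        dist = mem_fit(decay, irf, grid=SMALL_GRID)
        assert np.all(dist.g >= 0)
        assert shannon_jaynes_entropy(dist.g / dist.g.sum(), dist.prior) <= 1e-12

    def test_chi2_lands_in_discrepancy_band(self):
        decay, irf = _small_decay(((2.0, 1.0),), noise="poisson", seed=4)
        dist = mem_fit(decay, irf, grid=SMALL_GRID)
        assert 0.98 <= dist.chi2_red <= 1.05

    def test_two_well_separated_components_agree_with_nlls(self):
        # dual route: MEM band peaks and masses vs the NLLS fit of the
        # same realization
        spec = DecaySimSpec.from_fractional_intensities(
            [1.0, 8.0],
            [0.5, 0.5],
            n_channels=1024,
            channel_width=100.0 / 1024,
            noise="poisson",
            seed=4,
        )
        decay, irf = gen_tcspc_decay(spec)
        dist = mem_fit(decay, irf, grid=SMALL_GRID)
        bands = sorted(dist.bands, key=lambda b: b.peak_tau)
        assert len(bands) == 2
        nlls = fit_nlls(decay, irf, 2)
        # band peak lifetimes within 10% of the NLLS lifetimes
        assert bands[0].peak_tau == pytest.approx(nlls.lifetimes[1], rel=0.10)
        assert bands[1].peak_tau == pytest.approx(nlls.lifetimes[0], rel=0.10)
        # band masses track the NLLS amplitude fractions (g is an amplitude
        # density, so equal intensity fractions mean an 8:1 amplitude ratio)
        amp_frac = nlls.amplitudes / nlls.amplitudes.sum()
        assert bands[0].weight_percent / 100.0 == pytest.approx(amp_frac[1], rel=0.20)
        assert bands[1].weight_percent / 100.0 == pytest.approx(amp_frac[0], rel=0.20)

    def test_table_fixture_dominant_band_at_published_peak(self, mem_100um_noiseless):
        _, decay, irf = mem_100um_noiseless
        dist = mem_fit(decay, irf)
        dominant = max(dist.bands, key=lambda b: b.weight_percent)
        step = dist.grid.tau[1] / dist.grid.tau[0]
        assert abs(np.log(dominant.peak_tau / 0.90)) <= np.log(step)

    def test_larger_lambda_fits_more_closely(self):
        # discrepancy-principle monotonicity over the bracketing search
        from tyrspec.mem import _chi2_solver
        from tyrspec.tcspc import fit_window

        decay, irf = _small_decay(((2.0, 1.0),), noise="poisson", seed=8)
        sl = fit_window(decay.counts)
        y = decay.counts[sl]
        w = 1.0 / np.maximum(y, 1.0)
        from tyrspec.tcspc import _causal_convolve

        b = np.column_stack(
            [
                _causal_convolve(irf.unit_area(), np.exp(-decay.times / tau))[sl]
                for tau in SMALL_GRID.tau
            ]
        )
        m = SMALL_GRID.n_points
        ln_prior = np.log(np.full(m, 1.0 / m))
        solve = _chi2_solver(b, y, w, ln_prior, y.size)
        ln_g = ln_prior.copy()
        chis = []
        for lam in [1e-9, 1e-7, 1e-5, 1e-4]:
            ln_g, _, chi2 = solve(lam, ln_g)
            chis.append(chi2)
        assert all(c2 <= c1 + 1e-6 for c1, c2 in zip(chis, chis[1:]))
        # as lambda -> 0 the solution stays at the prior
        ln_g0, _, _ = solve(1e-15, ln_prior.copy())
        np.testing.assert_allclose(np.exp(ln_g0), np.full(m, 1.0 / m), rtol=1e-3)

    def test_grid_validation(self):
        with pytest.raises(ValidationError):
            LifetimeGrid(np.array([0.5, 0.4, 1.0]))
        with pytest.raises(ValidationError):
            LifetimeGrid.log_spaced(10, -1.0, 5.0)
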