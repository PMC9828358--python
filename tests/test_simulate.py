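"""Generator correctness: closed forms, determinism, exact state counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tyrspec.exceptions import ValidationError
from tyrspec.rotamers import classify_chi1
from tyrspec.simulate import (
    DecaySimSpec,
    IRFModel,
    gen_anisotropy_titration,
    gen_dihedral_series,
    gen_sasa_samples,
    gen_tcspc_decay,
    gen_tension_titration,
    largest_remainder_counts,
)


class TestTcspcDecay:
    def test_delta_irf_matches_closed_form_multiexponential(self):
        spec = DecaySimSpec(
            components=((4.80, 0.7), (1.2, 0.3)),
            irf=IRFModel(shape="delta"),
            n_channels=512,
            channel_width=0.1,
            noise="none",
        )
        decay, _ = gen_tcspc_decay(spec)
        t = decay.times
        expected = 0.7 * np.exp(-t / 4.80) + 0.3 * np.exp(-t / 1.2)
        expected *= spec.peak_counts / expected.max()
        np.testing.assert_allclose(decay.counts, expected, rtol=1e-12)

    def test_peak_scaled_to_requested_counts(self):
        spec = DecaySimSpec(components=((2.0, 1.0),), peak_counts=5e3, noise="none")
        decay, irf = gen_tcspc_decay(spec)
        assert decay.counts.max() == pytest.approx(5e3)
        assert irf.counts.max() == pytest.approx(5e3)

    def test_identical_seed_and_spec_reproduce_bitwise(self):
        spec = DecaySimSpec(components=((2.0, 1.0),), noise="poisson", seed=42)
        d1, _ = gen_tcspc_decay(spec)
        d2, _ = gen_tcspc_decay(spec)
        assert np.array_equal(d1.counts, d2.counts)

    def test_poisson_mean_converges_to_noiseless_curve(self):
        spec0 = DecaySimSpec(
            components=((2.0, 1.0),), n_channels=256, channel_width=0.1, noise="none"
        )
        noiseless, _ = gen_tcspc_decay(spec0)
        acc = np.zeros_like(noiseless.counts)
        n_rep = 200
        for seed in range(n_rep):
            spec = DecaySimSpec(
                components=((2.0, 1.0),),
                n_channels=256,
                channel_width=0.1,
                noise="poisson",
                seed=seed,
            )
            decay, _ = gen_tcspc_decay(spec)
            acc += decay.counts
        mean = acc / n_rep
        high = noiseless.counts > 100
        np.testing.assert_allclose(mean[high], noiseless.counts[high], rtol=0.05)

    @pytest.mark.parametrize(
        "components",
        [((1.0, 1.0), (1.0, 1.0)), ((-2.0, 1.0),), ()],
        ids=["duplicate-lifetimes", "negative-lifetime", "empty"],
    )
    def test_invalid_components_rejected(self, components):
        with pytest.raises(ValidationError):
            DecaySimSpec(components=components)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            DecaySimSpec(components=((1.0, 1.0),), n_channels=32)

    def test_irf_weights_are_area_normalized(self):
        for model in (IRFModel(shape="gaussian", fwhm=0.6), IRFModel(shape="delta")):
            w = model.weights(2048, 200.0 / 2048)
            assert abs(w.sum() - 1.0) < 1e-9

    def test_fractional_intensity_construction_roundtrip(self):
        spec = DecaySimSpec.from_fractional_intensities([4.0, 1.0], [0.25, 0.75])
        amps = np.array([a for _, a in spec.components])
        taus = np.array([t for t, _ in spec.components])
        f = amps * taus / (amps * taus).sum()
        np.testing.assert_allclose(np.sort(f), [0.25, 0.75])


class TestTitrationGenerators:
    def test_half_saturation_at_kd(self):
        t = gen_anisotropy_titration(165.0, 0.028, 0.16, [165.0, 330.0, 660.0, 1320.0])
        assert t.anisotropy[0] == pytest.approx((0.028 + 0.16) / 2)

    def test_low_concentration_limit_is_r_free(self):
        t = gen_anisotropy_titration(165.0, 0.028, 0.16, [1e-9, 1.0, 10.0, 100.0])
        assert t.anisotropy[0] == pytest.approx(0.028, abs=1e-9)

    def test_plateau_approached_at_high_concentration(self):
        t = gen_anisotropy_titration(165.0, 0.028, 0.16, np.geomspace(100, 1e6, 8))
        assert t.anisotropy[-1] == pytest.approx(0.16, abs=1e-3)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            gen_anisotropy_titration(165.0, 0.028, 0.16, [])

    def test_tension_plateau_above_cac(self):
        t = gen_tension_titration(75.0, 72.1, 63.8, np.geomspace(5, 2000, 10))
        assert np.all(t.gamma[t.concentration > 75.0] == 63.8)

    def test_tension_continuous_at_breakpoint(self):
        conc = np.array([5.0, 20.0, 75.0, 300.0, 1000.0, 2000.0])
        t = gen_tension_titration(75.0, 72.1, 63.8, conc)
        assert t.gamma[2] == pytest.approx(63.8)

    def test_tension_endpoints(self):
        t = gen_tension_titration(75.0, 72.1, 63.8, np.geomspace(5, 2000, 10))
        assert t.gamma[0] == pytest.approx(72.1)

    def test_cac_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            gen_tension_titration(1.0, 72.1, 63.8, [10.0, 100.0, 1000.0])


class TestDihedralGenerator:
    def test_pure_t_state_with_zero_spread_is_exactly_180(self):
        s = gen_dihedral_series({"t": 1.0}, 100, within_state_sd=0.0, seed=0)
        assert np.all(s.chi1 == 180.0)

    def test_three_frames_one_per_state(self):
        s = gen_dihedral_series(
            {"g+": 1 / 3, "t": 1 / 3, "g-": 1 / 3}, 3, within_state_sd=5.0, seed=1
        )
        assert sorted(classify_chi1(s.chi1)) == ["g+", "g-", "t"]

    @pytest.mark.parametrize("sd", [5.0, 15.0, 20.0])
    def test_classified_occupancies_equal_requested_fractions(self, sd):
        occ = {"g+": 0.07, "t": 0.49, "g-": 0.44}
        s = gen_dihedral_series(occ, 2000, within_state_sd=sd, seed=3)
        states = classify_chi1(s.chi1)
        for state, frac in occ.items():
            assert np.count_nonzero(states == state) == round(frac * 2000)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValidationError):
            gen_dihedral_series({"t": 1.2, "g-": -0.2}, 100)

    def test_determinism(self):
        a = gen_dihedral_series({"t": 0.5, "g-": 0.5}, 500, seed=9)
        b = gen_dihedral_series({"t": 0.5, "g-": 0.5}, 500, seed=9)
        assert np.array_equal(a.chi1, b.chi1)

    @given(n=st.integers(1, 500), split=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_largest_remainder_counts_sum_to_n(self, n, split):
        fracs = np.array([split / 2, split / 2, 1.0 - split])
        counts = largest_remainder_counts(fracs, n)
        assert counts.sum() == n
        assert np.all(counts >= 0)


class TestSasaGenerator:
    def test_single_tight_mode_concentrates_at_mean(self):
        s = gen_sasa_samples([(0.5, 1.0, 1e-6)], 200, seed=0)
        np.testing.assert_allclose(s.values, 0.5, atol=1e-4)

    def test_samples_are_non_negative(self):
        s = gen_sasa_samples([(0.05, 1.0, 0.2)], 2000, seed=1)
        assert np.all(s.values >= 0)

    def test_zero_modes_rejected(self):
        with pytest.raises(ValidationError):
            gen_sasa_samples([], 100)

    def test_determinism(self):
        a = gen_sasa_samples([(0.5, 0.6, 0.1), (1.2, 0.4, 0.1)], 300, seed=5)
        b = gen_sasa_samples([(0.5, 0.6, 0.1), (1.2, 0.4, 0.1)], 300, seed=5)
        assert np.array_equal(a.values, b.values)
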