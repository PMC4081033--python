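"""Energy/PWM/periodic affinity tracks and detrend+Fourier periodicity."""

import numpy as np
import pytest

from nuclattice.seqaff import (
    EnergyTrack,
    NoPeriodicityError,
    PWM,
    detrend_fourier_period,
    energy_to_affinity,
    periodic_surrogate_affinity,
    phasing_energy_track,
    pwm_affinity,
    tile_repeat,
)

RC = str.maketrans("ACGT", "TGCA")


class TestEnergyToAffinity:
    def test_constant_energy_normalizes_to_one(self):
        K = energy_to_affinity(EnergyTrack(np.full(50, 3.7)), beta=2.0)
        np.testing.assert_allclose(K, 1.0)

    def test_beta_zero_is_flat(self):
        K = energy_to_affinity(EnergyTrack(np.random.default_rng(0).normal(size=50)),
                               beta=0.0)
        np.testing.assert_allclose(K, 1.0)

    def test_boltzmann_ratio(self):
        K = energy_to_affinity(EnergyTrack(np.array([0.0, 1.0])), beta=2.0)
        assert K[0] / K[1] == pytest.approx(np.e**2)

    def test_monotone_order_preserving(self):
        e = np.array([0.3, -1.2, 2.0, 0.0])
        K = energy_to_affinity(EnergyTrack(e), beta=1.0)
        assert np.all(np.argsort(K) == np.argsort(-e))

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            EnergyTrack(np.array([1.0, np.nan]))


class TestPeriodicSurrogate:
    def test_contrast_one_is_uniform(self):
        np.testing.assert_allclose(periodic_surrogate_affinity(100, 10, 1.0), 1.0)

    def test_bounds_and_period_234(self):
        K = periodic_surrogate_affinity(11700, 234, 4.0)
        assert K.max() == pytest.approx(4.0)
        assert K.min() == pytest.approx(0.25)
        # first non-zero-lag autocorrelation maximum at the period
        x = np.log(K) - np.log(K).mean()
        ac = np.correlate(x, x, "full")[len(x) - 1 :]
        lag = 100 + np.argmax(ac[100:400])
        assert lag == 234

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            periodic_surrogate_affinity(100, 1, 2.0)
        with pytest.raises(ValueError):
            periodic_surrogate_affinity(100, 10, 0.5)


class TestPwmAffinity:
    def test_uniform_pwm_is_flat(self):
        pwm = PWM(np.full((4, 4), 0.25))
        K = pwm_affinity("ACGTACGTACGT", pwm, k_site=2.0)
        np.testing.assert_allclose(K, 2.0)

    def test_consensus_site_scores_k_site_at_unique_maximum(self):
        probs = np.full((5, 4), 0.01)
        for i, b in enumerate("ACGTA"):
            probs[i, "ACGT".index(b)] = 0.97
        pwm = PWM(probs / probs.sum(axis=1, keepdims=True))
        seq = "GGGGGGACGTAGGGGGG"
        K = pwm_affinity(seq, pwm, k_site=5.0)
        assert K.argmax() == seq.index("ACGTA")
        assert K.max() == pytest.approx(5.0)
        assert (K < 5.0).sum() == len(K) - 1

    def test_reverse_complement_strand_symmetry(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM(probs)
        seq = "".join(rng.choice(list("ACGT"), 40))
        K_f = pwm_affinity(seq, pwm, k_site=1.0)
        K_r = pwm_affinity(seq.translate(RC)[::-1], pwm, k_site=1.0)
        np.testing.assert_allclose(K_f, K_r[::-1], rtol=1e-12)

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            pwm_affinity("ACG", PWM(np.full((5, 4), 0.25)), 1.0)


class TestTileRepeat:
    def test_length_arithmetic_for_padded_tandem(self):
        unit = "ACGTACGTAA"
        out = tile_repeat(unit, 5, pad=3)
        assert len(out) == 53
        assert out.endswith(unit * 1 + "ACG"[:3]) or out[-3:] == "ACG"

    def test_identity(self):
        assert tile_repeat("ACGT", 1, 0) == "ACGT"

    def test_positional_periodicity(self):
        unit = "GATTACA"
        out = tile_repeat(unit, 3)
        for i in range(len(out)):
            assert out[i] == unit[i % len(unit)]

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            tile_repeat("", 3)


class TestPhasingEnergyTrack:
    def test_phased_ww_region_scores_below_gc_region(self):
        # frames over in-phase AA dinucleotides get favorable (negative)
        # energy; frames over G/C-only DNA score zero
        seq = ("AA" + "G" * 8) * 40 + "GC" * 200
        track = phasing_energy_track(seq, footprint=100, period=10.0)
        phased = track.values[:200].mean()
        gc_only = track.values[-100:].mean()
        assert gc_only == pytest.approx(0.0, abs=1e-12)
        assert phased < -0.05

    def test_track_length(self):
        seq = "ACGT" * 100
        track = phasing_energy_track(seq, footprint=147)
        assert len(track.values) == len(seq) - 147 + 1


class TestDetrendFourierPeriod:
    def test_pure_sinusoid(self):
        x = np.arange(3000)
        res = detrend_fourier_period(np.sin(2 * np.pi * x / 50), poly_degree=90)
        assert res.period == pytest.approx(50, abs=1.0)

    def test_sinusoid_with_dominant_cubic_trend_and_noise(self):
        rng = np.random.default_rng(11)
        x = np.arange(3000)
        sig = np.sin(2 * np.pi * x / 50)
        trend = 10.0 * (x / 3000 - 0.4) ** 3 * 50
        res = detrend_fourier_period(sig + trend + rng.normal(0, 0.2, x.size),
                                     poly_degree=90)
        assert res.period == pytest.approx(50, abs=1.0)

    @pytest.mark.parametrize("degree", [50, 70, 90, 120])
    def test_stable_across_polynomial_degrees(self, degree):
        # the window must hold well over degree/2 cycles, else the
        # polynomial itself can absorb the oscillation
        L = 30000
        rng = np.random.default_rng(degree)
        x = np.arange(L)
        sig = np.cos(2 * np.pi * x / 181.3) + 0.5 * (x / L) ** 2
        res = detrend_fourier_period(sig + rng.normal(0, 0.3, x.size), degree)
        bin_width = 181.3**2 / L
        assert abs(res.period - 181.3) <= max(bin_width, 0.5)

    @pytest.mark.parametrize("period", [30.0, 80.0, 150.0, 250.0])
    def test_recovers_implanted_periods_with_noise(self, period):
        # SNR ~ 2.5, ten seeded realizations per period; window sized so a
        # degree-90 polynomial cannot absorb the oscillation
        L = max(6000, int(150 * period))
        x = np.arange(L)
        bin_width = period**2 / L
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sig = np.sin(2 * np.pi * x / period) + rng.normal(0, 0.4, x.size)
            res = detrend_fourier_period(sig, poly_degree=90)
            assert abs(res.period - period) <= max(bin_width, 0.5)

    def test_constant_profile_raises(self):
        with pytest.raises(NoPeriodicityError):
            detrend_fourier_period(np.full(1000, 2.0), poly_degree=60)

    def test_spectrum_power_nonnegative(self):
        x = np.arange(1000)
        res = detrend_fourier_period(np.sin(2 * np.pi * x / 40), poly_degree=50)
        assert (res.spectrum["power"] >= 0).all()
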