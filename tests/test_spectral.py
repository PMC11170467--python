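"""Spectral estimation and the four dependence families: closed-form oracle
equivalence on 2x2 spectra, the additive/multiplicative decomposition
identities, symmetry, and blindness of lagged measures to instantaneous
mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegconn as e
from eegconn.core import RegionTimeSeries
from eegconn.spectral import DEFAULT_BANDS, pairwise_triples


def pair_spectrum(c: complex, px: float = 1.0, py: float = 1.0) -> np.ndarray:
    return np.array([[px, c], [np.conjugate(c), py]])


def scalar_oracle(c: complex, px: float = 1.0, py: float = 1.0):
    """Closed scalar forms of the coherence decomposition for a 2x2
    spectrum: total |c|^2, instantaneous Re(c)^2, lagged
    Im(c)^2 / (1 - Re(c)^2), all on the normalized coherency."""
    cn = c / np.sqrt(px * py)
    tot = abs(cn) ** 2
    inst = cn.real ** 2
    lag = cn.imag ** 2 / (1 - cn.real ** 2)
    return inst, lag, tot


@st.composite
def psd_cross_spectra(draw):
    px = draw(st.floats(0.1, 10.0))
    py = draw(st.floats(0.1, 10.0))
    mag = draw(st.floats(0.0, 0.95))
    phase = draw(st.floats(0.0, 2 * np.pi))
    c = mag * np.sqrt(px * py) * np.exp(1j * phase)
    return pair_spectrum(c, px, py)


class TestClosedFormOracles:
    @pytest.mark.parametrize("c, exp_inst, exp_lag", [
        (0.0, 0.0, 0.0),
        (0.6, 0.36, 0.0),
        (0.6j, 0.0, 0.36),
    ])
    def test_coherence_real_imag_split(self, c, exp_inst, exp_lag):
        t = e.coherence(pair_spectrum(c))
        assert t.instantaneous == pytest.approx(exp_inst, abs=1e-10)
        assert t.lagged == pytest.approx(exp_lag, abs=1e-10)
        exp_tot = abs(c) ** 2
        assert t.total == pytest.approx(exp_tot, abs=1e-10)

    @pytest.mark.parametrize("c", [0.6, 0.6j, 0.3 + 0.4j, 0.0])
    def test_linear_connectivity_matches_log_forms(self, c):
        t = e.linear_connectivity(pair_spectrum(c))
        inst, lag, tot = scalar_oracle(c)
        assert t.total == pytest.approx(-np.log(1 - tot), abs=1e-10)
        assert t.instantaneous == pytest.approx(-np.log(1 - inst), abs=1e-10)
        assert t.lagged == pytest.approx(t.total - t.instantaneous, abs=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(psd_cross_spectra())
    def test_determinant_forms_equal_scalar_forms(self, S):
        inst, lag, tot = scalar_oracle(S[0, 1], S[0, 0].real, S[1, 1].real)
        t = e.coherence(S)
        assert t.instantaneous == pytest.approx(inst, abs=1e-10)
        assert t.lagged == pytest.approx(lag, abs=1e-10)
        assert t.total == pytest.approx(tot, abs=1e-10)


class TestDecompositionIdentities:
    def _random_psd(self, rng):
        px, py = rng.uniform(0.1, 5.0, 2)
        mag = rng.uniform(0, 0.95)
        phase = rng.uniform(0, 2 * np.pi)
        return pair_spectrum(mag * np.sqrt(px * py) * np.exp(1j * phase),
                             px, py)

    def test_lc_additivity_and_coh_multiplicativity(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            S = self._random_psd(rng)
            lc = e.linear_connectivity(S)
            assert lc.total == pytest.approx(
                lc.instantaneous + lc.lagged, abs=1e-8)
            coh = e.coherence(S)
            assert (1 - coh.total) == pytest.approx(
                (1 - coh.instantaneous) * (1 - coh.lagged), abs=1e-8)

    def test_symmetry_under_pair_swap(self):
        rng = np.random.default_rng(11)
        S = self._random_psd(rng)
        swap = S[::-1, ::-1]
        for func in (e.linear_connectivity, e.coherence,
                     e.nonlinear_connectivity, e.phase_synchronization):
            a, b = func(S), func(swap)
            assert a.total == pytest.approx(b.total, abs=1e-10)
            assert a.lagged == pytest.approx(b.lagged, abs=1e-10)

    def test_ps_equals_coh_on_normalized_input(self):
        # identical determinant structure, so PS on S_norm == Coh on S_norm
        S = pair_spectrum(0.4 + 0.3j)
        ps = e.phase_synchronization(S)
        coh = e.coherence(S)
        assert ps.as_dict() == pytest.approx(coh.as_dict(), abs=1e-12)

    def test_degenerate_spectrum_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            e.linear_connectivity(np.array([[0.0, 0.0], [0.0, 1.0]]))

    def test_pairwise_matches_per_pair_functions(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((3, 40)) + 1j * rng.standard_normal((3, 40))
        S = A @ A.conj().T / 40
        tri = pairwise_triples(S, "Coh")
        iu, ju = np.triu_indices(3, k=1)
        for k, (i, j) in enumerate(zip(iu, ju)):
            block = S[np.ix_([i, j], [i, j])]
            t = e.coherence(block)
            assert tri["total"][k] == pytest.approx(t.total, rel=1e-9)
            assert tri["lagged"][k] == pytest.approx(t.lagged, abs=1e-9)


class TestCrossSpectralEstimation:
    def test_identical_series_give_unit_normalized_coherency(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256 * 20)
        ts = RegionTimeSeries(np.vstack([x, x]), fs=256.0)
        cs = e.estimate_banded_cross_spectra(ts)
        for band in cs.band_names():
            assert abs(cs.S_norm[band][0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_has_small_coherency(self):
        rng = np.random.default_rng(1)
        ts = RegionTimeSeries(rng.standard_normal((2, 256 * 60)), fs=256.0)
        cs = e.estimate_banded_cross_spectra(ts)
        for band_def in DEFAULT_BANDS:
            band = band_def.name
            n_bins = cs.n_epochs * max(
                1, int((band_def.f_hi - band_def.f_lo) * 2))
            # the Hann taper correlates adjacent frequency bins, reducing
            # the effective sample count by roughly the main-lobe width
            bound = 3.0 / np.sqrt(n_bins / 2.5)
            assert abs(cs.S_norm[band][0, 1]) < bound

    def test_phase_locked_sinusoids_cohere_in_their_band(self):
        fs, n = 256.0, 256 * 20
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 9 * t)
        y = np.sin(2 * np.pi * 9 * t + 0.7)
        ts = RegionTimeSeries(np.vstack([x, y]), fs=fs)
        cs = e.estimate_banded_cross_spectra(ts)
        num = abs(cs.S["alpha1"][0, 1])
        den = np.sqrt(cs.S["alpha1"][0, 0].real * cs.S["alpha1"][1, 1].real)
        assert num / den == pytest.approx(1.0, abs=1e-6)

    def test_constant_phase_shifted_pair_is_perfectly_synchronized(self):
        # rotate every Fourier coefficient of a broadband signal by a fixed
        # angle: the pair is phase-locked at all frequencies, so PS ~ 1
        rng = np.random.default_rng(8)
        x = rng.standard_normal(256 * 20)
        coeffs = np.fft.rfft(x)
        y = np.fft.irfft(coeffs * np.exp(0.7j), n=x.size)
        ts = RegionTimeSeries(np.vstack([x, y]), fs=256.0)
        cs = e.estimate_banded_cross_spectra(ts)
        t_ps = e.phase_synchronization(cs.S_norm["alpha1"])
        assert t_ps.total == pytest.approx(1.0, abs=1e-2)

    def test_too_short_recording_raises_with_minimum(self):
        ts = RegionTimeSeries(np.zeros((2, 100)), fs=256.0)
        with pytest.raises(ValueError, match="too short"):
            e.estimate_banded_cross_spectra(ts)

    def test_band_above_nyquist_raises(self):
        ts = RegionTimeSeries(np.zeros((2, 256 * 10)), fs=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            e.estimate_banded_cross_spectra(ts)


class TestMixingBlindness:
    def test_instantaneous_mixing_spares_lagged_measures(self):
        rng = np.random.default_rng(21)
        src = rng.standard_normal((2, 256 * 30))
        m = 0.4
        mixed = np.vstack([(1 - m) * src[0] + m * src[1],
                           (1 - m) * src[1] + m * src[0]])
        ts = RegionTimeSeries(mixed, fs=256.0)
        cs = e.estimate_banded_cross_spectra(ts)
        for band in ("alpha1", "beta2"):
            coh = e.coherence(cs.S[band])
            ps = e.phase_synchronization(cs.S_norm[band])
            assert coh.instantaneous > 0.2
            assert coh.lagged < 0.05
            assert ps.lagged < 0.05
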