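"""SNR profiles and on/off enhancement along the cochlea."""

import numpy as np
import pytest

from cochamp import (
    ChainConfig,
    bidirectional_enhancement,
    basal_apical_decomposition,
    enhancement_profile_broadband,
    enhancement_profile_narrowband,
    narrowband_noise_rms,
    normalized_signal_noise_curves,
    snr_profile,
)
from cochamp.snr import WKBProvider, make_provider

from conftest import UniformModel


class TestNoiseQuadrature:
    def test_zero_gamma_zero_noise(self, provider_fast):
        assert np.all(narrowband_noise_rms(provider_fast, 10e3, True, gamma=0.0) == 0)

    def test_uniform_medium_constant_integrand(self, uniform_model):
        """|G| constant in magnitude across sources at fixed |x - x'| ...
        the pure-local check: gamma * sqrt(int |G|^2) with the closed form."""
        prov = WKBProvider(uniform_model)
        rms = narrowband_noise_rms(prov, 10e3, True, gamma=2.0)
        G = prov.green_matrix(10e3, True)
        dx = prov.x[1] - prov.x[0]
        expected = 2.0 * np.sqrt(np.trapezoid(np.abs(G) ** 2, dx=dx, axis=1))
        assert np.allclose(rms, expected)

    def test_decomposition_conserves_total(self, provider_fast):
        basal, apical = basal_apical_decomposition(provider_fast, 10e3, True)
        total = narrowband_noise_rms(provider_fast, 10e3, True) ** 2
        idx = np.random.default_rng(0).integers(0, provider_fast.x.size, 10)
        assert np.allclose((basal + apical)[idx], total[idx], rtol=1e-9)

    def test_basal_power_vanishes_at_entrance(self, provider_fast):
        basal, _ = basal_apical_decomposition(provider_fast, 10e3, True)
        assert basal[0] == 0.0

    def test_apical_noise_negligible_at_peak(self, provider_fast):
        """At the characteristic place the cut-off squelches apical sources."""
        basal, apical = basal_apical_decomposition(provider_fast, 10e3, True)
        xh = provider_fast.model.characteristic_place(10e3)
        j = np.argmin(np.abs(provider_fast.x - xh))
        assert apical[j] < 0.01 * basal[j]


class TestSNRProfile:
    def test_snr_identity(self, provider_fast):
        prof = snr_profile(provider_fast, 10e3, True)
        assert np.allclose(prof.snr, prof.signal_rms / prof.noise_rms)
        assert np.allclose(
            prof.noise_rms**2,
            prof.basal_noise_power + prof.apical_noise_power,
            rtol=1e-9,
        )

    def test_passive_uniform_snr_monotone_decreasing(self, uniform_model):
        """In a lossy uniform medium noise accumulates while the signal
        decays: the SNR can only fall along the line."""
        prov = WKBProvider(uniform_model)
        prof = snr_profile(prov, 10e3, False)
        snr = prof.snr[10:-10]
        assert np.all(np.diff(snr) < 1e-9)

    def test_amplifier_boosts_snr_at_peak(self, provider_fast):
        xh = provider_fast.model.characteristic_place(10e3)
        j = np.argmin(np.abs(provider_fast.x - xh))
        on = snr_profile(provider_fast, 10e3, True)
        off = snr_profile(provider_fast, 10e3, False)
        assert on.snr[j] > off.snr[j]

    def test_noise_amplified_more_than_signal_toward_base(self, provider_fast):
        """Basal to the peak the on/off enhancement falls below its peak
        value and eventually below unity: away from the characteristic
        place, amplification favors the accumulated noise."""
        on = snr_profile(provider_fast, 10e3, True)
        off = snr_profile(provider_fast, 10e3, False)
        enh = on.snr / off.snr
        xh = provider_fast.model.characteristic_place(10e3)
        j = np.argmin(np.abs(provider_fast.x - xh))
        basal = enh[: j // 4]
        assert np.max(basal) < enh[j]
        assert np.min(basal) < 1.0 + 1e-9

    def test_enhancement_invariant_to_normalization(self, provider_fast):
        """Rescaling stimulus and noise strength leaves R_on/R_off fixed."""
        j = 300
        base = (
            snr_profile(provider_fast, 10e3, True).snr[j]
            / snr_profile(provider_fast, 10e3, False).snr[j]
        )
        scaled = (
            snr_profile(provider_fast, 10e3, True, gamma=3.7, signal_rms_in=0.2).snr[j]
            / snr_profile(provider_fast, 10e3, False, gamma=3.7, signal_rms_in=0.2).snr[
                j
            ]
        )
        assert scaled == pytest.approx(base, rel=1e-12)


class TestNarrowbandProfile:
    def test_passive_vs_passive_is_unity(self, provider_fast):
        """Same mode in numerator and denominator: enhancement exactly 1."""
        off = snr_profile(provider_fast, 10e3, False)
        assert np.allclose(off.snr / off.snr, 1.0)

    def test_near_base_region_flagged(self, provider_fast):
        prof = enhancement_profile_narrowband(provider_fast, num_freqs=17)
        high_f = [p for p in prof.points if p.frequency > 45e3]
        assert high_f and all(p.near_base_flag for p in high_f)
        # closest to the entrance there is no SNR benefit even at CF
        deep = [p for p in prof.points if p.frequency > 55e3]
        assert deep and all(p.enhancement_db < 2.0 for p in deep)

    def test_most_sensitive_locations_strongly_enhanced(self, provider_fast):
        prof = enhancement_profile_narrowband(provider_fast, num_freqs=17)
        assert prof.most_sensitive_enhancement_db > 10.0

    def test_out_of_band_frequencies_rejected(self, provider_fast):
        with pytest.raises(ValueError, match="outside"):
            enhancement_profile_narrowband(
                provider_fast, frequencies=np.array([1e3, 10e3])
            )


@pytest.fixture(scope="module")
def profiles_fast(provider_fast):
    nb = enhancement_profile_narrowband(provider_fast, num_freqs=17)
    bb = enhancement_profile_broadband(provider_fast, num_freqs=32, narrowband=nb)
    return nb, bb


class TestBroadbandProfile:
    def test_single_frequency_band_reduces_to_narrowband(self, provider_fast):
        bb1 = enhancement_profile_broadband(
            provider_fast,
            band=(10e3, 10e3),
            num_freqs=1,
            narrowband=enhancement_profile_narrowband(provider_fast, num_freqs=9),
        )
        on = snr_profile(provider_fast, 10e3, True)
        off = snr_profile(provider_fast, 10e3, False)
        expected = 20 * np.log10(on.snr / off.snr)
        assert np.allclose(bb1.enhancement_db, expected, atol=1e-9)

    def test_quadrature_self_convergence(self, provider_fast, profiles_fast):
        """Doubling the frequency count moves the reported peak by < 0.3 dB
        and the bulk of the profile by < 0.3 dB (the apical-most locations,
        where the cochlear filters are sharpest relative to the frequency
        spacing, converge last)."""
        nb, bb32 = profiles_fast
        bb64 = enhancement_profile_broadband(
            provider_fast, num_freqs=64, narrowband=nb
        )
        assert abs(bb64.peak_enhancement_db - bb32.peak_enhancement_db) < 0.3
        mask = bb32.reporting_mask
        diff = np.abs(bb64.enhancement_db[mask] - bb32.enhancement_db[mask])
        assert np.median(diff) < 0.3

    def test_bounded_by_pointwise_narrowband_maximum(self, provider_fast, profiles_fast):
        """At any location the broadband enhancement cannot exceed the best
        narrowband enhancement across the band at that same location."""
        nb, bb = profiles_fast
        freqs = np.geomspace(4.2e3, 66e3, 32)
        idx = np.linspace(50, provider_fast.x.size - 30, 7, dtype=int)
        point_max = np.full(idx.size, -np.inf)
        for f in freqs:
            on = snr_profile(provider_fast, f, True)
            off = snr_profile(provider_fast, f, False)
            e = 20 * np.log10(on.snr[idx] / off.snr[idx])
            point_max = np.maximum(point_max, e)
        assert np.all(bb.enhancement_db[idx] <= point_max + 0.3)

    def test_band_outside_cf_map_rejected(self, provider_fast):
        with pytest.raises(ValueError, match="outside the model CF map"):
            enhancement_profile_broadband(provider_fast, band=(1e3, 200e3))


class TestNormalizedCurves:
    def test_postmortem_equality_at_characteristic_place(self, provider_fast):
        cur = normalized_signal_noise_curves(provider_fast, 10e3)
        j = np.argmin(np.abs(cur.positions - cur.characteristic_place))
        assert cur.signal_off[j] == pytest.approx(cur.noise_off[j], rel=1e-12)

    def test_in_vivo_signal_exceeds_noise_at_peak(self, provider_fast):
        cur = normalized_signal_noise_curves(provider_fast, 10e3)
        j = np.argmin(np.abs(cur.positions - cur.characteristic_place))
        assert cur.signal_on[j] > cur.noise_on[j]

    def test_noise_relatively_amplified_toward_entrance(self, provider_fast):
        """Moving basally from the peak, the in vivo signal/noise ratio falls
        below its value at the characteristic place."""
        cur = normalized_signal_noise_curves(provider_fast, 10e3)
        j = np.argmin(np.abs(cur.positions - cur.characteristic_place))
        ratio = cur.signal_on / cur.noise_on
        assert np.min(ratio[20 : j // 2]) < ratio[j]

    def test_velocity_response_option(self, provider_fast):
        cur = normalized_signal_noise_curves(provider_fast, 10e3, response="velocity")
        assert cur.response == "velocity"
        with pytest.raises(ValueError):
            normalized_signal_noise_curves(provider_fast, 10e3, response="bogus")


class TestStructuralCorrespondence:
    def test_cochlear_gain_pattern_mirrors_discrete_optimum(self, provider_fast):
        """Exporting the cochlear per-segment gains (|G| ratios along the
        duct at 10 kHz) into the bidirectional chain reproduces the
        qualitative optimal-profile result: enhancement above unity at the
        target (peak) node and below unity somewhere else."""
        x = provider_fast.x
        xh = provider_fast.model.characteristic_place(10e3)
        j = np.argmin(np.abs(x - xh))
        # per-segment wave gains exp(int Im k dx) on a 12-node chain spanning
        # the gain region and the start of the cut-off
        k = provider_fast.model.wavenumber(x, 2 * np.pi * 10e3, True)
        nodes = np.linspace(0, min(int(j * 1.3), x.size - 1), 13, dtype=int)
        dx = x[1] - x[0]
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (np.imag(k)[1:] + np.imag(k)[:-1]) * dx)])
        seg = np.exp(np.diff(cum[nodes]))
        cfg = ChainConfig(num_nodes=12, gain=np.clip(seg, 1e-3, 1e3))
        enh = bidirectional_enhancement(cfg)
        target = np.argmin(np.abs(nodes - j))
        assert enh[target] > 1.0
        assert np.any(enh < 1.0)
        assert abs(int(np.argmax(enh)) - int(target)) <= 2

    def test_removing_cutoff_reduces_peak_enhancement(self, provider_fast):
        """Forcing Im(k) >= 0 apical to x_hat (no evanescent cut-off) lets
        apical noise reach the peak: the enhancement there must drop."""
        f = 10e3
        xh = provider_fast.model.characteristic_place(f)
        j = np.argmin(np.abs(provider_fast.x - xh))
        dx = provider_fast.x[1] - provider_fast.x[0]

        def enhancement(ablate):
            Gon = provider_fast.green_matrix(f, True, ablate_cutoff=ablate)
            Goff = provider_fast.green_matrix(f, False)
            k0 = provider_fast.model.wavenumber(np.array([0.0]), 2 * np.pi * f, True)[0]
            snr = lambda G: np.abs(2 * k0 * G[j, 0]) / np.sqrt(
                np.trapezoid(np.abs(G[j]) ** 2, dx=dx)
            )
            return snr(Gon) / snr(Goff)

        assert enhancement(True) < enhancement(False)
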