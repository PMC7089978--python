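"""IRF reconvolution, decay fitting, intensity-weighted averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zmwfcs.lifetime import (
    DecayComponent,
    fit_decay,
    intensity_weighted_lifetime,
    lifetime_fold_change,
    reconvolve_model,
    select_decay_order,
)
from zmwfcs.photon_data import IRFModel, TCSPCHistogram

CW, NCH = 16.0, 1563  # 16 ps channels spanning the 25 ns sync window
IRF110 = IRFModel(fwhm_ps=110.0, center_ps=2500.0)


def synth_histogram(rng, amps, taus_ns, n=100_000, fwhm=110.0, center=2500.0, scatter=0.0):
    """Microtimes from a multi-exponential decay blurred by a Gaussian IRF.

    Photons per component are proportional to a_i tau_i (steady-state
    intensity); a fraction ``scatter`` is replaced by a ~5 ps spike.
    """
    probs = np.asarray(amps) * np.asarray(taus_ns)
    probs = probs / probs.sum()
    comp = rng.choice(len(amps), size=n, p=probs)
    d = rng.exponential(np.asarray(taus_ns)[comp] * 1e3)
    if scatter:
        nsc = int(n * scatter)
        d[:nsc] = rng.exponential(5.0, nsc)
    d = d + rng.normal(0, fwhm / 2.3548, n) + center
    micro = np.floor(np.mod(d, 25_000)).astype(int)
    return TCSPCHistogram(CW, np.bincount(micro // 16, minlength=NCH))


class TestReconvolveModel:
    def test_delta_irf_is_pure_exponential(self):
        irf = IRFModel(fwhm_ps=1e-6, center_ps=0.0)
        m = reconvolve_model([DecayComponent(1.0, 4.0)], irf, CW, NCH)
        t = CW * np.arange(NCH)
        # compare against the channel-integrated wrapped exponential
        span = CW * NCH
        e = np.exp(-np.append(t, span) / 4000.0)
        expect = 4000.0 * (e[:-1] - e[1:]) / (1 - np.exp(-span / 4000.0)) / CW
        np.testing.assert_allclose(m, expect, rtol=1e-6)

    def test_shift_equivariance(self):
        a = IRFModel(fwhm_ps=110.0, center_ps=2000.0)
        b = IRFModel(fwhm_ps=110.0, center_ps=2000.0 + 320.0)  # 20 channels later
        ma = reconvolve_model([DecayComponent(1.0, 3.0)], a, CW, NCH)
        mb = reconvolve_model([DecayComponent(1.0, 3.0)], b, CW, NCH)
        np.testing.assert_allclose(np.roll(ma, 20), mb, rtol=1e-6, atol=1e-9)

    def test_tail_slope_is_minus_inverse_tau(self):
        tau_ns = 3.0
        m = reconvolve_model([DecayComponent(1.0, tau_ns)], IRF110, CW, NCH)
        t = CW * (np.arange(NCH) + 0.5)
        sel = (t > 4000) & (t < 15_000)  # far past the IRF, before the wrap tail
        slope = np.polyfit(t[sel], np.log(m[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / (tau_ns * 1e3), rel=1e-3)

    def test_conserves_total_intensity(self):
        comps = [DecayComponent(2.0, 1.0), DecayComponent(1.0, 4.0)]
        bare = reconvolve_model(comps, IRFModel(fwhm_ps=1e-6, center_ps=0.0), CW, NCH)
        blurred = reconvolve_model(comps, IRF110, CW, NCH)
        assert blurred.sum() == pytest.approx(bare.sum(), rel=1e-9)


class TestIntensityWeightedLifetime:
    def test_single_component_degenerate(self):
        assert intensity_weighted_lifetime([DecayComponent(0.7, 1.4)]) == pytest.approx(1.4)

    def test_hand_evaluated_two_component(self):
        comps = [DecayComponent(0.5, 1.0), DecayComponent(0.5, 3.0)]
        assert intensity_weighted_lifetime(comps) == pytest.approx(2.5)

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 10.0), st.floats(0.05, 20.0)), min_size=1, max_size=4
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_extreme_lifetimes(self, pairs):
        comps = [DecayComponent(a, t) for a, t in pairs]
        tau = intensity_weighted_lifetime(comps)
        taus = [t for _, t in pairs]
        assert min(taus) - 1e-9 <= tau <= max(taus) + 1e-9

    def test_amplitude_rescaling_invariance(self):
        comps = [DecayComponent(0.3, 0.8), DecayComponent(0.6, 2.5)]
        scaled = [DecayComponent(17 * c.amplitude, c.lifetime_ns) for c in comps]
        assert intensity_weighted_lifetime(comps) == pytest.approx(
            intensity_weighted_lifetime(scaled), rel=1e-12
        )

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            intensity_weighted_lifetime([])


class TestFoldChange:
    def test_identity(self):
        assert lifetime_fold_change(2.0, 2.0) == pytest.approx(1.0)

    def test_two_fold_regime(self):
        # hydrophilic labels: same ratio with or without passivation
        assert round(lifetime_fold_change(3.5, 1.78), 2) == 1.97
        assert round(lifetime_fold_change(3.5, 1.78)) == 2

    def test_three_fold_regime(self):
        # adhesion adds metal quenching on bare apertures
        assert round(lifetime_fold_change(4.0, 1.41), 2) == 2.84
        assert round(lifetime_fold_change(4.0, 1.41)) == 3

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            lifetime_fold_change(0.0, 1.0)


class TestFitDecay:
    def test_noiseless_limit_recovery(self):
        # counts generated by the model itself, no Poisson noise
        m = reconvolve_model([DecayComponent(1.0, 2.2)], IRF110, CW, NCH) * CW
        m *= 2e7 / m.sum()
        h = TCSPCHistogram(CW, np.rint(m).astype(np.int64))
        fit = fit_decay(h, IRF110, 1, fit_shift=False)
        assert fit.components[0].lifetime_ns == pytest.approx(2.2, rel=1e-3)

    def test_single_exponential_recovery(self, rng):
        h = synth_histogram(rng, [1.0], [4.0])
        fit = fit_decay(h, IRF110, 1)
        assert fit.components[0].lifetime_ns == pytest.approx(4.0, rel=0.02)
        # the 95% gate really holds >= 95% of the photons
        start, end = fit.gate
        sel = (h.channel_starts >= start) & (h.channel_starts < end)
        assert h.counts[sel].sum() >= 0.95 * h.total_photons

    def test_biexponential_recovery(self, rng):
        h = synth_histogram(rng, [0.7, 0.3], [0.5, 3.0])
        fit = fit_decay(h, IRF110, 2)
        taus = [c.lifetime_ns for c in fit.components]
        assert taus[0] == pytest.approx(0.5, rel=0.05)
        assert taus[1] == pytest.approx(3.0, rel=0.05)
        amps = np.array([c.amplitude for c in fit.components])
        amps = amps / amps.sum()
        assert amps[0] == pytest.approx(0.7, abs=0.05)

    def test_scatter_component_excluded(self, rng):
        clean = synth_histogram(rng, [0.7, 0.3], [0.5, 3.0])
        fit_clean = fit_decay(clean, IRF110, 2)
        dirty = synth_histogram(rng, [0.7, 0.3], [0.5, 3.0], scatter=0.15)
        fit_dirty = fit_decay(dirty, IRF110, 3)
        assert len(fit_dirty.excluded) >= 1
        assert all(c.lifetime_ns * 1e3 < 55 for c in fit_dirty.excluded)
        assert fit_dirty.intensity_weighted_lifetime == pytest.approx(
            fit_clean.intensity_weighted_lifetime, rel=0.01
        )

    def test_short_lifetime_with_sharp_irf(self, rng):
        # the shortest average reported in this system is ~1 ns; with the
        # 38 ps response it must come back within 5%
        h = synth_histogram(rng, [1.0], [1.02], fwhm=38.0)
        fit = fit_decay(h, IRFModel(fwhm_ps=38.0, center_ps=2500.0), 1)
        assert fit.components[0].lifetime_ns == pytest.approx(1.02, rel=0.05)

    def test_order_selection_prefers_single_for_single(self, rng):
        h = synth_histogram(rng, [1.0], [4.0])
        fit = select_decay_order(h, IRF110)
        assert len(fit.components) == 1

    def test_too_few_photons_rejected(self, rng):
        h = synth_histogram(rng, [1.0], [4.0], n=500)
        with pytest.raises(ValueError):
            fit_decay(h, IRF110, 1)
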