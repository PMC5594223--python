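"""Connectivity measures: identities, structural zeros, oracles, banding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegspect.connectivity import (
    band_average,
    coherency_family,
    compute_all,
    compute_tensors,
    dtf_family,
    granger_family,
    pdc_family,
    raw_family,
    ConnectivityTensor,
)
from eegspect.constants import BANDS, FREQ_GRID_HZ, MEASURES
from eegspect.mvar import MVARModel, fit_mvar

from conftest import random_stable_model


@pytest.fixture(scope="module")
def fitted_spec(bivar_sim):
    model = fit_mvar(bivar_sim, 2)
    return model, model.spectral()


def zero_model(m=3, sigma=None):
    return MVARModel(np.zeros((1, m, m)), sigma if sigma is not None else np.eye(m))


class TestCoherency:
    def test_self_coherence_is_one(self, fitted_spec):
        _, sp = fitted_spec
        coh = coherency_family(sp)["COH"].values
        d = np.diagonal(coh, axis1=1, axis2=2)
        assert np.abs(d - 1).max() < 1e-12

    def test_independent_channels_zero_offdiag(self):
        sp = zero_model(sigma=np.diag([1.0, 2.0, 0.5])).spectral()
        fam = coherency_family(sp)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(fam["COH"].values[:, off]).max() == 0
        assert np.abs(fam["iCOH"].values[:, off]).max() == 0

    def test_coh_matches_welch_oracle(self):
        """MVAR coherence vs nonparametric Welch estimate at peaks.

        An oscillatory coupled pair (10 Hz resonance, strong 1 -> 2
        coupling) has a pronounced coherence peak; the parametric and the
        Welch estimates must agree there.
        """
        from eegspect.cohort import make_template

        template = make_template(
            2, osc_freq_hz=10.0, damping=0.92, couplings={(1, 0): 0.5}
        )
        x = template.simulate(50000, np.random.default_rng(17))
        model = fit_mvar(x, 5)
        coh = coherency_family(model.spectral())["COH"].values[:, 1, 0]
        f_w, cxy = sps.coherence(x[0], x[1], fs=200.0, nperseg=1024)
        welch = np.interp(np.asarray(FREQ_GRID_HZ, float), f_w, np.sqrt(cxy))
        peak = np.argsort(coh)[-10:]  # strongest-coupling grid points
        assert coh[peak].min() > 0.5  # a real peak, not noise floor
        assert np.abs(coh[peak] - welch[peak]).max() < 0.1

    def test_bounds(self, fitted_spec):
        _, sp = fitted_spec
        fam = coherency_family(sp)
        assert fam["COH"].values.min() >= 0 and fam["COH"].values.max() <= 1 + 1e-12
        assert np.abs(fam["iCOH"].values).max() <= 1 + 1e-12
        assert fam["pCOH"].values.min() >= 0


class TestDirectedFamilies:
    def test_pdc_column_normalization(self, fitted_spec):
        _, sp = fitted_spec
        pdc = pdc_family(sp)["PDC"].values
        colsum = (pdc**2).sum(axis=1)
        assert np.abs(colsum - 1).max() < 1e-10

    def test_dtf_row_normalization(self, fitted_spec):
        _, sp = fitted_spec
        dtf = dtf_family(sp)["DTF"].values
        rowsum = (dtf**2).sum(axis=2)
        assert np.abs(rowsum - 1).max() < 1e-10

    def test_ffdtf_total_normalization(self, fitted_spec):
        _, sp = fitted_spec
        ff = dtf_family(sp)["ffDTF"].values
        total = (ff**2).sum(axis=(0, 2))
        assert np.abs(total - 1).max() < 1e-10

    def test_identity_model_trivials(self):
        sp = zero_model(2).spectral()
        pdc = pdc_family(sp)["PDC"].values
        dtf = dtf_family(sp)["DTF"].values
        eye = np.eye(2)
        assert np.allclose(pdc, eye[None]) and np.allclose(dtf, eye[None])

    def test_structural_zero_under_unidirectional_coupling(self, bivar_var2):
        """No direct 2 -> 1 coupling => PDC(1 <- 2) and DC(1 <- 2) exactly 0."""
        t = compute_tensors(bivar_var2)
        assert np.all(t["PDC"].values[:, 0, 1] == 0)
        assert np.all(t["DC"].values[:, 0, 1] == 0)
        assert np.any(t["PDC"].values[:, 1, 0] > 0)

    def test_ggc_matches_analytic_form(self, bivar_var2):
        sp = bivar_var2.spectral()
        ggc = granger_family(sp)["GGC"].values
        S22 = sp.S[:, 1, 1].real
        expected = np.log(S22 / (S22 - np.abs(sp.H[:, 1, 0]) ** 2))
        assert np.abs(ggc[:, 1, 0] - expected).max() < 1e-8
        assert ggc.min() >= 0

    def test_no_coupling_no_causality(self):
        sp = zero_model(2, np.diag([1.0, 3.0])).spectral()
        fam = granger_family(sp)
        off = ~np.eye(2, dtype=bool)
        assert np.abs(fam["GGC"].values[:, off]).max() == 0
        assert np.abs(fam["DC"].values[:, off]).max() == 0

    def test_singular_sigma_only_breaks_noise_weighted_measures(self, bivar_var2):
        sp = bivar_var2.spectral()
        singular = np.ones((2, 2))  # rank 1
        with pytest.raises(ValueError):
            pdc_family(sp, resid_cov=singular)
        # DTF does not use Sigma at all
        dtf_family(sp)


class TestRawFamily:
    def test_identity_pattern_for_zero_model(self):
        sp = zero_model(2).spectral()
        fam = raw_family(sp)
        assert np.allclose(fam["h"].values, np.eye(2)[None])
        assert np.allclose(fam["Af"].values, np.eye(2)[None])

    def test_af_closed_form_univariate(self):
        a, fs = 0.5, 200.0
        sp = MVARModel(np.array([[[a]]]), np.array([[1.0]]), sfreq=fs).spectral()
        f = sp.frequencies
        expected = np.abs(1 - a * np.exp(-2j * np.pi * f / fs))
        assert np.allclose(raw_family(sp)["Af"].values[:, 0, 0], expected)


class TestBandAverage:
    def _tensor(self, values):
        return ConnectivityTensor(
            "COH", np.asarray(FREQ_GRID_HZ, float), values
        )

    def test_constant_tensor(self):
        t = self._tensor(np.full((79, 2, 2), 0.7))
        banded = band_average(t)
        for mat in banded.bands.values():
            assert np.allclose(mat, 0.7)

    def test_delta_is_mean_of_2_3_4(self):
        vals = np.zeros((79, 1, 1))
        vals[:, 0, 0] = np.asarray(FREQ_GRID_HZ, float) ** 2
        banded = band_average(self._tensor(vals))
        assert banded.bands["delta"][0, 0] == pytest.approx((4 + 9 + 16) / 3)

    def test_linear_in_f_equals_band_midpoint(self):
        vals = np.zeros((79, 1, 1))
        f = np.asarray(FREQ_GRID_HZ, float)
        vals[:, 0, 0] = 2.0 * f + 1.0
        banded = band_average(self._tensor(vals))
        for name, (lo, hi) in BANDS.items():
            mid = np.mean(np.arange(lo, hi + 1))
            assert banded.bands[name][0, 0] == pytest.approx(2 * mid + 1)

    def test_grid_mismatch_rejected(self):
        t = ConnectivityTensor("COH", np.arange(2.0, 50.0), np.zeros((48, 1, 1)))
        with pytest.raises(ValueError, match="grid"):
            band_average(t)


class TestComputeAll:
    def test_seventeen_channel_shape(self):
        rng = np.random.default_rng(23)
        model = random_stable_model(rng, m=17, p=2, radius=0.7)
        model.sfreq = 200.0
        out = compute_all(model)
        assert set(out) == set(MEASURES)
        for bc in out.values():
            assert set(bc.bands) == set(BANDS)
            for mat in bc.bands.values():
                assert mat.shape == (17, 17)
                assert np.all(np.isfinite(mat))

    def test_zero_model_directed_measures_vanish(self):
        out = compute_all(zero_model(3))
        off = ~np.eye(3, dtype=bool)
        for m in ("PDC", "GPDC", "DTF", "GGC", "DC"):
            for mat in out[m].bands.values():
                assert np.abs(mat[off]).max() < 1e-12

    def test_deterministic(self, bivar_var2):
        a = compute_all(bivar_var2)
        b = compute_all(bivar_var2)
        for m in MEASURES:
            for band in a[m].bands:
                assert np.array_equal(a[m].bands[band], b[m].bands[band])


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_normalization_and_scale_invariance_properties(seed):
    """PDC/DTF identities and channel-rescaling invariance on random models."""
    rng = np.random.default_rng(seed)
    model = random_stable_model(rng, m=3, p=2)
    model.sfreq = 200.0
    x = model.simulate(4000, rng)
    fit1 = fit_mvar(x, 2)
    t1 = compute_tensors(fit1)
    assert np.abs((t1["PDC"].values ** 2).sum(axis=1) - 1).max() < 1e-10
    assert np.abs((t1["DTF"].values ** 2).sum(axis=2) - 1).max() < 1e-10
    for m in ("COH", "PDC", "GPDC", "DTF"):
        v = t1[m].values
        assert v.min() > -1e-12 and v.max() < 1 + 1e-12
    # uniform rescaling of the signal leaves the normalized families intact
    fit2 = fit_mvar(3.0 * x, 2)
    t2 = compute_tensors(fit2)
    for m in ("COH", "PDC", "GPDC", "DTF", "ffDTF", "dDTF"):
        assert np.allclose(t1[m].values, t2[m].values, atol=1e-8), m
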