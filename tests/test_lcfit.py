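"""Linear-combination fitting, CRLB propagation and reference scaling."""

import numpy as np
import pandas as pd
import pytest

from phosfit import (
    AcquisitionParams,
    FitModel,
    Lineshape,
    Resonance,
    SpinSystem,
    Spectrum,
    compute_crlb,
    derive_quantities,
    filter_by_crlb,
    fit_least_squares,
    reference_scale,
    simulate_basis,
    synthesize_spectrum,
)
from phosfit.errors import DomainError, FitError, ParameterError
from phosfit.spins import build_default_basis, default_linewidths
from phosfit.synth import ConcentrationProfile

FIT_NAMES = ("aATP", "NAD+", "NADH", "UDPG")
TRUTH = {"aATP": 2.8, "NAD+": 0.28, "NADH": 0.14, "UDPG": 0.1}


@pytest.fixture(scope="module")
def fit_basis(acq):
    return build_default_basis(acq, default_linewidths(), names=FIT_NAMES)


@pytest.fixture(scope="module")
def fit_model():
    return FitModel(components=FIT_NAMES)


def _spectrum(fit_basis, conc=None, snr=None, seed=None):
    profile = ConcentrationProfile(dict(conc or TRUTH))
    return synthesize_spectrum(profile, fit_basis, target_snr=snr, seed=seed)


class TestFitLeastSquares:
    def test_noiseless_exact_recovery(self, fit_basis, fit_model):
        spec = _spectrum(fit_basis)
        result = fit_least_squares(spec, fit_basis, fit_model)
        assert result.converged
        for name, truth in TRUTH.items():
            assert abs(result.amplitude[name] - truth) / truth < 1e-6

    def test_amplitude_linearity(self, fit_basis, fit_model):
        doubled = dict(TRUTH, **{"NAD+": 2 * TRUTH["NAD+"]})
        r1 = fit_least_squares(_spectrum(fit_basis), fit_basis, fit_model)
        r2 = fit_least_squares(_spectrum(fit_basis, doubled), fit_basis, fit_model)
        assert r2.amplitude["NAD+"] / r1.amplitude["NAD+"] == pytest.approx(2.0, rel=1e-6)

    def test_deterministic_given_same_input(self, fit_basis, fit_model):
        spec = _spectrum(fit_basis, snr=30, seed=9)
        r1 = fit_least_squares(spec, fit_basis, fit_model)
        r2 = fit_least_squares(spec, fit_basis, fit_model)
        assert r1.amplitude == r2.amplitude

    def test_mean_estimate_unbiased_at_snr30(self, fit_basis, fit_model):
        # model-matched noisy data: Monte Carlo mean within 3 SE of truth
        vals = []
        for seed in range(40):
            r = fit_least_squares(_spectrum(fit_basis, snr=30, seed=seed),
                                  fit_basis, fit_model)
            vals.append(r.amplitude["NAD+"])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - TRUTH["NAD+"]) < 3 * se

    def test_singular_design_rejected(self, acq):
        twin_a = SpinSystem("A", (Resonance(-8.0, 1.0),))
        twin_b = SpinSystem("B", (Resonance(-8.0, 1.0),))
        basis = [simulate_basis(s, acq, Lineshape(15.0)) for s in (twin_a, twin_b)]
        spec = Spectrum(basis[0].values + basis[1].values, basis[0].axis, acq)
        with pytest.raises(FitError, match="singular"):
            fit_least_squares(spec, basis, FitModel(components=("A", "B")))

    def test_missing_component_rejected(self, fit_basis):
        with pytest.raises(ParameterError, match="missing"):
            fit_least_squares(_spectrum(fit_basis), fit_basis,
                              FitModel(components=("aATP", "PCr")))


class TestCrlb:
    def test_noiseless_crlb_vanishes(self, fit_basis, fit_model):
        spec = _spectrum(fit_basis)
        result = fit_least_squares(spec, fit_basis, fit_model)
        # exact zero-noise limit
        crlb0 = compute_crlb(result, spec, fit_basis, fit_model, noise_sd=0.0)
        assert all(v == 0.0 for v in crlb0.values())
        # estimated noise on a noiseless spectrum is only metabolite tails
        crlb = compute_crlb(result, spec, fit_basis, fit_model)
        assert all(v < 0.1 for v in crlb.values())

    def test_nadh_less_precise_than_nad(self, fit_basis, fit_model):
        # NADH: half the concentration, closer to the alpha-ATP resonance
        spec = _spectrum(fit_basis, snr=30, seed=21)
        result = fit_least_squares(spec, fit_basis, fit_model)
        crlb = compute_crlb(result, spec, fit_basis, fit_model)
        assert crlb["NADH"] > crlb["NAD+"]

    def test_crlb_decreases_with_snr(self, fit_basis, fit_model):
        out = {}
        for snr in (20, 80):
            vals = []
            for seed in range(5):
                spec = _spectrum(fit_basis, snr=snr, seed=seed)
                r = fit_least_squares(spec, fit_basis, fit_model)
                vals.append(compute_crlb(r, spec, fit_basis, fit_model)["NAD+"])
            out[snr] = np.mean(vals)
        assert out[80] < out[20]

    def test_crlb_matches_monte_carlo_dispersion(self, fit_basis, fit_model):
        # Fisher-information bound within a factor 1.5 of the empirical
        # replicate scatter at SNR 50
        amps, crlbs = [], []
        for seed in range(100):
            spec = _spectrum(fit_basis, snr=50, seed=seed)
            r = fit_least_squares(spec, fit_basis, fit_model)
            amps.append(r.amplitude["NAD+"])
            crlbs.append(compute_crlb(r, spec, fit_basis, fit_model)["NAD+"])
        amps = np.asarray(amps)
        mc_rsd = 100.0 * amps.std(ddof=1) / amps.mean()
        ratio = np.mean(crlbs) / mc_rsd
        assert 1 / 1.5 < ratio < 1.5


class TestFilterByCrlb:
    @pytest.mark.parametrize("crlb,kept", [(31.0, False), (30.0, True), (10.0, True)])
    def test_cutoff_is_inclusive_maximum(self, crlb, kept):
        table = pd.DataFrame([{"metabolite": "NADH", "crlb_pct": crlb}])
        out = filter_by_crlb(table)
        assert (len(out) == 1) is kept

    def test_missing_column_rejected(self):
        with pytest.raises(ParameterError):
            filter_by_crlb(pd.DataFrame([{"metabolite": "NADH"}]))


class TestReferenceScale:
    def _phantom_fit(self, acq, nad=9.57, pi=9.57):
        from phosfit.spins import load_spin_systems

        systems = load_spin_systems()
        names = ("NAD+", "NADH", "Pi_int")
        basis = [simulate_basis(systems[n], acq, Lineshape(8.0)) for n in names]
        profile = ConcentrationProfile({"NAD+": nad, "NADH": 1.0, "Pi_int": pi})
        spec = synthesize_spectrum(profile, basis)
        model = FitModel(components=names, region=(-12.0, 8.0))
        return fit_least_squares(spec, basis, model)

    def test_equal_per_nucleus_amplitude_gives_reference_value(self, acq):
        result = self._phantom_fit(acq)
        scaled = reference_scale(result, "phantom_pi", 9.57)
        assert scaled.concentration["NAD+"] == pytest.approx(9.57, abs=1e-6)

    def test_pcr_external_unit_ratio(self, acq):
        basis = build_default_basis(acq, default_linewidths(), names=("PCr", "Pi_int"))
        profile = ConcentrationProfile({"PCr": 1.0, "Pi_int": 1.0})
        spec = synthesize_spectrum(profile, basis)
        model = FitModel(components=("PCr", "Pi_int"), region=(-3.0, 7.0))
        result = fit_least_squares(spec, basis, model)
        scaled = reference_scale(result, "pcr_external", 4.2)
        assert scaled.concentration["Pi_int"] == pytest.approx(4.2, rel=1e-6)

    def test_zero_reference_amplitude_rejected(self, acq):
        result = self._phantom_fit(acq, pi=0.0)
        with pytest.raises(ParameterError, match="zero"):
            reference_scale(result, "phantom_pi", 9.57)

    def test_scale_equivariance(self, acq):
        # scaling the spectrum leaves reference-scaled concentrations unchanged
        from phosfit.spins import load_spin_systems

        systems = load_spin_systems()
        names = ("NAD+", "NADH", "Pi_int")
        basis = [simulate_basis(systems[n], acq, Lineshape(8.0)) for n in names]
        profile = ConcentrationProfile({"NAD+": 2.0, "NADH": 1.0, "Pi_int": 9.57})
        spec = synthesize_spectrum(profile, basis)
        model = FitModel(components=names, region=(-12.0, 8.0))
        c1 = reference_scale(fit_least_squares(spec, basis, model),
                             "phantom_pi", 9.57).concentration
        scaled_spec = Spectrum(spec.values * 3.0, spec.axis, acq)
        c2 = reference_scale(fit_least_squares(scaled_spec, basis, model),
                             "phantom_pi", 9.57).concentration
        for name in names:
            assert c2[name] == pytest.approx(c1[name], rel=1e-6)


class TestDeriveQuantities:
    def test_redox_ratio_and_pool(self):
        d = derive_quantities({"NAD+": 0.383, "NADH": 0.043})
        assert d.rr == pytest.approx(8.907, abs=0.01)
        assert d.tnad == pytest.approx(0.426, abs=1e-12)

    def test_phosphoesters(self):
        d = derive_quantities({"PC": 0.5, "PE": 1.0, "GPC": 0.4, "GPE": 0.6})
        assert d.pme == pytest.approx(1.5)
        assert d.pde == pytest.approx(1.0)
        assert d.pme_pde_ratio == pytest.approx(1.5)

    def test_atp_is_mean_of_alpha_and_gamma(self):
        d = derive_quantities({"aATP": 2.9, "gATP": 3.1})
        assert d.atp == pytest.approx(3.0)

    def test_missing_inputs_give_none_not_zero(self):
        d = derive_quantities({"NAD+": 0.3, "NADH": 0.1})
        assert d.pme is None and d.atp is None

    def test_zero_nadh_rejected(self):
        with pytest.raises(DomainError):
            derive_quantities({"NAD+": 0.3, "NADH": 0.0})
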