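"""Shouldered/biphasic dose-response fitting and dose solving."""

import math

import numpy as np
import pytest

from sdcmpn import (
    REFERENCE_RELATIVE_FITS,
    DoseResponseFit,
    DoseResponsePoint,
    dose_for_rv,
    fit_dose_response,
    normalize_fits,
    predict_rv,
    simulate_dose_response,
)


def points_on(fit, doses):
    return [DoseResponsePoint(float(d), predict_rv(fit, float(d))) for d in doses]


class TestPredict:
    def test_zero_dose_returns_intercept(self):
        fit = DoseResponseFit(form="first_order", rv0=0.45, d_th=8.15, k=0.669)
        assert predict_rv(fit, 0.0) == pytest.approx(0.45)

    def test_one_log_per_unit_dose(self):
        fit = DoseResponseFit(form="first_order", rv0=1.0, d_th=0.0, k=math.log(10))
        assert predict_rv(fit, 1.0) == pytest.approx(0.1)

    def test_most_sensitive_reference_taxon_at_unit_dose(self):
        fit = REFERENCE_RELATIVE_FITS["Phaeocystis globosa"]
        assert predict_rv(fit, 1.0) == pytest.approx(0.01, rel=0.01)

    def test_continuous_at_threshold(self):
        for fit in REFERENCE_RELATIVE_FITS.values():
            if fit.d_th > 0:
                below = predict_rv(fit, fit.d_th * (1 - 1e-12))
                above = predict_rv(fit, fit.d_th * (1 + 1e-12))
                assert below == pytest.approx(above, rel=1e-9)
                assert below == pytest.approx(fit.rv0, rel=1e-9)

    def test_nonincreasing_in_dose(self):
        doses = np.linspace(0, 30, 400)
        for fit in REFERENCE_RELATIVE_FITS.values():
            rv = predict_rv(fit, doses)
            assert np.all(np.diff(rv) <= 1e-15)

    def test_rejects_negative_dose(self):
        fit = DoseResponseFit(form="first_order", rv0=1.0, d_th=0.0, k=1.0)
        with pytest.raises(ValueError):
            predict_rv(fit, -1.0)


class TestDoseForRv:
    @pytest.mark.parametrize(
        "species, expected",
        [
            ("Amphidinium carterae", 12.6),
            ("Pyramimonas parkeae", 13.8),
            ("Phaeocystis globosa", 1.00),
            ("Synechococcus elongatus", 10.5),  # biphasic, numeric solve
        ],
    )
    def test_reference_taxa_three_sig_figs(self, species, expected):
        fit = REFERENCE_RELATIVE_FITS[species]
        assert dose_for_rv(fit, 0.01) == pytest.approx(expected, rel=5e-3)

    def test_identity_with_predict(self):
        """dose_for_rv inverts predict_rv to 1e-9 relative on (0, rv0)."""
        for fit in REFERENCE_RELATIVE_FITS.values():
            for target in (0.5 * fit.rv0, 0.01, 1e-4):
                d = dose_for_rv(fit, target)
                assert predict_rv(fit, d) == pytest.approx(target, rel=1e-9)

    def test_target_above_intercept_rejected(self):
        fit = DoseResponseFit(form="first_order", rv0=0.45, d_th=8.15, k=0.669)
        with pytest.raises(ValueError):
            dose_for_rv(fit, 0.5)


class TestFitting:
    def test_noiseless_first_order_recovered(self):
        truth = DoseResponseFit(form="first_order", rv0=1.0, d_th=5.0, k=0.9)
        fit = fit_dose_response(points_on(truth, np.linspace(0, 20, 12)))
        assert fit.form == "first_order"
        assert fit.rv0 == pytest.approx(1.0, rel=1e-6)
        assert fit.d_th == pytest.approx(5.0, rel=1e-6)
        assert fit.k == pytest.approx(0.9, rel=1e-6)

    def test_noiseless_shouldered_intercept_recovered(self):
        truth = DoseResponseFit(form="first_order", rv0=0.45, d_th=8.15, k=0.669)
        fit = fit_dose_response(points_on(truth, np.linspace(0, 25, 14)))
        assert fit.form == "first_order"
        assert fit.rv0 == pytest.approx(0.45, rel=1e-6)
        assert fit.d_th == pytest.approx(8.15, rel=1e-6)
        assert fit.k == pytest.approx(0.669, rel=1e-6)

    def test_noiseless_biphasic_recovered(self):
        truth = DoseResponseFit(form="biphasic", rv0=1.0, d_th=0.0,
                                k1=1.0, k2=0.1, alpha=0.01)
        fit = fit_dose_response(points_on(truth, np.linspace(0, 40, 12)))
        assert fit.form == "biphasic"
        assert fit.rv0 == pytest.approx(1.0, rel=1e-6)
        assert fit.d_th == pytest.approx(0.0, abs=1e-6)
        assert fit.k1 == pytest.approx(1.0, rel=1e-6)
        assert fit.k2 == pytest.approx(0.1, rel=1e-6)
        assert fit.alpha == pytest.approx(0.01, rel=1e-4)

    def test_never_reports_nonpositive_k2(self):
        """Data with apparent upturn at high dose (the negative-k2
        pathology) must fall back to the first-order form."""
        doses = np.array([0, 2, 4, 6, 8, 10, 12, 14.0])
        rv = np.array([1.0, 0.15, 0.02, 3e-3, 5e-4, 6e-4, 8e-4, 1e-3])
        fit = fit_dose_response(list(zip(doses, rv)))
        if fit.form == "biphasic":
            assert fit.k2 > 0 and fit.k1 > fit.k2

    def test_invariant_to_point_order(self):
        truth = DoseResponseFit(form="first_order", rv0=1.0, d_th=3.0, k=1.2)
        pts = simulate_dose_response(truth, np.linspace(0, 10, 8), 1,
                                     seed=4, noise_sd=0.3)
        a = fit_dose_response(pts)
        b = fit_dose_response(list(reversed(pts)))
        assert a.form == b.form
        assert a.d_th == pytest.approx(b.d_th, abs=1e-6)
        assert (a.k or a.k1) == pytest.approx(b.k or b.k1, rel=1e-6)

    def test_censored_points_excluded_by_default(self):
        truth = DoseResponseFit(form="first_order", rv0=1.0, d_th=5.0, k=0.9)
        pts = points_on(truth, np.linspace(0, 20, 12))
        pts.append(DoseResponsePoint(30.0, 1e-7, censored=True))
        fit = fit_dose_response(pts)
        assert fit.k == pytest.approx(0.9, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([(0.0, 1.0), (1.0, 0.5), (2.0, 0.2), (3.0, 0.1)])

    def test_noisy_k_ci_coverage(self):
        """Over 200 seeded replicates at ln-scale noise SD 0.5, the true
        sensitivity lies inside the fitted 95% CI at least 90% of the time."""
        truth = DoseResponseFit(form="first_order", rv0=1.0, d_th=5.0, k=0.9)
        doses = np.linspace(0, 17.5, 8)
        covered = 0
        for i in range(200):
            pts = simulate_dose_response(truth, doses, 1, seed=5000 + i,
                                         noise_sd=0.5)
            fit = fit_dose_response(pts, forms=("first_order",))
            lo, hi = fit.ci["k"]
            covered += lo <= 0.9 <= hi
        assert covered / 200 >= 0.90


class TestNormalization:
    def test_reference_normalizes_to_unity(self):
        table = normalize_fits(REFERENCE_RELATIVE_FITS, "Phaeocystis globosa")
        assert table.loc["Phaeocystis globosa", "d_target_rel"] == pytest.approx(1.0)

    def test_k_times_d_invariant(self):
        fits = {
            "a": DoseResponseFit(form="first_order", rv0=1.0, d_th=2.0, k=1.5),
            "b": DoseResponseFit(form="first_order", rv0=1.0, d_th=4.0, k=0.5),
        }
        table = normalize_fits(fits, "a")
        for name, fit in fits.items():
            d01 = dose_for_rv(fit, 0.01)
            assert table.loc[name, "k_rel"] * table.loc[name, "d_target_rel"] \
                == pytest.approx(fit.k * d01)

    def test_scaled_dose_axes_collapse(self):
        """Two species whose curves differ only by a dose-axis scale give
        identical normalized tables."""
        a = DoseResponseFit(form="first_order", rv0=1.0, d_th=2.0, k=1.5)
        s = 7.3
        b = DoseResponseFit(form="first_order", rv0=1.0, d_th=2.0 * s, k=1.5 / s)
        ta = normalize_fits({"x": a}, "x")
        tb = normalize_fits({"x": b}, "x")
        for col in ("d_th_rel", "k_rel", "d_target_rel"):
            assert ta.loc["x", col] == pytest.approx(tb.loc["x", col])

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            normalize_fits(REFERENCE_RELATIVE_FITS, "nonesuch")
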