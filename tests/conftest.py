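import numpy as np
import pytest

from sdcmpn import CalibrationFit, DilutionDesign

#: inocula of the conventional 5-replicate tenfold table design
TABLE_INOCULA = (0.1, 0.01, 0.001)


@pytest.fixture
def standard_design():
    """The 5-replicate, 3-tier tenfold design with 5-mL tubes."""
    return DilutionDesign(X=-1, DR=10.0, q=3, r=5, V=5.0)


@pytest.fixture
def perfect_calibration():
    """A noise-free calibration: slope 1 fluorescence unit per cell/mL,
    detection limit pinned at 117 cells/mL (a realistic benchtop value)."""
    return CalibrationFit(m=1.0, intercept=0.0, sigma_xy=0.0,
                          lld_cell=117.0, lld_f=117.0, delta_f_min=0.0, n=5)


def grid_mle(positives, reps, inocula, lo=1e-3, hi=5e3, n=400_000):
    """Independent dense-grid maximizer of the product-binomial likelihood.

    Deliberately brute-force: evaluates the log-likelihood on a log-spaced
    lambda grid and returns the argmax, with no reference to the score
    equation used by the estimator under test.
    """
    lam = np.logspace(np.log10(lo), np.log10(hi), n)
    ll = np.zeros_like(lam)
    for p, r, v in zip(positives, reps, inocula):
        x = lam * v
        if p > 0:
            ll += p * np.log(-np.expm1(-x))
        ll += (r - p) * (-x)
    return float(lam[np.argmax(ll)])
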