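import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bloomfit import ChurchillParams, SampleMetadata, TimeSeries

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def golden_section_peak(p, lo=0.0, hi=2000.0, dps=40):
    """Independent numeric oracle for the curve's peak time.

    Golden-section minimization of the two-term denominator in 40-digit
    arithmetic (the denominator is nearly flat around its minimum, so
    double precision cannot localize it to 1e-6 h).
    """
    from mpmath import mp

    with mp.workdps(dps):
        k1, k2 = mp.mpf(p.k1), mp.mpf(p.k2)
        l1, l2 = mp.mpf(p.lambda1), mp.mpf(p.lambda2)

        def denom(t):
            return mp.e**(-l1 * t) / k1 + mp.e**(l2 * t) / k2

        invphi = (mp.sqrt(5) - 1) / 2
        a, b = mp.mpf(lo), mp.mpf(hi)
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = denom(c), denom(d)
        while b - a > mp.mpf("1e-9"):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = denom(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = denom(d)
        return float((a + b) / 2)


@pytest.fixture
def params():
    """A representative growth-decline parameter set."""
    return ChurchillParams(k1=2.0, k2=10.0, lambda1=0.1, lambda2=0.02)


@pytest.fixture
def metadata():
    return SampleMetadata(host="H1", inoculum="strainA", vitamin="replete",
                          replicate="1")


@pytest.fixture
def small_series(metadata):
    """Six hand-picked points of a rising-then-falling count trajectory."""
    return TimeSeries(
        times=np.array([0.0, 24.0, 72.0, 120.0, 200.0, 300.0]),
        counts=np.array([1.0, 5.0, 9.0, 10.0, 8.0, 2.0]),
        metadata=metadata,
    )
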