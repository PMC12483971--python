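import numpy as np
import pytest

from imkmn import CellParameters, RadiationQuality
from imkmn.core_model import IrradiationSchedule


@pytest.fixture
def hsg():
    return CellParameters(alpha0=0.150, beta0=4.67e-2, a_plus_c=2.19, r_d=0.42,
                          h_mn=0.275, label="HSG")


@pytest.fixture
def wi38():
    return CellParameters(alpha0=0.590, beta0=1.63e-2, a_plus_c=0.371, r_d=0.50,
                          h_mn=0.275, label="WI-38")


@pytest.fixture
def du145():
    return CellParameters(alpha0=7.74e-2, beta0=3.80e-2, a_plus_c=2.10, r_d=0.50,
                          h_mn=0.275, label="DU145")


@pytest.fixture
def photon():
    return RadiationQuality(0.0, label="photon")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_schedule(rng, max_segments=6):
    """A random non-overlapping piecewise-constant schedule."""
    n = int(rng.integers(1, max_segments + 1))
    t = 0.0
    segments = []
    for _ in range(n):
        t += float(rng.uniform(0.0, 0.8))  # gap
        dur = float(rng.uniform(0.01, 1.2))
        rate = float(rng.uniform(0.5, 10.0))
        segments.append((t, dur, rate))
        t += dur
    return IrradiationSchedule(segments)


def lea_catcheside_numeric(schedule, kappa, n=4001):
    """Brute-force Lea-Catcheside factor by numerical double integration.

    Independent oracle: per ordered segment pair the separable 1-D integrals
    (and the within-segment triangle integral) are evaluated with Simpson's
    rule on dense grids; no closed-form exponential identities are used.
    """
    from scipy.integrate import cumulative_trapezoid, simpson

    segs = [(s, d, r) for (s, d, r) in schedule.segments if d > 0 and r > 0]
    dose = sum(d * r for _, d, r in segs)
    acc = 0.0
    for i, (si, di, ri) in enumerate(segs):
        # triangle: iint_{tau' < tau} e^{-k(tau-tau')} over [0, di]^2
        tau = np.linspace(0.0, di, n)
        inner = cumulative_trapezoid(np.exp(kappa * tau), tau, initial=0.0)
        acc += ri**2 * simpson(np.exp(-kappa * tau) * inner, x=tau)
        end_i = si + di
        for sj, dj, rj in segs[i + 1:]:
            # separable rectangle, exponents referenced to end_i (all decaying)
            tj = np.linspace(sj, sj + dj, n)
            ti = np.linspace(si, end_i, n)
            left = simpson(np.exp(-kappa * (tj - end_i)), x=tj)
            right = simpson(np.exp(-kappa * (end_i - ti)), x=ti)
            acc += ri * rj * left * right
    return 2.0 * acc / dose**2
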