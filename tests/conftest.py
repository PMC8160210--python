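import numpy as np
import pytest

from titrafit.binding import BindingScheme
from titrafit.signals import TitrationCurve


@pytest.fixture
def scheme1():
    return BindingScheme(kd=(4.4,))


@pytest.fixture
def scheme3():
    return BindingScheme(kd=(4.4, 84.0, 1770.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_free_ligand(scheme, p_total, l_total):
    """Independent speciation oracle: enumerate all real roots of the full
    polynomial mass balance L*Q(L) + p*BM(L) - l_tot*Q(L) = 0 (degree
    n+1) and select the unique root in [0, l_total]."""
    beta = np.concatenate([[1.0], scheme.beta])  # beta_0..beta_n
    n = scheme.n_steps
    deg = n + 1
    coef = np.zeros(deg + 1)  # coef[k] multiplies L**k
    for i in range(n + 1):
        coef[i + 1] += beta[i]  # L * Q
        coef[i] -= l_total * beta[i]  # -l_tot * Q
        if i >= 1:
            coef[i] += p_total * i * beta[i]  # p * BM
    roots = np.roots(coef[::-1])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    tol = 1e-9 * max(l_total, 1.0)
    candidates = sorted(r for r in real if -tol <= r <= l_total + tol)
    assert candidates, f"no admissible root for {scheme.kd}, {p_total}, {l_total}"
    # the mass balance is strictly monotone on [0, l_total]: the root is
    # unique up to numerical duplicates
    return float(np.clip(candidates[0], 0.0, l_total))


def make_curve(l_total, signal, p_total=0.5, modality="fluorescence"):
    return TitrationCurve(
        modality=modality,
        l_total=np.asarray(l_total, dtype=float),
        signal=np.asarray(signal, dtype=float),
        p_total=p_total,
    )
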