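"""Independent oracles used by the test suite.

The Mie oracle here is deliberately implemented along a different route
than the package: Mie coefficients come from scipy's Riccati-Bessel
functions evaluated directly (upward recurrence inside scipy), not from a
logarithmic-derivative downward recurrence, and the efficiencies are
recovered by numerical quadrature of the amplitude functions over angle
rather than from the closed-form series sums.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import riccati_jn, riccati_yn


def oracle_mie_ab(m: float, x: float, nmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Mie a_n, b_n from direct Riccati-Bessel evaluation (Bohren-Huffman 4.56/4.57)."""
    psi_x, dpsi_x = riccati_jn(nmax, x)
    psi_mx, dpsi_mx = riccati_jn(nmax, m * x)
    upsilon, dupsilon = riccati_yn(nmax, x)  # x*y_n and derivative
    xi = psi_x + 1j * upsilon  # x*h1_n
    dxi = dpsi_x + 1j * dupsilon
    sl = slice(1, nmax + 1)
    a = (m * psi_mx[sl] * dpsi_x[sl] - psi_x[sl] * dpsi_mx[sl]) / (
        m * psi_mx[sl] * dxi[sl] - xi[sl] * dpsi_mx[sl]
    )
    b = (psi_mx[sl] * dpsi_x[sl] - m * psi_x[sl] * dpsi_mx[sl]) / (
        psi_mx[sl] * dxi[sl] - m * xi[sl] * dpsi_mx[sl]
    )
    return a, b


def _s1s2(a: np.ndarray, b: np.ndarray, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nmax = a.size
    s1 = np.zeros(mu.shape, dtype=complex)
    s2 = np.zeros(mu.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)
    pi_n = np.ones_like(mu)
    for k in range(1, nmax + 1):
        tau_n = k * mu * pi_n - (k + 1) * pi_nm1
        fac = (2 * k + 1) / (k * (k + 1))
        s1 += fac * (a[k - 1] * pi_n + b[k - 1] * tau_n)
        s2 += fac * (a[k - 1] * tau_n + b[k - 1] * pi_n)
        pi_nm1, pi_n = pi_n, ((2 * k + 1) * mu * pi_n - (k + 1) * pi_nm1) / k
    return s1, s2


def oracle_qsca_g_by_quadrature(m: float, x: float, n_nodes: int = 4000):
    """Qsca and g by Gauss-Legendre quadrature of |S1|^2 + |S2|^2 over angle.

    Qsca = (1/x^2) * int_0^pi (|S1|^2+|S2|^2) sin(theta) dtheta, and g is the
    intensity-weighted mean cosine.  Independent of the closed-form series
    sums used by the implementation under test.
    """
    nmax = int(np.ceil(x + 4.3 * x ** (1 / 3) + 4))
    a, b = oracle_mie_ab(m, x, nmax)
    mu, w = leggauss(n_nodes)  # nodes in cos(theta), weight includes sin via substitution
    s1, s2 = _s1s2(a, b, mu)
    intensity = np.abs(s1) ** 2 + np.abs(s2) ** 2
    qsca = np.sum(w * intensity) / x**2
    g = np.sum(w * intensity * mu) / np.sum(w * intensity)
    return float(qsca), float(g)


def rayleigh_qsca(m: float, x: float) -> float:
    """Small-particle limit: Qsca = (8/3) x^4 |(m^2-1)/(m^2+2)|^2."""
    return (8.0 / 3.0) * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
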