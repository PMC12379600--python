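"""Independent oracles used by the test suite.

``abeles_matrix_reflectivity`` is a from-scratch transfer-matrix (Abeles)
implementation of stratified-medium specular reflectivity — algebraically a
different route than the Parratt recursion in the package, coded against the
textbook interface/propagation matrix formalism.  It deliberately imports
nothing from ``monofilm``.
"""

import numpy as np


def abeles_matrix_reflectivity(sld_list, thickness_list, roughness_list, q):
    """Transfer-matrix reflectivity of a stack.

    Parameters
    ----------
    sld_list : sequence of complex
        SLDs from fronting medium to backing medium (length n+2 for n slabs).
    thickness_list : sequence of float
        Thicknesses of the n internal slabs.
    roughness_list : sequence of float
        Gaussian widths of the n+1 interfaces, top to bottom (Nevot-Croce).
    q : array
        Momentum transfer, 1/Angstrom.
    """
    q = np.atleast_1d(np.asarray(q, dtype=complex))
    slds = [complex(s) for s in sld_list]
    n_if = len(slds) - 1
    assert len(thickness_list) == len(slds) - 2
    assert len(roughness_list) == n_if

    kz = [np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (s - slds[0])) for s in slds]

    R = np.empty(q.shape, dtype=float)
    for m in range(q.size):
        M = np.eye(2, dtype=complex)
        for i in range(n_if):
            ki, kj = kz[i][m], kz[i + 1][m]
            denom = ki + kj
            r = 0.0 if denom == 0 else (ki - kj) / denom
            r *= np.exp(-2.0 * ki * kj * roughness_list[i] ** 2)
            t2 = 1.0 + r  # relative transmission; cancels in r_tot
            F = np.array([[1.0, r], [r, 1.0]], dtype=complex) / t2
            if i < n_if - 1:
                d = thickness_list[i]
                P = np.array([[np.exp(-1j * kj * d), 0.0], [0.0, np.exp(1j * kj * d)]])
                M = M @ F @ P
            else:
                M = M @ F
        R[m] = abs(M[1, 0] / M[0, 0]) ** 2
    return R


def brute_force_gaussian_smear(q_data, q_model, R_model, dq_over_q, n=4001, width=6.0):
    """Direct numerical convolution oracle for Gaussian dq/q smearing
    (FWHM = dq_over_q * q), with edge-clamped extrapolation."""
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.empty_like(np.asarray(q_data, dtype=float))
    for i, q0 in enumerate(q_data):
        s = dq_over_q * q0 * fwhm_to_sigma
        x = np.linspace(-width * s, width * s, n)
        w = np.exp(-x**2 / (2 * s**2))
        w /= np.trapezoid(w, x)
        Rv = np.interp(q0 + x, q_model, R_model)  # clamped at the edges
        out[i] = np.trapezoid(w * Rv, x)
    return out
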