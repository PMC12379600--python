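"""Chronocoulometry and differential-capacitance analysis of supported bilayers.

A potential-step experiment on a film-covered (or bare) Au(111) electrode
yields current transients whose integrals are relative charge densities
between each potential of interest and a common desorption potential.
Referencing against the potential of zero charge (pzc) of the bare electrode
makes the charge densities absolute, and the electrochemical film pressure
follows from the Lippmann relation as the double integral

    Pi(E) = integral_{E_des}^{E} (sigma_M,film - sigma_M,bare) dE'

i.e. the area between the film and bare charge-density curves.  One
uC/cm^2 x V equals 10 mN/m.

Sign conventions: cathodic currents are negative; sigma_M is positive at
potentials above the pzc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChronoTransient",
    "ChargeCurve",
    "FilmPressureCurve",
    "charge_density_from_transients",
    "find_pzc",
    "film_pressure",
    "capacitance_from_lockin",
    "UC_V_TO_MN_PER_M",
]

UC_V_TO_MN_PER_M = 10.0  # 1 uC cm^-2 * 1 V = 10^-2 J m^-2 = 10 mN m^-1


@dataclass
class ChronoTransient:
    """One potential-step current transient.

    ``E`` is the potential of interest (V); current density in uA/cm^2
    sampled at ``t`` seconds after the step to the desorption potential.
    """

    E: float
    t: np.ndarray
    current: np.ndarray
    E_base: float = -0.01
    E_des: float = -1.05

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.t.shape != self.current.shape or self.t.ndim != 1:
            raise ValueError("t and current must be 1-D arrays of equal length")
        if self.t[0] < 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time must increase from 0")


@dataclass
class ChargeCurve:
    """Charge density sigma_M(E) in uC/cm^2 for a film-covered or bare electrode."""

    E: np.ndarray
    sigma_M: np.ndarray
    label: str = "film"  # "film" | "bare"
    absolute: bool = True

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.sigma_M = np.asarray(self.sigma_M, dtype=float)
        if self.E.shape != self.sigma_M.shape:
            raise ValueError("E and sigma_M must have the same length")
        order = np.argsort(self.E)
        self.E, self.sigma_M = self.E[order], self.sigma_M[order]


@dataclass
class FilmPressureCurve:
    """Electrochemical film pressure Pi(E) = gamma_0 - gamma in mN/m."""

    E: np.ndarray
    Pi: np.ndarray

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.Pi = np.asarray(self.Pi, dtype=float)
        if self.E.shape != self.Pi.shape:
            raise ValueError("E and Pi must have the same length")


def integrate_transient(tr: ChronoTransient) -> float:
    """Trapezoidal charge of one transient, uC/cm^2."""
    return float(np.trapezoid(tr.current, tr.t))


def charge_density_from_transients(
    transients: list[ChronoTransient],
    pzc_bare: float | None = None,
    bare_transients: list[ChronoTransient] | None = None,
    label: str = "film",
) -> ChargeCurve:
    """Integrate step transients into a charge-density curve.

    Each transient's integral is the charge flowing from the state at ``E``
    to the shared desorbed state, so the relative charge density at E is
    sigma(E) - sigma(E_des) = -integral.  Absolute referencing anchors the
    desorbed state: the *bare* relative curve must cross zero charge exactly
    at ``pzc_bare``, and the film curve shares the same desorbed-state
    anchor because the film is desorbed at E_des.

    Without ``pzc_bare`` the curve is returned relative (``absolute=False``).
    For a film curve, pass the companion ``bare_transients`` so that the
    anchor can be evaluated; a bare curve anchors itself.
    """
    E = np.array([tr.E for tr in transients], dtype=float)
    rel = np.array([-integrate_transient(tr) for tr in transients])
    order = np.argsort(E)
    E, rel = E[order], rel[order]

    if pzc_bare is None:
        return ChargeCurve(E=E, sigma_M=rel, label=label, absolute=False)

    if label == "bare" or bare_transients is None:
        E_ref, rel_ref = E, rel
    else:
        E_ref = np.array([tr.E for tr in bare_transients], dtype=float)
        rel_ref = np.array([-integrate_transient(tr) for tr in bare_transients])
        o = np.argsort(E_ref)
        E_ref, rel_ref = E_ref[o], rel_ref[o]
    if not E_ref.min() <= pzc_bare <= E_ref.max():
        raise ValueError("pzc_bare lies outside the measured potential range")
    anchor = -float(np.interp(pzc_bare, E_ref, rel_ref))  # sigma at desorption
    return ChargeCurve(E=E, sigma_M=rel + anchor, label=label, absolute=True)


def find_pzc(curve: ChargeCurve) -> float:
    """Potential of zero charge: the zero crossing of sigma_M(E) nearest the
    positive potential limit, by linear interpolation between the bracketing
    samples.  Multiple crossings produce the most positive one (a warning is
    attached to the return through ``warnings``)."""
    s = curve.sigma_M
    sign_change = np.flatnonzero(np.diff(np.signbit(s)) | (s[:-1] == 0))
    exact = np.flatnonzero(s == 0)
    if len(sign_change) == 0 and len(exact) == 0:
        raise ValueError("charge density curve does not cross zero")
    candidates = []
    for i in sign_change:
        if s[i] == 0:
            candidates.append(curve.E[i])
        else:
            e = curve.E[i] + (curve.E[i + 1] - curve.E[i]) * (0.0 - s[i]) / (s[i + 1] - s[i])
            candidates.append(e)
    for i in exact:
        candidates.append(curve.E[i])
    candidates = sorted(set(float(c) for c in candidates))
    if len(candidates) > 1:
        import warnings

        warnings.warn(
            f"{len(candidates)} zero crossings; returning the most positive",
            stacklevel=2,
        )
    return candidates[-1]


def film_pressure(film: ChargeCurve, bare: ChargeCurve, E_des: float) -> FilmPressureCurve:
    """Film pressure by double integration of the charge-density difference.

    The film curve is linearly interpolated onto the bare curve's potential
    grid; the integral runs from the desorption potential, where Pi = 0 by
    construction.  Output in mN/m.
    """
    lo = max(film.E.min(), bare.E.min())
    hi = min(film.E.max(), bare.E.max())
    if lo >= hi:
        raise ValueError("film and bare potential ranges do not overlap")
    if not lo - 1e-9 <= E_des <= hi + 1e-9:
        raise ValueError("E_des must lie inside the common potential range")
    E = bare.E[(bare.E >= lo) & (bare.E <= hi)]
    if E_des not in E:
        E = np.sort(np.append(E, E_des))
    d_sigma = np.interp(E, film.E, film.sigma_M) - np.interp(E, bare.E, bare.sigma_M)
    # cumulative trapezoid from E_des outward
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (d_sigma[1:] + d_sigma[:-1]) * np.diff(E))))
    i_des = int(np.argmin(np.abs(E - E_des)))
    Pi = (cum - cum[i_des]) * UC_V_TO_MN_PER_M
    return FilmPressureCurve(E=E, Pi=Pi)


def capacitance_from_lockin(in_phase, quadrature, omega: float, dE_amplitude: float):
    """Series-RC differential capacitance from lock-in current components.

    For a series RC circuit driven at angular frequency ``omega`` with AC
    amplitude ``dE_amplitude``, the in-phase (resistive) and quadrature
    (capacitive) current amplitudes i_ip, i_q (uA/cm^2) invert to

        C = (i_ip^2 + i_q^2) / (omega * dE * i_q)    [uF/cm^2]

    which reduces to C = i_q / (omega dE) for a purely capacitive response.
    """
    if dE_amplitude <= 0:
        raise ValueError("dE_amplitude must be > 0")
    i_ip = np.asarray(in_phase, dtype=float)
    i_q = np.asarray(quadrature, dtype=float)
    if np.any(i_q <= 0):
        raise ValueError("quadrature current must be > 0 (non-capacitive response)")
    c = (i_ip**2 + i_q**2) / (omega * dE_amplitude * i_q)
    return c if c.ndim else float(c)
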