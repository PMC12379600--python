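"""Specular reflectivity of stratified interfaces.

Exact slab-model (Parratt) reflectivity with Nevot--Croce roughness factors,
Gaussian ``dq/q`` resolution smearing and error-function SLD profiles.  This
is the physics engine behind all X-ray and neutron reflectometry fitting in
the package.

Conventions
-----------
* ``q`` is the momentum transfer normal to the surface in 1/Angstrom.
* SLDs are in 1/Angstrom^2 (e.g. D2O ~ 6.38e-6); they may be complex, with
  the imaginary part describing absorption (default 0).
* Resolution widths (``dq`` column or a global ``dq/q``) are Gaussian FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "Slab",
    "SlabStack",
    "ReflectivityCurve",
    "parratt_reflectivity",
    "smeared_reflectivity",
    "apply_resolution",
    "sld_profile",
]

# Gauss-Hermite (probabilists') quadrature for Gaussian resolution smearing.
_NGAUSS = 17
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(_NGAUSS)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)  # weights of the standard normal

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer of an interfacial model.

    Parameters
    ----------
    thickness : float
        Layer thickness in Angstrom (>= 0).
    sld : complex
        Scattering length density in 1/Angstrom^2.
    roughness_top : float
        Gaussian width (Angstrom) of the interface *above* this slab.
    """

    thickness: float
    sld: complex
    roughness_top: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.thickness) or self.thickness < 0:
            raise ValueError(f"slab thickness must be finite and >= 0, got {self.thickness}")
        if not np.isfinite(self.roughness_top) or self.roughness_top < 0:
            raise ValueError(f"roughness must be finite and >= 0, got {self.roughness_top}")
        if not np.isfinite(complex(self.sld)):
            raise ValueError("slab SLD must be finite")


@dataclass(frozen=True)
class SlabStack:
    """Ordered stack of slabs between two semi-infinite media.

    ``medium_above`` is the fronting (air for a Langmuir film, SLD 0) and
    ``medium_below`` the backing subphase.  ``roughness_below`` is the
    Gaussian width of the interface between the last slab (or the fronting,
    for an empty stack) and the backing medium.
    """

    medium_above: complex = 0.0
    slabs: tuple[Slab, ...] = field(default_factory=tuple)
    medium_below: complex = 0.0
    roughness_below: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "slabs", tuple(self.slabs))
        for s in self.slabs:
            if not isinstance(s, Slab):
                raise TypeError("stack entries must be Slab instances")
        if not (np.isfinite(complex(self.medium_above)) and np.isfinite(complex(self.medium_below))):
            raise ValueError("medium SLDs must be finite")
        if not np.isfinite(self.roughness_below) or self.roughness_below < 0:
            raise ValueError("roughness_below must be finite and >= 0")

    # Convenience layer tables used by both the recursion and the profile.
    def _layers(self):
        """(sld, thickness, roughness) arrays; roughness[i] is the interface
        above layer i (length n+2 media-inclusive representation)."""
        slds = np.array(
            [complex(self.medium_above)]
            + [complex(s.sld) for s in self.slabs]
            + [complex(self.medium_below)]
        )
        thick = np.array([0.0] + [s.thickness for s in self.slabs] + [0.0])
        rough = np.array([s.roughness_top for s in self.slabs] + [self.roughness_below])
        return slds, thick, rough


@dataclass
class ReflectivityCurve:
    """A measured or modelled specular reflectivity curve.

    ``dq`` (optional) is the per-point Gaussian resolution FWHM in q.
    """

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None
    dq: np.ndarray | None = None
    contrast_label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.R.shape:
            raise ValueError("q and R must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.q)) or np.any(self.q <= 0):
            raise ValueError("q must be finite and > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.R < 0):
            raise ValueError("R must be >= 0")
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
            if self.dR.shape != self.q.shape or np.any(self.dR < 0):
                raise ValueError("dR must match q and be >= 0")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
            if self.dq.shape != self.q.shape or np.any(self.dq < 0):
                raise ValueError("dq must match q and be >= 0")


def _kz(q, slds, fronting):
    """Normal wavevector in every layer, relative to the fronting medium."""
    q = np.asarray(q, dtype=complex)
    k0sq = (q / 2.0) ** 2
    # slds shape (n_layers,), q shape (m,) -> (n_layers, m)
    return np.sqrt(k0sq[None, :] - 4.0 * np.pi * (slds[:, None] - fronting))


def parratt_reflectivity(
    stack: SlabStack,
    q: np.ndarray,
    *,
    microslice: bool = False,
    slice_width: float = 0.5,
) -> ReflectivityCurve:
    """Specular reflectivity |r(q)|^2 of a slab stack by the Parratt recursion.

    Interfacial roughness enters through Nevot--Croce damping factors
    ``exp(-2 k_i k_{i+1} sigma^2)``, adequate while sigma is well below the
    slab thicknesses.  For very rough interfaces set ``microslice=True`` to
    discretise the error-function SLD profile into thin zero-roughness
    slices before running the recursion.

    Parameters
    ----------
    stack : SlabStack
    q : array
        Momentum transfer values, 1/Angstrom, all > 0.
    microslice : bool
        Discretise the continuous profile instead of using Nevot-Croce.
    slice_width : float
        Slice thickness (Angstrom) used when ``microslice`` is on.

    Returns
    -------
    ReflectivityCurve
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if not np.all(np.isfinite(q)) or np.any(q <= 0):
        raise ValueError("q must be finite and > 0")
    R = _reflectivity_values(stack, q, microslice=microslice, slice_width=slice_width)
    return ReflectivityCurve(q=q, R=R, contrast_label="model")


def _reflectivity_values(stack, q, *, microslice=False, slice_width=0.5):
    """Raw |r|^2 values without curve packaging (q need not be sorted)."""
    if microslice:
        stack = _microsliced(stack, slice_width)

    slds, thick, rough = stack._layers()
    fronting = slds[0]
    k = _kz(q, slds, fronting)

    # recursion from the backing medium upwards
    r_tot = np.zeros_like(q, dtype=complex)
    n = len(slds)
    for i in range(n - 2, -1, -1):
        ki, kj = k[i], k[i + 1]
        denom = ki + kj
        # a zero denominator only occurs for identical layers where r = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom != 0, (ki - kj) / np.where(denom != 0, denom, 1.0), 0.0)
        r = r * np.exp(-2.0 * ki * kj * rough[i] ** 2)
        if i == n - 2:
            r_next = r
        else:
            beta = np.exp(2j * k[i + 1] * thick[i + 1])
            r_next = (r + r_tot * beta) / (1.0 + r * r_tot * beta)
        r_tot = r_next

    return np.abs(r_tot) ** 2


def _microsliced(stack: SlabStack, slice_width: float) -> SlabStack:
    """Discretise the erf-broadened profile into thin zero-roughness slabs."""
    slds, thick, rough = stack._layers()
    total = float(np.sum(thick))
    pad = 4.0 * max(float(np.max(rough)), slice_width)
    z = np.arange(-pad, total + pad + slice_width, slice_width)
    centres = 0.5 * (z[1:] + z[:-1])
    prof = _profile_at(stack, centres)
    slabs = tuple(Slab(thickness=slice_width, sld=s, roughness_top=0.0) for s in prof)
    return SlabStack(
        medium_above=stack.medium_above,
        slabs=slabs,
        medium_below=stack.medium_below,
        roughness_below=0.0,
    )


def smeared_reflectivity(stack: SlabStack, q, dq_over_q: float = 0.0, dq=None) -> ReflectivityCurve:
    """Resolution-smeared model reflectivity.

    Gaussian smearing with FWHM ``dq_over_q * q`` (or a per-point FWHM array
    ``dq``), evaluated by 17-point Gauss-Hermite quadrature on the exact
    model — the preferred route when the slab model is available, since no
    interpolation of the curve is involved.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq is None:
        if dq_over_q < 0:
            raise ValueError("dq_over_q must be >= 0")
        if dq_over_q == 0:
            return parratt_reflectivity(stack, q)
        sigma = dq_over_q * q / _FWHM
    else:
        dq = np.asarray(dq, dtype=float)
        sigma = dq / _FWHM
    qs = q[None, :] + sigma[None, :] * _GH_X[:, None]
    qs = np.clip(qs, 1e-8, None)
    Rnodes = _reflectivity_values(stack, qs.ravel()).reshape(qs.shape)
    R = _GH_W @ Rnodes
    return ReflectivityCurve(q=q, R=R, contrast_label="model")


def apply_resolution(curve: ReflectivityCurve, dq_over_q: float) -> ReflectivityCurve:
    """Smear a sampled reflectivity curve with a Gaussian of FWHM ``dq_over_q * q``.

    The curve is oversampled by monotone interpolation of log10 R before the
    Gaussian quadrature; beyond the sampled range the endpoints are clamped.
    ``dq_over_q = 0`` returns the input unchanged.
    """
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return curve

    q, R = curve.q, curve.R
    floor = max(R[R > 0].min() * 1e-6, 1e-300) if np.any(R > 0) else 1e-300
    logR = np.log10(np.clip(R, floor, None))

    def interp(qq):
        return 10.0 ** np.interp(qq, q, logR)  # np.interp clamps at the edges

    sigma = dq_over_q * q / _FWHM
    qs = q[None, :] + sigma[None, :] * _GH_X[:, None]
    Rs = _GH_W @ interp(np.clip(qs, 1e-12, None))
    return ReflectivityCurve(q=q, R=Rs, dR=curve.dR, dq=curve.dq, contrast_label=curve.contrast_label)


def _profile_at(stack: SlabStack, z: np.ndarray) -> np.ndarray:
    slds, thick, rough = stack._layers()
    z = np.asarray(z, dtype=float)
    prof = np.full(z.shape, slds[0], dtype=complex)
    z_if = np.concatenate(([0.0], np.cumsum(thick[1:-1])))  # interface depths
    for i, zi in enumerate(z_if):
        step = slds[i + 1] - slds[i]
        s = rough[i]
        if s == 0:
            prof = prof + step * (z >= zi)
        else:
            prof = prof + step * 0.5 * (1.0 + erf((z - zi) / (np.sqrt(2.0) * s)))
    return prof


def sld_profile(stack: SlabStack, z: np.ndarray) -> np.ndarray:
    """Error-function-broadened SLD depth profile.

    ``z`` increases from the fronting into the backing; z = 0 is the first
    interface.  Far above/below the stack the profile equals the fronting /
    backing SLD.  Returned real for real-SLD stacks.
    """
    prof = _profile_at(stack, z)
    if np.all(np.abs(prof.imag) < 1e-300):
        return prof.real
    return prof


def fresnel_reflectivity(sld_front: complex, sld_back: complex, q) -> np.ndarray:
    """Closed-form single-interface (Fresnel) reflectivity, zero roughness."""
    stack = SlabStack(medium_above=sld_front, medium_below=sld_back)
    return parratt_reflectivity(stack, q).R


def critical_q(sld_back: complex, sld_front: complex = 0.0) -> float:
    """Critical momentum transfer sqrt(16 pi (rho_back - rho_front))."""
    d = (complex(sld_back) - complex(sld_front)).real
    return float(np.sqrt(16.0 * np.pi * d)) if d > 0 else 0.0
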