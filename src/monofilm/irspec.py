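"""PM-IRRAS band analysis for lipid films on electrodes.

Deconvolves the C-H and C=O stretching regions into pseudo-Voigt bands on a
linear baseline and derives two quantities of interest:

* the solvated-carbonyl fraction — the share of the ester C=O envelope in
  the lower-wavenumber, hydrogen-bonded component;
* acyl-chain tilt — on a metal surface only the component of a transition
  dipole moment (TDM) along the surface normal absorbs, so comparing the
  integrated absorbance of a band with the value expected for an isotropic
  layer gives the TDM angle from the normal,

      cos^2(theta) = A_measured / (3 * A_random),

  and since the CH2 symmetric and antisymmetric stretch TDMs and the chain
  axis form an orthogonal triad, the chain tilt t follows from

      cos^2(t) = 1 - cos^2(theta_sym) - cos^2(theta_asym).

The random-orientation reference absorbances are inputs (computed with
external thin-film optics software); this module does not model the optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "IRSpectrum",
    "BandTemplate",
    "BandFit",
    "fit_bands",
    "solvated_carbonyl_fraction",
    "tilt_from_absorbance",
]


@dataclass
class IRSpectrum:
    """Absorbance-like spectrum over a wavenumber axis (cm^-1)."""

    wavenumber: np.ndarray
    signal: np.ndarray
    region: str = ""

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.wavenumber.shape != self.signal.shape:
            raise ValueError("wavenumber and signal must have equal length")
        d = np.diff(self.wavenumber)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber must be monotone")
        if d[0] < 0:
            self.wavenumber = self.wavenumber[::-1]
            self.signal = self.signal[::-1]


@dataclass(frozen=True)
class BandTemplate:
    """Initial guess for one band: centre/width in cm^-1 and its role, one of
    {'sym', 'asym', 'fermi', 'free-CO', 'hbond-CO', 'other'}."""

    center: float
    fwhm: float
    role: str = "other"


@dataclass
class BandFit:
    """Result of a multi-band deconvolution."""

    centers: np.ndarray
    fwhms: np.ndarray
    areas: np.ndarray
    roles: list
    baseline: tuple
    redchi: float
    solvated_fraction: float | None = None

    def area_of(self, role: str) -> float:
        return float(sum(a for a, r in zip(self.areas, self.roles) if r == role))


def fit_bands(spec: IRSpectrum, templates: list[BandTemplate], max_center_shift: float = 8.0) -> BandFit:
    """Least-squares fit of a sum of pseudo-Voigt bands plus linear baseline.

    Band centres may move by at most ``max_center_shift`` cm^-1 from their
    template positions.  For a C=O region fit (templates with roles
    'free-CO'/'hbond-CO') the hydrogen-bonded area fraction is attached.
    Raises on non-convergence, reporting the residual norm.
    """
    x, y = spec.wavenumber, spec.signal
    model = lmfit.models.LinearModel(prefix="bg_")
    params = model.make_params(bg_slope=0.0, bg_intercept=float(np.min(y)))
    for j, t in enumerate(templates):
        pv = lmfit.models.PseudoVoigtModel(prefix=f"b{j}_")
        model = model + pv
        params.update(pv.make_params())
        params[f"b{j}_center"].set(value=t.center, min=t.center - max_center_shift, max=t.center + max_center_shift)
        params[f"b{j}_sigma"].set(value=t.fwhm / 2, min=t.fwhm / 20, max=t.fwhm * 5)
        amp0 = max(float(np.interp(t.center, x, y) - np.min(y)), 1e-12) * t.fwhm
        params[f"b{j}_amplitude"].set(value=amp0, min=0)
        params[f"b{j}_fraction"].set(value=0.3, min=0, max=1)
    out = model.fit(y, params, x=x)
    if not out.success:
        raise RuntimeError(
            f"band fit did not converge: {out.message}; residual norm "
            f"{float(np.linalg.norm(out.residual)):.3g}"
        )
    centers = np.array([out.params[f"b{j}_center"].value for j in range(len(templates))])
    fwhms = np.array([out.params[f"b{j}_fwhm"].value for j in range(len(templates))])
    areas = np.array([out.params[f"b{j}_amplitude"].value for j in range(len(templates))])
    roles = [t.role for t in templates]
    fit = BandFit(
        centers=centers,
        fwhms=fwhms,
        areas=areas,
        roles=roles,
        baseline=(float(out.params["bg_intercept"].value), float(out.params["bg_slope"].value)),
        redchi=float(out.redchi),
    )
    if {"free-CO", "hbond-CO"} & set(roles):
        fit.solvated_fraction = solvated_carbonyl_fraction(fit)
    return fit


def solvated_carbonyl_fraction(fit: BandFit) -> float:
    """area(H-bonded C=O) / total C=O area."""
    hb = fit.area_of("hbond-CO")
    free = fit.area_of("free-CO")
    total = hb + free
    if total <= 0:
        raise ValueError("no C=O band area in fit")
    return hb / total


def tilt_from_absorbance(A_measured: dict, A_random: dict) -> tuple[dict, float]:
    """TDM angles and chain tilt from integrated absorbances.

    ``A_measured`` / ``A_random`` map mode name ('sym', 'asym') to integrated
    absorbance of the CH2 stretches and of the simulated randomly oriented
    layer.  Returns ({mode: theta_deg}, chain_tilt_deg).  Raises when the
    implied cos^2 values are inconsistent (outside [0, 1] or summing beyond 1).
    """
    cos2 = {}
    for mode in ("sym", "asym"):
        if mode not in A_measured or mode not in A_random:
            raise ValueError(f"both CH2 modes required, missing {mode!r}")
        if A_random[mode] <= 0:
            raise ValueError("A_random must be > 0")
        c2 = A_measured[mode] / (3.0 * A_random[mode])
        if not 0.0 <= c2 <= 1.0:
            raise ValueError(f"cos^2(theta_{mode}) = {c2:.3f} outside [0, 1]")
        cos2[mode] = c2
    c2t = 1.0 - cos2["sym"] - cos2["asym"]
    if c2t < -1e-12:
        raise ValueError("inconsistent inputs: cos^2 tilt negative")
    c2t = min(max(c2t, 0.0), 1.0)
    theta = {m: float(np.degrees(np.arccos(np.sqrt(c)))) for m, c in cos2.items()}
    tilt = float(np.degrees(np.arccos(np.sqrt(c2t))))
    return theta, tilt
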