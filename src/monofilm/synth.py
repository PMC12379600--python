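"""Seeded synthetic-data generators for every analysis stage.

Each generator draws from the forward models in this package, adds a stated
noise model and returns both the data and a machine-readable truth record,
so the whole pipeline is testable without downloading beamline or electrode
raw data.  Identical seeds give bit-identical output (NumPy Generator with
PCG64, which is platform-stable).

Noise models (the measurements themselves do not dictate one):

* reflectivity — multiplicative Gaussian, sigma = noise_rel * R, floored
  (counting statistics at high rates);
* GIXD — Poisson counts on peaks plus a smooth background;
* isotherms and chronocoulometry — additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .echem import ChronoTransient
from .gixd import GIXDImage
from .irspec import IRSpectrum
from .isotherm import Isotherm
from .monolayer import ContrastSpec, MonolayerParams, build_stack
from .reflectivity import ReflectivityCurve, smeared_reflectivity

__all__ = [
    "gen_reflectivity",
    "gen_gixd",
    "gen_isotherm",
    "gen_chrono",
    "gen_ir_spectrum",
]

DEFAULT_DQ_OVER_Q = 0.07  # neutron time-of-flight resolution used throughout


def _rng(seed):
    return np.random.default_rng(seed)


def gen_reflectivity(
    true_params: MonolayerParams,
    contrasts: list[ContrastSpec],
    noise_rel: float = 0.02,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
    q: np.ndarray | None = None,
    seed: int = 0,
    R_floor: float = 1e-10,
) -> tuple[list[ReflectivityCurve], dict]:
    """Reflectivity datasets for one film measured under several contrasts.

    Forward model -> Gaussian dq/q smearing -> multiplicative Gaussian noise
    with sigma = noise_rel * R (floored at ``R_floor``); the dR column is
    consistent with the noise actually added.  Returns (curves, truth).
    """
    if q is None:
        q = np.geomspace(0.018, 0.6, 120)
    rng = _rng(seed)
    curves = []
    for contrast in contrasts:
        stack = build_stack(true_params, contrast)
        model = smeared_reflectivity(stack, q, dq_over_q)
        dR = np.maximum(noise_rel * model.R, R_floor)
        if noise_rel > 0:
            R = model.R + rng.normal(0.0, 1.0, size=q.size) * dR
            R = np.maximum(R, 0.0)
        else:
            R = model.R
        dq = dq_over_q * q if dq_over_q > 0 else None
        curves.append(
            ReflectivityCurve(q=q.copy(), R=R, dR=dR, dq=dq, contrast_label=contrast.label or contrast.subphase)
        )
    truth = {
        "V_tail": true_params.V_tail,
        "d_tail": true_params.d_tail,
        "d_hg": true_params.d_hg,
        "sigma": true_params.sigma,
        "headgroup_solvent_fraction": true_params.headgroup_solvent_fraction,
        "A_M": true_params.A_M,
        "n_w": true_params.headgroup_solvent_fraction * true_params.A_M * true_params.d_hg / 30.0,
        "dq_over_q": dq_over_q,
        "noise_rel": noise_rel,
        "seed": seed,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# GIXD


def peak_positions_from_cell(cell_G: dict, tilt_deg: float, azimuth_deg: float):
    """Forward peak positions (q_xy, q_z) from reciprocal vectors and tilt.

    ``cell_G`` maps reflection label -> in-plane G vector (2,); the chains
    tilt by ``tilt_deg`` toward the in-plane direction at ``azimuth_deg``
    from the x axis: q_z = tan(t) * (G . u), folded to >= 0 (the experiment
    sees |q_z| of the rod maximum for a 2D powder).
    """
    u = np.array([np.cos(np.radians(azimuth_deg)), np.sin(np.radians(azimuth_deg))])
    tant = np.tan(np.radians(tilt_deg))
    out = {}
    for lab, G in cell_G.items():
        G = np.asarray(G, dtype=float)
        out[lab] = (float(np.hypot(*G)), float(abs(tant * np.dot(G, u))))
    return out


def reciprocal_vectors(a: float, b: float, gamma_deg: float) -> dict:
    """Reciprocal vectors of a 2D lattice with |a|, |b| and cell angle gamma."""
    g = np.radians(gamma_deg)
    A = np.array([a, 0.0])
    B = np.array([b * np.cos(g), b * np.sin(g)])
    area = abs(A[0] * B[1] - A[1] * B[0])
    # 2D reciprocal: G10 = 2 pi (B x z)/area rotated into plane
    G10 = 2 * np.pi * np.array([B[1], -B[0]]) / area
    G01 = 2 * np.pi * np.array([-A[1], A[0]]) / area
    return {"10": G10, "01": G01, "1-1": G01 - G10}


def gen_gixd(
    a: float = 4.9,
    b: float = 4.9,
    gamma_deg: float = 120.0,
    tilt_deg: float = 0.0,
    azimuth_deg: float | None = None,
    intensities: dict | None = None,
    fwhm_xy: float = 0.02,
    fwhm_z: float = 0.25,
    background: float = 20.0,
    poisson_noise: bool = True,
    seed: int = 0,
    q_xy: np.ndarray | None = None,
    q_z: np.ndarray | None = None,
) -> tuple[GIXDImage, dict]:
    """Synthetic GIXD map of a 2D chain lattice.

    Peaks are pseudo-Voigt in q_xy times Gaussian in q_z on a smooth
    background, with optional Poisson counting noise.  Reflections that
    coincide in (q_xy, q_z) (the hexagonal / NN-tilt degeneracies) merge
    naturally by adding intensity.  ``azimuth_deg=None`` tilts the chains
    along the nearest-neighbour (a+b) direction, the convention that keeps
    the {1-1} reflection on the horizon.  Returns (image, truth).
    """
    if q_xy is None:
        q_xy = np.linspace(1.2, 1.8, 400)
    if q_z is None:
        q_z = np.linspace(0.0, 0.72, 180)
    G = reciprocal_vectors(a, b, gamma_deg)
    if azimuth_deg is None:
        g = np.radians(gamma_deg)
        nn = np.array([a, 0.0]) + np.array([b * np.cos(g), b * np.sin(g)])
        azimuth_deg = float(np.degrees(np.arctan2(nn[1], nn[0])))
    pos = peak_positions_from_cell(G, tilt_deg, azimuth_deg)
    if intensities is None:
        intensities = {lab: 1500.0 for lab in pos}
    rng = _rng(seed)

    X, Z = np.meshgrid(q_xy, q_z)
    img = background * (1.0 + 0.2 * (X - q_xy.mean()) ** 2)
    sx = fwhm_xy / (2 * np.sqrt(2 * np.log(2)))
    sz = fwhm_z / (2 * np.sqrt(2 * np.log(2)))
    for lab, (qc, zc) in pos.items():
        amp = intensities.get(lab, 0.0)
        if amp <= 0:
            continue
        gx = np.exp(-((X - qc) ** 2) / (2 * sx**2))
        lx = 1.0 / (1.0 + ((X - qc) / (fwhm_xy / 2)) ** 2)
        fx = 0.7 * gx + 0.3 * lx
        # Bragg rod: Gaussian around the rod maximum (mirror below horizon)
        fz = np.exp(-((Z - zc) ** 2) / (2 * sz**2)) + np.exp(-((Z + zc) ** 2) / (2 * sz**2))
        img = img + amp * fx * fz / fz.max()
    if poisson_noise:
        img = rng.poisson(img).astype(float)
    cross = abs(G["10"][0] * G["01"][1] - G["10"][1] * G["01"][0])
    truth = {
        "a": a,
        "b": b,
        "gamma_deg": gamma_deg,
        "tilt_deg": tilt_deg,
        "azimuth_deg": azimuth_deg,
        "A_chain": (2 * np.pi) ** 2 / cross,
        "peaks": {lab: list(p) for lab, p in pos.items()},
        "seed": seed,
    }
    return GIXDImage(q_xy=q_xy, q_z=q_z, intensity=img), truth


# ---------------------------------------------------------------------------
# isotherms


@dataclass(frozen=True)
class IsothermPhaseModel:
    """Piecewise phase model of a compression isotherm.

    Branch slopes are dPi/dA in mN m^-1 / Angstrom^2 (negative on
    compression); areas in Angstrom^2 per molecule.  The plateau pressure is
    the pressure at the Le->plateau corner and the kink pressure the
    pressure at the Lc->S corner.  ``corner_width`` rounds the corners.
    """

    A_lift: float = 95.0  # area where Pi lifts off zero
    slope_le: float = -0.35
    Pi_plateau: float = 12.0
    plateau_slope: float = -0.02
    A_plateau_end: float = 50.0
    slope_lc: float = -1.9
    Pi_kink: float = 27.0
    slope_s: float = -6.0
    A_min: float = 38.0
    corner_width: float = 1.0

    def __post_init__(self):
        if not self.Pi_plateau < self.Pi_kink:
            raise ValueError("plateau pressure must lie below the kink pressure")
        if max(self.slope_le, self.plateau_slope, self.slope_lc, self.slope_s) > 0:
            raise ValueError("compression branch slopes dPi/dA must be <= 0")

    def curve(self, A: np.ndarray) -> np.ndarray:
        """Continuous Pi(A) with smoothly rounded corners."""
        # construct corner areas from the pressures and slopes
        A_on = self.A_lift - (self.Pi_plateau - 0.0) / (-self.slope_le)  # Le->plateau corner
        A_pe = self.A_plateau_end
        Pi_pe = self.Pi_plateau + self.plateau_slope * (A_pe - A_on)
        A_k = A_pe - (self.Pi_kink - Pi_pe) / (-self.slope_lc)

        def seg(Aa):
            Pi = np.where(Aa >= self.A_lift, 0.0, self.slope_le * (Aa - self.A_lift))
            Pi = np.where(Aa < A_on, self.Pi_plateau + self.plateau_slope * (Aa - A_on), Pi)
            Pi = np.where(Aa < A_pe, Pi_pe + self.slope_lc * (Aa - A_pe), Pi)
            Pi = np.where(Aa < A_k, self.Pi_kink + self.slope_s * (Aa - A_k), Pi)
            return Pi

        if self.corner_width <= 0:
            return seg(A)
        # Gaussian smoothing of the piecewise curve in A
        w = self.corner_width
        xs = np.linspace(-3 * w, 3 * w, 13)
        ker = np.exp(-(xs**2) / (2 * (w / 2) ** 2))
        ker /= ker.sum()
        return np.sum(ker[:, None] * seg(A[None, :] + xs[:, None]), axis=0)


def gen_isotherm(
    model: IsothermPhaseModel | None = None,
    noise_Pi: float = 0.1,
    n_points: int = 600,
    seed: int = 0,
) -> tuple[Isotherm, dict]:
    """Synthetic compression isotherm with Gaussian pressure noise."""
    model = model or IsothermPhaseModel()
    rng = _rng(seed)
    A = np.linspace(model.A_min, model.A_lift + 10.0, n_points)
    Pi = model.curve(A)
    if noise_Pi > 0:
        Pi = Pi + rng.normal(0.0, noise_Pi, size=A.size)
    truth = {
        "Pi_plateau": model.Pi_plateau,
        "Pi_kink": model.Pi_kink,
        "slopes": {
            "le": model.slope_le,
            "plateau": model.plateau_slope,
            "lc": model.slope_lc,
            "s": model.slope_s,
        },
        "noise_Pi": noise_Pi,
        "seed": seed,
    }
    return Isotherm(A=A, Pi=Pi, T=19.5, label="synthetic"), truth


# ---------------------------------------------------------------------------
# chronocoulometry


def gen_chrono(
    C_film: float = 2.0,
    C_bare: float = 25.0,
    pzc_film: float = -0.2,
    pzc_bare: float = 0.09,
    R_cell: float = 10.0,
    E_grid: np.ndarray | None = None,
    E_des: float = -1.05,
    t_pulse: float = 0.15,
    n_samples: int = 600,
    noise_current: float = 0.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Capacitor-model chronocoulometry transients for film and bare states.

    Both electrodes are ideal capacitors, sigma(E) = C (E - pzc) with
    state-dependent C (uF/cm^2); at the desorption potential the film is
    desorbed, so both experiments relax to the bare state
    sigma_des = C_bare (E_des - pzc_bare).  Each step produces a single
    exponential transient I(t) = (Q_step / tau) exp(-t / tau) with
    tau = R_cell * C_bare, whose integral is the step charge.

    Returns ({"film": [...], "bare": [...]}, truth).
    """
    if C_film <= 0 or C_bare <= 0:
        raise ValueError("capacitances must be positive")
    if E_grid is None:
        E_grid = np.arange(-1.0, 0.401, 0.05)
    rng = _rng(seed)
    tau = R_cell * C_bare * 1e-6  # s (ohm cm^2 * F/cm^2)
    # geometric time grid: resolves the fast RC decay without an absurd
    # number of samples over the full 0.15 s pulse
    t = np.concatenate(([0.0], np.geomspace(tau / 200.0, t_pulse, n_samples - 1)))
    sigma_des = C_bare * (E_des - pzc_bare)

    def make(label, C, pzc):
        trs = []
        for E in E_grid:
            q_step = sigma_des - C * (E - pzc)  # uC/cm^2 flowing during the pulse
            scale = 1.0 - np.exp(-t_pulse / tau)  # truncation of the exponential
            current = (q_step / tau / scale) * np.exp(-t / tau)
            if noise_current > 0:
                current = current + rng.normal(0.0, noise_current, size=t.size)
            trs.append(ChronoTransient(E=float(E), t=t, current=current, E_des=E_des))
        return trs

    data = {"film": make("film", C_film, pzc_film), "bare": make("bare", C_bare, pzc_bare)}
    truth = {
        "C_film": C_film,
        "C_bare": C_bare,
        "pzc_film": pzc_film,
        "pzc_bare": pzc_bare,
        "sigma_des": sigma_des,
        "E_des": E_des,
        "tau": tau,
        "seed": seed,
        "sigma_film": {float(E): C_film * (E - pzc_film) for E in E_grid},
        "sigma_bare": {float(E): C_bare * (E - pzc_bare) for E in E_grid},
    }
    return data, truth


def film_pressure_parabola(C_film, C_bare, pzc_film, pzc_bare, E, E_des):
    """Closed-form film pressure for two capacitor states (mN/m)."""
    E = np.asarray(E, dtype=float)

    def anti(C, pzc, x):
        return 0.5 * C * (x - pzc) ** 2

    val = (anti(C_film, pzc_film, E) - anti(C_film, pzc_film, E_des)) - (
        anti(C_bare, pzc_bare, E) - anti(C_bare, pzc_bare, E_des)
    )
    return 10.0 * val


# ---------------------------------------------------------------------------
# IR


def gen_ir_spectrum(
    region: str = "CO",
    areas: dict | None = None,
    noise: float = 0.0005,
    seed: int = 0,
) -> tuple[IRSpectrum, dict]:
    """Multi-band synthetic PM-IRRAS envelope.

    ``region='CO'``: two carbonyl components (H-bonded ~1728, free ~1742
    cm^-1); ``region='CH'``: methylene/methyl stretches plus Fermi
    resonances.  ``areas`` overrides per-band integrated areas.
    """
    rng = _rng(seed)
    if region == "CO":
        bands = {"hbond-CO": (1728.0, 18.0), "free-CO": (1742.0, 14.0)}
        default_areas = {"hbond-CO": 0.6, "free-CO": 0.4}
        x = np.linspace(1680.0, 1790.0, 600)
    elif region == "CH":
        bands = {
            "sym": (2853.0, 8.5),
            "asym": (2923.0, 10.0),
            "ch3-sym": (2874.0, 9.0),
            "ch3-asym": (2962.0, 10.0),
            "fermi": (2898.0, 12.0),
        }
        default_areas = {"sym": 0.05, "asym": 0.08, "ch3-sym": 0.5, "ch3-asym": 0.7, "fermi": 0.15}
        x = np.linspace(2800.0, 3000.0, 900)
    else:
        raise ValueError("region must be 'CO' or 'CH'")
    areas = {**default_areas, **(areas or {})}
    y = np.zeros_like(x)
    for lab, (c, w) in bands.items():
        a = areas.get(lab, 0.0)
        sg = w / (2 * np.sqrt(2 * np.log(2)))
        g = np.exp(-((x - c) ** 2) / (2 * sg**2)) / (sg * np.sqrt(2 * np.pi))
        l = (w / 2) / (np.pi * ((x - c) ** 2 + (w / 2) ** 2))
        y = y + a * (0.7 * g + 0.3 * l)
    if noise > 0:
        y = y + rng.normal(0.0, noise, size=x.size)
    truth = {"areas": areas, "bands": bands, "noise": noise, "seed": seed}
    return IRSpectrum(wavenumber=x, signal=y, region=region), truth
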