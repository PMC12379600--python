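"""Grazing-incidence diffraction analysis of monolayer in-plane order.

Reduces gridded GIXD intensity maps I(q_xy, q_z) to Bragg peaks, indexes the
2D unit cell of the chain lattice (hexagonal, nearest-neighbour-tilt
distorted hexagonal, or oblique), and reports areas per chain / per pair of
chains, the collective chain tilt and the cross-sectional chain area.

Geometry
--------
The chain lattice is a 2D cell with real vectors a, b; reciprocal vectors
G_hk give in-plane peak positions q_xy = |G_hk| = 2 pi / d_hk.  Collective
tilt of the chains by angle t toward the in-plane unit vector u moves the
Bragg-rod maximum of reflection G out of the horizon:

    q_z(G) = tan(t) * (G . u)

so an untilted lattice has all peaks at q_z = 0, nearest-neighbour tilt
leaves the {1-1} reflection (G perpendicular to u) at q_z = 0 while the
degenerate {10},{01} pair moves up, and tilt between symmetry directions
splits all three reflections (oblique cell).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

import lmfit

__all__ = [
    "GIXDImage",
    "BraggPeak",
    "BraggPeakSet",
    "UnitCell2D",
    "NoPeaksError",
    "IndexingError",
    "reduce_to_bragg_peaks",
    "solve_unit_cell",
    "chain_areas_and_tilt",
    "excess_area",
]


class NoPeaksError(RuntimeError):
    """No Bragg peak above the detection threshold."""


class IndexingError(RuntimeError):
    """No 2D cell reproduces the observed peak positions within tolerance."""


@dataclass
class GIXDImage:
    """Gridded diffraction intensity I(q_xy, q_z) in counts."""

    q_xy: np.ndarray  # shape (nx,), 1/Angstrom
    q_z: np.ndarray  # shape (nz,), 1/Angstrom
    intensity: np.ndarray  # shape (nz, nx), counts

    def __post_init__(self):
        self.q_xy = np.asarray(self.q_xy, dtype=float)
        self.q_z = np.asarray(self.q_z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.q_z.size, self.q_xy.size):
            raise ValueError("intensity must have shape (len(q_z), len(q_xy))")
        if np.any(np.diff(self.q_xy) <= 0) or np.any(np.diff(self.q_z) <= 0):
            raise ValueError("axis grids must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")


@dataclass
class BraggPeak:
    q_xy: float
    q_z: float
    fwhm_xy: float
    intensity: float
    label: str = "unassigned"

    def __post_init__(self):
        if self.q_xy <= 0 or self.q_z < 0:
            raise ValueError("require q_xy > 0 and q_z >= 0")


@dataclass
class BraggPeakSet:
    peaks: list = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.q_xy)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class UnitCell2D:
    """Solved 2D chain lattice.

    Areas in Angstrom^2; A_pair = 2 * A_chain; the cross-section
    A_xs = A_chain * cos(t) is the area normal to the chain axis.  Tilt and
    azimuth in degrees; the azimuth is measured from the in-plane direction
    of G_10 and is only defined up to lattice symmetry.
    """

    cell_class: str  # "hexagonal" | "nn-tilt" | "oblique"
    d_spacings: dict
    A_chain: float
    tilt: float
    tilt_azimuth: float = 0.0
    G_vectors: dict | None = None
    residual: float = 0.0

    def __post_init__(self):
        if self.A_chain <= 0:
            raise ValueError("A_chain must be positive")
        if not 0.0 <= self.tilt < 90.0:
            raise ValueError("tilt must lie in [0, 90)")

    @property
    def A_pair(self) -> float:
        return 2.0 * self.A_chain

    @property
    def A_xs(self) -> float:
        return self.A_chain * np.cos(np.radians(self.tilt))


# ---------------------------------------------------------------------------
# peak reduction


def _pseudo_voigt(x, amplitude, center, sigma, fraction):
    """Area-normalised pseudo-Voigt (lmfit convention)."""
    sg = sigma / np.sqrt(2 * np.log(2))
    g = np.exp(-((x - center) ** 2) / (2 * sg**2)) / (sg * np.sqrt(2 * np.pi))
    l = sigma / (np.pi * ((x - center) ** 2 + sigma**2))
    return amplitude * ((1 - fraction) * g + fraction * l)


def reduce_to_bragg_peaks(
    image: GIXDImage,
    n_peaks: int | None = None,
    qz_range: tuple[float, float] | None = None,
    min_snr: float = 5.0,
) -> BraggPeakSet:
    """Reduce an intensity map to fitted Bragg peaks.

    The map is integrated over ``qz_range`` (default: full range) to give
    I(q_xy), which is fitted with ``n_peaks`` pseudo-Voigt profiles on a
    linear background; each peak's q_z position then comes from a Gaussian
    fit to the Bragg-rod slice integrated over +-3 FWHM around the fitted
    q_xy.  With ``n_peaks=None`` candidate peaks are found automatically.

    Raises ``NoPeaksError`` when nothing rises above ``min_snr`` standard
    deviations of the background.
    """
    qxy, qz, img = image.q_xy, image.q_z, image.intensity
    if qz_range is not None:
        sel = (qz >= qz_range[0]) & (qz <= qz_range[1])
        img_i = img[sel]
        qz_i = qz[sel]
    else:
        img_i, qz_i = img, qz
    profile = np.trapezoid(img_i, qz_i, axis=0)

    # candidate detection on a background-subtracted profile
    base = np.polyval(np.polyfit(qxy, profile, 1), qxy)
    resid = profile - base
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid))) or 1.0
    from scipy.signal import find_peaks

    idx, props = find_peaks(resid, height=min_snr * noise, distance=max(3, len(qxy) // 100))
    if len(idx) == 0:
        raise NoPeaksError(f"no peak above {min_snr} sigma of the background")
    order = np.argsort(props["peak_heights"])[::-1]
    idx = idx[order]
    if n_peaks is not None:
        idx = idx[:n_peaks]

    # composite pseudo-Voigt + linear background fit of I(q_xy)
    model = lmfit.models.LinearModel(prefix="bg_")
    params = model.make_params(bg_slope=0.0, bg_intercept=float(np.median(profile)))
    dq = qxy[1] - qxy[0]
    for j, i0 in enumerate(sorted(idx)):
        pv = lmfit.models.PseudoVoigtModel(prefix=f"p{j}_")
        model = model + pv
        params.update(pv.make_params())
        params[f"p{j}_center"].set(value=qxy[i0], min=qxy[0], max=qxy[-1])
        params[f"p{j}_sigma"].set(value=5 * dq, min=dq / 2, max=(qxy[-1] - qxy[0]))
        params[f"p{j}_amplitude"].set(value=max(resid[i0], noise) * 10 * dq, min=0)
        params[f"p{j}_fraction"].set(value=0.5, min=0, max=1)
    out = model.fit(profile, params, x=qxy)
    if not out.success:
        raise RuntimeError(f"Bragg peak fit failed: {out.message}")

    centers, fwhms, amps, windows = [], [], [], []
    for j in range(len(idx)):
        c = float(out.params[f"p{j}_center"].value)
        fwhm = float(out.params[f"p{j}_fwhm"].value)
        centers.append(c)
        fwhms.append(fwhm)
        amps.append(float(out.params[f"p{j}_amplitude"].value))
        half = max(3.0 * fwhm / 2, 2 * dq)
        windows.append((qxy >= c - half) & (qxy <= c + half))
    qz_centers = _fit_rods_jointly(image, out, len(idx), windows)
    peaks = [
        BraggPeak(q_xy=c, q_z=max(zc, 0.0), fwhm_xy=w, intensity=a)
        for c, w, a, zc in zip(centers, fwhms, amps, qz_centers)
    ]
    return BraggPeakSet(peaks)


def _fit_rods_jointly(image: GIXDImage, profile_fit, n_peaks: int, windows) -> list[float]:
    """Joint Bragg-rod fit deconvolving in-plane peak overlap.

    The rod slice for peak j contains leakage from every peak k in
    proportion to the integral of k's fitted in-plane profile over window j
    (a known number r_kj), so the slices are modelled together as

        rod_j(z) = sum_k a_k r_kj mg(z; c_k, s_k) + off_j

    with mirrored-Gaussian rods mg.  Centres/widths are the nonlinear
    parameters; amplitudes and offsets are projected out linearly.
    """
    from scipy.optimize import least_squares as _lsq

    qxy, qz, img = image.q_xy, image.q_z, image.intensity
    rods = [np.trapezoid(img[:, w], qxy[w], axis=1) for w in windows]
    # leakage matrix from the fitted in-plane components (background excluded)
    comps = profile_fit.eval_components(x=qxy)
    r = np.empty((n_peaks, n_peaks))
    for k in range(n_peaks):
        pk = comps[f"p{k}_"]
        for j, w in enumerate(windows):
            r[k, j] = np.trapezoid(pk[w], qxy[w])

    span = qz[-1] - qz[0]
    z0 = [float(abs(qz[int(np.argmax(rod))])) for rod in rods]
    s0 = [span / 8.0] * n_peaks

    def design(theta):
        c = theta[:n_peaks]
        s = np.exp(theta[n_peaks:])
        cols = []
        for k in range(n_peaks):
            mg = np.exp(-((qz - c[k]) ** 2) / (2 * s[k] ** 2)) + np.exp(
                -((qz + c[k]) ** 2) / (2 * s[k] ** 2)
            )
            cols.append(mg)
        # stacked design: rows = concatenated rods
        n = qz.size
        A = np.zeros((n * n_peaks, 2 * n_peaks))
        y = np.concatenate(rods)
        for j in range(n_peaks):
            for k in range(n_peaks):
                A[j * n:(j + 1) * n, k] = r[k, j] * cols[k]
            A[j * n:(j + 1) * n, n_peaks + j] = 1.0  # offset_j
        return A, y

    def resid(theta):
        A, y = design(theta)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return A @ coef - y

    theta0 = np.array(z0 + list(np.log(s0)))
    lo = np.array([0.0] * n_peaks + [np.log(span / 500)] * n_peaks)
    hi = np.array([qz[-1] + 0.2 * span] * n_peaks + [np.log(span)] * n_peaks)
    sol = _lsq(resid, np.clip(theta0, lo + 1e-9, hi - 1e-9), bounds=(lo, hi))
    return [abs(float(v)) for v in sol.x[:n_peaks]]


def _mirrored_gaussian(x, amplitude, center, sigma, offset):
    """Bragg-rod profile of a 2D powder: symmetric under q_z -> -q_z, so a
    Gaussian rod maximum at +-center contributes on both sides of the horizon."""
    g = np.exp(-((x - center) ** 2) / (2 * sigma**2)) + np.exp(-((x + center) ** 2) / (2 * sigma**2))
    return amplitude * g + offset


def _fit_rod_center(qz: np.ndarray, rod: np.ndarray) -> float:
    """Mirrored-Gaussian fit of a Bragg-rod slice; returns |q_z| of the maximum."""
    gm = lmfit.Model(_mirrored_gaussian)
    i0 = int(np.argmax(rod))
    span = qz[-1] - qz[0]
    pars = gm.make_params(
        center=dict(value=float(abs(qz[i0])), min=0.0, max=float(qz[-1]) + 0.1 * span),
        sigma=dict(value=span / 10, min=span / 500, max=span),
        amplitude=dict(value=float(rod.max() - rod.min()), min=0),
        offset=float(rod.min()),
    )
    out = gm.fit(rod, pars, x=qz)
    return abs(float(out.params["center"].value))


# ---------------------------------------------------------------------------
# unit-cell solution


def _hexagonal_cell(q: float) -> UnitCell2D:
    d = 2 * np.pi / q
    A = 2 * d**2 / np.sqrt(3.0)
    a = 2 * d / np.sqrt(3.0)
    G = 2 * np.pi / (a * np.sqrt(3) / 2)  # == q
    return UnitCell2D(
        cell_class="hexagonal",
        d_spacings={"10": d, "01": d, "1-1": d},
        A_chain=A,
        tilt=0.0,
        tilt_azimuth=0.0,
        G_vectors={
            "10": np.array([G * np.cos(np.pi / 6), G * np.sin(np.pi / 6)]),
            "01": np.array([G * np.cos(-np.pi / 6), G * np.sin(-np.pi / 6)]),
        },
    )


def _nn_tilt_cell(p_deg: BraggPeak, p_nd: BraggPeak, qz_tol: float) -> UnitCell2D:
    """Distorted-hexagonal cell from a degenerate {10,01} peak (q_z > 0) and
    an {1-1} peak at q_z = 0; tilt along the nearest-neighbour direction."""
    qd, qzd = p_deg.q_xy, p_deg.q_z
    qn = p_nd.q_xy
    gy = qn / 2.0
    gx_sq = qd**2 - gy**2
    if gx_sq <= 0:
        raise IndexingError(
            f"inconsistent 2-peak set: |G_1-1| = {qn:.4f} too large for |G_10| = {qd:.4f}"
        )
    gx = np.sqrt(gx_sq)
    t = float(np.degrees(np.arctan2(qzd, gx)))
    G10 = np.array([gx, gy])
    G01 = np.array([gx, -gy])
    A = (2 * np.pi) ** 2 / abs(G10[0] * G01[1] - G10[1] * G01[0])
    return UnitCell2D(
        cell_class="nn-tilt",
        d_spacings={"10": 2 * np.pi / qd, "01": 2 * np.pi / qd, "1-1": 2 * np.pi / qn},
        A_chain=A,
        tilt=t,
        tilt_azimuth=float(np.degrees(np.arctan2(-gy, gx))),  # from G10 to u = x
        G_vectors={"10": G10, "01": G01, "1-1": G01 - G10},
        residual=abs(p_nd.q_z),
    )


def _oblique_cell(peaks: list[BraggPeak], qz_tol: float) -> UnitCell2D:
    """Oblique cell from three reflections with closure G_1-1 = G_01 - G_10.

    The tilt direction is taken along +x.  Each reflection i has
    G_i = (u_i, y_i) with u_i = s_i * q_z,i / tan(t); the in-plane magnitudes
    and the reciprocal-triangle closure determine tan(t) by a 1D root search
    over label permutations and sign choices.
    """
    best = None
    qxy = [p.q_xy for p in peaks]
    qzv = [p.q_z for p in peaks]

    for perm in itertools.permutations(range(3)):
        i1, i2, i3 = perm  # roles: G1={10}, G2={01}, G3={1-1}=G2-G1
        q1, q2, q3 = qxy[i1], qxy[i2], qxy[i3]
        z1, z2, z3 = qzv[i1], qzv[i2], qzv[i3]
        for s1, s2 in itertools.product((1, -1), repeat=2):
            # closure along the tilt axis: s3*z3 = s2*z2 - s1*z1
            u3s = s2 * z2 - s1 * z1
            if abs(abs(u3s) - z3) > max(qz_tol, 0.05 * max(z3, 1e-9)) and z3 > qz_tol:
                continue
            for e1, e2 in itertools.product((1, -1), repeat=2):

                def closure(tant, _s1=s1, _s2=s2, _e1=e1, _e2=e2, _q=(q1, q2, q3), _z=(z1, z2, z3)):
                    u1 = _s1 * _z[0] / tant
                    u2 = _s2 * _z[1] / tant
                    y1sq = _q[0] ** 2 - u1**2
                    y2sq = _q[1] ** 2 - u2**2
                    if y1sq < 0 or y2sq < 0:
                        return np.nan
                    y1 = _e1 * np.sqrt(y1sq)
                    y2 = _e2 * np.sqrt(y2sq)
                    return (u2 - u1) ** 2 + (y2 - y1) ** 2 - _q[2] ** 2

                # bracket tan(t) in (tan 0.05deg, tan 89deg)
                lo = max(z1 / q1 if z1 else 0, z2 / q2 if z2 else 0) + 1e-12
                ts = np.geomspace(max(lo, 1e-4), 60.0, 400)
                vals = np.array([closure(t) for t in ts])
                ok = np.isfinite(vals)
                ts, vals = ts[ok], vals[ok]
                for a, b, fa, fb in zip(ts[:-1], ts[1:], vals[:-1], vals[1:]):
                    if fa == 0 or fa * fb < 0:
                        tant = brentq(closure, a, b, xtol=1e-14, rtol=1e-15)
                        u1, u2 = s1 * z1 / tant, s2 * z2 / tant
                        y1 = e1 * np.sqrt(max(q1**2 - u1**2, 0))
                        y2 = e2 * np.sqrt(max(q2**2 - u2**2, 0))
                        G1, G2 = np.array([u1, y1]), np.array([u2, y2])
                        G3 = G2 - G1
                        cross = abs(G1[0] * G2[1] - G1[1] * G2[0])
                        if cross < 1e-12:
                            continue
                        res = abs(np.hypot(*G3) - q3) + abs(abs(tant * G3[0]) - z3)
                        cand = (res, tant, G1, G2, (q1, q2, q3))
                        if best is None or res < best[0]:
                            best = cand
    if best is None:
        raise IndexingError("no oblique cell reproduces the three peak positions")
    res, tant, G1, G2, (q1, q2, q3) = best
    scale = max(q1, q2, q3)
    if res > 50 * max(qz_tol, 1e-9) + 1e-3 * scale:
        raise IndexingError(f"oblique indexing residual {res:.3e} exceeds tolerance")
    A = (2 * np.pi) ** 2 / abs(G1[0] * G2[1] - G1[1] * G2[0])
    t = float(np.degrees(np.arctan(tant)))
    return UnitCell2D(
        cell_class="oblique",
        d_spacings={"10": 2 * np.pi / q1, "01": 2 * np.pi / q2, "1-1": 2 * np.pi / q3},
        A_chain=A,
        tilt=t,
        tilt_azimuth=float(np.degrees(np.arctan2(-G1[1], G1[0]))),
        G_vectors={"10": G1, "01": G2, "1-1": G2 - G1},
        residual=float(res),
    )


def solve_unit_cell(peak_set: BraggPeakSet, qz_tol: float = 0.05, q_tol: float = 0.005) -> UnitCell2D:
    """Index 1-3 Bragg peaks as a 2D chain lattice.

    * one peak at q_z ~ 0: untilted hexagonal close packing;
    * two peaks (degenerate {10,01} off the horizon, {1-1} at q_z = 0):
      nearest-neighbour-tilt distorted hexagonal cell — the peak with the
      smaller |q_z| is taken as {1-1};
    * three peaks: oblique cell, tilt between symmetry directions.
    """
    peaks = list(peak_set)
    if not 1 <= len(peaks) <= 3:
        raise IndexingError(f"can index 1-3 peaks, got {len(peaks)}")
    if len(peaks) == 1:
        p = peaks[0]
        if p.q_z > qz_tol:
            raise IndexingError(
                f"single peak at q_z = {p.q_z:.3f} cannot be indexed as an untilted cell"
            )
        return _hexagonal_cell(p.q_xy)
    if len(peaks) == 2:
        p_nd = min(peaks, key=lambda p: abs(p.q_z))
        p_deg = max(peaks, key=lambda p: abs(p.q_z))
        if p_deg.q_z <= qz_tol:  # all peaks on the horizon: degenerate hexagonal split
            cell = _nn_tilt_cell(BraggPeak(p_deg.q_xy, 0.0, p_deg.fwhm_xy, p_deg.intensity), p_nd, qz_tol)
            return UnitCell2D(
                cell_class="nn-tilt",
                d_spacings=cell.d_spacings,
                A_chain=cell.A_chain,
                tilt=0.0,
                tilt_azimuth=cell.tilt_azimuth,
                G_vectors=cell.G_vectors,
            )
        return _nn_tilt_cell(p_deg, p_nd, qz_tol)
    # three peaks
    if all(p.q_z <= qz_tol for p in peaks):
        qs = [p.q_xy for p in peaks]
        if np.ptp(qs) <= q_tol * np.mean(qs):
            return _hexagonal_cell(float(np.mean(qs)))
        zeroed = [BraggPeak(p.q_xy, 0.0, p.fwhm_xy, p.intensity) for p in peaks]
        return _oblique_untilted(zeroed, q_tol)
    return _oblique_cell(peaks, qz_tol)


def _oblique_untilted(peaks: list[BraggPeak], q_tol: float) -> UnitCell2D:
    """Three in-horizon reflections: untilted oblique lattice via triangle closure."""
    for perm in itertools.permutations(range(3)):
        q1, q2, q3 = (peaks[i].q_xy for i in perm)
        # law of cosines: angle between G1 and G2 such that |G2-G1| = q3
        c = (q1**2 + q2**2 - q3**2) / (2 * q1 * q2)
        if abs(c) <= 1:
            G1 = np.array([q1, 0.0])
            G2 = np.array([q2 * c, q2 * np.sqrt(1 - c**2)])
            cross = abs(G1[0] * G2[1] - G1[1] * G2[0])
            if cross < 1e-12:
                continue
            A = (2 * np.pi) ** 2 / cross
            return UnitCell2D(
                cell_class="oblique",
                d_spacings={"10": 2 * np.pi / q1, "01": 2 * np.pi / q2, "1-1": 2 * np.pi / q3},
                A_chain=A,
                tilt=0.0,
                G_vectors={"10": G1, "01": G2, "1-1": G2 - G1},
            )
    raise IndexingError("three in-plane peaks violate the reciprocal triangle closure")


def chain_areas_and_tilt(cell: UnitCell2D) -> tuple[float, float, float, float]:
    """(A_chain, A_pair, A_xs, tilt) of a solved cell."""
    return cell.A_chain, cell.A_pair, cell.A_xs, cell.tilt


def excess_area(
    area_mix: float,
    component_areas: list[float],
    fractions: list[float],
    n_chains: list[int] | None = None,
    basis: str = "molecules",
) -> float:
    """Excess mixing area A_mix - sum_i x_i A_i.

    With ``basis='chains'`` the mole fractions are first converted to chain
    fractions using ``n_chains`` (a four-chain cardiolipin counts 4), which
    is the natural basis when the component areas are per chain.
    """
    x = np.asarray(fractions, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    a = np.asarray(component_areas, dtype=float)
    if basis == "chains":
        if n_chains is None:
            raise ValueError("basis='chains' requires n_chains")
        w = x * np.asarray(n_chains, dtype=float)
        x = w / w.sum()
    elif basis != "molecules":
        raise ValueError("basis must be 'molecules' or 'chains'")
    return float(area_mix - np.dot(x, a))
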