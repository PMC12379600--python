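"""Surface pressure - area isotherm analysis.

Provides the lateral compressibility modulus

    Cs^-1 = -A_M * (dPi / dA_M)   at fixed molecule count and temperature,

and extraction of the two phase-transition pressures of myristoyl-lipid
monolayers: the onset of the liquid-expanded -> liquid-condensed (Le-Lc)
coexistence plateau and the kink of the second-order Lc -> solid (Lc-S)
transition.  A stiffer monolayer has a higher Cs^-1; a first-order plateau
drives Cs^-1 toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Isotherm",
    "TransitionSet",
    "compressibility_modulus",
    "detect_transitions",
]


@dataclass
class Isotherm:
    """Pi(A) compression isotherm.

    A in Angstrom^2 per molecule, Pi in mN/m, temperature in Celsius.
    Stored sorted by increasing area; cleaning drops barrier-reversal points
    so that A is strictly monotone.
    """

    A: np.ndarray
    Pi: np.ndarray
    T: float = 19.5
    label: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        Pi = np.asarray(self.Pi, dtype=float)
        if A.shape != Pi.shape or A.ndim != 1:
            raise ValueError("A and Pi must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(Pi))):
            raise ValueError("A and Pi must be finite")
        order = np.argsort(A)
        A, Pi = A[order], Pi[order]
        keep = np.concatenate(([True], np.diff(A) > 0))
        self.A, self.Pi = A[keep], Pi[keep]

    def __len__(self):
        return len(self.A)


@dataclass
class TransitionSet:
    """Extracted phase-transition pressures (mN/m) and the areas where they
    occur; a feature that is absent from the isotherm stays None."""

    Pi_LeLc_onset: float | None = None
    A_LeLc_onset: float | None = None
    Pi_LcS: float | None = None
    A_LcS: float | None = None

    def __post_init__(self):
        if self.Pi_LeLc_onset is not None and self.Pi_LcS is not None:
            if not self.Pi_LeLc_onset < self.Pi_LcS:
                raise ValueError("Le-Lc onset must lie below the Lc-S kink")


def _smoothed(y: np.ndarray, window: int, order: int = 3) -> np.ndarray:
    if window and window >= order + 2 and len(y) >= window:
        w = window if window % 2 else window + 1
        return savgol_filter(y, w, order)
    return y


def _uniform(iso: Isotherm, n: int | None = None):
    """Resample onto a uniform area grid (derivative filters assume one)."""
    n = n or len(iso)
    A = np.linspace(iso.A[0], iso.A[-1], n)
    return A, np.interp(A, iso.A, iso.Pi)


def compressibility_modulus(iso: Isotherm, smoothing_window: int = 9) -> np.ndarray:
    """Cs^-1 = -A dPi/dA evaluated at the isotherm's own area points.

    Pi(A) is optionally smoothed with a local cubic (Savitzky-Golay) filter
    on a uniform resampling of the area axis before centred differencing;
    ``smoothing_window=0`` differentiates the raw data.
    """
    if len(iso) < 5:
        raise ValueError("need at least 5 isotherm points")
    if np.any(np.diff(iso.A) <= 0):
        raise ValueError("area must be strictly monotone after cleaning")
    Au, Piu = _uniform(iso)
    Piu = _smoothed(Piu, smoothing_window)
    dPi_dA = np.gradient(Piu, Au)
    cs = -Au * dPi_dA
    return np.interp(iso.A, Au, cs)


def detect_transitions(
    iso: Isotherm,
    smoothing_window: int = 9,
    plateau_modulus: float = 15.0,
    kink_slope_ratio: float = 1.4,
) -> TransitionSet:
    """Locate the Le-Lc onset and the Lc-S kink of a compression isotherm.

    Le-Lc onset: intersection of tangents fitted to the liquid-expanded
    branch and to the coexistence plateau, where the plateau is the
    low-compressibility region (Cs^-1 below ``plateau_modulus`` mN/m)
    bracketed by stiffer branches.  Lc-S kink: extremum of the second
    derivative of Pi(A) between the plateau and full compression, accepted
    only when the slope steepens by at least ``kink_slope_ratio``.

    Both criteria are invariant to a uniform rescaling of the area axis.
    Features that are absent are reported as None, never fabricated.
    """
    out = TransitionSet()
    if len(iso) < 9:
        return out
    n = max(len(iso), 200)
    A, Pi = _uniform(iso, n)
    Pis = _smoothed(Pi, max(smoothing_window, 2 * (n // 40) + 1))
    dPi = np.gradient(Pis, A)
    cs = -A * dPi

    # --- plateau between two stiffer branches -------------------------------
    # median-filter the modulus so isolated noise spikes neither break the
    # plateau nor fake a stiff branch
    from scipy.ndimage import median_filter

    csf = median_filter(cs, size=max(5, n // 40), mode="nearest")
    low = csf < plateau_modulus
    runs = [r for r in _runs(low) if r[1] - r[0] >= n // 50]
    plateau = None
    w = max(n // 20, 10)

    def _stiff(segment):
        # a branch is stiff only if it is *sustained*: enough points whose
        # median modulus exceeds the plateau threshold
        return segment.size >= w // 2 and np.median(segment) > plateau_modulus

    for i0, i1 in runs:
        left_stiff = _stiff(csf[max(0, i0 - w):i0])
        right_stiff = _stiff(csf[i1:i1 + w])
        if left_stiff and right_stiff:
            if plateau is None or (i1 - i0) > (plateau[1] - plateau[0]):
                plateau = (i0, i1)  # keep the longest such run
    if plateau is not None:
        i0, i1 = plateau
        # tangent to the plateau
        c_p = np.polyfit(A[i0:i1], Pis[i0:i1], 1)
        # tangent to the Le branch: the stretch at larger area, after the
        # compressibility recovers
        j0 = i1 + int(np.argmax(csf[i1:] > plateau_modulus))
        j1 = min(n, j0 + max(n // 10, 5))
        c_e = np.polyfit(A[j0:j1], Pis[j0:j1], 1)
        if abs(c_e[0] - c_p[0]) > 1e-12:
            A_star = (c_p[1] - c_e[1]) / (c_e[0] - c_p[0])
            Pi_star = np.polyval(c_p, A_star)
            if A[0] < A_star < A[-1]:
                out.Pi_LeLc_onset = float(Pi_star)
                out.A_LeLc_onset = float(A_star)

    # --- Lc-S kink below the plateau -----------------------------------------
    # A slope discontinuity between the two condensed branches: located by a
    # two-segment broken-line fit of Pi(A) over the condensed region, accepted
    # only when the solid branch is at least ``kink_slope_ratio`` steeper.
    if plateau is None:
        return out  # single-branch isotherm: no transitions reported
    hi = plateau[0]
    if hi > n // 10:
        As, Ps = A[:hi], Pi[:hi]
        m = len(As)
        margin = max(4, m // 12)
        best = None
        for k in range(margin, m - margin):
            c1 = np.polyfit(As[:k + 1], Ps[:k + 1], 1)
            c2 = np.polyfit(As[k:], Ps[k:], 1)
            sse = (np.sum((np.polyval(c1, As[:k + 1]) - Ps[:k + 1]) ** 2)
                   + np.sum((np.polyval(c2, As[k:]) - Ps[k:]) ** 2))
            if best is None or sse < best[0]:
                best = (sse, c1, c2)
        if best is not None:
            _, c1, c2 = best
            if abs(c2[0]) > 1e-12 and abs(c1[0]) >= kink_slope_ratio * abs(c2[0]):
                A_k = (c2[1] - c1[1]) / (c1[0] - c2[0])
                Pi_k = float(np.polyval(c1, A_k))
                if As[0] <= A_k <= As[-1] and (out.Pi_LeLc_onset is None or Pi_k > out.Pi_LeLc_onset):
                    out.Pi_LcS = Pi_k
                    out.A_LcS = float(A_k)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))
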