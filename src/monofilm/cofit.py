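"""Grid-scan multi-contrast co-refinement of two-slab monolayer models.

Reflectometry of a thin film cannot determine roughness, tail volume,
thicknesses and solvation all at once from a single curve, so the fitting
procedure is a grid scan: for each fixed (roughness sigma, tail volume
V_tail) pair, the free parameters — tail and headgroup thicknesses, the
headgroup solvent fraction and a per-dataset intensity scale — are refined
by weighted least squares *jointly* across all contrasts, sharing the
structural parameters.  Model selection then balances the goodness of fit
against the closeness of the implied molecular area A_M = V_tail/d_tail to
an independent reference area (from diffraction or from the isotherm):
among all grid points within a relative chi-square band of the best fit,
the one with A_M closest to the reference wins.

Confidence ranges are obtained by chi-square profiling (delta chi2 = 3.84
for 95%, one parameter), re-optimising the remaining free parameters at
each profile point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2 as chi2_dist

from .monolayer import ContrastSpec, MonolayerParams, build_stack, derive_structure, WATER_VOLUME
from .reflectivity import ReflectivityCurve, critical_q, smeared_reflectivity

__all__ = [
    "FitResult",
    "ConfidenceRange",
    "cofit_grid",
    "cofit_single",
    "confidence_ranges",
    "select_best_model",
]

DEFAULT_SIGMA_GRID = np.arange(3.0, 4.51, 0.1)
DEFAULT_VTAIL_GRID = np.arange(650.0, 685.1, 2.5)

_BOUNDS = {"d_tail": (10.0, 25.0), "d_hg": (3.0, 15.0), "f": (0.0, 0.95), "scale": (0.7, 1.3)}


@dataclass
class FitResult:
    """One converged (or flagged) grid-point fit."""

    params: MonolayerParams
    scales: np.ndarray
    chi2: float
    redchi: float
    n_points: int
    n_free: int
    grid_point: tuple  # (sigma, V_tail)
    per_dataset_chi2: list
    derived: object = None
    converged: bool = True
    message: str = ""

    @property
    def A_M(self) -> float:
        return self.params.A_M


@dataclass(frozen=True)
class ConfidenceRange:
    parameter: str
    best: float
    low: float
    high: float
    level: float = 0.95
    open_low: bool = False
    open_high: bool = False

    def __post_init__(self):
        if not (self.low <= self.best <= self.high):
            raise ValueError("require low <= best <= high")


@dataclass
class _Problem:
    datasets: list
    contrasts: list
    template: MonolayerParams
    dq_over_q: float
    V_water: float

    def masked(self, truncate_below_qc: bool):
        """Per-dataset (q, R, dR, dq) with the total-reflection region of
        high-SLD subphases removed (normalisation region)."""
        out = []
        for curve, contrast in zip(self.datasets, self.contrasts):
            from .monolayer import subphase_sld

            qc = critical_q(subphase_sld(contrast, self.V_water))
            keep = curve.q > (qc * 1.05 if truncate_below_qc and qc > 0 else 0.0)
            dR = curve.dR if curve.dR is not None else np.maximum(0.03 * curve.R, 1e-12)
            out.append((curve.q[keep], curve.R[keep], dR[keep], None if curve.dq is None else curve.dq[keep]))
        return out

    def residuals(self, x: np.ndarray, sigma: float, V_tail: float, data) -> np.ndarray:
        d_tail, d_hg, f = x[0], x[1], x[2]
        scales = x[3:]
        params = replace(
            self.template,
            V_tail=V_tail,
            sigma=sigma,
            d_tail=d_tail,
            d_hg=d_hg,
            headgroup_solvent_fraction=f,
            V_hg_material=None,
        )
        res = []
        for (q, R, dR, dq), contrast, s in zip(data, self.contrasts, scales):
            stack = build_stack(params, contrast, self.V_water)
            if dq is not None:
                model = smeared_reflectivity(stack, q, dq=dq)
            else:
                model = smeared_reflectivity(stack, q, self.dq_over_q)
            res.append((s * model.R - R) / dR)
        return np.concatenate(res)


def _fit_at_grid_point(
    prob: _Problem,
    data,
    sigma: float,
    V_tail: float,
    n_starts: int,
    seed: int,
    max_nfev: int | None = None,
) -> FitResult:
    nds = len(prob.datasets)
    lo = np.array([_BOUNDS["d_tail"][0], _BOUNDS["d_hg"][0], _BOUNDS["f"][0]] + [_BOUNDS["scale"][0]] * nds)
    hi = np.array([_BOUNDS["d_tail"][1], _BOUNDS["d_hg"][1], _BOUNDS["f"][1]] + [_BOUNDS["scale"][1]] * nds)
    rng = np.random.default_rng(seed)
    starts = [np.array([prob.template.d_tail, prob.template.d_hg,
                        prob.template.headgroup_solvent_fraction] + [1.0] * nds)]
    for _ in range(max(0, n_starts - 1)):
        x0 = starts[0].copy()
        x0[0] = rng.uniform(14.0, 19.0)
        x0[1] = rng.uniform(5.0, 10.0)
        x0[2] = rng.uniform(0.0, 0.6)
        starts.append(x0)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                prob.residuals, x0, bounds=(lo, hi), args=(sigma, V_tail, data),
                x_scale=[1.0, 1.0, 0.1] + [0.05] * nds, max_nfev=max_nfev,
            )
        except Exception as e:  # optimiser failure at a grid point is flagged, not fatal
            if best is None:
                best = ("fail", str(e))
            continue
        if best is None or best[0] == "fail" or sol.cost < best[1].cost:
            best = ("ok", sol)
    if best is None or best[0] == "fail":
        params = replace(prob.template, sigma=sigma, V_tail=V_tail)
        return FitResult(
            params=params, scales=np.ones(nds), chi2=np.inf, redchi=np.inf,
            n_points=sum(len(d[0]) for d in data), n_free=3 + nds,
            grid_point=(sigma, V_tail), per_dataset_chi2=[], converged=False,
            message=best[1] if best else "no start converged",
        )
    sol = best[1]
    x = sol.x
    params = replace(
        prob.template, V_tail=V_tail, sigma=sigma, d_tail=x[0], d_hg=x[1],
        headgroup_solvent_fraction=x[2], V_hg_material=None,
    )
    chi2 = float(2 * sol.cost)
    npts = sum(len(d[0]) for d in data)
    nfree = 3 + nds
    per_ds = []
    off = 0
    for d in data:
        m = len(d[0])
        per_ds.append(float(np.sum(sol.fun[off:off + m] ** 2)))
        off += m
    # derived structure from the first contrast's headgroup slab SLD
    stack = build_stack(params, prob.contrasts[0], prob.V_water)
    derived = derive_structure(params, stack.slabs[1].sld.real if hasattr(stack.slabs[1].sld, "real") else stack.slabs[1].sld, prob.contrasts[0], prob.V_water)
    return FitResult(
        params=params, scales=x[3:].copy(), chi2=chi2,
        redchi=chi2 / max(npts - nfree, 1), n_points=npts, n_free=nfree,
        grid_point=(float(sigma), float(V_tail)), per_dataset_chi2=per_ds,
        derived=derived, converged=bool(sol.success), message=sol.message,
    )


def cofit_grid(
    datasets: list[ReflectivityCurve],
    template: MonolayerParams,
    contrasts: list[ContrastSpec],
    sigma_grid=None,
    vtail_grid=None,
    dq_over_q: float = 0.07,
    truncate_below_qc: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    V_water: float = WATER_VOLUME,
) -> list[FitResult]:
    """Joint refinement over a (sigma, V_tail) grid.

    Returns every grid point's FitResult sorted by chi-square (failed grid
    points sort last, flagged ``converged=False``).
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    if len(datasets) != len(contrasts):
        raise ValueError("one contrast per dataset required")
    sigma_grid = DEFAULT_SIGMA_GRID if sigma_grid is None else np.atleast_1d(sigma_grid)
    vtail_grid = DEFAULT_VTAIL_GRID if vtail_grid is None else np.atleast_1d(vtail_grid)
    if sigma_grid.size == 0 or vtail_grid.size == 0:
        raise ValueError("grids must be non-empty")
    prob = _Problem(datasets, contrasts, template, dq_over_q, V_water)
    data = prob.masked(truncate_below_qc)
    results = []
    for sg in sigma_grid:
        for vt in vtail_grid:
            results.append(_fit_at_grid_point(prob, data, float(sg), float(vt), n_starts, seed))
    return sorted(results, key=lambda r: r.chi2)


def cofit_single(datasets, template, contrasts, sigma, V_tail, **kw) -> FitResult:
    """One grid point only."""
    return cofit_grid(datasets, template, contrasts, sigma_grid=[sigma], vtail_grid=[V_tail], **kw)[0]


# ---------------------------------------------------------------------------
# confidence ranges by chi-square profiling

_PROFILE_PARS = {"d_tail": 0, "d_hg": 1, "f": 2}


def profile_chi2(objective, x_best, index, bounds, delta: float, span_rel: float = 0.25, n_scan: int = 12):
    """Generic delta-chi-square profile of one coordinate of a least-squares
    objective (callable -> residual vector), re-optimising the others.

    Returns (low, high, open_low, open_high) where the bounds are the
    crossings of chi2_min + delta.
    """
    lo_b, hi_b = bounds
    x_best = np.asarray(x_best, dtype=float)
    chi2_min = float(np.sum(objective(x_best) ** 2))
    free = [i for i in range(x_best.size) if i != index]

    def chi2_at(v):
        if not free:
            x = x_best.copy()
            x[index] = v
            return float(np.sum(objective(x) ** 2))
        x0 = x_best[free]

        def part(xf):
            x = x_best.copy()
            x[free] = xf
            x[index] = v
            return objective(x)

        sol = least_squares(part, np.clip(x0, lo_b[free] + 1e-12, hi_b[free] - 1e-12),
                            bounds=(lo_b[free], hi_b[free]))
        return float(2 * sol.cost)

    def crossing(direction):
        b_edge = hi_b[index] if direction > 0 else lo_b[index]
        span = span_rel * max(abs(x_best[index]), 1.0)
        vs = x_best[index] + direction * np.linspace(0, 1, n_scan + 1)[1:] ** 1.5 * span
        vs = np.clip(vs, lo_b[index], hi_b[index])
        prev_v, prev_c = x_best[index], chi2_min
        for v in vs:
            c = chi2_at(v)
            if c >= chi2_min + delta:
                f = lambda u: chi2_at(u) - (chi2_min + delta)
                a, b = sorted((prev_v, v))
                try:
                    return brentq(f, a, b, xtol=1e-6 * max(abs(v), 1.0)), False
                except ValueError:
                    return v, False
            prev_v, prev_c = v, c
            if v == b_edge:
                break
        return prev_v, True  # never crossed inside the window: open-ended

    low, open_low = crossing(-1)
    high, open_high = crossing(+1)
    return low, high, open_low, open_high


def confidence_ranges(
    result: FitResult,
    datasets,
    contrasts,
    level: float = 0.95,
    parameters=("d_tail", "d_hg", "f"),
    dq_over_q: float = 0.07,
    truncate_below_qc: bool = True,
    V_water: float = WATER_VOLUME,
) -> list[ConfidenceRange]:
    """Profile-likelihood confidence ranges for the free structural
    parameters of a converged grid-point fit (delta chi2 = 3.84 at 95%)."""
    if not result.converged:
        raise ValueError("confidence ranges require a converged fit")
    delta = float(chi2_dist.ppf(level, 1))
    prob = _Problem(datasets, contrasts, result.params, dq_over_q, V_water)
    data = prob.masked(truncate_below_qc)
    sigma, V_tail = result.grid_point
    x_best = np.concatenate((
        [result.params.d_tail, result.params.d_hg, result.params.headgroup_solvent_fraction],
        result.scales,
    ))
    nds = len(datasets)
    lo = np.array([_BOUNDS["d_tail"][0], _BOUNDS["d_hg"][0], _BOUNDS["f"][0]] + [_BOUNDS["scale"][0]] * nds)
    hi = np.array([_BOUNDS["d_tail"][1], _BOUNDS["d_hg"][1], _BOUNDS["f"][1]] + [_BOUNDS["scale"][1]] * nds)

    def objective(x):
        return prob.residuals(x, sigma, V_tail, data)

    out = []
    for name in parameters:
        idx = _PROFILE_PARS[name]
        low, high, ol, oh = profile_chi2(objective, x_best, idx, (lo, hi), delta)
        best = x_best[idx]
        out.append(ConfidenceRange(
            parameter=name, best=float(best),
            low=float(min(low, best)), high=float(max(high, best)),
            level=level, open_low=ol, open_high=oh,
        ))
    return out


def select_best_model(
    results: list[FitResult],
    reference_area: float,
    chi2_rel_tol: float = 0.02,
) -> FitResult:
    """GIXD/isotherm-aware model selection.

    Among converged results whose chi-square lies within ``1 + chi2_rel_tol``
    of the minimum, return the one whose molecular area is closest to
    ``reference_area``.  Both criteria are reported on the result
    (``selection_note`` attribute).
    """
    ok = [r for r in results if r.converged and np.isfinite(r.chi2)]
    if not ok:
        raise ValueError("no converged fit results to select from")
    chi2_min = min(r.chi2 for r in ok)
    band = [r for r in ok if r.chi2 <= (1.0 + chi2_rel_tol) * chi2_min]
    best = min(band, key=lambda r: abs(r.A_M - reference_area))
    best.message = (
        f"selected: chi2 = {best.chi2:.4g} (min {chi2_min:.4g}, band {chi2_rel_tol:.0%}); "
        f"|A_M - ref| = {abs(best.A_M - reference_area):.3f} A^2"
    )
    return best
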