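"""Two-slab lipid-monolayer model and derived structural quantities.

A floating monolayer is modelled as air | tail slab | headgroup slab |
subphase.  The tail slab contains only the hydrocarbon chains; the glycerol
backbone, carbonyls, phosphate and polar group live in the headgroup slab,
which is partly solvated by subphase water.  From a fitted model the
molecular area A_M = V_tail/d_tail, the unsolvated headgroup volume V_hg and
the number of hydration waters n_w per lipid follow by volume balance:

    A_M * d_hg = V_hg + n_w * V_water
    rho_slab   = (b_hg + n_w * b_water) / (A_M * d_hg)

All per-molecule quantities are normalised *per pair of chains*, so a
four-chain cardiolipin contributes two pairs and stays comparable with
two-chain lipids.

Neutron contrasts support tail deuteration and explicit H/D exchange
scenarios: an exchange scenario states, per lipid, how many labile headgroup
hydrogens take the subphase deuterium fraction (1.0 in D2O, 0.08 in ACMW).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .reflectivity import Slab, SlabStack

__all__ = [
    "LipidComponent",
    "ContrastSpec",
    "MonolayerParams",
    "DerivedStructure",
    "load_lipid",
    "make_composition",
    "contrast_slds",
    "build_stack",
    "derive_structure",
    "WATER_VOLUME",
]

# Coherent neutron scattering lengths, fm (Sears tables), and atomic numbers.
NEUTRON_B_FM = {"H": -3.7390, "D": 6.671, "C": 6.6460, "N": 9.36, "O": 5.803, "P": 5.13, "Na": 3.63}
ELECTRONS = {"H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15, "Na": 11}

R_E = 2.818e-5  # classical electron radius, Angstrom
FM_TO_ANG = 1e-5  # 1 fm in Angstrom

WATER_VOLUME = 30.0  # Angstrom^3 per molecule at 19.5 C; configurable per call

_B_H2O = 2 * NEUTRON_B_FM["H"] + NEUTRON_B_FM["O"]  # fm
_B_D2O = 2 * NEUTRON_B_FM["D"] + NEUTRON_B_FM["O"]
ACMW_D2O_FRACTION = 0.08  # volume fraction of D2O in air-contrast-matched water


def _sum_b(formula: dict[str, float]) -> float:
    """Total coherent neutron scattering length of a formula, in Angstrom."""
    try:
        return sum(n * NEUTRON_B_FM[el] for el, n in formula.items()) * FM_TO_ANG
    except KeyError as e:  # pragma: no cover - exercised via contrast_slds
        raise ValueError(f"unknown element in formula: {e.args[0]}") from None


def _sum_electrons(formula: dict[str, float]) -> float:
    try:
        return sum(n * ELECTRONS[el] for el, n in formula.items())
    except KeyError as e:
        raise ValueError(f"unknown element in formula: {e.args[0]}") from None


@dataclass(frozen=True)
class LipidComponent:
    """One lipid species in a composition."""

    name: str
    n_chains: int
    mole_fraction: float
    tail_formula: dict = field(default_factory=dict)
    headgroup_formula: dict = field(default_factory=dict)
    n_exchangeable_H: int = 0
    tails_deuterated: bool = False

    def __post_init__(self):
        if self.n_chains not in (2, 4):
            raise ValueError("n_chains must be 2 or 4")
        if not 0.0 <= self.mole_fraction <= 1.0:
            raise ValueError("mole_fraction must lie in [0, 1]")

    @property
    def pairs(self) -> int:
        return self.n_chains // 2


@dataclass(frozen=True)
class ContrastSpec:
    """Radiation and subphase defining one measured contrast.

    ``exchange_scenario`` maps lipid name -> number of labile headgroup
    hydrogens exchanged with the subphase (required whenever the subphase
    carries deuterium); it is never defaulted silently.
    """

    radiation: str = "xray"  # "xray" | "neutron"
    subphase: str = "water"  # "water" | "D2O" | "ACMW"
    photon_energy_keV: float = 12.5
    exchange_scenario: dict | None = None
    label: str = ""

    def __post_init__(self):
        if self.radiation not in ("xray", "neutron"):
            raise ValueError("radiation must be 'xray' or 'neutron'")
        if self.subphase not in ("water", "D2O", "ACMW"):
            raise ValueError("subphase must be 'water', 'D2O' or 'ACMW'")
        if self.radiation == "xray" and self.subphase != "water":
            raise ValueError("D2O/ACMW subphases are neutron contrasts")

    @property
    def d_fraction(self) -> float:
        """Deuterium fraction of exchangeable sites set by the subphase."""
        return {"water": 0.0, "D2O": 1.0, "ACMW": ACMW_D2O_FRACTION}[self.subphase]


@dataclass
class MonolayerParams:
    """Two-slab monolayer parameterisation.

    ``V_tail`` is the tail volume per pair of chains (held fixed during a
    fit), ``sigma`` the common Gaussian roughness of all three interfaces,
    ``headgroup_solvent_fraction`` the volume fraction of subphase in the
    headgroup slab.  ``V_hg_material`` optionally pins the unsolvated
    headgroup volume; by default the headgroup material is taken to fill the
    non-solvent part of the slab, V_hg = (1 - f) * A_M * d_hg, which keeps
    the slab volume balance exact.
    """

    composition: list
    V_tail: float
    d_tail: float
    d_hg: float
    sigma: float
    headgroup_solvent_fraction: float = 0.0
    V_hg_material: float | None = None

    def __post_init__(self):
        if min(self.V_tail, self.d_tail, self.d_hg) <= 0:
            raise ValueError("V_tail, d_tail and d_hg must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.headgroup_solvent_fraction <= 1.0:
            raise ValueError("headgroup_solvent_fraction must lie in [0, 1]")
        total = sum(c.mole_fraction for c in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mole fractions must sum to 1, got {total}")

    @property
    def A_M(self) -> float:
        """Molecular area per pair of chains, A_M = V_tail / d_tail."""
        return self.V_tail / self.d_tail


@dataclass(frozen=True)
class DerivedStructure:
    """Structural quantities derived from a fitted monolayer model,
    all per pair of chains."""

    A_M: float
    V_hg: float
    n_w: float
    V_total: float
    negative_solvation: bool = False


# ---------------------------------------------------------------------------
# lipid registry


def _lipid_db() -> dict:
    with resources.files("monofilm.data").joinpath("lipids.json").open() as fh:
        db = json.load(fh)
    db.pop("_comment", None)
    return db


def load_lipid(name: str, mole_fraction: float = 1.0) -> LipidComponent:
    """Instantiate a lipid from the shipped definitions file."""
    db = _lipid_db()
    if name not in db:
        raise KeyError(f"unknown lipid {name!r}; known: {sorted(db)}")
    d = db[name]
    return LipidComponent(
        name=name,
        n_chains=d["n_chains"],
        mole_fraction=mole_fraction,
        tail_formula=d["tail_formula"],
        headgroup_formula=d["headgroup_formula"],
        n_exchangeable_H=d["n_exchangeable_H"],
        tails_deuterated=d["tails_deuterated"],
    )


def make_composition(spec: str | dict) -> list[LipidComponent]:
    """Build a composition from ``"DMPE:0.8,DMPG:0.2"`` or a name->fraction dict."""
    if isinstance(spec, str):
        pairs = {}
        for tok in spec.split(","):
            name, _, frac = tok.partition(":")
            pairs[name.strip()] = float(frac) if frac else 1.0
    else:
        pairs = dict(spec)
    total = sum(pairs.values())
    if total <= 0:
        raise ValueError("composition fractions must be positive")
    return [load_lipid(n, f / total) for n, f in pairs.items()]


# ---------------------------------------------------------------------------
# scattering length densities


def subphase_sld(contrast: ContrastSpec, V_water: float = WATER_VOLUME) -> float:
    """SLD of the subphase for the given contrast."""
    if contrast.radiation == "xray":
        return R_E * 10.0 / V_water  # 10 electrons per water molecule
    fD = contrast.d_fraction
    b = (fD * _B_D2O + (1.0 - fD) * _B_H2O) * FM_TO_ANG
    return b / V_water


def water_b(contrast: ContrastSpec) -> float:
    """Scattering length of one subphase water molecule, in Angstrom."""
    if contrast.radiation == "xray":
        return R_E * 10.0
    fD = contrast.d_fraction
    return (fD * _B_D2O + (1.0 - fD) * _B_H2O) * FM_TO_ANG


def _scattering_length(formula: dict, contrast: ContrastSpec) -> float:
    if contrast.radiation == "xray":
        return R_E * _sum_electrons(formula)
    return _sum_b(formula)


def _headgroup_b_per_pair(comp: list[LipidComponent], contrast: ContrastSpec) -> float:
    """Mixture headgroup scattering length per pair of chains, including H/D
    exchange for neutron contrasts."""
    scenario = contrast.exchange_scenario
    if contrast.radiation == "neutron" and contrast.d_fraction > 0 and scenario is None:
        raise ValueError(
            "a neutron contrast with deuterated subphase requires an explicit "
            "exchange_scenario (lipid name -> number of exchanged hydrogens)"
        )
    b_tot = 0.0
    w_tot = 0.0
    for c in comp:
        w = c.mole_fraction * c.pairs
        b = _scattering_length(c.headgroup_formula, contrast)
        if contrast.radiation == "neutron" and scenario is not None:
            n_ex = scenario.get(c.name, 0)
            if n_ex < 0 or n_ex > c.n_exchangeable_H:
                raise ValueError(
                    f"{c.name}: scenario exchanges {n_ex} H but only "
                    f"{c.n_exchangeable_H} are labile"
                )
            b += n_ex * contrast.d_fraction * (NEUTRON_B_FM["D"] - NEUTRON_B_FM["H"]) * FM_TO_ANG
        b_tot += w * b / c.pairs  # per pair within the molecule
        w_tot += w
    return b_tot / w_tot * 1.0 if w_tot else 0.0


def _tail_b_per_pair(comp: list[LipidComponent], contrast: ContrastSpec) -> float:
    b_tot = 0.0
    w_tot = 0.0
    for c in comp:
        w = c.mole_fraction * c.pairs
        b_tot += w * _scattering_length(c.tail_formula, contrast) / c.pairs
        w_tot += w
    return b_tot / w_tot if w_tot else 0.0


def contrast_slds(
    comp: list[LipidComponent],
    contrast: ContrastSpec,
    V_tail: float,
    V_hg: float,
    V_water: float = WATER_VOLUME,
) -> tuple[float, float, float]:
    """(tail SLD, unsolvated headgroup material SLD, subphase SLD).

    ``V_tail`` and ``V_hg`` are volumes per pair of chains; scattering
    lengths are mole-fraction-weighted per pair of chains across the mixture.
    """
    bt = _tail_b_per_pair(comp, contrast)
    bh = _headgroup_b_per_pair(comp, contrast)
    return bt / V_tail, bh / V_hg, subphase_sld(contrast, V_water)


def build_stack(params: MonolayerParams, contrast: ContrastSpec, V_water: float = WATER_VOLUME) -> SlabStack:
    """Realise the two-slab model for one contrast.

    air | tail (d_tail, b_tail/V_tail) | headgroup (d_hg, linear mix of
    headgroup material and subphase) | subphase, with the same roughness at
    all three interfaces.
    """
    f = params.headgroup_solvent_fraction
    A_M = params.A_M
    V_hg = params.V_hg_material
    if V_hg is None:
        V_hg = (1.0 - f) * A_M * params.d_hg
    rho_sub = subphase_sld(contrast, V_water)
    rho_tail = _tail_b_per_pair(params.composition, contrast) / params.V_tail
    if V_hg > 0:
        rho_hg = _headgroup_b_per_pair(params.composition, contrast) / V_hg
    else:
        rho_hg = 0.0  # fully solvated slab; material term vanishes below
    rho_slab = (1.0 - f) * rho_hg + f * rho_sub

    fronting = 0.0  # air
    tail = Slab(params.d_tail, rho_tail, roughness_top=params.sigma)
    head = Slab(params.d_hg, rho_slab, roughness_top=params.sigma)
    return SlabStack(
        medium_above=fronting,
        slabs=(tail, head),
        medium_below=rho_sub,
        roughness_below=params.sigma,
    )


def derive_structure(
    params: MonolayerParams,
    headgroup_slab_sld: float,
    contrast: ContrastSpec,
    V_water: float = WATER_VOLUME,
    tolerance: float = 1e-9,
) -> DerivedStructure:
    """Invert the headgroup slab SLD for V_hg and n_w.

    Volume balance per pair of chains: the solvated headgroup volume is
    A_M * d_hg; the waters it contains follow from the slab SLD,

        n_w = (rho_slab * A_M * d_hg - b_hg) / b_water,

    and the unsolvated headgroup volume is what remains.  If the implied
    V_hg exceeds the solvated volume beyond tolerance the result is flagged
    (``negative_solvation``) rather than silently clipped.
    """
    A_M = params.A_M
    if A_M <= 0:
        raise ValueError("A_M must be positive")
    V_solv = A_M * params.d_hg
    b_hg = _headgroup_b_per_pair(params.composition, contrast)
    b_w = water_b(contrast)
    n_w = (headgroup_slab_sld * V_solv - b_hg) / b_w
    V_hg = V_solv - n_w * V_water
    flagged = n_w < -abs(tolerance) * max(1.0, V_solv / V_water)
    return DerivedStructure(
        A_M=A_M,
        V_hg=V_hg,
        n_w=n_w,
        V_total=params.V_tail + V_hg,
        negative_solvation=bool(flagged),
    )
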