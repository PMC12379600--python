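"""Readers and writers for the plain-text formats the analysis consumes.

Reflectivity curves travel as whitespace-separated columns (q, R, dR[, dq])
with ``#`` comments, or as ORSO-style ``.ort`` text (a ``#``-prefixed YAML-ish
header followed by the same columns).  Isotherms and charge curves are CSV;
GIXD maps are either a simple text block with axis vectors or an HDF5 file
with ``q_xy``, ``q_z`` and ``intensity`` datasets.

Writers emit full-precision decimal ASCII (repr of float64), so a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .echem import ChargeCurve, ChronoTransient
from .gixd import GIXDImage
from .isotherm import Isotherm
from .reflectivity import ReflectivityCurve

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "read_transients_csv",
    "write_transients_csv",
    "read_gixd",
    "write_gixd",
    "write_charge_curve_csv",
]


class FormatError(ValueError):
    """Unparseable input file."""


def _fmt(x: float) -> str:
    return repr(float(x))


def read_reflectivity(path, dialect: str | None = None) -> ReflectivityCurve:
    """Read a reflectivity curve from columnar text or ORSO-style .ort.

    Columns are mapped (q, R, dR[, dq]); ``#`` lines are skipped; q is in
    1/Angstrom.  Non-monotone q is sorted with a warning; fewer than three
    columns or a malformed row raise ``FormatError`` naming the line.
    """
    path = Path(path)
    if dialect is None:
        dialect = "ort" if path.suffix == ".ort" else "columns"
    label = ""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if dialect == "ort" and "data_set:" in s:
                    label = s.split("data_set:", 1)[1].strip()
                continue
            parts = s.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts[:4]])
            except ValueError:
                raise FormatError(f"{path}:{ln}: malformed numeric row: {s!r}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q, R, dR = arr[:, 0], arr[:, 1], arr[:, 2]
    dq = arr[:, 3] if ncol >= 4 else None
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: q not strictly increasing; sorting", stacklevel=2)
        order = np.argsort(q)
        q, R, dR = q[order], R[order], dR[order]
        if dq is not None:
            dq = dq[order]
    return ReflectivityCurve(q=q, R=R, dR=dR, dq=dq, contrast_label=label)


def write_reflectivity(curve: ReflectivityCurve, path, dialect: str | None = None) -> None:
    """Write a curve as columnar text or ORSO-style .ort (bit-exact round trip)."""
    path = Path(path)
    if dialect is None:
        dialect = "ort" if path.suffix == ".ort" else "columns"
    cols = [curve.q, curve.R, curve.dR if curve.dR is not None else np.zeros_like(curve.q)]
    names = ["Qz (1/angstrom)", "R", "sR"]
    if curve.dq is not None:
        cols.append(curve.dq)
        names.append("sQz (FWHM)")
    with open(path, "w") as fh:
        if dialect == "ort":
            fh.write("# # ORSO reflectivity data file | 1.0 text\n")
            fh.write("# data_source:\n#   measurement:\n#     instrument_settings: {}\n")
            fh.write(f"# data_set: {curve.contrast_label}\n")
        fh.write("# " + "  ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_isotherm_csv(path, label: str = "") -> Isotherm:
    """CSV with columns area[, pressure] (header optional: A or area_per_molecule,
    Pi or pressure, and optionally T/temperature)."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    a_col = next((cols[k] for k in ("a", "area", "area_per_molecule", "a_m") if k in cols), df.columns[0])
    p_col = next((cols[k] for k in ("pi", "pressure", "surface_pressure") if k in cols), df.columns[1])
    T = 19.5
    for k in ("t", "temperature"):
        if k in cols:
            T = float(df[cols[k]].iloc[0])
    return Isotherm(A=df[a_col].to_numpy(float), Pi=df[p_col].to_numpy(float), T=T, label=label)


def write_isotherm_csv(iso: Isotherm, path) -> None:
    pd.DataFrame({"area": iso.A, "pressure": iso.Pi, "temperature": iso.T}).to_csv(path, index=False)


def read_transients_csv(path) -> list[ChronoTransient]:
    """Long-format table: columns E, t, current[, E_des] — one block per step."""
    df = pd.read_csv(path, comment="#")
    out = []
    for E, grp in df.groupby("E", sort=True):
        kw = {}
        if "E_des" in df.columns:
            kw["E_des"] = float(grp["E_des"].iloc[0])
        out.append(ChronoTransient(E=float(E), t=grp["t"].to_numpy(float),
                                   current=grp["current"].to_numpy(float), **kw))
    return out


def write_transients_csv(transients: list[ChronoTransient], path) -> None:
    frames = [
        pd.DataFrame({"E": tr.E, "t": tr.t, "current": tr.current, "E_des": tr.E_des})
        for tr in transients
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_charge_curve_csv(curve: ChargeCurve, path) -> None:
    pd.DataFrame({"E": curve.E, "sigma_M": curve.sigma_M, "label": curve.label}).to_csv(path, index=False)


def read_gixd(path) -> GIXDImage:
    """GIXD map from HDF5 (datasets q_xy, q_z, intensity) or from the text
    block written by :func:`write_gixd`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".nxs"):
        import h5py

        with h5py.File(path, "r") as fh:
            return GIXDImage(q_xy=fh["q_xy"][...], q_z=fh["q_z"][...], intensity=fh["intensity"][...])
    with open(path) as fh:
        header = {}
        rows = []
        for line in fh:
            s = line.strip()
            if s.startswith("#"):
                key, _, val = s[1:].partition(":")
                header[key.strip()] = val.strip()
            elif s:
                rows.append([float(v) for v in s.split()])
    if "q_xy" not in header or "q_z" not in header:
        raise FormatError(f"{path}: missing q_xy/q_z axis headers")
    q_xy = np.array([float(v) for v in header["q_xy"].split()])
    q_z = np.array([float(v) for v in header["q_z"].split()])
    return GIXDImage(q_xy=q_xy, q_z=q_z, intensity=np.array(rows))


def write_gixd(image: GIXDImage, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".nxs"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh["q_xy"] = image.q_xy
            fh["q_z"] = image.q_z
            fh["intensity"] = image.intensity
        return
    with open(path, "w") as fh:
        fh.write("# q_xy: " + " ".join(_fmt(v) for v in image.q_xy) + "\n")
        fh.write("# q_z: " + " ".join(_fmt(v) for v in image.q_z) + "\n")
        for row in image.intensity:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")
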