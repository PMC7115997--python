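"""File formats and unit-safe readers/writers.

All on-disk formats are column-named CSV/TSV with the unit embedded in
the column name (``time_s``, ``c_mM``, ``x_um``): a file can never be
read in the wrong unit silently.  Conversion to internal CGS happens
here, at the boundary, and nowhere else.  Optional metadata travels in a
YAML sidecar next to the data file (``<name>.meta.yaml``).
"""

from __future__ import annotations

import os
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import units
from .determinants import CatalogEntry
from .energetics import ArrheniusSeries
from .errors import ParseError
from .census import FcsCensus, SlopeCensus
from .unstirred import ConcentrationProfile
from .vesicle import IntensityTrace, VolumeTrace

__all__ = [
    "read_trace", "write_trace",
    "read_profile", "write_profile",
    "read_catalog", "write_catalog",
    "read_census", "read_slope",
    "read_arrhenius", "write_arrhenius",
    "read_sidecar", "write_sidecar",
]


def _require_columns(df: pd.DataFrame, path, options: List[List[str]]):
    for cols in options:
        if all(c in df.columns for c in cols):
            return cols
    raise ParseError(
        f"{path}: expected columns {' or '.join(map(str, options))}, "
        f"found {list(df.columns)}"
    )


def _read_csv(path, sep=","):
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(str(path))
    return base + ".meta.yaml"


def write_sidecar(path: str, metadata: dict) -> str:
    sc = sidecar_path(path)
    with open(sc, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)
    return sc


def read_sidecar(path: str) -> Optional[dict]:
    sc = sidecar_path(path)
    if not os.path.exists(sc):
        return None
    with open(sc) as fh:
        return yaml.safe_load(fh)


# --- deflation traces --------------------------------------------------------

def write_trace(path: str, trace: Union[VolumeTrace, IntensityTrace],
                metadata: Optional[dict] = None) -> None:
    if isinstance(trace, VolumeTrace):
        df = pd.DataFrame({"time_s": trace.t, "volume_cm3": trace.V})
    else:
        df = pd.DataFrame({"time_s": trace.t, "intensity_au": trace.I})
    df.to_csv(path, index=False)
    if metadata is not None:
        write_sidecar(path, metadata)


def read_trace(path: str) -> Tuple[Union[VolumeTrace, IntensityTrace],
                                   Optional[dict]]:
    """Read a deflation trace; the column name decides volume vs intensity."""
    df = _read_csv(path)
    cols = _require_columns(df, path, [["time_s", "volume_cm3"],
                                       ["time_s", "intensity_au"]])
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(
            f"{path}: time_s not strictly increasing at data row {bad[0] + 2}")
    y = df[cols[1]].to_numpy(dtype=float)
    if cols[1] == "volume_cm3":
        if np.any(y <= 0):
            row = int(np.flatnonzero(y <= 0)[0]) + 2
            raise ParseError(f"{path}: non-positive volume at data row {row}")
        trace = VolumeTrace(t=t - t[0] if t[0] != 0 else t, V=y)
    else:
        trace = IntensityTrace(t=t - t[0] if t[0] != 0 else t, I=y)
    return trace, read_sidecar(path)


# --- unstirred-layer profiles ------------------------------------------------

def write_profile(path: str, profile: ConcentrationProfile,
                  metadata: Optional[dict] = None) -> None:
    df = pd.DataFrame({"x_um": units.cm_to_um(profile.x),
                       "c_mM": units.mol_cm3_to_mM(profile.C)})
    df.to_csv(path, index=False)
    meta = dict(metadata or {})
    meta.setdefault("D_cm2_s", profile.D)
    write_sidecar(path, meta)


def read_profile(path: str, D: Optional[float] = None
                 ) -> Tuple[ConcentrationProfile, Optional[dict]]:
    """Read an electrode scan; D comes from the sidecar unless given."""
    df = _read_csv(path)
    _require_columns(df, path, [["x_um", "c_mM"]])
    meta = read_sidecar(path)
    if D is None:
        if not meta or "D_cm2_s" not in meta:
            raise ParseError(
                f"{path}: diffusion coefficient missing (no D argument and "
                "no D_cm2_s in sidecar)")
        D = float(meta["D_cm2_s"])
    c = df["c_mM"].to_numpy(dtype=float)
    if np.any(c <= 0):
        row = int(np.flatnonzero(c <= 0)[0]) + 2
        raise ParseError(f"{path}: non-positive concentration at data row {row}")
    profile = ConcentrationProfile(
        x=units.um_to_cm(df["x_um"].to_numpy(dtype=float)),
        C=units.mM_to_mol_cm3(c),
        D=D,
    )
    return profile, meta


# --- catalogs ----------------------------------------------------------------

_CATALOG_COLS = ["name", "N", "N_H", "pf_cm3_s", "dG_kcal_mol", "quality"]


def write_catalog(path: str, catalog: List[CatalogEntry]) -> None:
    rows = [{"name": e.name, "N": e.N, "N_H": e.N_H, "pf_cm3_s": e.p_f,
             "dG_kcal_mol": e.dG, "quality": e.quality} for e in catalog]
    pd.DataFrame(rows, columns=_CATALOG_COLS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> List[CatalogEntry]:
    df = _read_csv(path, sep="\t")
    _require_columns(df, path, [["name", "pf_cm3_s"]])
    entries = []
    for i, row in df.iterrows():
        def opt(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])
        try:
            entries.append(CatalogEntry(
                name=str(row["name"]),
                N=opt("N", int),
                N_H=opt("N_H", int),
                p_f=opt("pf_cm3_s"),
                dG=opt("dG_kcal_mol"),
                quality=(str(row["quality"]) if "quality" in df.columns
                         and not pd.isna(row.get("quality"))
                         else "direct_count"),
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: data row {i + 2}: {exc}") from exc
    return entries


# --- census files ------------------------------------------------------------

def read_census(path: str) -> List[Tuple[str, FcsCensus]]:
    """TSV: sample, vesicle_count, micelle_count, protomers_per_oligomer, labeling_efficiency."""
    df = _read_csv(path, sep="\t")
    _require_columns(df, path, [["sample", "vesicle_count", "micelle_count"]])
    out = []
    for i, row in df.iterrows():
        try:
            out.append((str(row["sample"]), FcsCensus(
                vesicle_count=float(row["vesicle_count"]),
                micelle_count=float(row["micelle_count"]),
                protomers_per_oligomer=(
                    int(row["protomers_per_oligomer"])
                    if "protomers_per_oligomer" in df.columns else 1),
                labeling_efficiency=(
                    float(row["labeling_efficiency"])
                    if "labeling_efficiency" in df.columns else 1.0),
            )))
        except ValueError as exc:
            raise ParseError(f"{path}: data row {i + 2}: {exc}") from exc
    return out


def read_slope(path: str) -> SlopeCensus:
    """CSV: x (conductance_S or density_per_cm2), Pf (cm/s)."""
    df = _read_csv(path)
    cols = _require_columns(
        df, path, [["x", "Pf"], ["conductance_S", "Pf"],
                   ["density_per_cm2", "Pf"]])
    return SlopeCensus(x=df[cols[0]].to_numpy(dtype=float),
                       P_f=df["Pf"].to_numpy(dtype=float))


# --- Arrhenius series --------------------------------------------------------

def write_arrhenius(path: str, series: ArrheniusSeries,
                    Pf_units: str = "cm_s") -> None:
    pd.DataFrame({"temperature_K": series.T, "Pf_value": series.P_f,
                  "Pf_units": Pf_units}).to_csv(path, index=False)


def read_arrhenius(path: str) -> Tuple[ArrheniusSeries, str]:
    df = _read_csv(path)
    _require_columns(df, path, [["temperature_K", "Pf_value"]])
    unit_col = df["Pf_units"] if "Pf_units" in df.columns else None
    if unit_col is not None and unit_col.nunique() > 1:
        raise ParseError(f"{path}: mixed Pf_units in one series")
    series = ArrheniusSeries(T=df["temperature_K"].to_numpy(dtype=float),
                             P_f=df["Pf_value"].to_numpy(dtype=float))
    return series, (str(unit_col.iloc[0]) if unit_col is not None else "cm_s")
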