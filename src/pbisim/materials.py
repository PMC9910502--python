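"""X-ray optical properties of the simulated tissues.

A :class:`Material` couples a mass density with two small lookup tables:
the refractive-index decrement ``delta`` (the deviation of the real part of
the refractive index from unity, ``n = 1 - delta``) and the linear
attenuation coefficient ``mu`` in mm^-1.  ``delta`` drives the phase shift
``phi = -(2*pi/lambda) * integral(delta dz)`` that propagation-based imaging
converts into fringes; ``mu`` drives the ordinary Beer-Lambert attenuation.

The built-in table ships the three tissues of the isolated-airway scenario
(air, muscle, lung parenchyma) with their decrement values anchored at
60 keV, plus aluminum (beam filtration) and CdTe (detector sensor, carried
as metadata only).  Attenuation coefficients are bundled reference data
derived from standard mass-attenuation compilations; they can be overridden
by a user-supplied table file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "MaterialTable",
    "MaterialError",
    "MaterialParseError",
    "builtin_table",
    "load_material_table",
    "write_material_table",
]


class MaterialError(KeyError):
    """Unknown material or invalid material data."""


class MaterialParseError(ValueError):
    """Malformed material table file."""


def _as_table(rows) -> np.ndarray:
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr.reshape(-1, 2)
    return arr


@dataclass
class Material:
    """A named tissue/material with density and optical-property tables.

    Parameters
    ----------
    name : str
        Label used for lookups in scenes and thickness maps.
    density : float
        Mass density in g/cm^3.  Must be positive.
    delta_table : array-like of (energy_keV, delta)
        Refractive-index decrement anchors, strictly increasing in energy.
    mu_table : array-like of (energy_keV, mu_per_mm)
        Linear attenuation coefficient anchors, strictly increasing in
        energy.  May be empty only for ``vacuum_like`` materials.
    vacuum_like : bool
        If true, ``mu_at`` returns 0 regardless of the table.
    """

    name: str
    density: float
    delta_table: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    mu_table: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    vacuum_like: bool = False

    def __post_init__(self):
        self.delta_table = _as_table(self.delta_table)
        self.mu_table = _as_table(self.mu_table)
        if not self.density > 0:
            raise MaterialError(f"{self.name}: density must be > 0, got {self.density}")
        if len(self.delta_table) < 1:
            raise MaterialError(f"{self.name}: delta_table needs at least one entry")
        for label, tab in (("delta", self.delta_table), ("mu", self.mu_table)):
            if len(tab) == 0:
                continue
            if np.any(tab[:, 1] < 0):
                raise MaterialError(f"{self.name}: negative {label} value")
            if len(tab) > 1 and not np.all(np.diff(tab[:, 0]) > 0):
                raise MaterialError(
                    f"{self.name}: {label}_table energies must be strictly increasing"
                )
        if len(self.mu_table) == 0 and not self.vacuum_like:
            raise MaterialError(
                f"{self.name}: empty mu_table is only allowed for vacuum-like materials"
            )

    # -- evaluation ---------------------------------------------------------

    def delta_at(self, energy: float) -> float:
        """Refractive-index decrement at ``energy`` (keV).

        Exact at tabulated energies.  Elsewhere the value is obtained by the
        physical far-from-edge scaling ``delta(E) = delta(E0) * (E0/E)**2``
        anchored at the nearest tabulated energy; the same rule extrapolates
        beyond the table ends.
        """
        if not energy > 0:
            raise ValueError(f"energy must be > 0, got {energy}")
        e = self.delta_table[:, 0]
        d = self.delta_table[:, 1]
        idx = int(np.argmin(np.abs(e - energy)))
        if e[idx] == energy:
            return float(d[idx])
        return float(d[idx] * (e[idx] / energy) ** 2)

    def mu_at(self, energy: float) -> float:
        """Linear attenuation coefficient (mm^-1) at ``energy`` (keV).

        Log-linear interpolation of the tabulated values in energy; the
        end-segment slope extrapolates slightly beyond the table range.
        Vacuum-like materials return 0.
        """
        if not energy > 0:
            raise ValueError(f"energy must be > 0, got {energy}")
        if self.vacuum_like or len(self.mu_table) == 0:
            return 0.0
        e = self.mu_table[:, 0]
        m = self.mu_table[:, 1]
        exact = np.flatnonzero(e == energy)
        if exact.size:
            return float(m[exact[0]])
        if len(e) == 1:
            return float(m[0])
        logm = np.log(np.maximum(m, 1e-300))
        if energy <= e[0]:
            lo, hi = 0, 1
        elif energy >= e[-1]:
            lo, hi = len(e) - 2, len(e) - 1
        else:
            hi = int(np.searchsorted(e, energy))
            lo = hi - 1
            if e[hi] == energy:
                return float(m[hi])
        frac = (energy - e[lo]) / (e[hi] - e[lo])
        return float(np.exp(logm[lo] + frac * (logm[hi] - logm[lo])))


@dataclass
class MaterialTable:
    """Mapping of material name to :class:`Material`."""

    materials: dict[str, Material] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def __getitem__(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise MaterialError(
                f"unknown material {name!r}; known: {sorted(self.materials)}"
            ) from None

    def add(self, material: Material) -> None:
        self.materials[material.name] = material

    def delta_at(self, name: str, energy: float) -> float:
        return self[name].delta_at(energy)

    def mu_at(self, name: str, energy: float) -> float:
        return self[name].mu_at(energy)


# -- built-in data ----------------------------------------------------------

_REFERENCE_FILE = "reference_materials.csv"


def _read_table_text(text: str, source: str) -> MaterialTable:
    lines = [ln for ln in text.splitlines()]
    body = "\n".join(ln for ln in lines if not ln.lstrip().startswith("#"))
    if not body.strip():
        return MaterialTable()
    first = body.lstrip().splitlines()[0]
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(io.StringIO(body), sep=sep,
                         skip_blank_lines=True, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MaterialParseError(f"{source}: cannot parse table: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"material", "energy_kev", "delta"}
    if not required.issubset(df.columns):
        raise MaterialParseError(
            f"{source}: need columns {sorted(required)} plus mu_per_mm or "
            f"mu_over_rho_cm2_g, got {list(df.columns)}"
        )
    has_mu = "mu_per_mm" in df.columns
    has_mor = "mu_over_rho_cm2_g" in df.columns
    if not (has_mu or has_mor):
        raise MaterialParseError(
            f"{source}: need a mu_per_mm or mu_over_rho_cm2_g column"
        )
    if "density_g_cm3" not in df.columns:
        raise MaterialParseError(f"{source}: need a density_g_cm3 column")

    table = MaterialTable()
    for name, grp in df.groupby("material", sort=False):
        grp = grp.reset_index()
        for col in ("energy_kev", "delta", "density_g_cm3"):
            bad = grp[pd.to_numeric(grp[col], errors="coerce").isna()]
            if len(bad):
                line = int(bad["index"].iloc[0]) + 2  # header is line 1
                raise MaterialParseError(
                    f"{source}: malformed value in column {col!r} at line {line}"
                )
        energies = grp["energy_kev"].astype(float).to_numpy()
        if len(np.unique(energies)) != len(energies):
            raise MaterialParseError(
                f"{source}: duplicate (material, energy) rows for {name!r}"
            )
        if np.any(np.diff(energies) <= 0):
            line = int(grp["index"][np.argmin(np.diff(energies) > 0) + 1]) + 2
            raise MaterialParseError(
                f"{source}: energies for {name!r} not strictly increasing "
                f"(line {line})"
            )
        density = float(grp["density_g_cm3"].iloc[0])
        if has_mu:
            mu = pd.to_numeric(grp["mu_per_mm"], errors="coerce").to_numpy(float)
        else:
            mor = pd.to_numeric(grp["mu_over_rho_cm2_g"], errors="coerce").to_numpy(float)
            mu = mor * density / 10.0  # cm^2/g * g/cm^3 = cm^-1 -> mm^-1
        deltas = grp["delta"].astype(float).to_numpy()
        keep = ~np.isnan(mu)
        vacuum_like = bool(grp.get("vacuum_like", pd.Series([False])).iloc[0])
        table.add(Material(
            name=str(name),
            density=density,
            delta_table=np.column_stack([energies, deltas]),
            mu_table=np.column_stack([energies[keep], mu[keep]]),
            vacuum_like=vacuum_like,
        ))
    return table


def builtin_table() -> MaterialTable:
    """The bundled reference material table.

    Carries the airway-scenario decrements (air 6.91e-11, muscle 6.66e-8,
    lung parenchyma 3.37e-8, anchored at 60 keV) with their densities
    (0.0012, 1.05, 0.53 g/cm^3), plus aluminum and CdTe reference data.
    """
    text = resources.files("pbisim.data").joinpath(_REFERENCE_FILE).read_text()
    return _read_table_text(text, _REFERENCE_FILE)


def load_material_table(path: str | Path) -> MaterialTable:
    """Read a delimited material table and merge it over the built-ins.

    The file needs a header with columns ``material, density_g_cm3,
    energy_keV, delta`` and either ``mu_per_mm`` or ``mu_over_rho_cm2_g``
    (converted as ``mu = (mu/rho) * rho``, reported in mm^-1).  ``#`` lines
    are comments.  An empty file yields just the built-in table.
    """
    text = Path(path).read_text()
    table = builtin_table()
    user = _read_table_text(text, str(path))
    for mat in user.materials.values():
        table.add(mat)
    return table


def write_material_table(table: MaterialTable, path: str | Path) -> None:
    """Write a table in the same delimited format ``load_material_table`` reads."""
    rows = []
    for mat in table.materials.values():
        mu = {float(e): float(v) for e, v in mat.mu_table}
        energies = sorted(set(mat.delta_table[:, 0]) | set(mu))
        dmap = {float(e): float(v) for e, v in mat.delta_table}
        for e in energies:
            rows.append({
                "material": mat.name,
                "density_g_cm3": mat.density,
                "energy_keV": e,
                "delta": dmap.get(e, mat.delta_at(e)),
                "mu_per_mm": mu.get(e, np.nan),
                "vacuum_like": mat.vacuum_like,
            })
    with open(path, "w") as fh:
        fh.write("# pbisim material table: energies in keV, mu in 1/mm, "
                 "density in g/cm^3, delta dimensionless\n")
        fh.write("material,density_g_cm3,energy_keV,delta,mu_per_mm,vacuum_like\n")
        for r in rows:
            mu = "" if np.isnan(r["mu_per_mm"]) else repr(float(r["mu_per_mm"]))
            fh.write(f"{r['material']},{float(r['density_g_cm3'])!r},"
                     f"{float(r['energy_keV'])!r},{float(r['delta'])!r},"
                     f"{mu},{r['vacuum_like']}\n")
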