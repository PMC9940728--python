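"""Pigment bases: per-unit-concentration optical properties of a pigment set.

Each pigment is characterized by its absorption and reduced-scattering
spectra normalized to mass fraction (mg pigment per g of total phantom
mass), so phantom properties are concentration-linear:

    mua(lambda)  = sum_i c_i * abs_i(lambda)
    musp(lambda) = sum_i c_i * scat_i(lambda)

Pigments are tagged by category: yellow and magenta absorbers cover the blue
and green hemoglobin peaks, miscellaneous pigments cover orange/red/NIR
features, blacks supply baseline absorption, and whites (metal-oxide
scatterers) supply the Mie-Rayleigh scattering slope.  A synthetic 20-pigment
generator emulates the measured characterization so every downstream fit is
testable without the original laboratory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scattering import PowerLawParams, power_law_eval
from .spectra import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    read_spectra_table,
)

__all__ = [
    "CATEGORIES",
    "PigmentRecord",
    "PigmentBasis",
    "Recipe",
    "mix_properties",
    "generate_synthetic_basis",
    "read_basis",
    "write_basis",
]

CATEGORIES = ("yellow", "magenta", "miscellaneous", "white", "black")


@dataclass
class PigmentRecord:
    """Per-unit-concentration optical properties of one pigment."""

    name: str
    category: str
    abs_per_conc: Spectrum   # mm^-1 per (mg/g)
    scat_per_conc: Spectrum  # mm^-1 per (mg/g)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.abs_per_conc.grid != self.scat_per_conc.grid:
            raise ValueError("absorption and scattering grids differ")
        for spec, what in ((self.abs_per_conc, "absorption"), (self.scat_per_conc, "scattering")):
            if np.any(spec.values < 0):
                raise ValueError(f"{self.name}: negative {what} value in basis")


@dataclass
class PigmentBasis:
    """An ordered collection of pigment records sharing one grid."""

    records: list[PigmentRecord]
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pigment names in basis")
        for r in self.records:
            if r.abs_per_conc.grid != self.grid:
                raise ValueError(f"{r.name}: grid mismatch with basis grid")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __getitem__(self, name: str) -> PigmentRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def subset(self, names: list[str]) -> "PigmentBasis":
        return PigmentBasis([self[n] for n in names], self.grid)

    def by_category(self, *categories: str) -> "PigmentBasis":
        recs = [r for r in self.records if r.category in categories]
        return PigmentBasis(recs, self.grid)

    def abs_matrix(self) -> np.ndarray:
        """(n_wavelengths, n_pigments) absorption design matrix."""
        return np.column_stack([r.abs_per_conc.values for r in self.records])

    def scat_matrix(self) -> np.ndarray:
        return np.column_stack([r.scat_per_conc.values for r in self.records])


@dataclass
class Recipe:
    """Nonnegative pigment concentrations in mass-fraction units (mg/g)."""

    concentrations: dict[str, float]
    basis_id: str = ""

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")

    def vector(self, basis: PigmentBasis) -> np.ndarray:
        unknown = set(self.concentrations) - set(basis.names)
        if unknown:
            raise KeyError(f"recipe names not in basis: {sorted(unknown)}")
        return np.array([self.concentrations.get(n, 0.0) for n in basis.names])

    def merged(self, other: "Recipe") -> "Recipe":
        out = dict(self.concentrations)
        for k, v in other.concentrations.items():
            out[k] = out.get(k, 0.0) + v
        return Recipe(out, self.basis_id or other.basis_id)


def mix_properties(basis: PigmentBasis, recipe: Recipe) -> tuple[Spectrum, Spectrum]:
    """Concentration-linear superposition of basis spectra.

    Returns ``(mua, musp)`` on the basis grid.
    """
    c = recipe.vector(basis)
    mua = basis.abs_matrix() @ c if basis.records else np.zeros(len(basis.grid))
    musp = basis.scat_matrix() @ c if basis.records else np.zeros(len(basis.grid))
    return (Spectrum(basis.grid, mua, units="mm^-1", name="mua"),
            Spectrum(basis.grid, musp, units="mm^-1", name="musp"))


# ---------------------------------------------------------------------------
# Synthetic basis generator

def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def generate_synthetic_basis(seed: int = 0, grid: WavelengthGrid = DEFAULT_GRID) -> PigmentBasis:
    """Deterministic synthetic 20-pigment basis emulating the measured set.

    Composition (names carry the category prefix):

    * 6 yellows ``Y1..Y6`` — single Gaussian absorption peaks centred
      400-460 nm, broad (sigma 25-40 nm), like the blue-absorbing yellows.
    * 6 magentas ``M1..M6`` — bimodal Gaussian pairs in 500-600 nm, narrower
      (sigma 12-20 nm); ``M6`` carries an extra ~625 nm peak (dioxazine-like).
    * 3 miscellaneous ``X1..X3`` — one ~500 nm orange-like peak; two
      phthalo-like pigments with red/NIR absorption out to ~750 nm.
    * 2 blacks — ``K_flat`` (nearly flat) and ``K_ink`` (monotone decreasing,
      India-ink-like).
    * 3 whites — ``W_tio2``, ``W_zno``, ``W_al2o3`` with distinct
      Mie-Rayleigh scattering power laws; the first two have short-wavelength
      absorption edges at 410 and 380 nm, the alumina-like white has none.

    All colored and black pigments also carry a small power-law scattering
    term, as the characterization shows it is measurable.  Deterministic in
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    lam = grid.wavelengths
    records: list[PigmentRecord] = []

    def small_scat() -> np.ndarray:
        p = PowerLawParams(a=float(rng.uniform(0.002, 0.02)),
                           f_ray=float(rng.uniform(0.0, 0.3)),
                           b_mie=float(rng.uniform(0.5, 2.0)))
        return power_law_eval(p, grid).values

    def add(name, category, absv, scatv):
        records.append(PigmentRecord(
            name, category,
            Spectrum(grid, absv, units="mm^-1"),
            Spectrum(grid, scatv, units="mm^-1"),
        ))

    # yellows: stratified centres so the basis stays well-conditioned
    centers = np.linspace(402, 458, 6) + rng.uniform(-4, 4, 6)
    for i, c in enumerate(centers):
        sigma = rng.uniform(25, 40)
        amp = rng.uniform(0.1, 0.5)
        add(f"Y{i+1}", "yellow", amp * _gauss(lam, c, sigma), small_scat())

    # magentas: bimodal pairs
    lo_centers = np.linspace(515, 545, 6) + rng.uniform(-3, 3, 6)
    for i, c1 in enumerate(lo_centers):
        c2 = c1 + rng.uniform(28, 42)
        s1, s2 = rng.uniform(12, 20, 2)
        a1 = rng.uniform(0.2, 0.6)
        a2 = a1 * rng.uniform(0.6, 1.1)
        absv = a1 * _gauss(lam, c1, s1) + a2 * _gauss(lam, c2, s2)
        if i == 5:  # dioxazine-like third peak in the red
            absv = absv + 0.5 * a1 * _gauss(lam, 625 + rng.uniform(-3, 3), rng.uniform(14, 20))
        add(f"M{i+1}", "magenta", absv, small_scat())

    # miscellaneous: orange-like, plus two red/NIR absorbers
    add("X1", "miscellaneous",
        rng.uniform(0.2, 0.5) * _gauss(lam, 500 + rng.uniform(-5, 5), rng.uniform(25, 35)),
        small_scat())
    for j, c in enumerate((640.0, 690.0)):
        absv = rng.uniform(0.2, 0.5) * _gauss(lam, c + rng.uniform(-8, 8), rng.uniform(35, 50))
        add(f"X{j+2}", "miscellaneous", absv, small_scat())

    # blacks
    flat = rng.uniform(0.03, 0.08)
    add("K_flat", "black", np.full(lam.size, flat) * (1 + 0.02 * (650 - lam) / 580), small_scat())
    a_ink = rng.uniform(0.04, 0.10)
    add("K_ink", "black", a_ink * (lam / 500.0) ** -rng.uniform(0.8, 1.4), small_scat())

    # whites: distinct power-law scattering, UV absorption edges for two
    white_specs = [
        ("W_tio2", rng.uniform(0.6, 1.0), rng.uniform(0.05, 0.15), rng.uniform(2.2, 3.0), 410.0),
        ("W_zno", rng.uniform(0.3, 0.6), rng.uniform(0.2, 0.4), rng.uniform(1.2, 2.0), 380.0),
        ("W_al2o3", rng.uniform(0.1, 0.3), rng.uniform(0.4, 0.7), rng.uniform(0.4, 1.0), None),
    ]
    for name, a, f, b, edge in white_specs:
        scat = power_law_eval(PowerLawParams(a=a, f_ray=f, b_mie=b), grid).values
        if edge is None:
            absv = np.zeros(lam.size)
        else:
            # sigmoid band edge: strong absorption below `edge`, ~0 above
            absv = rng.uniform(0.1, 0.3) / (1.0 + np.exp((lam - edge) / 5.0))
            absv[absv < 1e-12] = 0.0
        add(name, "white", absv, scat)

    return PigmentBasis(records, grid)


# ---------------------------------------------------------------------------
# Basis CSV dialect: row 1 `wavelength_nm,<names...>`, row 2
# `#category,<categories...>`, then data rows; absorption and scattering in
# sibling files suffixed `_abs.csv` and `_scat.csv`.

def write_basis(basis: PigmentBasis, path_prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(path_prefix)
    paths = (prefix.with_name(prefix.name + "_abs.csv"),
             prefix.with_name(prefix.name + "_scat.csv"))
    for path, matrix in zip(paths, (basis.abs_matrix(), basis.scat_matrix())):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm," + ",".join(basis.names) + "\n")
            fh.write("#category," + ",".join(r.category for r in basis.records) + "\n")
            for lam, row in zip(basis.grid.wavelengths, matrix):
                fh.write(f"{lam:.10g}," + ",".join(f"{v:.12g}" for v in row) + "\n")
    return paths


def _read_categories(path: Path, names: list[str]) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        sidecar = fh.readline().strip()
    if not sidecar.startswith("#category,"):
        raise ValueError(f"{path}: missing '#category' sidecar line")
    cats = sidecar.split(",")[1:]
    if len(cats) != len(names):
        raise ValueError(f"{path}: category count does not match pigment count")
    return cats


def read_basis(path_prefix: str | Path) -> PigmentBasis:
    prefix = Path(path_prefix)
    abs_path = prefix.with_name(prefix.name + "_abs.csv")
    scat_path = prefix.with_name(prefix.name + "_scat.csv")
    grid_a, abs_cols = read_spectra_table(abs_path)
    grid_s, scat_cols = read_spectra_table(scat_path)
    if grid_a != grid_s:
        raise ValueError("absorption and scattering files have different grids")
    if list(abs_cols) != list(scat_cols):
        raise ValueError("absorption and scattering files list different pigments")
    names = list(abs_cols)
    cats = _read_categories(abs_path, names)
    records = [
        PigmentRecord(n, c,
                      Spectrum(grid_a, abs_cols[n], units="mm^-1"),
                      Spectrum(grid_a, scat_cols[n], units="mm^-1"))
        for n, c in zip(names, cats)
    ]
    return PigmentBasis(records, grid_a)
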