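"""Reference ε(λ) spectra of the transient radicals.

The spectral-resolution step needs one molar-absorption curve εj(λ) per
radical.  Published work anchors each radical at its absorption maximum
(λmax, ε at λmax); the full band shapes are modelled here as symmetric
Gaussians in wavelength with a configurable full width at half maximum.
For multi-band components the band amplitudes are solved jointly so that
the summed curve passes exactly through every printed (λmax, ε) anchor
even when the bands overlap.

Default components for the HO•-oxidised methionine model peptide:

====== ============================== ===========================
name   radical                        anchors (nm, M⁻¹ cm⁻¹)
====== ============================== ===========================
HOS    sulfuranyl (HO• adduct at S)   340, 3400
alphaC Cα-centred (backbone)          270, 6200 and 370, 1800
alphaS α-(alkylthio)alkyl             290, 3000
SS     S∴S dimer radical cation       480, 6880
SN     cyclic S∴N radical             390, 4500
====== ============================== ===========================
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "ComponentSpectrum",
    "SpectralLibrary",
    "DEFAULT_BANDS",
    "DEFAULT_FWHM_NM",
    "default_grid",
    "build_default_library",
    "component_epsilon",
]

logger = logging.getLogger(__name__)

#: Default band full width at half maximum (nm).
DEFAULT_FWHM_NM = 70.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class Band:
    """One absorption band: centre (nm), ε at the centre, FWHM (nm)."""

    center: float
    peak_epsilon: float
    fwhm: float = DEFAULT_FWHM_NM

    def __post_init__(self) -> None:
        if self.peak_epsilon < 0:
            raise ValueError(f"peak_epsilon must be >= 0, got {self.peak_epsilon}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile of this band."""
        lam = np.asarray(wavelengths, dtype=float)
        return np.exp(-0.5 * ((lam - self.center) / self.sigma) ** 2)


#: Printed (λmax, ε) anchors for the five default transients.
DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    "HOS": (Band(340.0, 3400.0),),
    "alphaC": (Band(270.0, 6200.0), Band(370.0, 1800.0)),
    "alphaS": (Band(290.0, 3000.0),),
    "SS": (Band(480.0, 6880.0),),
    "SN": (Band(390.0, 4500.0),),
}


def default_grid(start: float = 270.0, stop: float = 700.0, step: float = 2.0) -> np.ndarray:
    """Default wavelength grid: 270–700 nm in 2 nm steps (inclusive)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


class ComponentSpectrum:
    """A named radical with its sampled ε(λ) curve.

    Band amplitudes are chosen so that the sampled curve equals each
    band's ``peak_epsilon`` at that band's centre; for non-overlapping
    bands this reduces to the amplitude being the peak value itself.
    """

    def __init__(self, name: str, bands: Sequence[Band], grid: np.ndarray):
        if not bands:
            raise ValueError("a component needs at least one band")
        self.name = str(name)
        self.bands = tuple(bands)
        self.grid = np.asarray(grid, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be 1-D and strictly increasing")
        for band in self.bands:
            if not (self.grid[0] <= band.center <= self.grid[-1]):
                logger.warning(
                    "band center %.1f nm of component %r lies outside the "
                    "grid range %.1f-%.1f nm",
                    band.center, self.name, self.grid[0], self.grid[-1],
                )
        self.epsilon = self._sample()

    def _sample(self) -> np.ndarray:
        centers = np.array([b.center for b in self.bands])
        peaks = np.array([b.peak_epsilon for b in self.bands])
        # cross-talk matrix: value of band k's unit profile at centre i
        M = np.stack([b.profile(centers) for b in self.bands], axis=1)
        amplitudes = np.linalg.solve(M, peaks)
        profiles = np.stack([b.profile(self.grid) for b in self.bands], axis=1)
        eps = profiles @ amplitudes
        return np.maximum(eps, 0.0)

    def epsilon_at(self, wavelength: float) -> float:
        """ε at a wavelength inside the grid range (linear interpolation)."""
        if not (self.grid[0] <= wavelength <= self.grid[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid range "
                f"[{self.grid[0]}, {self.grid[-1]}] nm"
            )
        return float(np.interp(wavelength, self.grid, self.epsilon))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ComponentSpectrum({self.name!r}, {len(self.bands)} band(s))"


def component_epsilon(component: ComponentSpectrum, wavelength: float) -> float:
    """ε(λ) of a component by linear interpolation on its sampled curve."""
    return component.epsilon_at(wavelength)


class SpectralLibrary:
    """An ordered set of component spectra sharing one wavelength grid."""

    def __init__(self, grid: np.ndarray, components: Sequence[ComponentSpectrum]):
        self.grid = np.asarray(grid, dtype=float)
        self.components = list(components)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")
        for c in self.components:
            if not np.array_equal(c.grid, self.grid):
                raise ValueError(f"component {c.name!r} sampled on a different grid")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __getitem__(self, name: str) -> ComponentSpectrum:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.components)

    def design_matrix(self) -> np.ndarray:
        """The εj(λi) matrix (n_wavelengths × n_components)."""
        return np.stack([c.epsilon for c in self.components], axis=1)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": c.name,
                "bands": [
                    {"center_nm": b.center, "peak_epsilon": b.peak_epsilon,
                     "fwhm_nm": b.fwhm}
                    for b in c.bands
                ],
            }
            for c in self.components
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"grid": {"start": float(self.grid[0]),
                                "stop": float(self.grid[-1]),
                                "step": float(self.grid[1] - self.grid[0])},
                       "components": payload}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path,
                  grid: Optional[np.ndarray] = None) -> "SpectralLibrary":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if grid is None:
            g = payload["grid"]
            grid = default_grid(g["start"], g["stop"], g["step"])
        components = [
            ComponentSpectrum(
                entry["name"],
                [Band(b["center_nm"], b["peak_epsilon"], b["fwhm_nm"])
                 for b in entry["bands"]],
                grid,
            )
            for entry in payload["components"]
        ]
        return cls(grid, components)

    def to_csv(self, path: str | Path) -> None:
        """Export the sampled curves: wavelength_nm plus one column per component."""
        df = pd.DataFrame({"wavelength_nm": self.grid})
        for c in self.components:
            df[c.name] = c.epsilon
        df.to_csv(path, index=False)


def build_default_library(
    grid: Optional[np.ndarray] = None,
    fwhm: float = DEFAULT_FWHM_NM,
    epsilon_perturbation: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SpectralLibrary:
    """The five-component default library on a 270–700 nm grid.

    Parameters
    ----------
    grid
        Wavelength grid; defaults to 270–700 nm step 2 nm.
    fwhm
        Band full width at half maximum (nm) applied to every band.
    epsilon_perturbation
        Optional relative half-width of a uniform random rescaling of each
        component's ε curve (e.g. 0.15 for the ±15% coefficient
        uncertainty quoted for these transients); off by default.
    rng
        Random generator used when ``epsilon_perturbation`` > 0.
    """
    if grid is None:
        grid = default_grid()
    components = []
    for name, bands in DEFAULT_BANDS.items():
        scale = 1.0
        if epsilon_perturbation > 0.0:
            if rng is None:
                rng = np.random.default_rng()
            scale = 1.0 + rng.uniform(-epsilon_perturbation, epsilon_perturbation)
        scaled = [Band(b.center, b.peak_epsilon * scale, fwhm) for b in bands]
        components.append(ComponentSpectrum(name, scaled, grid))
    return SpectralLibrary(grid, components)
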