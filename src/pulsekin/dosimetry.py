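"""Radiation-chemical-yield calibration for pulse radiolysis.

Converts measured transient absorbances into radiation-chemical yields
(G-values, µmol J⁻¹) via thiocyanate dosimetry:

* the Schuler scavenging formula gives the total radical yield available
  at a given scavenger concentration,
* the dosimeter conversion factor F = ε₄₇₂ · G((SCN)₂•⁻) / A₄₇₂ rescales
  an observed absorbance spectrum A(λ) into a Gε(λ) spectrum
  (µmol J⁻¹ M⁻¹ cm⁻¹).

Units package-wide: concentration mol L⁻¹, time s, yields µmol J⁻¹,
molar absorption coefficients M⁻¹ cm⁻¹, optical path length 1 cm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PRIMARY_YIELDS",
    "G_FRICKE",
    "ScavengerContext",
    "DosimetryCalibration",
    "YieldSpectrum",
    "n2o_hydroxyl_yield",
    "schuler_yield",
    "dose_conversion_factor",
    "absorbance_to_yield_spectrum",
    "yield_spectrum_to_absorbance",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_dosimetry_config",
]

#: Primary yields of water radiolysis at neutral pH (µmol J⁻¹).
PRIMARY_YIELDS: dict[str, float] = {
    "e_aq": 0.28,
    "HO": 0.28,
    "H": 0.06,
    "H_plus": 0.28,
    "H2O2": 0.07,
}

#: Fricke dosimeter yield G(Fe³⁺) (µmol J⁻¹), stored as a named constant.
G_FRICKE: float = 1.61


def n2o_hydroxyl_yield() -> float:
    """Total HO• yield in N₂O-saturated solution (µmol J⁻¹).

    N₂O converts hydrated electrons quantitatively into HO•, so the
    available hydroxyl yield is the sum of the primary e⁻(aq) and HO•
    yields (0.56 µmol J⁻¹).
    """
    return PRIMARY_YIELDS["e_aq"] + PRIMARY_YIELDS["HO"]


@dataclass(frozen=True)
class ScavengerContext:
    """Parameters of the Schuler scavenging formula.

    Parameters
    ----------
    concentration
        HO•-scavenger molarity [S] (mol L⁻¹).
    g0
        Plateau-free yield constant (µmol J⁻¹).
    g1
        Scavenging increment (µmol J⁻¹); the yield saturates at g0 + g1.
    a
        Scavenging coefficient (L mol⁻¹).
    """

    concentration: float
    g0: float = 0.539
    g1: float = 0.307
    a: float = 19.6

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"scavenger concentration must be >= 0, got {self.concentration}"
            )
        for name in ("g0", "g1", "a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def schuler_yield(ctx: ScavengerContext) -> float:
    """Scavenged radical yield G(S•) (µmol J⁻¹) from the Schuler formula.

    G = g0 + g1·√(a[S]) / (1 + √(a[S])).  Monotone nondecreasing in [S]
    and bounded in [g0, g0 + g1]; with the default constants,
    [S] = 0.2 mM gives 0.557 µmol J⁻¹.
    """
    s = math.sqrt(ctx.a * ctx.concentration)
    return ctx.g0 + ctx.g1 * s / (1.0 + s)


@dataclass(frozen=True)
class DosimetryCalibration:
    """Thiocyanate dosimeter calibration.

    ``A472`` is the absorbance change observed in the N₂O-saturated
    10 mM KSCN dosimeter at 472 nm; ``epsilon472`` and ``G_dosimeter``
    are the molar absorption coefficient and radiation-chemical yield of
    the (SCN)₂•⁻ radical.
    """

    A472: float
    epsilon472: float = 7580.0
    G_dosimeter: float = 0.635

    def __post_init__(self) -> None:
        if self.A472 <= 0:
            raise ValueError(f"A472 must be > 0, got {self.A472}")
        if self.epsilon472 <= 0 or self.G_dosimeter <= 0:
            raise ValueError("epsilon472 and G_dosimeter must be > 0")

    @property
    def F(self) -> float:
        """Conversion factor F = ε₄₇₂·G/A₄₇₂ (µmol J⁻¹ M⁻¹ cm⁻¹ per a.u.)."""
        return dose_conversion_factor(self)


def dose_conversion_factor(cal: DosimetryCalibration) -> float:
    """F = ε₄₇₂ · G_dosimeter / A₄₇₂; scales absorbance to Gε units."""
    return cal.epsilon472 * cal.G_dosimeter / cal.A472


@dataclass
class YieldSpectrum:
    """A Gε(λ) spectrum: absorbance rescaled to yield × ε units.

    ``values`` are in µmol J⁻¹ M⁻¹ cm⁻¹ on a strictly increasing
    nanometre grid; ``time`` is the optional pump–probe delay (s).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    time: Optional[float] = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError(
                f"grid/value length mismatch: {self.wavelengths.shape} vs {self.values.shape}"
            )
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Gε values must be finite")


def absorbance_to_yield_spectrum(
    wavelengths: np.ndarray,
    absorbances: np.ndarray,
    F: float,
    time: Optional[float] = None,
) -> YieldSpectrum:
    """Rescale A(λ) to Gε(λ) = F·A(λ).

    Exactly linear in both the absorbances and F.
    """
    if F <= 0:
        raise ValueError(f"conversion factor F must be > 0, got {F}")
    absorbances = np.asarray(absorbances, dtype=float)
    if not np.all(np.isfinite(absorbances)):
        raise ValueError("absorbances must be finite")
    return YieldSpectrum(
        wavelengths=np.asarray(wavelengths, dtype=float),
        values=F * absorbances,
        time=time,
    )


def yield_spectrum_to_absorbance(spectrum: YieldSpectrum, F: float) -> np.ndarray:
    """Inverse of :func:`absorbance_to_yield_spectrum`: A(λ) = Gε(λ)/F."""
    if F <= 0:
        raise ValueError(f"conversion factor F must be > 0, got {F}")
    return spectrum.values / F


# ---------------------------------------------------------------------------
# I/O

def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a single-delay absorbance spectrum CSV.

    Expects columns ``wavelength_nm, absorbance`` with a header row,
    UTF-8, '.' decimal separator.
    """
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "absorbance"} - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV missing columns: {sorted(missing)}")
    df = df.sort_values("wavelength_nm")
    return df["wavelength_nm"].to_numpy(float), df["absorbance"].to_numpy(float)


def write_spectrum_csv(
    path: str | Path, wavelengths: np.ndarray, absorbances: np.ndarray
) -> None:
    pd.DataFrame(
        {"wavelength_nm": wavelengths, "absorbance": absorbances}
    ).to_csv(path, index=False)


def load_dosimetry_config(
    path: str | Path,
) -> tuple[DosimetryCalibration, ScavengerContext]:
    """Load a JSON config with ``dosimetry`` and ``schuler`` blocks.

    ``dosimetry``: {epsilon472, G_dosimeter, A472};
    ``schuler``: {concentration, g0, g1, a} (all but concentration optional).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = json.load(fh)
    dos = cfg.get("dosimetry", {})
    sch = cfg.get("schuler", {})
    cal = DosimetryCalibration(
        A472=dos["A472"],
        epsilon472=dos.get("epsilon472", 7580.0),
        G_dosimeter=dos.get("G_dosimeter", 0.635),
    )
    ctx = ScavengerContext(
        concentration=sch["concentration"],
        g0=sch.get("g0", 0.539),
        g1=sch.get("g1", 0.307),
        a=sch.get("a", 19.6),
    )
    return cal, ctx
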