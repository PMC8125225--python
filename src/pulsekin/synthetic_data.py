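"""Seeded synthetic transient-absorption datasets with ground truth.

The generator emulates the forward model the analysis chain assumes:

1. the kinetic network produces per-radical yield trajectories Gj(t),
2. each delay's Gε(λ) spectrum is the concentration-weighted sum of the
   library ε curves,
3. division by the dosimetry factor F returns absorbance units,
4. i.i.d. Gaussian noise (mean 0, σ = ``noise_sigma``) is added in
   absorbance space.

Datasets are bit-for-bit reproducible for a given (spec, seed) and carry
their ground-truth component yields, so every pipeline stage can be
tested closed loop without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dosimetry import ScavengerContext, schuler_yield
from .kinetics import (
    OBSERVABLE_SPECIES,
    KineticScheme,
    RateConstantSet,
    simulate_scheme,
)
from .resolution import CompositeSpectrum
from .spectral_library import SpectralLibrary, build_default_library

__all__ = [
    "default_time_grid",
    "SyntheticDatasetSpec",
    "TransientAbsorptionDataset",
    "generate_dataset",
    "generate_fixed_composition_spectrum",
]


def default_time_grid(n: int = 60) -> np.ndarray:
    """Observation window 200 ns → 400 µs, logarithmically spaced."""
    return np.geomspace(2e-7, 4e-4, n)


@dataclass
class SyntheticDatasetSpec:
    """Everything needed to generate one dataset.

    ``initial_yield`` defaults to the Schuler-scavenged HO• yield at the
    scheme's substrate concentration; ``noise_sigma`` is in absorbance
    units.
    """

    scheme: KineticScheme = field(default_factory=KineticScheme)
    rates: RateConstantSet = field(default_factory=RateConstantSet)
    library: Optional[SpectralLibrary] = None
    dose_factor: float = 48133.0
    times: Optional[np.ndarray] = None
    noise_sigma: float = 0.0
    seed: int = 0
    initial_yield: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dose_factor <= 0:
            raise ValueError("dose factor F must be > 0")
        if self.library is None:
            self.library = build_default_library()
        if self.times is None:
            self.times = default_time_grid()
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be nonempty and strictly increasing")
        if self.initial_yield is None:
            self.initial_yield = schuler_yield(
                ScavengerContext(self.scheme.substrate_M)
            )


@dataclass
class TransientAbsorptionDataset:
    """An A(λ, t) matrix plus metadata and optional ground truth.

    ``absorbance`` has shape (n_times, n_wavelengths); ``truth`` maps
    component name → ground-truth yield trajectory (µmol J⁻¹).
    """

    wavelengths: np.ndarray
    times: np.ndarray
    absorbance: np.ndarray
    dose_factor: float
    noise_sigma: float = 0.0
    seed: Optional[int] = None
    truth: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"(n_times={len(self.times)}, n_wavelengths={len(self.wavelengths)})"
            )

    def truth_total(self) -> np.ndarray:
        """Total ground-truth yield of the observable components."""
        if self.truth is None:
            raise ValueError("dataset carries no ground truth")
        return np.sum([traj for traj in self.truth.values()], axis=0)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: time_s, wavelength_nm, absorbance."""
        tt, ll = np.meshgrid(self.times, self.wavelengths, indexing="ij")
        pd.DataFrame({
            "time_s": tt.ravel(),
            "wavelength_nm": ll.ravel(),
            "absorbance": self.absorbance.ravel(),
        }).to_csv(path, index=False)

    def truth_to_csv(self, path: str | Path) -> None:
        if self.truth is None:
            raise ValueError("dataset carries no ground truth")
        rows = []
        for name, traj in self.truth.items():
            for t, g in zip(self.times, traj):
                rows.append({"time_s": t, "component": name, "G_umol_per_J": g})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, dose_factor: float, noise_sigma: float = 0.0
    ) -> "TransientAbsorptionDataset":
        df = pd.read_csv(path)
        missing = {"time_s", "wavelength_nm", "absorbance"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
        pivot = df.pivot_table(
            index="time_s", columns="wavelength_nm", values="absorbance"
        ).sort_index()
        return cls(
            wavelengths=pivot.columns.to_numpy(float),
            times=pivot.index.to_numpy(float),
            absorbance=pivot.to_numpy(float),
            dose_factor=dose_factor,
            noise_sigma=noise_sigma,
        )


def generate_dataset(spec: SyntheticDatasetSpec) -> TransientAbsorptionDataset:
    """Generate one dataset: kinetics → ε mixing → dose scaling → noise."""
    library = spec.library
    profiles = simulate_scheme(
        spec.scheme, spec.rates, spec.initial_yield, spec.times
    )
    missing = [n for n in library.names if n not in OBSERVABLE_SPECIES]
    if missing:
        raise ValueError(
            f"library components without simulated trajectories: {missing}"
        )
    G = np.stack([profiles[name] for name in library.names], axis=1)
    E = library.design_matrix()  # (n_wl, n_comp)
    clean = (G @ E.T) / spec.dose_factor
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=clean.shape) \
        if spec.noise_sigma > 0 else 0.0
    return TransientAbsorptionDataset(
        wavelengths=library.grid,
        times=spec.times,
        absorbance=clean + noise,
        dose_factor=spec.dose_factor,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        truth={name: profiles[name].copy() for name in library.names},
    )


def generate_fixed_composition_spectrum(
    total_G: float,
    percents: dict[str, float],
    library: Optional[SpectralLibrary] = None,
    time: Optional[float] = None,
) -> tuple[CompositeSpectrum, dict[str, float]]:
    """A single noiseless Gε(λ) slice with an exactly specified composition.

    ``percents`` maps component name → percent of ``total_G``; any
    remainder (100 − Σ percents) is split equally among the unnamed
    library components.  Returns the composite spectrum and the exact
    per-component yields used to build it.
    """
    if library is None:
        library = build_default_library()
    unknown = set(percents) - set(library.names)
    if unknown:
        raise KeyError(f"unknown component names: {sorted(unknown)}")
    if any(p < 0 for p in percents.values()):
        raise ValueError("percents must be >= 0")
    assigned = sum(percents.values())
    if assigned > 100.0 + 1e-9:
        raise ValueError(f"percents sum to {assigned} > 100")
    remainder = max(100.0 - assigned, 0.0)
    unnamed = [n for n in library.names if n not in percents]
    full = dict(percents)
    for name in unnamed:
        full[name] = remainder / len(unnamed) if unnamed else 0.0
    yields = {name: total_G * full.get(name, 0.0) / 100.0 for name in library.names}
    g = np.array([yields[name] for name in library.names])
    gepsilon = library.design_matrix() @ g
    return CompositeSpectrum(grid=library.grid, gepsilon=gepsilon, time=time), yields
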