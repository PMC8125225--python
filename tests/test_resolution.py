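"""Spectral resolution: closed-loop recovery, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsekin.kinetics import KineticScheme, RateConstantSet
from pulsekin.resolution import (
    CompositeSpectrum,
    GridMismatchError,
    IdentifiabilityError,
    percent_contributions,
    resolve_spectrum,
    resolve_time_series,
)
from pulsekin.spectral_library import (
    Band,
    ComponentSpectrum,
    SpectralLibrary,
    build_default_library,
)
from pulsekin.synthetic_data import (
    SyntheticDatasetSpec,
    TransientAbsorptionDataset,
    generate_dataset,
    generate_fixed_composition_spectrum,
)


def _mix(library, yields):
    g = np.array([yields.get(name, 0.0) for name in library.names])
    return CompositeSpectrum(library.grid, library.design_matrix() @ g)


class TestResolveSpectrum:
    def test_single_component_identity(self, library):
        composite = _mix(library, {"HOS": 0.5})
        result = resolve_spectrum(composite, library)
        assert result.yields["HOS"] == pytest.approx(0.5, abs=1e-12)
        for name in ("alphaC", "alphaS", "SS", "SN"):
            assert result.yields[name] == pytest.approx(0.0, abs=1e-10)

    def test_printed_composition_recovered(self, library):
        """The 1.1 us composition (73.6% sulfuranyl) survives a
        generate-then-resolve round trip exactly."""
        composite, _ = generate_fixed_composition_spectrum(
            0.53, {"HOS": 73.6, "alphaS": 1.9, "alphaC": 11.35}, library
        )
        result = resolve_spectrum(composite, library, nonnegative=True)
        assert result.percents["HOS"] == pytest.approx(73.6, abs=1e-8)
        assert result.total_G == pytest.approx(0.53, rel=1e-9)

    @given(
        g=st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False),
            min_size=5, max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_noiseless_closed_loop_exact(self, library, g):
        """Arbitrary nonnegative truth vectors are recovered to 1e-9."""
        truth = dict(zip(library.names, g))
        result = resolve_spectrum(_mix(library, truth), library)
        for name in library.names:
            assert result.yields[name] == pytest.approx(truth[name], abs=1e-9)

    def test_matches_brute_force_grid_search(self):
        """Two-component toy agrees with exhaustive grid search at 1e-3."""
        grid = np.linspace(280, 660, 20)
        lib = SpectralLibrary(grid, [
            ComponentSpectrum("HOS", [Band(340, 3400)], grid),
            ComponentSpectrum("SS", [Band(480, 6880)], grid),
        ])
        truth = np.array([0.313, 0.622])
        y = lib.design_matrix() @ truth

        # brute-force oracle: evaluate the SSE on a 1e-3 lattice of [0,1]^2
        E = lib.design_matrix()
        cand = np.arange(0, 1.0 + 1e-9, 1e-3)
        g1, g2 = np.meshgrid(cand, cand, indexing="ij")
        EtE = E.T @ E
        Ety = E.T @ y
        sse = (
            EtE[0, 0] * g1**2 + 2 * EtE[0, 1] * g1 * g2 + EtE[1, 1] * g2**2
            - 2 * (Ety[0] * g1 + Ety[1] * g2)
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        oracle = np.array([cand[i], cand[j]])

        result = resolve_spectrum(CompositeSpectrum(grid, y), lib)
        fitted = np.array([result.yields["HOS"], result.yields["SS"]])
        assert np.all(np.abs(fitted - oracle) <= 1e-3 + 1e-9)

    def test_unconstrained_matches_normal_equations(self, rng):
        """OLS path equals the closed-form normal-equations solution."""
        grid = np.linspace(280, 660, 40)
        lib = SpectralLibrary(grid, [
            ComponentSpectrum("a", [Band(340, 3400)], grid),
            ComponentSpectrum("b", [Band(480, 6880)], grid),
            ComponentSpectrum("c", [Band(390, 4500)], grid),
        ])
        E = lib.design_matrix()
        for _ in range(10):
            y = E @ rng.normal(size=3) + 0.1 * rng.normal(size=len(grid))
            oracle = np.linalg.solve(E.T @ E, E.T @ y)
            result = resolve_spectrum(
                CompositeSpectrum(grid, y), lib, nonnegative=False
            )
            fitted = np.array([result.yields[n] for n in lib.names])
            np.testing.assert_allclose(fitted, oracle, atol=1e-9)

    def test_nonnegativity_enforced(self, library, rng):
        y = library.design_matrix() @ rng.random(5) + rng.normal(0, 50, len(library.grid))
        result = resolve_spectrum(CompositeSpectrum(library.grid, y), library)
        assert all(g >= 0 for g in result.yields.values())

    def test_order_permutation_invariance(self, library, rng):
        truth = dict(zip(library.names, rng.random(5)))
        composite = _mix(library, truth)
        shuffled = SpectralLibrary(library.grid, library.components[::-1])
        r1 = resolve_spectrum(composite, library)
        r2 = resolve_spectrum(
            CompositeSpectrum(shuffled.grid, composite.gepsilon), shuffled
        )
        for name in library.names:
            assert r1.yields[name] == pytest.approx(r2.yields[name], abs=1e-10)

    def test_rank_deficiency_names_collinear_components(self):
        grid = np.linspace(280, 660, 30)
        a = ComponentSpectrum("a", [Band(340, 3400)], grid)
        twin = ComponentSpectrum("a_twin", [Band(340, 1700)], grid)
        lib = SpectralLibrary(grid, [a, twin])
        with pytest.raises(IdentifiabilityError, match="a_twin"):
            resolve_spectrum(CompositeSpectrum(grid, a.epsilon.copy()), lib)

    def test_grid_mismatch_rejected(self, library):
        other = np.linspace(280, 660, 30)
        with pytest.raises(GridMismatchError):
            resolve_spectrum(CompositeSpectrum(other, np.zeros(30)), library)

    def test_baseline_flag_absorbs_offset(self, library):
        composite = _mix(library, {"HOS": 0.4})
        shifted = CompositeSpectrum(library.grid, composite.gepsilon + 100.0)
        result = resolve_spectrum(shifted, library, baseline=True)
        assert result.baseline == pytest.approx(100.0, rel=1e-6)
        assert result.yields["HOS"] == pytest.approx(0.4, abs=1e-8)


class TestPercentContributions:
    def test_symmetric_pair(self, library):
        composite = _mix(library, {"HOS": 1.0, "SS": 1.0})
        p = percent_contributions(resolve_spectrum(composite, library))
        assert p["HOS"] == pytest.approx(50.0, abs=1e-8)
        assert p["SS"] == pytest.approx(50.0, abs=1e-8)

    def test_arithmetic_of_printed_split(self, library):
        yields = {"HOS": 0.39, "alphaS": 0.01, "alphaC": 0.06, "SS": 0.05, "SN": 0.02}
        p = percent_contributions(resolve_spectrum(_mix(library, yields), library))
        assert p["HOS"] == pytest.approx(100 * 0.39 / 0.53, abs=1e-8)
        assert sum(p.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_component_is_100(self, library):
        p = percent_contributions(
            resolve_spectrum(_mix(library, {"SN": 0.2}), library)
        )
        assert p["SN"] == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_undefined(self, library):
        result = resolve_spectrum(
            CompositeSpectrum(library.grid, np.zeros(len(library.grid))), library
        )
        with pytest.raises(ValueError, match="undefined"):
            percent_contributions(result)


class TestResolveTimeSeries:
    def test_constant_truth_constant_yields(self, library):
        truth = {"HOS": 0.3, "alphaC": 0.05, "alphaS": 0.1, "SS": 0.08, "SN": 0.02}
        g = np.array([truth[n] for n in library.names])
        F = 48133.0
        A = np.tile(library.design_matrix() @ g / F, (8, 1))
        dataset = TransientAbsorptionDataset(
            wavelengths=library.grid,
            times=np.geomspace(2e-7, 4e-4, 8),
            absorbance=A,
            dose_factor=F,
        )
        series = resolve_time_series(dataset, library)
        for name in library.names:
            np.testing.assert_allclose(
                series.yields[name], truth[name], atol=1e-9
            )

    def test_conservation_against_kinetics_truth(self, library, scheme, rates):
        """Noiseless scheme-driven data: resolved total G(t) equals the
        simulated total of the observable components at every delay."""
        spec = SyntheticDatasetSpec(
            scheme=scheme, rates=rates, library=library, noise_sigma=0.0,
            times=np.geomspace(2e-7, 4e-4, 20),
        )
        dataset = generate_dataset(spec)
        series = resolve_time_series(dataset, library)
        np.testing.assert_allclose(
            series.total, dataset.truth_total(), rtol=1e-6
        )

    def test_late_delay_leaves_only_alpha_s(self, library, scheme, rates):
        """By ~5 ms every transient except the terminal alphaS radical
        has decayed; the resolver must see a single component."""
        spec = SyntheticDatasetSpec(
            scheme=scheme, rates=rates, library=library,
            times=np.geomspace(2e-7, 5e-3, 25),
        )
        series = resolve_time_series(generate_dataset(spec), library)
        for name in ("HOS", "alphaC", "SS", "SN"):
            assert series.yields[name][-1] < 1e-9
        assert series.yields["alphaS"][-1] > 0.1

    def test_failure_names_the_delay(self, library):
        dataset = TransientAbsorptionDataset(
            wavelengths=library.grid,
            times=np.array([1e-6, 2e-6]),
            absorbance=np.zeros((2, len(library.grid))),
            dose_factor=48133.0,
        )
        dataset.absorbance[1, 0] = np.nan
        with pytest.raises(RuntimeError, match="2.000e-06"):
            resolve_time_series(dataset, library)

    def test_residual_scales_linearly_with_noise(self, library, scheme, rates):
        sigmas = [1e-4, 2e-4, 4e-4]
        means = []
        for sigma in sigmas:
            spec = SyntheticDatasetSpec(
                scheme=scheme, rates=rates, library=library,
                noise_sigma=sigma, seed=11,
                times=np.geomspace(2e-7, 4e-4, 15),
            )
            series = resolve_time_series(generate_dataset(spec), library)
            means.append(series.residual_norms.mean())
        ratios = np.diff(np.log(means)) / np.log(2)
        np.testing.assert_allclose(ratios, 1.0, atol=0.15)
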