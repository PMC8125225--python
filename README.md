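# pulsekin

Analysis toolkit for pulse-radiolysis transient-absorption studies of
methionine model peptides oxidised by hydroxyl radicals.

When HO• attacks the thioether of a methionine residue (modelled by
Ac-Met-OMe so the terminal amine/carboxylate cannot interfere), a
cascade of sulfur-centred and carbon-centred radicals follows:
the sulfuranyl adduct HOS•, the sulfide radical cation S•⁺ and its
two-centre three-electron complexes SS•⁺ and SN•, and the
α-(alkylthio)alkyl (αS•) and backbone αC• radicals. Quantifying this
cascade from time-resolved absorbance data takes four steps, each of
which this package implements as a tested module:

1. **dosimetry** — radiation-chemical yields (G, µmol J⁻¹) from the
   Schuler scavenging formula, G(S•) = g₀ + g₁√(a[S])/(1+√(a[S])), and
   conversion of absorbance to Gε(λ) units via the thiocyanate
   dosimeter factor F = ε₄₇₂·G((SCN)₂•⁻)/A₄₇₂;
2. **spectral_library / resolution** — decomposition of each composite
   spectrum, Gε(λi) = Σj εj(λi)·Gj, into per-radical yields Gj by
   nonnegative least squares against parametric reference bands
   anchored at the published (λmax, ε) pairs;
3. **kinetics** — exact simulation of the first-order radical
   transformation network, formation/decay fitting that corrects the
   formation constant for decay during the rise, and rate-constant
   arithmetic (pseudo-first-order ↔ second-order, K = k_f/k_r,
   pH-driven rates);
4. **products** — diastereomer enumeration of radical-coupling dimers
   under swap/mirror symmetry, statistical coupling ratios (r²:2r:1),
   and monoisotopic-mass / neutral-loss arithmetic for peak assignment.

A **synthetic_data** module generates seeded, ground-truth-tagged
A(λ, t) datasets (kinetics → ε mixing → dose scaling → Gaussian noise)
so the whole chain is testable without an accelerator.

## Worked example

```python
import numpy as np
from pulsekin import (
    ScavengerContext, schuler_yield, build_default_library,
    KineticScheme, RateConstantSet, simulate_scheme,
    resolve_spectrum, generate_fixed_composition_spectrum,
    fit_formation_decay,
)

# Yield available at 0.2 mM substrate
g0 = schuler_yield(ScavengerContext(2e-4))
print(f"G(scavenged) = {g0:.3f} umol/J")           # 0.557 umol/J

# Resolve a composite spectrum at the early-time composition
lib = build_default_library()
composite, _ = generate_fixed_composition_spectrum(
    0.53, {"HOS": 73.6, "alphaS": 1.9, "alphaC": 11.35}, lib)
res = resolve_spectrum(composite, lib)
print(f"HOS share = {res.percents['HOS']:.1f}%")   # 73.6%

# Simulate the network and fit the sulfuranyl trace
t = np.linspace(5e-8, 1.2e-5, 120)
prof = simulate_scheme(KineticScheme(), RateConstantSet(), g0, t)
print(f"total G at 3 us = {prof.downstream_total()[np.searchsorted(t, 3e-6)]:.2f}")
fit = fit_formation_decay(t, prof["HOS"])
print(f"k_form = {fit.k_form:.3g} /s, k_decay = {fit.k_decay:.3g} /s")
```

Output:

```
G(scavenged) = 0.557 umol/J
HOS share = 73.6%
total G at 3 us = 0.56
k_form = 2.2e+06 /s, k_decay = 5.6e+05 /s
```

The scavenged yield at 0.2 mM is 0.557 µmol J⁻¹; the resolver returns
the exact composition a noiseless composite was built with; the
simulated radical pool reaches the full available hydroxyl yield
(0.56 µmol J⁻¹) by 3 µs because termination is excluded; and the
formation/decay fit recovers the generating constants — the HO• attack
rate at 0.2 mM (2.2×10⁶ s⁻¹) and the HOS• decay (5.6×10⁵ s⁻¹).

A `pulsekin` console script wraps the same functions
(`simulate`, `resolve`, `fit-kinetics`, `simulate-dataset`,
`products enumerate|mass`); see `pulsekin --help`.

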