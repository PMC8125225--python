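# Methods

`pulsekin` implements the computational chain used to analyse
pulse-radiolysis transient-absorption experiments on Ac-Met-OMe, a model
of a methionine residue inside a peptide backbone, oxidised by HO•
radicals in N₂O-saturated water. The chain has four quantitative stages
— dosimetry calibration, spectral resolution, kinetic-network modelling,
and end-product accounting — plus a synthetic-data generator that
replaces the instrument for testing.

## Dosimetry and yield calibration

Radiation-chemical yields (G-values) are expressed in µmol J⁻¹
throughout; concentrations in mol L⁻¹, time in s, molar absorption
coefficients in M⁻¹ cm⁻¹ at 1 cm path length.

The total radical yield available at a scavenger concentration [S]
follows the Schuler scavenging expression

    G(S•) = g₀ + g₁·√(a[S]) / (1 + √(a[S])),

with defaults g₀ = 0.539 µmol J⁻¹, g₁ = 0.307 µmol J⁻¹ and
a = 19.6 L mol⁻¹. This square-root form is the standard one and is the
unique reading that reproduces both published anchor values for these
constants (0.557 µmol J⁻¹ at 0.2 mM; ≈0.635 µmol J⁻¹ at 10 mM — the
latter agrees to 0.3%, consistent with rounding of the constants in
print); a form without the square root misses the 10 mM anchor by ~7%.

Observed absorbances are rescaled to Gε(λ) units by the thiocyanate
dosimeter factor F = ε₄₇₂·G((SCN)₂•⁻)/A₄₇₂ with ε₄₇₂ = 7580 M⁻¹ cm⁻¹
and G = 0.635 µmol J⁻¹. A₄₇₂ is an instrument reading with no canonical
value, so F is configuration, not a derived constant; the default used
by the synthetic generator (48 133, from A₄₇₂ = 0.1) is merely a
plausible magnitude and cancels exactly in every closed-loop analysis.

In N₂O-saturated solution the hydrated electron is converted
quantitatively to HO•, so the available hydroxyl yield is the sum of
the primary e⁻(aq) and HO• yields, 0.28 + 0.28 = 0.56 µmol J⁻¹. The
Fricke dosimeter yield G(Fe³⁺) = 1.61 µmol J⁻¹ is stored as a named
constant only.

## Reference spectra

Resolution needs one ε(λ) curve per transient. The published record
anchors each radical at its (λmax, ε) pair: HOS• 340 nm/3400;
αC• 270 nm/6200 and 370 nm/1800; αS• 290 nm/3000; SS•⁺ 480 nm/6880;
SN• 390 nm/4500 M⁻¹ cm⁻¹. Full literature band shapes are not
reproduced here; each band is modelled as a Gaussian in wavelength with
a default FWHM of 70 nm on a 270–700 nm grid in 2 nm steps (of the
order of the 2.4 nm monochromator resolution). For the two-band αC•
component the band amplitudes are solved from a 2×2 linear system so
the summed curve passes exactly through both printed anchors despite
band overlap.

Any smooth unimodal shape preserves what the resolution stage needs —
identifiability (the default design matrix has condition number ≈ 11)
and the anchor values. Because all quantitative tests are closed loop
(data generated and resolved with the same library), conclusions about
*real* spectra depend on the true band shapes, which may have
asymmetric tails; users ingesting instrument data should supply their
own library JSON. A ±15% uniform rescaling of each component's ε curve
is available as an optional perturbation for robustness studies, off by
default.

## Spectral resolution

Each delay's spectrum is modelled as Gε(λi) = Σj εj(λi)·Gj and solved
for the per-radical yields Gj. Yields are physical, so the default
solver is nonnegative least squares (`scipy.optimize.nnls`); ordinary
least squares is available by flag and agrees with the closed-form
normal-equations solution. Wavelength weighting is uniform (no per-λ
noise model is asserted) and there is no intercept by default; a flat
baseline column can be enabled for offset data. Rank deficiency raises
an error naming the collinear components instead of silently
pseudo-inverting. Percent contributions are 100·Gj/ΣGj.

Time series are resolved slice by slice (absorbance → Gε → NNLS) rather
than by global target analysis with shared kinetic parameters,
mirroring the two-stage procedure the experiment used; kinetic
constants are then extracted from the resolved trajectories.

## Kinetic network

The transformation scheme is a linear first-order network in which the
substrate (≥200-fold excess) makes every bimolecular step pseudo-first
order:

| step | constant | default |
|---|---|---|
| HO• + substrate (total) | k(HO•+1) | 1.1×10¹⁰ M⁻¹ s⁻¹ |
| HOS• → S•⁺ | k_d | 5.6×10⁵ s⁻¹ |
| S•⁺ + substrate → SS•⁺ | k_f | 2.2×10⁹ M⁻¹ s⁻¹ |
| SS•⁺ → S•⁺ | k_r | 3.6×10⁴ s⁻¹ |
| S•⁺ → αS• (fast deprotonation) | | 4.1×10⁵ s⁻¹ |
| S•⁺ → SN• (cyclisation, observed) | | 3.7×10⁵ s⁻¹ |
| SN• → αC• | | 8.2×10³ s⁻¹ |
| αC• → sink | | 1.4×10⁶ s⁻¹ |

Primary radiolysis is treated as an instantaneous initial condition —
HO• carries the full Schuler-scavenged yield at t = 0 — because the
e⁻(aq) → HO• conversion is complete well before the first observed
delay (200 ns). The HO• attack is split over three parallel paths with
default branching 0.85 (HOS•), 0.02 (direct αS•), 0.13 (direct αC•).
These fractions are not printed anywhere; the defaults echo the
observed early-time dominance of HOS• (>70% of radicals at 1.1 µs) and
are configurable. No quantitative acceptance check depends on them:
with termination excluded the network conserves total radical
equivalents regardless of branching, which is what fixes the 3 µs total
of 0.56 µmol J⁻¹.

Two deliberate simplifications: the slow αS•-formation channel
(3.6×10⁴ s⁻¹) is not an independent edge — it is the flux through the
SS•⁺ reverse step followed by deprotonation, which is exactly why its
observed rate coincides with the SS•⁺ decay; and radical–radical
termination, which dominates only after ~6 µs, is excluded, so the
model is not meant to reproduce the measured 400 µs total
(0.12 µmol J⁻¹). The αC• decay is routed to an inert sink standing for
the suggested β-fragmentation; the sink is counted in the
radical-equivalent balance.

Because the system is linear with constant coefficients it is solved
exactly with the matrix exponential (`scipy.linalg.expm`) at each
requested time — there is no integrator tolerance to tune and the
solution matches the consecutive-reaction (Bateman) closed form to
floating-point accuracy. Sub-epsilon negative round-off is clipped to
zero.

Formation/decay traces are fitted to the consecutive-reaction
intermediate c(t) = A·k_f/(k_d−k_f)·(e^(−k_f·t) − e^(−k_d·t)) with the
equal-rate limit A·k·t·e^(−kt) handled continuously; this is how a
formation constant is recovered when the species decays appreciably
during its rise. Initial guesses come from the peak position and the
tail log-slope. The two constants of an unconstrained biexponential are
interchangeable up to an amplitude rescaling, so the faster constant is
reported as the rising-phase (`k_form`) by convention. Monotone traces
leave one constant unidentifiable and are flagged (pure decay:
`k_form = inf`).

Rate-constant arithmetic is provided as explicit operations:
second-order constants from pseudo-first-order observations
(k₂ = k_obs/[Q]), equilibrium constants (K = k_f/k_r = 6.1×10⁴ M⁻¹ for
the SS•⁺ equilibrium, so the plateau ratio [SS•⁺]/[S•⁺] = K[1] = 12.2
at 0.2 mM), and proton-driven pseudo-first-order constants
(k₂·10^(−pH)).

## Synthetic datasets

The generator runs the kinetic network, mixes the observable
trajectories (HOS•, αC•, αS•, SS•⁺, SN•; S•⁺ is a fleeting
intermediate without a usable band and the sink is non-absorbing)
through the library, divides by F, and adds i.i.d. Gaussian noise of
constant σ in absorbance space — a detector-like, homoscedastic model
chosen because the resolution stage assumes unweighted least squares.
Default time grid: 200 ns → 400 µs, logarithmic, 60 points, the
experimental observation window. Datasets are bit-for-bit reproducible
per (spec, seed) and carry their ground truth. What passing closed-loop
tests show is that the chain is self-consistent and numerically exact;
they cannot certify band-shape or noise-model assumptions against real
instruments.

Fixed-composition slices (used for the published percentage checks)
allocate any unassigned percentage equally among the unnamed
components; the published record does not print the SS/SN split at each
delay, and recovery of the named components is unaffected by this
convention.

## Product accounting

Diastereomer counting works on abstract R/S labels attached to declared
stereocentres, the level at which the product assignment argument is
made — no CIP perception from molecular graphs. A coupling product's
centres are the fixed S centres inherited from the starting peptide
plus any new centres created at the radical carbons (secondary radical
carbons create one; the primary αS(1)• carbon none). Descriptor strings
are merged under exchange of the two halves of a homo-dimer and, only
when no fixed centre is present, under global mirror inversion
(enantiomer pairs count once; a fixed S centre breaks mirror symmetry).
This reproduces the observed multiplicities: αS(2)–αS(2) 3, αS(2)–αS(1)
2 (five radiolysis dimers in total), CBH–CBH 2 (erythro/threo),
αS(2)–CBH 4. Counts are verified against exhaustive orbit enumeration,
including randomized radicals with up to three new centres.

Statistical coupling proportions for a major:minor radical ratio r are
r² : 2r : 1 (homo-major : cross : homo-minor), normalised. At r = 2
(radiolysis) the minor homo-dimer is 1/9 of couplings; at the r ≈ 5
photolysis ratio it falls below 3%, consistent with its absence from
the chromatogram.

Monoisotopic masses are sums of most-abundant-isotope atomic masses
from the NIST table shipped with pyteomics; [M+H]⁺ adds a true proton
(H minus the 0.55 mDa electron) with a flag to add a neutral H for
legacy comparisons. The published instrument m/z values sit 4–10 ppm
above theory (e.g. αS-dimer [M+H]⁺ theory 409.1462 vs 409.1478–409.1484
printed), so mass checks are data-sanity bounds at 5 mDa, not
equalities. The αS(2)–CBH cross peaks at m/z 414.139x match the
water-loss ion [M+H−H₂O]⁺ (theory 414.1370) within 5 mDa while the
intact adduct (432.1475) does not; the package reports ppm errors for
both hypotheses rather than asserting an assignment.

## Problem sizes and numerical choices

Default analyses use the 216-point wavelength grid and ≤300-point time
grids; the acceptance script resolves two 216-point composites, and
integrates the network on 25 log-spaced points to 3 µs. Fit tolerances
are scipy defaults; NNLS is deterministic; conservation is asserted at
1e-8 relative and closed-loop recovery at 1e-9.

## Known limitations

- Band shapes are parametric Gaussians; resolved percentages on real
  data depend on the true literature spectra.
- Termination kinetics (t > 6 µs decay of the total yield) are out of
  model.
- The 7.5×10⁹ M⁻¹ s⁻¹ constant attributed to the direct αC• path is
  stored as printed alongside the 1.1×10¹⁰ M⁻¹ s⁻¹ overall constant;
  the two are not reconciled (an observed growth of a parallel-branch
  product tracks total precursor consumption, not the branch flux).
- MS support is neutral-loss arithmetic only; no fragmentation
  prediction or isotope envelopes.
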