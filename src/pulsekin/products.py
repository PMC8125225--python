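"""Radical-coupling end products: stereochemistry, statistics and masses.

Radical–radical termination of the α-(alkylthio)alkyl radicals (αS(1)•,
αS(2)•) and of the benzophenone ketyl (CBH•) produces dimers and cross
products whose LC-MS peak multiplicity is fixed by diastereomer
counting: every coupling event may create new stereocentres (R or S)
next to centres inherited from the S-configured starting peptide.  This
module enumerates the distinct diastereomers under the relevant
symmetries, predicts statistical coupling ratios, and does the
monoisotopic-mass and neutral-loss arithmetic used to assign the
high-resolution MS peaks.

Stereodescriptors are abstract R/S labels on declared centres — the
reasoning operates at the level of configuration bookkeeping, not CIP
perception from a molecular graph.  Two descriptor strings describe the
same compound when related by swapping the two halves of a homo-dimer;
global mirror images (R↔S everywhere) are merged only when the product
carries no configurationally fixed centre, since a fixed S centre breaks
mirror symmetry.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping

from pyteomics import mass as _pmass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "StereoRadical",
    "CouplingProduct",
    "ALPHA_S1",
    "ALPHA_S2",
    "CBH",
    "AC_MET_OME",
    "enumerate_diastereomers",
    "coupling_distribution",
    "monoisotopic_mass",
    "mh_plus",
    "neutral_loss_mz",
    "ppm_error",
]

#: Electron rest mass (Da, CODATA).
ELECTRON_MASS = 5.48579909065e-4

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition as sorted (element, count) pairs."""

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, count in self.items:
            if count < 0 or count != int(count):
                raise ValueError(
                    f"count for {element} must be a nonnegative integer, got {count}"
                )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted((el, int(n)) for el, n in counts.items() if n)))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C16H28N2O6S2``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.counts()
        for element, n in other.items:
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula.from_counts(merged)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.items
        )


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass (Da): sum of most-abundant-isotope atomic masses.

    Atomic masses come from the NIST table shipped with pyteomics.
    Unknown elements raise ``KeyError``.
    """
    total = 0.0
    for element, count in formula.items:
        if element not in _pmass.nist_mass:
            raise KeyError(f"unknown element {element!r}")
        total += count * _pmass.nist_mass[element][0][0]
    return total


#: Proton mass (Da): ¹H minus one electron.
PROTON_MASS = _pmass.nist_mass["H"][0][0] - ELECTRON_MASS


def mh_plus(formula: ElementalFormula, electron_correction: bool = True) -> float:
    """m/z of the protonated ion [M+H]⁺.

    By default the attached particle is a true proton (hydrogen atom
    minus one electron).  ``electron_correction=False`` adds a neutral H
    atom instead, for comparison with legacy tables that ignore the
    0.55 mDa electron deficit.
    """
    adduct = PROTON_MASS if electron_correction else _pmass.nist_mass["H"][0][0]
    return monoisotopic_mass(formula) + adduct


def neutral_loss_mz(precursor_mz: float, loss: ElementalFormula) -> float:
    """Fragment m/z after ejection of a neutral of the given composition."""
    m_loss = monoisotopic_mass(loss)
    if m_loss >= precursor_mz:
        raise ValueError(
            f"neutral loss mass {m_loss:.4f} is not below the precursor "
            f"m/z {precursor_mz:.4f}"
        )
    return precursor_mz - m_loss


def ppm_error(theoretical: float, measured: float) -> float:
    """Relative mass error in parts per million: 10⁶·(measured−theory)/theory."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be > 0")
    return 1e6 * (measured - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Stereochemistry

@dataclass(frozen=True)
class StereoRadical:
    """A coupling partner: formula plus stereocentre bookkeeping.

    ``fixed_centers`` lists configurations inherited unchanged from the
    starting material (the peptide α-carbon is fixed at S);
    ``creates_new_center`` is True when the radical carbon becomes a new
    R/S stereocentre upon coupling (secondary radical carbons do, the
    primary αS(1)• carbon does not).
    """

    name: str
    formula: ElementalFormula
    fixed_centers: tuple[str, ...] = ()
    creates_new_center: bool | int = False

    def __post_init__(self) -> None:
        bad = set(self.fixed_centers) - {"R", "S"}
        if bad:
            raise ValueError(f"stereodescriptors must be R or S, got {sorted(bad)}")
        if int(self.creates_new_center) < 0:
            raise ValueError("creates_new_center must be a flag or a count >= 0")

    @property
    def n_new_centers(self) -> int:
        return int(self.creates_new_center)


#: Ac-Met-OMe, the starting model peptide (C₈H₁₅NO₃S).
AC_MET_OME = ElementalFormula.parse("C8H15NO3S")

_AS_FORMULA = ElementalFormula.parse("C8H14NO3S")  # peptide minus one H

#: Primary α-(alkylthio)alkyl radical (•CH₂-S-): coupling carbon never
#: becomes a stereocentre.
ALPHA_S1 = StereoRadical("alphaS1", _AS_FORMULA, fixed_centers=("S",),
                         creates_new_center=False)

#: Secondary α-(alkylthio)alkyl radical (-•CH-S-CH₃): coupling creates a
#: new stereocentre.
ALPHA_S2 = StereoRadical("alphaS2", _AS_FORMULA, fixed_centers=("S",),
                         creates_new_center=True)

#: 3-carboxybenzophenone ketyl radical (C₁₄H₁₁O₃); its carbinol carbon
#: becomes a stereocentre, and it carries no fixed centre.
CBH = StereoRadical("CBH", ElementalFormula.parse("C14H11O3"),
                    creates_new_center=True)


@dataclass(frozen=True)
class CouplingProduct:
    """A radical–radical coupling product and its distinct diastereomers.

    ``stereocenters`` is the ordered descriptor template
    (fixed_A..., new_A..., new_B..., fixed_B... with '?' for variable
    centres); the B half is written in reverse so descriptor strings
    read palindromically across the new bond, matching the usual
    SSSS/SRSS/... notation for such dimers.
    """

    name: str
    formula: ElementalFormula
    stereocenters: tuple[str, ...]
    diastereomers: frozenset[str]
    is_homo: bool

    @property
    def n_stereocenters(self) -> int:
        return len(self.stereocenters)

    @property
    def n_diastereomers(self) -> int:
        return len(self.diastereomers)


_MIRROR = str.maketrans("RS", "SR")

Monomers = tuple[tuple[str, ...], tuple[str, ...]]


def _symmetry_images(pair: Monomers, is_homo: bool, has_fixed: bool) -> set[Monomers]:
    """All center assignments equivalent to ``pair`` under the product's
    symmetry group.

    The state is a pair of per-monomer descriptor tuples
    (fixed centres followed by new centres, in each monomer's own
    order).  Generators: exchanging the two monomers (homo-coupling
    only) and global mirror inversion R↔S (only when no centre is
    configurationally fixed — a fixed S centre breaks mirror symmetry).
    """
    images = {pair}
    if is_homo:
        images |= {(b, a) for a, b in images}
    if not has_fixed:
        images |= {
            tuple(tuple(c.translate(_MIRROR) for c in mono) for mono in img)
            for img in images
        }
        if is_homo:  # closure of swap ∘ inversion
            images |= {(b, a) for a, b in images}
    return images


def _display(pair: Monomers) -> str:
    """Palindromic descriptor string: monomer A forward, monomer B reversed."""
    a, b = pair
    return "".join(a) + "".join(reversed(b))


def enumerate_diastereomers(radA: StereoRadical, radB: StereoRadical) -> CouplingProduct:
    """Enumerate the distinct diastereomers of the A–B coupling product.

    All R/S assignments of the newly created centres are generated and
    merged under monomer swap (homo-coupling only) and, for products
    with no fixed centre, under global mirror inversion (enantiomer
    pairs count once).
    """
    is_homo = radA == radB
    nA, nB = radA.n_new_centers, radB.n_new_centers
    has_fixed = bool(radA.fixed_centers or radB.fixed_centers)
    template = (
        radA.fixed_centers + ("?",) * nA + ("?",) * nB
        + tuple(reversed(radB.fixed_centers))
    )

    canonical: set[str] = set()
    for assignment in itertools.product("RS", repeat=nA + nB):
        pair: Monomers = (
            radA.fixed_centers + assignment[:nA],
            radB.fixed_centers + assignment[nA:],
        )
        images = _symmetry_images(pair, is_homo, has_fixed)
        canonical.add(min(_display(img) for img in images))

    return CouplingProduct(
        name=f"{radA.name}-{radB.name}",
        formula=radA.formula + radB.formula,
        stereocenters=template,
        diastereomers=frozenset(canonical),
        is_homo=is_homo,
    )


def coupling_distribution(r: float) -> dict[str, float]:
    """Statistical termination proportions for two radicals at ratio r.

    With [major]/[minor] = r and purely statistical encounters, the
    homo-major : cross : homo-minor products form in proportions
    r² : 2r : 1, normalised to sum to one.  At r = 2 (radiolysis) the
    minor homo-dimer is 1/9 of couplings; at r = 5 (photolysis) it drops
    below 3%, rationalising its absence from the chromatogram.
    """
    if r <= 0:
        raise ValueError(f"concentration ratio must be > 0, got {r}")
    norm = (r + 1.0) ** 2
    return {
        "homo_major": r * r / norm,
        "cross": 2.0 * r / norm,
        "homo_minor": 1.0 / norm,
    }
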