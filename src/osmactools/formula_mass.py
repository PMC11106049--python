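"""Molecular-formula arithmetic for HRESIMS annotation.

Monoisotopic masses, adduct m/z with electron-mass correction, ppm mass
deviations and degrees of unsaturation (ring-and-double-bond equivalents),
reproducing the arithmetic behind "calcd for ..." annotations in
natural-product isolation reports.

Isotope masses are taken from the NIST table shipped with
:mod:`pyteomics.mass` (monoisotopic, i.e. the lightest / most abundant
isotope of each element, to >=9 decimal places).  Display rounding is
half-up, as used when printing calcd m/z to 4 decimals, and the ppm
deviation is computed against the *displayed* (4-decimal) calculated m/z —
the convention that reproduces printed deviations such as +4.2 ppm for an
observed 547.2215 against calcd 547.2238.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping

from pyteomics.mass import nist_mass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "SUPPORTED_ELEMENTS",
    "ADDUCTS",
    "MolecularFormula",
    "AdductSpec",
    "MassMatch",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "degrees_of_unsaturation",
    "ppm_delta",
    "mass_match",
    "round_half_up",
]

#: CODATA electron rest mass, Da.
ELECTRON_MASS = 0.000548579909

#: Mass of H+ (monoisotopic H minus one electron), Da.
PROTON_MASS = nist_mass["H"][0][0] - ELECTRON_MASS

#: Elements accepted by the parser.  Covers CHNOPS plus the halogens and the
#: alkali metals that appear as adduct partners.
SUPPORTED_ELEMENTS = frozenset(
    {"C", "H", "N", "O", "S", "P", "Na", "K", "F", "Cl", "Br", "I"}
)

#: Monovalent elements counted like hydrogen in the unsaturation formula.
_MONOVALENT = frozenset({"H", "F", "Cl", "Br", "I"})
#: Trivalent elements counted like nitrogen.
_TRIVALENT = frozenset({"N", "P"})

_HILL_FIRST = ("C", "H")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
#: Markup such as ``C_34_H_32_N_2_O_5_`` (subscript underscores) is accepted.
_MARKUP_RE = re.compile(r"[_\s]+")


class FormulaError(ValueError):
    """Malformed formula string, unsupported element or impossible adduct."""


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition of a neutral molecule.

    ``composition`` maps element symbols to strictly positive counts.
    """

    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        for el, n in comp.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element: {el!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "composition", comp)

    def count(self, element: str) -> int:
        return self.composition.get(element, 0)

    def hill_string(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        rest = sorted(el for el in self.composition if el not in _HILL_FIRST)
        order = [el for el in _HILL_FIRST if el in self.composition] + rest
        return "".join(
            f"{el}{self.composition[el]}" if self.composition[el] != 1 else el
            for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_string()


@dataclass(frozen=True)
class AdductSpec:
    """An ionization rule: elements gained/lost and the resulting charge."""

    name: str
    element_delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError(f"adduct {self.name!r} must carry a nonzero charge")


#: Common electrospray adducts.  Keys use ASCII "-"; a Unicode minus sign in
#: lookups is normalized to it.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, +1),
    "[M+K]+": AdductSpec("[M+K]+", {"K": 1}, +1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
}


def _resolve_adduct(adduct: "AdductSpec | str") -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    key = adduct.replace("−", "-").replace("–", "-")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise FormulaError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        ) from None


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C34H32N2O5"`` (or markup ``"C_34_H_32_N_2_O_5_"``) into a
    :class:`MolecularFormula`.  Implicit counts of 1 are expanded; repeated
    element symbols are summed."""
    cleaned = _MARKUP_RE.sub("", text)
    if not cleaned:
        raise FormulaError("empty formula string")
    comp: Dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {cleaned[pos:]!r}"
            )
        el, digits = m.groups()
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for element {el!r} in formula {text!r}")
        comp[el] = comp.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(comp)


def monoisotopic_mass(formula: "MolecularFormula | str") -> float:
    """Monoisotopic (exact) mass of the neutral composition, Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(nist_mass[el][0][0] * n for el, n in formula.composition.items())


def adduct_mz(
    formula: "MolecularFormula | str",
    adduct: "AdductSpec | str" = "[M+H]+",
) -> float:
    """m/z of an adduct ion, full precision.

    (neutral mass + delta-element masses - charge x electron mass) / |charge|.
    The electron-mass correction is what separates e.g. [M+Na]+ from a bare
    "M + Na" sum at the fourth decimal.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    spec = _resolve_adduct(adduct)
    for el, dn in spec.element_delta.items():
        if dn < 0 and formula.count(el) + dn < 0:
            raise FormulaError(
                f"adduct {spec.name} removes more {el} than present in "
                f"{formula.hill_string()}"
            )
    mass = monoisotopic_mass(formula)
    mass += sum(nist_mass[el][0][0] * dn for el, dn in spec.element_delta.items())
    mass -= spec.charge * ELECTRON_MASS
    return mass / abs(spec.charge)


def degrees_of_unsaturation(formula: "MolecularFormula | str") -> float:
    """Ring-and-double-bond equivalents: C + 1 + N/2 - H/2.

    Divalent elements (O, S) do not contribute; halogens count like H and
    P like N.  Integer-valued for even-electron neutral formulas.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    c = formula.count("C")
    h = sum(formula.count(el) for el in _MONOVALENT)
    n = sum(formula.count(el) for el in _TRIVALENT)
    dbe = c + 1 + n / 2 - h / 2
    return int(dbe) if dbe == int(dbe) else dbe


def ppm_delta(observed_mz: float, calculated_mz: float) -> float:
    """(calculated - observed) / calculated x 1e6.

    Sign convention: a positive deviation means the observed ion was lighter
    than calculated, matching printed annotations like "547.2215 ... calcd
    547.2238, delta +4.2 ppm".
    """
    if observed_mz <= 0 or calculated_mz <= 0:
        raise FormulaError("m/z values must be positive")
    return (calculated_mz - observed_mz) / calculated_mz * 1e6


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MassMatch:
    """An observed ion matched against a calculated adduct m/z.

    ``calculated_mz`` is the displayed 4-decimal value and ``ppm_delta`` is
    computed from it (1-decimal display rounding), so the record is
    self-consistent: the stored ppm is recomputable from the two m/z fields.
    """

    observed_mz: float
    calculated_mz: float
    ppm_delta: float
    formula: str = ""
    adduct: str = ""

    def as_dict(self) -> Dict[str, object]:
        return {
            "formula": self.formula,
            "adduct": self.adduct,
            "observed_mz": self.observed_mz,
            "calculated_mz": self.calculated_mz,
            "ppm_delta": self.ppm_delta,
        }


def mass_match(
    formula: "MolecularFormula | str",
    observed_mz: float,
    adduct: "AdductSpec | str",
) -> MassMatch:
    """Match an observed m/z against the calculated adduct m/z of a formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    spec = _resolve_adduct(adduct)
    calc_display = round_half_up(adduct_mz(formula, spec), 4)
    ppm = round_half_up(ppm_delta(observed_mz, calc_display), 1)
    return MassMatch(
        observed_mz=observed_mz,
        calculated_mz=calc_display,
        ppm_delta=ppm,
        formula=formula.hill_string(),
        adduct=spec.name,
    )
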