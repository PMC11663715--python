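"""Molecular-formula algebra, monoisotopic ion m/z, and conjugate libraries.

The exact-mass layer under the whole pipeline.  A :class:`MolecularFormula`
is an element->count mapping supporting addition and subtraction, so that
amide condensation of a phytohormone carboxyl with the amino group of a free
amino acid is literally ``hormone + amino_acid - H2O``.  Ion m/z values are
computed from most-abundant-isotope element masses and include the electron
mass, which is what high-resolution "calcd." values require at the fourth
decimal place (a singly charged anion is one electron heavier than its
neutral-minus-proton mass suggests).

:func:`build_conjugate_library` enumerates every hormone x proteinogenic
amino acid amide conjugate with per-ion m/z values; Leu/Ile (and any other
equal-formula pair) are flagged as mass-indistinguishable.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "IonSpecies",
    "ION_SPECIES",
    "ConjugateEntry",
    "AMINO_ACIDS",
    "DEFAULT_HORMONES",
    "WATER",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "conjugate_formula",
    "build_conjugate_library",
    "library_to_frame",
]

#: Most-abundant-isotope masses in Da (IUPAC/CIAAW atomic mass evaluation,
#: 2021 values). No isotope-pattern modelling anywhere in the package.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825031898,
    "N": 14.003074004251,
    "O": 15.994914619257,
    "P": 30.973761998842,
    "S": 31.972071174414,
    "Na": 22.989769282019,
    "K": 38.963706486449,
    "Cl": 34.968852682,
}

ELECTRON_MASS: float = 0.000548579909065  # Da, CODATA 2018
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string, unknown element, or negative count."""


class MolecularFormula(Mapping[str, int]):
    """Immutable element->count mapping for a neutral molecule or fragment.

    Elements are restricted to :data:`MONOISOTOPIC_MASS`; counts are
    non-negative and zero counts are dropped, so equality is plain count
    equality.  ``+`` and ``-`` act element-wise; subtraction below zero
    raises :class:`FormulaError`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for element, n in (counts or {}).items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"count for {element} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "_counts", clean)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("MolecularFormula is immutable")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # Algebra --------------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "MolecularFormula":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: Mapping[str, int]) -> "MolecularFormula":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) - n
            if counts[element] < 0:
                raise FormulaError(
                    f"subtraction yields negative {element} count in "
                    f"{self.hill()} - {MolecularFormula._hill_of(dict(other))}"
                )
        return MolecularFormula(counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    @staticmethod
    def _hill_of(counts: dict[str, int]) -> str:
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(e for e in counts if e not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        return self._hill_of(self._counts)

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"


#: One water molecule; the leaving group of amide condensation.
WATER: MolecularFormula


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C21H31NO6"``.

    Grammar: element symbol (capital + optional lowercase letter) followed by
    an optional positive integer count.  Round-trips with
    :meth:`MolecularFormula.hill`.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


WATER = parse_formula("H2O")


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of count x isotope mass."""
    try:
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.items())
    except KeyError as exc:  # element outside the mass table
        raise FormulaError(f"element {exc.args[0]!r} missing from mass table") from None


@dataclass(frozen=True)
class IonSpecies:
    """An ionization rule: signed element delta applied to the neutral M.

    ``delta`` may contain negative counts (loss of protons); ``charge`` sign
    must match ``polarity``.  Applying the delta to a neutral formula must
    leave all counts non-negative, otherwise the ion is inapplicable.
    """

    name: str
    polarity: int
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError(f"{self.name}: ion charge cannot be zero")
        if self.polarity not in (1, -1):
            raise ValueError(f"{self.name}: polarity must be +1 or -1")
        if (self.charge > 0) != (self.polarity > 0):
            raise ValueError(f"{self.name}: charge sign must match polarity")
        object.__setattr__(self, "delta", dict(self.delta))


class InapplicableIonError(ValueError):
    """The ion delta would drive an element count below zero."""


#: Singly charged ion species used across the pipeline. Protonated /
#: deprotonated forms are the reference ions; the rest are the adducts the
#: redundancy-cleaning stage looks for.
ION_SPECIES: dict[str, IonSpecies] = {
    ion.name: ion
    for ion in [
        IonSpecies("[M+H]+", +1, {"H": 1}, +1),
        IonSpecies("[M+Na]+", +1, {"Na": 1}, +1),
        IonSpecies("[M+K]+", +1, {"K": 1}, +1),
        IonSpecies("[M+NH4]+", +1, {"N": 1, "H": 4}, +1),
        IonSpecies("[M-H]-", -1, {"H": -1}, -1),
        IonSpecies("[M+Na-2H]-", -1, {"Na": 1, "H": -2}, -1),
        IonSpecies("[M+K-2H]-", -1, {"K": 1, "H": -2}, -1),
        IonSpecies("[M+Cl]-", -1, {"Cl": 1}, -1),
        IonSpecies("[M+HCOO]-", -1, {"C": 1, "H": 1, "O": 2}, -1),
        IonSpecies("[M+NO3]-", -1, {"N": 1, "O": 3}, -1),
        IonSpecies("[M+CH3COO]-", -1, {"C": 2, "H": 3, "O": 2}, -1),
        # sodium-formate cluster on the deprotonated form:
        # [M-H+HCOOH+HCOONa]-; stoichiometry is a configurable choice.
        IonSpecies("[M+HCOO+HCOONa]-", -1, {"C": 2, "H": 2, "O": 4, "Na": 1}, -1),
    ]
}


def ion_mz(neutral: Mapping[str, int], ion: IonSpecies | str) -> float:
    """m/z of ``neutral`` ionized as ``ion``, electron mass included.

    m/z = (monoisotopic(M + delta) - charge * m_e) / |charge|.  Including the
    electron mass is what makes singly charged anion values agree with
    high-resolution calcd. masses at the 4th decimal.
    """
    if isinstance(ion, str):
        ion = ION_SPECIES[ion]
    counts = dict(neutral)
    for element, n in ion.delta.items():
        counts[element] = counts.get(element, 0) + n
        if counts[element] < 0:
            raise InapplicableIonError(
                f"{ion.name} inapplicable to "
                f"{MolecularFormula._hill_of({k: v for k, v in neutral.items() if v})}: "
                f"negative {element} count"
            )
    mass = monoisotopic_mass({e: n for e, n in counts.items() if n})
    return (mass - ion.charge * ELECTRON_MASS) / abs(ion.charge)


def conjugate_formula(
    hormone: MolecularFormula, amino_acid: MolecularFormula
) -> MolecularFormula:
    """Amide-condensation formula: hormone + amino acid - H2O.

    Only count feasibility is checked (both partners jointly supply the
    leaving water; the hormone must be a carbon acid), not structure.
    """
    if hormone.get("C", 0) < 1:
        raise FormulaError(
            f"hormone {hormone.hill() or '(empty)'} has no carbon; "
            "cannot form an amide conjugate"
        )
    return (hormone + amino_acid) - WATER


#: The 20 proteinogenic free amino acids (not residue masses); Sec excluded.
AMINO_ACIDS: dict[str, MolecularFormula] = {
    code: parse_formula(f)
    for code, f in {
        "Gly": "C2H5NO2",
        "Ala": "C3H7NO2",
        "Ser": "C3H7NO3",
        "Pro": "C5H9NO2",
        "Val": "C5H11NO2",
        "Thr": "C4H9NO3",
        "Cys": "C3H7NO2S",
        "Leu": "C6H13NO2",
        "Ile": "C6H13NO2",
        "Asn": "C4H8N2O3",
        "Asp": "C4H7NO4",
        "Gln": "C5H10N2O3",
        "Lys": "C6H14N2O2",
        "Glu": "C5H9NO4",
        "Met": "C5H11NO2S",
        "His": "C6H9N3O2",
        "Phe": "C9H11NO2",
        "Arg": "C6H14N4O2",
        "Tyr": "C9H11NO3",
        "Trp": "C11H12N2O2",
    }.items()
}

#: Default hormone set. The dinor-OPDA neutral formula is reconstructed from
#: its conjugate ion formulas (it is not directly tabulated anywhere);
#: OPDA and jasmonic acid follow from standard oxylipin chemistry.
DEFAULT_HORMONES: dict[str, MolecularFormula] = {
    "dn-iso-OPDA": parse_formula("C16H24O3"),
    "OPDA": parse_formula("C18H28O3"),
    "JA": parse_formula("C12H18O3"),
}


@dataclass(frozen=True)
class ConjugateEntry:
    """One hormone-amino-acid conjugate with per-ion m/z values.

    ``indistinguishable_from`` lists other amino-acid codes of the same
    hormone whose conjugates share this exact formula (Leu/Ile).
    """

    hormone: str
    amino_acid: str
    formula: MolecularFormula
    neutral_mass: float
    mz: Mapping[str, float] = field(default_factory=dict)
    indistinguishable_from: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        aas = "/".join(sorted((self.amino_acid, *self.indistinguishable_from)))
        return f"{self.hormone}-{aas}"


def build_conjugate_library(
    hormones: Mapping[str, MolecularFormula] | Iterable[tuple[str, MolecularFormula]] | None = None,
    ions: Iterable[IonSpecies | str] = ("[M-H]-", "[M+H]+"),
    amino_acids: Mapping[str, MolecularFormula] | None = None,
) -> list[ConjugateEntry]:
    """Enumerate hormone x amino-acid conjugates with per-ion m/z.

    One entry per (hormone, amino acid); equal-formula conjugates of the same
    hormone are cross-flagged as mass-indistinguishable.  An empty hormone
    collection yields an empty library.
    """
    if hormones is None:
        hormones = DEFAULT_HORMONES
    hormone_items = list(hormones.items()) if isinstance(hormones, Mapping) else list(hormones)
    aa_items = list((amino_acids or AMINO_ACIDS).items())
    ion_list = [ION_SPECIES[i] if isinstance(i, str) else i for i in ions]

    entries: list[ConjugateEntry] = []
    for hormone_name, hormone in hormone_items:
        formulas = {aa: conjugate_formula(hormone, f) for aa, f in aa_items}
        by_formula: dict[MolecularFormula, list[str]] = {}
        for aa, f in formulas.items():
            by_formula.setdefault(f, []).append(aa)
        for aa, f in formulas.items():
            twins = tuple(x for x in by_formula[f] if x != aa)
            entries.append(
                ConjugateEntry(
                    hormone=hormone_name,
                    amino_acid=aa,
                    formula=f,
                    neutral_mass=monoisotopic_mass(f),
                    mz={ion.name: ion_mz(f, ion) for ion in ion_list},
                    indistinguishable_from=twins,
                )
            )
    return entries


def library_to_frame(entries: Iterable[ConjugateEntry]) -> pd.DataFrame:
    """Conjugate library as a flat table (one column per ion species)."""
    rows = []
    for e in entries:
        row = {
            "name": f"{e.hormone}-{e.amino_acid}",
            "hormone": e.hormone,
            "amino_acid": e.amino_acid,
            "formula": e.formula.hill(),
            "neutral_mass": e.neutral_mass,
            "mass_indistinguishable_from": ";".join(e.indistinguishable_from),
        }
        row.update(e.mz)
        rows.append(row)
    return pd.DataFrame(rows)
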