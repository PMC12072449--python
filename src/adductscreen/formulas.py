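"""Molecular-formula algebra and adduct-ion mass bookkeeping.

Elemental compositions are the currency of the whole pipeline: every ion
species observed in a post-column nucleoside-addition experiment —
[M+H]+, [M−H]−, [M+HCOO]−, [M+Cl]−, [M+dG+H]+, [M+G+H]+ — is a sum (or
difference) of neutral compositions, and both its monoisotopic m/z and its
unit-resolution nominal m/z follow from the composition by table lookup.

Isotope masses come from the NIST table shipped with :mod:`pyteomics`
(``pyteomics.mass.nist_mass``). Nominal masses are computed from the integer
mass number of each element's most abundant isotope (C=12, H=1, N=14, O=16,
Cl=35, ...), never by rounding the monoisotopic float: rounding drifts for
large compositions, while the mass-number sum reproduces the m/z values a
unit-resolution quadrupole reports.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from pyteomics.mass import nist_mass

__all__ = [
    "ElementCounts",
    "Attachment",
    "AdductIon",
    "Compound",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "combine",
    "subtract",
    "monoisotopic_mass",
    "nominal_mass",
    "dof",
    "make_adduct",
    "read_panel",
    "DEOXYGUANOSINE",
    "GUANOSINE",
    "NUCLEOSIDES_BY_NAME",
    "PROTON",
    "FORMATE",
    "CHLORIDE",
    "ELECTRON_MASS",
]

#: Electron rest mass in Da. Deliberately ignored in m/z values: at
#: ±0.00055 Da it is far below the unit-resolution use case served here.
ELECTRON_MASS = 0.00054857990907


class FormulaError(ValueError):
    """Raised for malformed formulas or compositions violating invariants."""


def _most_abundant_isotope(symbol: str) -> tuple[int, float]:
    """(mass number, exact mass) of the most abundant isotope of *symbol*."""
    isotopes = nist_mass[symbol]
    number = max(
        (k for k in isotopes if k != 0), key=lambda k: isotopes[k][1]
    )
    return number, isotopes[number][0]


class ElementCounts(Mapping[str, int]):
    """Immutable element → count mapping with strictly positive counts.

    Behaves as a read-only mapping and supports ``+`` / ``-`` for the
    composition algebra. Zero counts are never stored; subtraction below
    zero raises.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        cleaned: dict[str, int] = {}
        for symbol, n in counts.items():
            if symbol not in nist_mass:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(
                    f"count for {symbol} must be an integer, got {n!r}"
                )
            if n < 0:
                raise FormulaError(f"negative count for {symbol}: {n}")
            if n > 0:
                cleaned[symbol] = n
        if not cleaned:
            raise FormulaError("empty composition (total atom count 0)")
        self._counts = cleaned

    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementCounts):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementCounts({format_formula(self)!r})"

    @property
    def atom_count(self) -> int:
        """Total number of atoms N."""
        return sum(self._counts.values())

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        return combine([self, other])

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        return subtract(self, other)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-notation formula string such as ``"C10H13N5O4"``.

    The accepted grammar is ``(ElementSymbol Count?)+`` with counts ≥ 1; no
    parentheses, isotope labels, or charge signs. Repeated symbols are
    summed.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r} at position {pos}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in nist_mass:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {text!r}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return ElementCounts(counts)


def format_formula(c: ElementCounts) -> str:
    """Render a composition in Hill order (C, H, then alphabetical)."""
    symbols = sorted(c)
    ordered: list[str] = []
    for special in ("C", "H"):
        if special in c:
            ordered.append(special)
            symbols.remove(special)
    if "C" not in c:
        # Hill convention: without carbon, everything is alphabetical.
        ordered = sorted(ordered + symbols)
    else:
        ordered += symbols
    return "".join(
        s if c[s] == 1 else f"{s}{c[s]}" for s in ordered
    )


def combine(parts: Iterable[ElementCounts]) -> ElementCounts:
    """Element-wise sum of compositions (e.g. ligand ⊕ nucleoside ⊕ H)."""
    parts = list(parts)
    if not parts:
        raise FormulaError("combine() requires at least one composition")
    total: dict[str, int] = {}
    for part in parts:
        for symbol, n in part.items():
            total[symbol] = total.get(symbol, 0) + n
    return ElementCounts(total)


def subtract(c: ElementCounts, removed: ElementCounts) -> ElementCounts:
    """Element-wise difference; raises if any count would go negative."""
    total = dict(c)
    for symbol, n in removed.items():
        have = total.get(symbol, 0)
        if have < n:
            raise FormulaError(
                f"cannot remove {symbol}{n} from {format_formula(c)}"
            )
        total[symbol] = have - n
    return ElementCounts(total)


def monoisotopic_mass(c: ElementCounts) -> float:
    """Exact mass in Da using each element's most abundant isotope."""
    return sum(n * _most_abundant_isotope(s)[1] for s, n in c.items())


def nominal_mass(c: ElementCounts) -> int:
    """Integer mass from most-abundant-isotope mass numbers."""
    return sum(n * _most_abundant_isotope(s)[0] for s, n in c.items())


def dof(c: ElementCounts) -> int:
    """Vibrational degrees of freedom, 3N − 6 for an N-atom species.

    The convention counts every atom of the ion's composition, including any
    added proton. Undefined for N < 3 (atoms and the linear-molecule 3N − 5
    case are outside this pipeline's scope).
    """
    n = c.atom_count
    if n < 3:
        raise FormulaError(f"DOF 3N−6 undefined for N={n} (< 3 atoms)")
    return 3 * n - 6


# ---------------------------------------------------------------------------
# Adduct ions

DEOXYGUANOSINE = parse_formula("C10H13N5O4")
GUANOSINE = parse_formula("C10H13N5O5")
PROTON = parse_formula("H")
FORMATE = parse_formula("CHO2")
CHLORIDE = parse_formula("Cl")

#: Post-column reagent nucleosides by their conventional short names.
NUCLEOSIDES_BY_NAME = {"dG": DEOXYGUANOSINE, "G": GUANOSINE}


class Attachment(str, Enum):
    """Ion-forming attachment species observed in ESI for this assay."""

    PROTON_ADD = "proton_add"            # [M+H]+
    PROTON_LOSS = "proton_loss"          # [M−H]−
    FORMATE_ADD = "formate_add"          # [M+HCOO]−
    CHLORIDE_ADD = "chloride_add"        # [M+Cl]−
    NUCLEOSIDE_PROTON_ADD = "nucleoside_proton_add"  # [M+dG/G+H]+


_ATTACHMENT_LABEL = {
    Attachment.PROTON_ADD: "[M+H]+",
    Attachment.PROTON_LOSS: "[M-H]-",
    Attachment.FORMATE_ADD: "[M+HCOO]-",
    Attachment.CHLORIDE_ADD: "[M+Cl]-",
}


@dataclass(frozen=True)
class AdductIon:
    """A singly charged ion: ligand plus attachment species (± nucleoside).

    ``mz_mono`` is the monoisotopic mass of the composition per unit charge
    (electron mass ignored); ``mz_nominal`` the integer mass-number sum; and
    ``dof`` the 3N − 6 vibrational degree-of-freedom count over the entire
    ion composition.
    """

    ligand: ElementCounts
    attachment: Attachment
    nucleoside: ElementCounts | None
    charge: int
    composition: ElementCounts
    mz_mono: float
    mz_nominal: int
    dof: int

    @property
    def label(self) -> str:
        if self.attachment is Attachment.NUCLEOSIDE_PROTON_ADD:
            nuc = "dG" if self.nucleoside == DEOXYGUANOSINE else (
                "G" if self.nucleoside == GUANOSINE
                else format_formula(self.nucleoside)
            )
            return f"[M+{nuc}+H]+"
        return _ATTACHMENT_LABEL[self.attachment]


def make_adduct(
    ligand: ElementCounts,
    species: Attachment | str,
    nucleoside: ElementCounts | None = None,
) -> AdductIon:
    """Build the :class:`AdductIon` for *ligand* and an attachment species.

    ``nucleoside`` must be given exactly for
    :attr:`Attachment.NUCLEOSIDE_PROTON_ADD` (dG or G in practice, any
    composition accepted). Deprotonation of an H-free ligand is rejected.
    """
    species = Attachment(species)
    if (nucleoside is not None) != (
        species is Attachment.NUCLEOSIDE_PROTON_ADD
    ):
        raise FormulaError(
            "nucleoside must be supplied iff species is nucleoside_proton_add"
        )
    if species is Attachment.PROTON_ADD:
        composition, charge = combine([ligand, PROTON]), +1
    elif species is Attachment.PROTON_LOSS:
        if ligand.get("H", 0) < 1:
            raise FormulaError(
                f"cannot deprotonate H-free composition "
                f"{format_formula(ligand)}"
            )
        composition, charge = subtract(ligand, PROTON), -1
    elif species is Attachment.FORMATE_ADD:
        composition, charge = combine([ligand, FORMATE]), -1
    elif species is Attachment.CHLORIDE_ADD:
        composition, charge = combine([ligand, CHLORIDE]), -1
    else:  # NUCLEOSIDE_PROTON_ADD
        composition, charge = combine([ligand, nucleoside, PROTON]), +1
    return AdductIon(
        ligand=ligand,
        attachment=species,
        nucleoside=nucleoside,
        charge=charge,
        composition=composition,
        mz_mono=monoisotopic_mass(composition),
        mz_nominal=nominal_mass(composition),
        dof=dof(composition),
    )


# ---------------------------------------------------------------------------
# Compound panel I/O

@dataclass(frozen=True)
class Compound:
    """One panel entry: a named ligand with its retention-time window."""

    name: str
    formula: ElementCounts
    rt_min: float
    rt_max: float
    compound_class: str = ""

    def __post_init__(self) -> None:
        if not self.rt_min < self.rt_max:
            raise ValueError(
                f"{self.name}: rt_min ({self.rt_min}) must be < rt_max "
                f"({self.rt_max})"
            )


_PANEL_COLUMNS = ("name", "formula", "rt_min", "rt_max")


def read_panel(path: str | Path) -> list[Compound]:
    """Read a compound panel from CSV/TSV.

    Required columns: ``name, formula, rt_min, rt_max``; optional ``class``.
    Parse failures are reported with the offending row's name.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in _PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"panel {path} missing columns: {missing}")
    compounds = []
    for _, row in table.iterrows():
        try:
            formula = parse_formula(str(row["formula"]))
        except FormulaError as exc:
            raise FormulaError(f"row {row['name']!r}: {exc}") from exc
        cls = row.get("class", "")
        compounds.append(
            Compound(
                name=str(row["name"]),
                formula=formula,
                rt_min=float(row["rt_min"]),
                rt_max=float(row["rt_max"]),
                compound_class="" if pd.isna(cls) else str(cls),
            )
        )
    if not compounds:
        raise ValueError(f"panel {path} contains no compounds")
    return compounds
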