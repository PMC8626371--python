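"""Elements, isotopes, molecular formulas, peptides and m/z.

The isotope reference table (exact masses and natural abundances) ships as
an editable YAML file; :func:`default_isotope_table` loads it once.  All
mass arithmetic in the package goes through this table so that a user
override propagates consistently.

Formulas are plain element->count mappings with algebra (`+`, `-`,
integer `*`).  Peptide compositions come from the standard residue table
(via :mod:`pyteomics`), plus an N-/C-terminal water and any modification
deltas.  Only protonated ions are modelled.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from pyteomics import mass as _pmass

from .errors import (
    FormulaParseError,
    InvalidLabelError,
    UnknownElementError,
    UnknownModificationError,
    UnknownResidueError,
)

#: Mass of a proton in Da; the only adduct supported is protonation.
PROTON_MASS = 1.007276

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Isotope:
    """One stable isotope of an element."""

    element: str
    mass_number: int
    mass: float  # Da
    abundance: float  # mole fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"abundance out of [0,1]: {self.abundance!r}")
        if abs(self.mass - self.mass_number) >= 0.2:
            raise ValueError(
                f"exact mass {self.mass} inconsistent with mass number "
                f"{self.mass_number}"
            )

    @property
    def key(self) -> str:
        """Canonical code such as ``'C13'``."""
        return f"{self.element}{self.mass_number}"


class IsotopeTable:
    """Per-element ordered isotope lists with a designated principal isotope.

    The principal isotope is the most abundant one (for the elements of
    organic chemistry this is also the lightest).  Heavy-isotope mass
    shifts are always relative to the principal isotope.
    """

    def __init__(self, isotopes: Mapping[str, list[Isotope]]):
        self._table: dict[str, tuple[Isotope, ...]] = {}
        self._principal: dict[str, Isotope] = {}
        for element, species in isotopes.items():
            ordered = tuple(sorted(species, key=lambda s: s.mass_number))
            total = sum(s.abundance for s in ordered)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances of {element} sum to {total}, not 1"
                )
            self._table[element] = ordered
            self._principal[element] = max(ordered, key=lambda s: s.abundance)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IsotopeTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            {
                el: [Isotope(el, s["mass_number"], s["mass"], s["abundance"])
                     for s in entries]
                for el, entries in raw.items()
            }
        )

    def elements(self) -> Iterator[str]:
        return iter(self._table)

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def isotopes(self, element: str) -> tuple[Isotope, ...]:
        try:
            return self._table[element]
        except KeyError:
            raise UnknownElementError(element) from None

    def principal(self, element: str) -> Isotope:
        try:
            return self._principal[element]
        except KeyError:
            raise UnknownElementError(element) from None

    def heavy_isotopes(self, element: str) -> tuple[Isotope, ...]:
        """Non-principal isotopes of *element*, ascending mass."""
        p = self.principal(element)
        return tuple(s for s in self.isotopes(element) if s is not p)

    def isotope(self, element: str, mass_number: int) -> Isotope:
        for s in self.isotopes(element):
            if s.mass_number == mass_number:
                return s
        raise UnknownElementError(f"{element}{mass_number}")

    def shift(self, element: str, mass_number: int) -> float:
        """Exact mass shift of an isotope relative to the principal one."""
        return self.isotope(element, mass_number).mass - self.principal(element).mass


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """The packaged natural-abundance table (loaded once, cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("skewcor.data") / "isotopes.yaml"
        ) as p:
            _DEFAULT_TABLE = IsotopeTable.from_yaml(p)
    return _DEFAULT_TABLE


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping):
    """Immutable element->count mapping with formula algebra.

    Supports ``+``, ``-`` (raises on negative counts) and multiplication
    by a non-negative integer.  Zero counts are dropped.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if n < 0 or n != int(n):
                raise FormulaParseError(
                    f"count for {el} must be a non-negative integer, got {n!r}"
                )
            if n:
                clean[el] = int(n)
        self._counts = dict(sorted(clean.items()))

    @classmethod
    def parse(cls, text: str, table: IsotopeTable | None = None) -> "Formula":
        """Parse ``'C46H83N15O14'``-style strings.

        An element symbol may be followed by a positive integer count
        (default 1); whitespace between tokens is tolerated.  Repeated
        symbols accumulate.
        """
        table = table or default_isotope_table()
        stripped = re.sub(r"\s+", "", text)
        if not stripped:
            raise FormulaParseError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(stripped):
            m = _FORMULA_TOKEN.match(stripped, pos)
            if not m or not m.group(1):
                raise FormulaParseError(
                    f"malformed formula {text!r} at position {pos}"
                )
            el, digits = m.group(1), m.group(2)
            if el not in table:
                raise UnknownElementError(el)
            n = int(digits) if digits else 1
            if n <= 0:
                raise FormulaParseError(f"count for {el} must be positive")
            counts[el] = counts.get(el, 0) + n
            pos = m.end()
        return cls(counts)

    # Mapping interface
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise FormulaParseError(
                    f"subtraction yields negative {el} count"
                )
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self._counts!r})"

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self._counts.items()
        )

    def total_atoms(self) -> int:
        return sum(self._counts.values())


@dataclass(frozen=True)
class Modification:
    """A named composition delta added to a peptide (e.g. acetyl = C2H2O)."""

    name: str
    delta: Formula


_MOD_DICT: dict[str, Modification] | None = None


def default_modifications() -> dict[str, Modification]:
    """The shipped modification dictionary (acetyl, phospho, methyl, ...)."""
    global _MOD_DICT
    if _MOD_DICT is None:
        with resources.as_file(
            resources.files("skewcor.data") / "modifications.yaml"
        ) as p:
            _MOD_DICT = load_modifications(p)
    return _MOD_DICT


def load_modifications(path: str | Path) -> dict[str, Modification]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: Modification(name, Formula.parse(f)) for name, f in raw.items()}


def parse_formula(text: str, table: IsotopeTable | None = None) -> Formula:
    """Alias for :meth:`Formula.parse`."""
    return Formula.parse(text, table)


def peptide_formula(
    sequence: str,
    modifications: list[str | Modification] | None = None,
) -> Formula:
    """Elemental composition of a peptide plus modifications.

    The composition is the sum of the standard residue compositions, one
    water for the termini, and each modification's delta.  Modifications
    may be given by name (resolved against the shipped dictionary) or as
    :class:`Modification` objects.
    """
    bad = set(sequence) - _STANDARD_RESIDUES
    if bad or not sequence:
        raise UnknownResidueError(
            f"non-standard residue(s) {sorted(bad)!r} in {sequence!r}"
        )
    comp = _pmass.Composition(sequence=sequence)
    formula = Formula(dict(comp))
    mods = default_modifications()
    for mod in modifications or []:
        if isinstance(mod, str):
            if mod not in mods:
                raise UnknownModificationError(mod)
            mod = mods[mod]
        formula = formula + mod.delta
    return formula


class LabelSpec:
    """An isotope-label signature: tracer isotope -> number of labelled atoms.

    A label like ``{13C: 2, 15N: 1}`` identifies one measured isotopologue.
    Its exact mass shift is the sum of per-atom heavy-minus-principal mass
    differences.  ``'No label'`` is the empty label with zero shift.

    The canonical string grammar is a space-separated list of
    ``<count><element><mass number>`` tokens, e.g. ``'2C13 1N15'``, or the
    literal ``'No label'``.
    """

    _TOKEN = re.compile(r"^(\d+)([A-Z][a-z]?)([1-9]\d*)$")

    def __init__(self, counts: Mapping[tuple[str, int], int] | None = None):
        clean: dict[tuple[str, int], int] = {}
        for (el, mn), n in (counts or {}).items():
            if n < 0:
                raise InvalidLabelError(f"negative label count for {el}{mn}")
            if n:
                clean[(el, mn)] = int(n)
        self._counts = dict(sorted(clean.items()))

    @classmethod
    def parse(cls, text: str, table: IsotopeTable | None = None) -> "LabelSpec":
        table = table or default_isotope_table()
        stripped = text.strip()
        if stripped.lower() in {"no label", "nolabel", "unlabelled", "unlabeled"}:
            return cls()
        counts: dict[tuple[str, int], int] = {}
        for token in stripped.split():
            m = cls._TOKEN.match(token)
            if not m:
                raise InvalidLabelError(
                    f"cannot parse label token {token!r}; expected e.g. "
                    "'2C13', '1N15' or the literal 'No label'"
                )
            n, el, mn = int(m.group(1)), m.group(2), int(m.group(3))
            if n == 0:
                raise InvalidLabelError(f"zero count in label token {token!r}")
            try:
                iso = table.isotope(el, mn)
            except UnknownElementError:
                raise InvalidLabelError(
                    f"unknown isotope code {el}{mn} in {text!r}"
                ) from None
            if iso is table.principal(el):
                raise InvalidLabelError(
                    f"{el}{mn} is the principal isotope; it cannot be a tracer"
                )
            counts[(el, mn)] = counts.get((el, mn), 0) + n
        return cls(counts)

    def items(self):
        return self._counts.items()

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, LabelSpec):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    @property
    def name(self) -> str:
        if not self._counts:
            return "No label"
        return " ".join(f"{n}{el}{mn}" for (el, mn), n in self._counts.items())

    def __repr__(self) -> str:
        return f"LabelSpec({self.name!r})"

    def exact_shift(self, table: IsotopeTable | None = None) -> float:
        """Exact neutral-mass shift of this label in Da (>= 0)."""
        table = table or default_isotope_table()
        return sum(n * table.shift(el, mn) for (el, mn), n in self._counts.items())

    def element_counts(self) -> dict[str, int]:
        """Number of labelled atoms per element (summed over isotopes)."""
        out: dict[str, int] = {}
        for (el, _), n in self._counts.items():
            out[el] = out.get(el, 0) + n
        return out

    def validate_for(self, formula: Formula) -> None:
        for el, n in self.element_counts().items():
            if n > formula.get(el, 0):
                raise InvalidLabelError(
                    f"label {self.name!r} needs {n} {el} atoms but formula "
                    f"{formula} has {formula.get(el, 0)}"
                )


NO_LABEL = LabelSpec()


def residual_formula(formula: Formula, label: LabelSpec) -> Formula:
    """Atoms of *formula* still able to carry natural heavy isotopes.

    Labelled atoms are isotopically defined by the tracer, so they are
    removed from the pool over which natural abundance acts; once every
    atom of an element is labelled, no heavier natural species of that
    element can occur.
    """
    label.validate_for(formula)
    counts = dict(formula)
    for el, n in label.element_counts().items():
        counts[el] = counts[el] - n
    return Formula(counts)


def monoisotopic_mass(
    formula: Formula,
    label: LabelSpec | None = None,
    table: IsotopeTable | None = None,
) -> float:
    """Neutral monoisotopic mass, with an optional label shift applied."""
    table = table or default_isotope_table()
    if not formula:
        raise FormulaParseError("empty formula has no mass")
    m = sum(n * table.principal(el).mass for el, n in formula.items())
    if label is not None:
        label.validate_for(formula)
        m += label.exact_shift(table)
    return m


def monoisotopic_mz(
    formula: Formula,
    charge: int,
    label: LabelSpec | None = None,
    table: IsotopeTable | None = None,
) -> float:
    """m/z of the [M + zH]^z+ ion (protonation only)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(formula, label, table) + charge * PROTON_MASS) / charge
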