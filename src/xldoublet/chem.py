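"""Elemental-composition arithmetic, peptide masses, and cleavable-crosslinker models.

All masses are monoisotopic and in Dalton. Compositions are exact integer
element counts, so complementarity checks (stub + complement == spacer) are
exact, not floating-point approximate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "H_MASS",
    "WATER",
    "ConfigError",
    "ElementalComposition",
    "Peptide",
    "CrosslinkerDefinition",
    "DeltaMassSet",
    "monoisotopic_mass",
    "peptide_mass",
    "stub_masses",
    "doublet_delta_set",
    "stub_fragment_mz",
    "load_crosslinker",
    "bundled_crosslinkers",
]

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.00727646688
#: Mass of a hydrogen atom (H-transfer shifts), Da.
H_MASS = 1.0078250319


class ConfigError(ValueError):
    """Raised for invalid element symbols or inconsistent crosslinker configs."""


def _load_atomic_masses() -> dict[str, float]:
    with resources.files("xldoublet.data").joinpath("atomic_masses.json").open() as fh:
        return json.load(fh)


ATOMIC_MASSES: dict[str, float] = _load_atomic_masses()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition:
    """Immutable bag of element counts with exact integer arithmetic.

    Supports ``+`` and ``-``; subtraction that would produce a negative
    count raises :class:`ValueError`. Zero counts are dropped, so two
    compositions are equal iff they contain the same atoms.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: dict[str, int] = {}
        for symbol, n in (counts or {}).items():
            if symbol not in ATOMIC_MASSES:
                raise ConfigError(f"unknown element symbol: {symbol!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise ConfigError(f"element count for {symbol} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {symbol}: {n}")
            if n > 0:
                clean[symbol] = n
        self._counts = dict(sorted(clean.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula like ``"C2H2OS"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ConfigError(f"cannot parse formula {formula!r} at position {pos}")
            if not match.group(0):
                break
            symbol, digits = match.groups()
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise ConfigError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(counts)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    @property
    def mass(self) -> float:
        return sum(n * ATOMIC_MASSES[el] for el, n in self._counts.items())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for {el}: {self} - {other}"
                )
        return ElementalComposition(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        formula = "".join(f"{el}{n if n > 1 else ''}" for el, n in self._counts.items())
        return f"ElementalComposition({formula or 'empty'})"


WATER = ElementalComposition({"H": 2, "O": 1})

# Standard residue compositions (unmodified, peptide-bond form).
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "G": ElementalComposition.from_formula("C2H3NO"),
    "A": ElementalComposition.from_formula("C3H5NO"),
    "S": ElementalComposition.from_formula("C3H5NO2"),
    "P": ElementalComposition.from_formula("C5H7NO"),
    "V": ElementalComposition.from_formula("C5H9NO"),
    "T": ElementalComposition.from_formula("C4H7NO2"),
    "C": ElementalComposition.from_formula("C3H5NOS"),
    "L": ElementalComposition.from_formula("C6H11NO"),
    "I": ElementalComposition.from_formula("C6H11NO"),
    "N": ElementalComposition.from_formula("C4H6N2O2"),
    "D": ElementalComposition.from_formula("C4H5NO3"),
    "Q": ElementalComposition.from_formula("C5H8N2O2"),
    "K": ElementalComposition.from_formula("C6H12N2O"),
    "E": ElementalComposition.from_formula("C5H7NO3"),
    "M": ElementalComposition.from_formula("C5H9NOS"),
    "H": ElementalComposition.from_formula("C6H7N3O"),
    "F": ElementalComposition.from_formula("C9H9NO"),
    "R": ElementalComposition.from_formula("C6H12N4O"),
    "Y": ElementalComposition.from_formula("C9H9NO2"),
    "W": ElementalComposition.from_formula("C11H10N2O"),
}

RESIDUE_MASSES: dict[str, float] = {r: c.mass for r, c in RESIDUE_COMPOSITIONS.items()}


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with optional fixed modifications and a link site.

    ``fixed_mods`` maps residue letter -> mass delta in Da, applied to every
    occurrence of that residue. ``link_site`` is the 1-based index of the
    crosslinked residue (``None`` when not applicable).
    """

    sequence: str
    fixed_mods: Mapping[str, float] = field(default_factory=dict)
    link_site: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASSES)
        if bad:
            raise ValueError(f"unknown residues in sequence: {sorted(bad)}")
        if self.link_site is not None and not (1 <= self.link_site <= len(self.sequence)):
            raise ValueError(
                f"link_site {self.link_site} outside sequence of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> list[float]:
        """Per-residue masses with fixed modifications applied."""
        return [
            RESIDUE_MASSES[r] + self.fixed_mods.get(r, 0.0) for r in self.sequence
        ]


@dataclass(frozen=True)
class DeltaMassSet:
    """The doublet delta mass and its hydrogen-shift variants, sorted ascending."""

    base_delta: float
    variants: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("delta-mass variants must be distinct")
        if any(b < a for a, b in zip(self.variants, self.variants[1:])):
            raise ValueError("delta-mass variants must be sorted ascending")


@dataclass(frozen=True)
class CrosslinkerDefinition:
    """An MS-cleavable crosslinker: spacer, stub compositions and doublet model.

    ``stubs`` is ordered; stub masses must strictly increase in the declared
    label order. ``complement_pairs`` lists label pairs whose compositions sum
    exactly to the spacer (one stub ends up on each peptide).
    """

    name: str
    spacer: ElementalComposition
    stubs: Mapping[str, ElementalComposition]
    doublet_pair: tuple[str, str]
    complement_pairs: tuple[tuple[str, str], ...] = ()
    hydrogen_shifts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        labels = list(self.stubs)
        if len(labels) < 2:
            raise ConfigError(f"{self.name}: need at least two stub labels")
        for label in self.doublet_pair:
            if label not in self.stubs:
                raise ConfigError(f"{self.name}: doublet label {label!r} not among stubs")
        masses = [self.stubs[l].mass for l in labels]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ConfigError(
                f"{self.name}: stub masses must strictly increase in label order"
            )
        for l1, l2 in self.complement_pairs:
            if self.stubs[l1] + self.stubs[l2] != self.spacer:
                raise ConfigError(
                    f"{self.name}: complementary pair {l1}+{l2} does not sum to spacer"
                )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CrosslinkerDefinition":
        def comp(value) -> ElementalComposition:
            if isinstance(value, str):
                return ElementalComposition.from_formula(value)
            return ElementalComposition(value)

        return cls(
            name=raw["name"],
            spacer=comp(raw["spacer"]),
            stubs={label: comp(c) for label, c in raw["stubs"].items()},
            doublet_pair=tuple(raw["doublet_pair"]),
            complement_pairs=tuple(tuple(p) for p in raw.get("complement_pairs", ())),
            hydrogen_shifts=tuple(raw.get("hydrogen_shifts", (0,))),
        )

    @classmethod
    def from_json(cls, path) -> "CrosslinkerDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def bundled_crosslinkers() -> list[str]:
    """Names of crosslinker configs shipped with the package."""
    return ["UCCL", "DSSO", "DSBU"]


def load_crosslinker(name: str) -> CrosslinkerDefinition:
    """Load a bundled crosslinker config by name (case-insensitive)."""
    key = name.lower()
    if key not in {"uccl", "dsso", "dsbu"}:
        raise ConfigError(f"no bundled crosslinker named {name!r}")
    with resources.files("xldoublet.data").joinpath(f"{key}.json").open() as fh:
        return CrosslinkerDefinition.from_dict(json.load(fh))


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass of a composition in Da."""
    return composition.mass


def peptide_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic peptide mass: residue sum + one water + fixed mods."""
    return sum(peptide.residue_masses()) + WATER.mass


def stub_masses(xl: CrosslinkerDefinition) -> dict[str, float]:
    """Neutral mass of each stub remnant, keyed by label, in declared order."""
    return {label: comp.mass for label, comp in xl.stubs.items()}


def doublet_delta_set(
    xl: CrosslinkerDefinition, shifts: Iterable[int] | None = None
) -> DeltaMassSet:
    """Delta masses between the trigger doublet's stubs, with H-shift variants.

    ``shifts`` defaults to the config's ``hydrogen_shifts``. The base delta is
    heavier-stub mass minus lighter-stub mass; each variant adds ``k`` H-atom
    masses.
    """
    shifts = tuple(xl.hydrogen_shifts if shifts is None else shifts)
    if not shifts:
        raise ValueError("shifts must be non-empty")
    l1, l2 = xl.doublet_pair
    m1, m2 = xl.stubs[l1].mass, xl.stubs[l2].mass
    base = abs(m2 - m1)
    variants = tuple(sorted(base + k * H_MASS for k in shifts))
    return DeltaMassSet(base_delta=base, variants=variants)


def stub_fragment_mz(
    peptide: Peptide,
    xl: CrosslinkerDefinition,
    label: str,
    shift: int = 0,
    charge: int = 1,
) -> float:
    """m/z of a peptide+stub fragment at the given hydrogen shift and charge."""
    if charge <= 0:
        raise ValueError(f"charge must be positive, got {charge}")
    if label not in xl.stubs:
        raise ConfigError(f"{xl.name}: unknown stub label {label!r}")
    neutral = peptide_mass(peptide) + xl.stubs[label].mass + shift * H_MASS
    return (neutral + charge * PROTON_MASS) / charge
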