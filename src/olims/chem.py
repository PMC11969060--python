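"""Sequence notation, elemental composition and exact masses for modified
oligonucleotides.

The notation covers the modification chemistry found in current ASO and
siRNA therapeutics: per-residue sugar choice (2'-deoxyribose, ribose,
2'-O-methyl, 2'-O-methoxyethyl, 2'-fluoro), 5-methyl-cytosine, and
phosphodiester (PO) or phosphorothioate (PS) internucleotide linkages.

Grammar
-------
A sequence is a run of residue tokens, optionally separated by whitespace::

    token   := [sugar] base
    sugar   := "d" (deoxy) | "r" (ribo) | "m" (2'-OMe) | "e" (2'-MOE) | "f" (2'-F)
    base    := "A" | "G" | "C" | "U" | "T" | "5mC"

A literal ``*`` between two residues marks the linkage joining them as
phosphorothioate; the default linkage is phosphodiester. A bare base letter
defaults to deoxyribose, except ``U`` which defaults to ribose. Examples:
``dA*dT`` (PS dinucleotide), ``mU rA fC`` (2'-OMe-U, ribo-A, 2'-F-C, all PO).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .constants import AVERAGE_MASS, ELEMENTS, MONOISOTOPIC_MASS


class OligoChemError(ValueError):
    """Raised for invalid notation or impossible compositions."""


# ---------------------------------------------------------------------------
# Elemental composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts over C, H, N, O, P, S, F.

    Closed under addition and (non-negative) subtraction; subtracting more
    atoms than are present raises :class:`OligoChemError`.
    """

    counts: tuple[int, ...] = (0,) * len(ELEMENTS)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ElementalComposition":
        unknown = set(d) - set(ELEMENTS)
        if unknown:
            raise OligoChemError(f"unsupported elements: {sorted(unknown)}")
        return cls(tuple(int(d.get(e, 0)) for e in ELEMENTS))

    def as_dict(self) -> dict[str, int]:
        return {e: c for e, c in zip(ELEMENTS, self.counts) if c != 0}

    def __getitem__(self, element: str) -> int:
        return self.counts[ELEMENTS.index(element)]

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            tuple(a + b for a, b in zip(self.counts, other.counts))
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = tuple(a - b for a, b in zip(self.counts, other.counts))
        if any(c < 0 for c in out):
            raise OligoChemError(
                f"subtraction yields negative atom count: {self.as_dict()} - {other.as_dict()}"
            )
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise OligoChemError("cannot multiply composition by a negative count")
        return ElementalComposition(tuple(c * k for c in self.counts))

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return any(self.counts)

    def total_atoms(self) -> int:
        return sum(self.counts)

    def hill_formula(self) -> str:
        """Molecular formula in Hill order (C, H, then alphabetical)."""
        d = self.as_dict()
        order = ["C", "H"] + sorted(set(d) - {"C", "H"})
        return "".join(
            f"{e}{d[e]}" if d[e] != 1 else e for e in order if e in d
        ) or ""


def comp(**kwargs: int) -> ElementalComposition:
    """Shorthand constructor: ``comp(C=6, H=15, N=1)``."""
    return ElementalComposition.from_dict(kwargs)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Exact mass using the lightest isotope of each element, Da."""
    return sum(
        c * MONOISOTOPIC_MASS[e] for e, c in zip(ELEMENTS, composition.counts)
    )


def average_mass(composition: ElementalComposition) -> float:
    """Mass using standard atomic weights, Da."""
    return sum(c * AVERAGE_MASS[e] for e, c in zip(ELEMENTS, composition.counts))


# ---------------------------------------------------------------------------
# Residues and sequences
# ---------------------------------------------------------------------------


class Base(str, Enum):
    A = "A"
    G = "G"
    C = "C"
    U = "U"
    T = "T"
    MC = "5mC"  # 5-methyl-cytosine


class Sugar(str, Enum):
    DEOXY = "deoxyribose"
    RIBO = "ribose"
    OME = "2'-OMe"
    MOE = "2'-MOE"
    F2 = "2'-F"


class Linkage(str, Enum):
    PO = "phosphodiester"
    PS = "phosphorothioate"
    NONE = "none"  # 3'-terminal residue


#: Free (neutral) nucleobase compositions.
BASE_COMPOSITION: dict[Base, ElementalComposition] = {
    Base.A: comp(C=5, H=5, N=5),
    Base.G: comp(C=5, H=5, N=5, O=1),
    Base.C: comp(C=4, H=5, N=3, O=1),
    Base.T: comp(C=5, H=6, N=2, O=2),
    Base.U: comp(C=4, H=4, N=2, O=2),
    Base.MC: comp(C=5, H=7, N=3, O=1),
}

#: Sugar moiety contribution such that nucleoside = base + sugar (the water
#: of the glycosidic bond is already accounted for).
SUGAR_COMPOSITION: dict[Sugar, ElementalComposition] = {
    Sugar.DEOXY: comp(C=5, H=8, O=3),
    Sugar.RIBO: comp(C=5, H=8, O=4),
    Sugar.OME: comp(C=6, H=10, O=4),  # ribose + CH2
    Sugar.MOE: comp(C=8, H=14, O=5),  # ribose + C3H6O (O-CH2CH2-O-CH3 for OH)
    Sugar.F2: comp(C=5, H=7, O=3, F=1),  # ribose with 2'-OH -> 2'-F
}

#: One internucleotide bridge adds HPO3 (PO) or HPO2S (PS, one non-bridging
#: O replaced by S) and condenses out one water.
_BRIDGE: dict[Linkage, ElementalComposition] = {
    Linkage.PO: comp(H=1, P=1, O=3),
    Linkage.PS: comp(H=1, P=1, O=2, S=1),
}
_WATER = comp(H=2, O=1)
_PHOSPHATE = comp(H=1, P=1, O=3)  # HPO3, terminal monophosphate


@dataclass(frozen=True)
class Residue:
    base: Base
    sugar: Sugar
    linkage_to_next: Linkage = Linkage.PO

    def __post_init__(self) -> None:
        if self.base is Base.T and self.sugar is not Sugar.DEOXY:
            raise OligoChemError("T is restricted to deoxyribose")
        if self.base is Base.U and self.sugar is Sugar.DEOXY:
            raise OligoChemError("U is restricted to ribose-family sugars")

    def nucleoside_composition(self) -> ElementalComposition:
        return BASE_COMPOSITION[self.base] + SUGAR_COMPOSITION[self.sugar]


@dataclass(frozen=True)
class OligoSequence:
    """An ordered single strand of residues with terminal group tags.

    Default terminal chemistry is 5'-OH / 3'-OH (the synthesis-standard
    default for therapeutic oligonucleotides); a 5'-monophosphate can be
    requested with ``five_prime_end="phosphate"``.
    """

    residues: tuple[Residue, ...]
    five_prime_end: str = "OH"
    three_prime_end: str = "OH"
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise OligoChemError("sequence must contain at least one residue")
        if self.residues[-1].linkage_to_next is not Linkage.NONE:
            object.__setattr__(
                self,
                "residues",
                self.residues[:-1]
                + (replace(self.residues[-1], linkage_to_next=Linkage.NONE),),
            )
        for r in self.residues[:-1]:
            if r.linkage_to_next is Linkage.NONE:
                raise OligoChemError("internal residue with no linkage")
        if self.five_prime_end not in ("OH", "phosphate"):
            raise OligoChemError(f"unknown 5' end {self.five_prime_end!r}")
        if self.three_prime_end != "OH":
            raise OligoChemError(f"unknown 3' end {self.three_prime_end!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_ps_linkages(self) -> int:
        return sum(r.linkage_to_next is Linkage.PS for r in self.residues)

    def composition(self) -> ElementalComposition:
        """Total elemental composition of the neutral molecule."""
        total = ElementalComposition()
        n_bridges = 0
        for r in self.residues:
            total = total + r.nucleoside_composition()
            if r.linkage_to_next is not Linkage.NONE:
                total = total + _BRIDGE[r.linkage_to_next]
                n_bridges += 1
        total = total - n_bridges * _WATER
        if self.five_prime_end == "phosphate":
            total = total + _PHOSPHATE
        return total

    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition())

    def average_mass(self) -> float:
        return average_mass(self.composition())


# ---------------------------------------------------------------------------
# Parsing and serialization
# ---------------------------------------------------------------------------

_SUGAR_PREFIX = {
    "d": Sugar.DEOXY,
    "r": Sugar.RIBO,
    "m": Sugar.OME,
    "e": Sugar.MOE,
    "f": Sugar.F2,
}
_PREFIX_OF_SUGAR = {v: k for k, v in _SUGAR_PREFIX.items()}
_BASE_LETTERS = {"A": Base.A, "G": Base.G, "C": Base.C, "U": Base.U, "T": Base.T}


def _tokenize(notation: str):
    """Yield ("ps", pos) or ("res", base, sugar, pos) tokens."""
    i, n = 0, len(notation)
    while i < n:
        ch = notation[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "*":
            yield ("ps", i)
            i += 1
            continue
        pos = i
        sugar: Sugar | None = None
        if ch in _SUGAR_PREFIX and i + 1 < n and (
            notation[i + 1] in _BASE_LETTERS or notation.startswith("5mC", i + 1)
        ):
            sugar = _SUGAR_PREFIX[ch]
            i += 1
            ch = notation[i]
        if notation.startswith("5mC", i):
            base = Base.MC
            i += 3
        elif ch in _BASE_LETTERS:
            base = _BASE_LETTERS[ch]
            i += 1
        else:
            raise OligoChemError(
                f"unrecognised token {notation[i]!r} at position {i}"
            )
        if sugar is None:
            sugar = Sugar.RIBO if base is Base.U else Sugar.DEOXY
        yield ("res", base, sugar, pos)


def parse_sequence(notation: str, name: str = "", five_prime_end: str = "OH") -> OligoSequence:
    """Parse the mini-notation into an :class:`OligoSequence`.

    Raises :class:`OligoChemError` naming the character position of the
    first unrecognised token; a trailing or doubled ``*`` is an error.
    """
    residues: list[tuple[Base, Sugar]] = []
    linkages: list[Linkage] = []
    star = False
    for tok in _tokenize(notation):
        if tok[0] == "ps":
            if not residues:
                raise OligoChemError(f"'*' before any residue at position {tok[1]}")
            if star:
                raise OligoChemError(f"repeated '*' at position {tok[1]}")
            star = True
        else:
            _, base, sugar, _pos = tok
            if residues:
                linkages.append(Linkage.PS if star else Linkage.PO)
            star = False
            residues.append((base, sugar))
    if not residues:
        raise OligoChemError("empty sequence")
    if star:
        raise OligoChemError("trailing '*' with no residue after it")
    built = tuple(
        Residue(
            base=b,
            sugar=s,
            linkage_to_next=(linkages[j] if j < len(residues) - 1 else Linkage.NONE),
        )
        for j, (b, s) in enumerate(residues)
    )
    return OligoSequence(residues=built, name=name, five_prime_end=five_prime_end)


def serialize(seq: OligoSequence) -> str:
    """Canonical notation: explicit sugar prefixes, ``*`` for PS linkages."""
    parts: list[str] = []
    for r in seq.residues:
        token = _PREFIX_OF_SUGAR[r.sugar] + r.base.value
        parts.append(token)
        if r.linkage_to_next is Linkage.PS:
            parts.append("*")
    return "".join(parts)


def read_sequence_file(path: str) -> list[OligoSequence]:
    """Read one notation per line; ``>name`` headers name the next sequence."""
    sequences: list[OligoSequence] = []
    pending_name = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                pending_name = line[1:].strip()
                continue
            sequences.append(parse_sequence(line, name=pending_name))
            pending_name = ""
    return sequences
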