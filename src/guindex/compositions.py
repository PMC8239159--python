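"""Chemistry layer: elemental formulas, dextrin and N-glycan compositions.

Monosaccharide residue increments follow the standard glycomics
conventions for native and fully permethylated sugars.  A permethylated
glycan with a free (methylated) reducing end is the sum of its
permethylated residue increments plus dimethylated water (C2H6O); a
native glycan is the residue sum plus H2O.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable

from .constants import ADDUCT_MASS, MONOISOTOPIC_MASS

__all__ = [
    "ElementalFormula",
    "GlycanComposition",
    "dextrin_formula",
    "glycan_formula",
    "mz",
    "enumerate_glycans",
    "is_biosynthetically_plausible",
    "DEFAULT_BOUNDS",
]


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element→count mapping with formula arithmetic."""

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: dict[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        clean = tuple(sorted((el, n) for el, n in items.items() if n > 0))
        object.__setattr__(self, "counts", clean)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula(d)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return ElementalFormula(d)  # raises if any count goes negative

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula scaling requires a non-negative integer")
        return ElementalFormula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    @property
    def monoisotopic_mass(self) -> float:
        """Mass with every atom as its lightest isotope, Da."""
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        d = self.as_dict()
        parts = []
        order = [el for el in ("C", "H") if el in d] + sorted(
            el for el in d if el not in ("C", "H")
        )
        for el in order:
            parts.append(el + (str(d[el]) if d[el] != 1 else ""))
        return "".join(parts) or "(empty)"


def _f(**counts: int) -> ElementalFormula:
    return ElementalFormula(counts)


WATER = _f(H=2, O=1)
#: Water with both hydrogens methylated — the terminus of a fully
#: permethylated glycan with a free reducing end.
DIMETHYL_WATER = _f(C=2, H=6, O=1)
#: Extra CH4 a reduced (alditol) permethylated end carries: ring opening
#: adds H2 and the liberated hydroxyl is methylated (+CH2).
REDUCED_END_INCREMENT = _f(C=1, H=4)

PERMETHYLATED_RESIDUES: dict[str, ElementalFormula] = {
    "Hex": _f(C=9, H=16, O=5),
    "HexNAc": _f(C=11, H=19, N=1, O=5),
    "Fuc": _f(C=7, H=12, O=4),
    "NeuAc": _f(C=16, H=27, N=1, O=7),
}

NATIVE_RESIDUES: dict[str, ElementalFormula] = {
    "Hex": _f(C=6, H=10, O=5),
    "HexNAc": _f(C=8, H=13, N=1, O=5),
    "Fuc": _f(C=6, H=10, O=4),
    "NeuAc": _f(C=11, H=17, N=1, O=8),
}

RESIDUE_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc")

#: Default per-residue enumeration maxima (HexNAc, Hex, Fuc, NeuAc).
DEFAULT_BOUNDS = (12, 12, 5, 4)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """N-glycan monosaccharide composition (no linkage/topology)."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_fuc: int = 0
    n_neuac: int = 0

    def __post_init__(self):
        for n in self.as_tuple():
            if n < 0:
                raise ValueError("negative residue count")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_hexnac, self.n_hex, self.n_fuc, self.n_neuac)

    def __str__(self) -> str:
        return (
            f"HexNAc{self.n_hexnac}Hex{self.n_hex}"
            f"Fuc{self.n_fuc}NeuAc{self.n_neuac}"
        )

    @classmethod
    def from_string(cls, s: str) -> "GlycanComposition":
        import re

        m = re.fullmatch(r"HexNAc(\d+)Hex(\d+)Fuc(\d+)NeuAc(\d+)", s)
        if not m:
            raise ValueError(f"cannot parse composition {s!r}")
        return cls(*(int(g) for g in m.groups()))


def dextrin_formula(gu: int) -> ElementalFormula:
    """Fully permethylated linear glucan of ``gu`` glucose units.

    Closed form C(9g+2) H(16g+6) O(5g+1): g permethylated Hex residues
    plus a dimethylated-water terminus (free, methylated reducing end).
    """
    if gu < 1:
        raise ValueError(f"glucose unit count must be >= 1, got {gu}")
    return gu * PERMETHYLATED_RESIDUES["Hex"] + DIMETHYL_WATER


def glycan_formula(
    comp: GlycanComposition,
    derivatization: str = "permethylated",
    reduced_end: bool = False,
) -> ElementalFormula:
    """Elemental formula of a glycan composition.

    derivatization: ``"permethylated"`` (default) or ``"native"``.
    ``reduced_end`` applies the alditol-end convention (permethylated
    only); default off, matching the free-reducing-end ladder chemistry.
    """
    if derivatization == "permethylated":
        residues, terminus = PERMETHYLATED_RESIDUES, DIMETHYL_WATER
    elif derivatization == "native":
        residues, terminus = NATIVE_RESIDUES, WATER
    else:
        raise ValueError(f"unknown derivatization {derivatization!r}")
    total = terminus
    for name, n in zip(RESIDUE_ORDER, comp.as_tuple()):
        total = total + n * residues[name]
    if reduced_end:
        if derivatization != "permethylated":
            raise ValueError("reduced_end is defined for permethylated glycans only")
        total = total + REDUCED_END_INCREMENT
    return total


def mz(formula: ElementalFormula, charge: int, adduct: str = "proton") -> float:
    """m/z (Th) of [M + charge·adduct]^charge+.

    Electron mass is neglected (documented convention; < 0.0006 Da).
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    try:
        a = ADDUCT_MASS[adduct]
    except KeyError:
        raise ValueError(f"unknown adduct {adduct!r}") from None
    return (formula.monoisotopic_mass + charge * a) / charge


def is_biosynthetically_plausible(comp: GlycanComposition) -> bool:
    """N-glycan biosynthesis filter (single replaceable predicate).

    (a) trimannosyl-chitobiose core: >= 2 HexNAc and >= 3 Hex;
    (b) each fucose needs a GlcNAc attachment site;
    (c) sialic acids capped by the antennary GlcNAc count (HexNAc - 2).
    """
    return (
        comp.n_hexnac >= 2
        and comp.n_hex >= 3
        and comp.n_fuc <= comp.n_hexnac
        and comp.n_neuac <= max(0, comp.n_hexnac - 2)
    )


def enumerate_glycans(
    bounds: tuple[int, int, int, int] = DEFAULT_BOUNDS,
    predicate: Callable[[GlycanComposition], bool] = is_biosynthetically_plausible,
) -> list[GlycanComposition]:
    """All compositions within ``bounds`` passing the biosynthesis filter.

    Output is duplicate-free and lexicographically ordered by
    (HexNAc, Hex, Fuc, NeuAc).
    """
    if any(b < 0 for b in bounds):
        raise ValueError("bounds must be non-negative")
    out = []
    for tup in itertools.product(*(range(b + 1) for b in bounds)):
        comp = GlycanComposition(*tup)
        if predicate(comp):
            out.append(comp)
    return out
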