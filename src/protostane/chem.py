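"""Elemental-formula arithmetic for accurate-mass work.

Monoisotopic masses, protonated-ion m/z, ppm errors and bounded CHO formula
enumeration — the arithmetic that underlies accurate-mass identification of
small molecules on a QTOF instrument.

Atomic masses are fixed constants (not read from an external table) so that
every derived number in this package is bit-stable across platforms.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "HYDROGEN_ATOM_MASS",
    "ElementalFormula",
    "AdductConvention",
    "HYDROGEN_ATOM",
    "PROTON",
    "EnumerationBounds",
    "parse_formula",
    "monoisotopic_mass",
    "mz_protonated",
    "ppm_error",
    "round_ppm",
    "rdbe",
    "enumerate_formulas",
]

#: Monoisotopic atomic masses (Da) of the elements this package supports.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "O": 15.99491462,
    "N": 14.00307401,
    "Na": 22.98976928,
}

#: Mass of a bare proton (H nucleus, electron removed), Da.
PROTON_MASS = 1.007276
#: Mass of a neutral hydrogen atom, Da.
HYDROGEN_ATOM_MASS = 1.007825

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element → count map; the unit of all mass arithmetic.

    An all-zero (empty) formula is legal and has mass zero.
    """

    counts: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_dict(counts: dict[str, int]) -> "ElementalFormula":
        for elem, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {elem!r}")
        items = tuple(sorted((e, n) for e, n in counts.items() if n > 0))
        return ElementalFormula(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, elem: str) -> int:
        return dict(self.counts).get(elem, 0)

    def __str__(self) -> str:
        return render_formula(self)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-order style formula string such as ``"C30H48O6"``.

    Element symbols are one capital letter optionally followed by one lower
    case letter, each with an optional integer count (default 1).  Unknown
    element symbols and malformed strings raise :class:`ValueError`.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(
                f"malformed formula {text!r}: unexpected token at {text[pos:m.start()]!r}"
            )
        pos = m.end()
        elem = m.group(1)
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {elem!r} in {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    return ElementalFormula.from_dict(counts)


def render_formula(f: ElementalFormula) -> str:
    """Render in Hill-like order: C, H, then remaining elements alphabetically."""
    d = f.as_dict()
    parts = []
    for elem in ["C", "H"] + sorted(e for e in d if e not in ("C", "H")):
        n = d.get(elem, 0)
        if n == 0:
            continue
        parts.append(elem if n == 1 else f"{elem}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count x tabulated atomic mass."""
    total = 0.0
    for elem, n in f.counts:
        try:
            total += n * MONOISOTOPIC_MASS[elem]
        except KeyError:
            raise ValueError(f"no tabulated monoisotopic mass for {elem!r}") from None
    return total


@dataclass(frozen=True)
class AdductConvention:
    """Mass added on protonation.

    Accurate-mass software disagrees on whether ``[M+H]+`` adds the mass of a
    neutral hydrogen atom (1.007825 Da) or of a bare proton (1.007276 Da,
    i.e. electron-corrected).  Both are supported; the hydrogen-atom value is
    the package default because it reproduces the packaged library's printed
    mass errors at 1-decimal rounding for the majority of entries.
    """

    name: str
    added_mass: float

    def __post_init__(self) -> None:
        expected = {"hydrogen-atom": HYDROGEN_ATOM_MASS, "proton": PROTON_MASS}
        if self.name not in expected:
            raise ValueError(f"unknown adduct convention {self.name!r}")
        if abs(self.added_mass - expected[self.name]) > 5e-7:
            raise ValueError(
                f"added_mass {self.added_mass} inconsistent with convention {self.name!r}"
            )


HYDROGEN_ATOM = AdductConvention("hydrogen-atom", HYDROGEN_ATOM_MASS)
PROTON = AdductConvention("proton", PROTON_MASS)


def mz_protonated(f: ElementalFormula, conv: AdductConvention = HYDROGEN_ATOM) -> float:
    """m/z of the singly protonated ion [M+H]+ under the given convention."""
    return monoisotopic_mass(f) + conv.added_mass


def ppm_error(
    observed: float, f: ElementalFormula, conv: AdductConvention = HYDROGEN_ATOM
) -> float:
    """Signed relative mass error, in parts per million, of an observed [M+H]+."""
    if observed <= 0:
        raise ValueError(f"observed m/z must be positive, got {observed}")
    theo = mz_protonated(f, conv)
    return (observed - theo) / theo * 1e6

def round_ppm(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used when reporting ppm errors."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents, C − H/2 + 1 (CHO formulas).

    Half-integer for odd hydrogen counts; the empty formula returns 1.0 by
    convention. Nitrogen adds +N/2 in the general CHNO rule.
    """
    return float(f["C"] - Fraction(f["H"], 2) + Fraction(f["N"], 2) + 1)


@dataclass(frozen=True)
class EnumerationBounds:
    """Search box for CHO formula enumeration.

    Defaults are wide enough to cover C30–C32 triterpenoids and their
    fragments while keeping exhaustive search cheap.
    """

    c_range: tuple[int, int] = (5, 40)
    h_range: tuple[int, int] = (10, 64)
    o_range: tuple[int, int] = (0, 10)
    rdbe_range: tuple[float, float] = (0.0, 15.0)
    even_electron_only: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.c_range, self.h_range, self.o_range, self.rdbe_range):
            if lo > hi:
                raise ValueError("enumeration bounds require min <= max")


def enumerate_formulas(
    observed: float,
    tol_ppm: float,
    bounds: EnumerationBounds | None = None,
    conv: AdductConvention = HYDROGEN_ATOM,
) -> list[tuple[ElementalFormula, float]]:
    """All CHO formulas inside ``bounds`` whose [M+H]+ lies within ``tol_ppm``.

    Returns ``(formula, ppm_error)`` pairs sorted by |ppm| ascending, ties
    broken by the rendered formula string, so output is deterministic.  The
    even-electron constraint restricts to even hydrogen counts (integer RDBE),
    which is what singly protonated even-electron species require.
    """
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    if bounds is None:
        bounds = EnumerationBounds()
    target = observed - conv.added_mass  # neutral monoisotopic mass window centre
    # coarse absolute window (slightly widened); the exact criterion is |ppm| <= tol
    half_width = observed * tol_ppm * 1e-6 * (1 + 1e-9) + 1e-12
    out: list[tuple[ElementalFormula, float]] = []
    c_lo, c_hi = bounds.c_range
    h_lo, h_hi = bounds.h_range
    o_lo, o_hi = bounds.o_range
    m_c, m_h, m_o = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"], MONOISOTOPIC_MASS["O"]
    for c in range(c_lo, c_hi + 1):
        for h in range(h_lo, h_hi + 1):
            if bounds.even_electron_only and h % 2:
                continue
            r = c - h / 2 + 1
            if not bounds.rdbe_range[0] <= r <= bounds.rdbe_range[1]:
                continue
            base = c * m_c + h * m_h
            if base - half_width > target + o_hi * m_o:
                continue
            for o in range(o_lo, o_hi + 1):
                mass = base + o * m_o
                if abs(mass - target) <= half_width:
                    f = ElementalFormula.from_dict({"C": c, "H": h, "O": o})
                    ppm = ppm_error(observed, f, conv)
                    if abs(ppm) <= tol_ppm:
                        out.append((f, ppm))
    out.sort(key=lambda pair: (abs(pair[1]), render_formula(pair[0])))
    return out
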