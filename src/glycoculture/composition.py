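"""Glycan composition parsing and classification.

Glycopeptide search engines report glycans as monosaccharide *compositions*
(e.g. ``HexNAc(4)Hex(5)Fuc(1)NeuAc(2)``), not structures.  This module turns
such strings into typed counts and applies the composition-level
classification rules used for site-specific N-glycan reporting:

* **antennarity** — every HexNAc beyond the two of the chitobiose core is
  counted as one antenna (a bisecting GlcNAc is indistinguishable from an
  antenna at composition level and is counted as one; see the docs);
* **fucose placement** — the first fucose is always assigned to the core,
  any remainder to the antennae;
* **LacdiNAc possibility** — after placing all non-core Hex onto LacNAc
  antennae (one Hex caps one antennal HexNAc), at least two antennal HexNAc
  left bare imply a possible GalNAc-GlcNAc (LacdiNAc) pair;
* **diagnostic oxonium ions** — monoisotopic m/z of singly protonated
  glycan fragments, e.g. [HexNAc2 + H]+ at m/z 407.166 used as the
  LacdiNAc-diagnostic fragment in HCD spectra.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MonosaccharideCounts",
    "GlycanClass",
    "CompositionError",
    "GlycanClassError",
    "parse_composition",
    "format_composition",
    "count_antennae",
    "split_fucose",
    "lacdinac_by_composition",
    "classify_n_glycan",
    "oxonium_mz",
    "match_oxonium",
    "PROTON_MASS",
    "RESIDUE_MASSES",
]


class CompositionError(ValueError):
    """A composition string could not be parsed."""


class GlycanClassError(ValueError):
    """A composition is not a valid N-glycan (fewer than 2 HexNAc)."""


#: Monoisotopic residue (dehydrated) masses, Da.
RESIDUE_MASSES = {
    "hexnac": 203.079373,
    "hex": 162.052824,
    "fuc": 146.057909,
    "neuac": 291.095417,
    "neugc": 307.090331,
}

PROTON_MASS = 1.007276

# Canonical composition alphabet; aliases map named sugars onto it.
_CANONICAL = {
    "HexNAc": "hexnac",
    "Hex": "hex",
    "Fuc": "fuc",
    "NeuAc": "neuac",
    "NeuGc": "neugc",
}
_ALIASES = {
    "GalNAc": "hexnac",
    "GlcNAc": "hexnac",
    "Gal": "hex",
    "Man": "hex",
    "Glc": "hex",
    "Neu5Ac": "neuac",
    "Neu5Gc": "neugc",
    "dHex": "fuc",
}


@dataclass(frozen=True)
class MonosaccharideCounts:
    """Integer monosaccharide counts of one glycan composition."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac", "neugc"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(f"{name} count must be an int, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} count must be non-negative, got {value}")

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.fuc + self.neuac + self.neugc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_composition(self)


@dataclass(frozen=True)
class GlycanClass:
    """Composition-level classification of an N-glycan."""

    family: str  # "high-mannose" | "paucimannose-or-core" | "hybrid-or-complex"
    antennae: int
    core_fucose: int
    antenna_fucose: int
    galactosylated_antennae: int
    unoccupied_hexnac: int
    lacdinac_possible: bool
    neugc_present: bool


def _token_regex(aliases: bool) -> re.Pattern[str]:
    names = list(_CANONICAL)
    if aliases:
        names += list(_ALIASES)
    # longest-first so "HexNAc" wins over "Hex", "GalNAc" over "Gal"
    names.sort(key=len, reverse=True)
    alternation = "|".join(re.escape(n) for n in names)
    return re.compile(rf"({alternation})(?:\((\d+)\)|(\d+))?")


_RE_STRICT = _token_regex(aliases=False)
_RE_ALIASED = _token_regex(aliases=True)


def parse_composition(text: str, aliases: bool = False) -> MonosaccharideCounts:
    """Parse a composition string into :class:`MonosaccharideCounts`.

    Accepts both the parenthesized dialect ``HexNAc(4)Hex(5)`` and the
    compact one ``HexNAc4Hex5``; tokens may appear in any order and repeat
    (counts are summed).  A token without a multiplicity counts once.

    Parameters
    ----------
    text:
        Non-empty composition string.
    aliases:
        When true, named-sugar vocabulary (Gal, GalNAc, GlcNAc, Man, Glc,
        Neu5Ac/Gc, dHex) is mapped onto the Hex/HexNAc/Fuc/NeuAc/NeuGc
        alphabet, so O-glycan names like ``NeuAc2GalGalNAc`` parse.

    Raises
    ------
    CompositionError
        On empty input, an unknown monosaccharide name, or a zero
        multiplicity; the message names the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise CompositionError("empty composition string")
    pattern = _RE_ALIASED if aliases else _RE_STRICT
    counts = dict.fromkeys(RESIDUE_MASSES, 0)
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        match = pattern.match(stripped, pos)
        if match is None:
            raise CompositionError(
                f"unrecognized token at {stripped[pos:]!r} in composition {text!r}"
            )
        name = match.group(1)
        digits = match.group(2) or match.group(3)
        mult = int(digits) if digits is not None else 1
        if mult == 0:
            raise CompositionError(f"zero multiplicity for {name!r} in {text!r}")
        key = _CANONICAL.get(name) or _ALIASES[name]
        counts[key] += mult
        pos = match.end()
    return MonosaccharideCounts(**counts)


def format_composition(c: MonosaccharideCounts, compact: bool = False) -> str:
    """Render counts in canonical order, omitting zero-count residues."""
    parts = []
    for name, key in _CANONICAL.items():
        n = getattr(c, key)
        if n:
            parts.append(f"{name}{n}" if compact else f"{name}({n})")
    return "".join(parts)


def count_antennae(c: MonosaccharideCounts) -> int:
    """Number of antennae: HexNAc beyond the two-HexNAc chitobiose core.

    High-mannose / paucimannose compositions (hexnac == 2) have zero.
    """
    if c.hexnac < 2:
        raise GlycanClassError(
            f"not a valid N-glycan core: hexnac={c.hexnac} < 2"
        )
    return c.hexnac - 2


def split_fucose(c: MonosaccharideCounts) -> tuple[int, int]:
    """Split total fucose into (core, antenna): the first Fuc is core."""
    core = min(c.fuc, 1)
    return core, c.fuc - core


def lacdinac_by_composition(c: MonosaccharideCounts) -> tuple[bool, int]:
    """LacdiNAc possibility from composition arithmetic.

    All non-core Hex (beyond the 3 of the trimannosyl core) are placed on
    LacNAc antennae, one Hex per antennal HexNAc; LacdiNAc is possible when
    at least two antennal HexNAc remain bare (a GalNAc-GlcNAc pair could
    occupy them).

    Returns ``(lacdinac_possible, unoccupied_hexnac)``.
    """
    antennae = count_antennae(c)
    non_core_hex = max(c.hex - 3, 0)
    occupied = min(non_core_hex, antennae)
    unoccupied = antennae - occupied
    return unoccupied >= 2, unoccupied


def classify_n_glycan(c: MonosaccharideCounts) -> GlycanClass:
    """Full composition-level classification of an N-glycan."""
    antennae = count_antennae(c)
    if c.hexnac == 2:
        family = "high-mannose" if c.hex >= 5 else "paucimannose-or-core"
    else:
        family = "hybrid-or-complex"
    core_fuc, antenna_fuc = split_fucose(c)
    lacdinac, unoccupied = lacdinac_by_composition(c)
    return GlycanClass(
        family=family,
        antennae=antennae,
        core_fucose=core_fuc,
        antenna_fucose=antenna_fuc,
        galactosylated_antennae=antennae - unoccupied,
        unoccupied_hexnac=unoccupied,
        lacdinac_possible=lacdinac,
        neugc_present=c.neugc > 0,
    )


def oxonium_mz(c: MonosaccharideCounts) -> float:
    """Monoisotopic m/z of the singly protonated oxonium ion of ``c``.

    Sum of residue masses plus one proton; e.g. HexNAc2 gives 407.1660,
    the diagnostic LacdiNAc fragment.
    """
    if c.total == 0:
        raise ValueError("empty composition has no oxonium ion")
    mass = sum(getattr(c, key) * m for key, m in RESIDUE_MASSES.items())
    return mass + PROTON_MASS


def match_oxonium(
    peaks: list[tuple[float, float]],
    target: float,
    tolerance_ppm: float = 20.0,
) -> bool:
    """True iff a peak with positive intensity lies within ``tolerance_ppm``
    of ``target`` m/z.  An empty peak list matches nothing."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    window = target * tolerance_ppm * 1e-6
    return any(
        abs(mz - target) <= window and intensity > 0 for mz, intensity in peaks
    )
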