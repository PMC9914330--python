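"""Fatty-acid shorthand nomenclature.

Fatty acids are referred to throughout by the compact ``C<carbons>:<double
bonds>`` shorthand used on gas-chromatography reports, optionally decorated
with double-bond geometry/position (``cis-9``), the omega family counted from
the methyl end (``n-3``), a branching prefix (``anteiso-``) and a trivial
alias in parentheses (``EPA``, ``DHA``, ``DPA``). This module parses that
grammar into :class:`FattyAcidDescriptor` objects and classifies each acid
into the saturation (SFA/MUFA/PUFA) and enoic (mono- … hexaenoic) classes
that the nutritional-quality formulas are defined over.

Canonical spelling is ``[anteiso-]C<c>:<d>[ cis-<p>[,<p>…]][ n-<k>]``:
typographic italics markers and aliases are normalized away so every table
join uses one unambiguous key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FattyAcidDescriptor",
    "FAParseError",
    "UnsupportedEnoicClassError",
    "parse_fa_name",
    "format_fa_name",
    "canonical_name",
    "saturation_class",
    "enoic_class",
    "ALIASES",
]

#: Trivial names accepted in a trailing parenthesis and their identities.
ALIASES = {
    "EPA": (20, 5, "n-3"),
    "DHA": (22, 6, "n-3"),
    "DPA": (22, 5, "n-3"),
}

_FAMILIES = ("n-3", "n-6", "n-4")

#: Names of the enoic classes indexed by double-bond count.
ENOIC_NAMES = (
    "saturated",
    "monoenoic",
    "dienoic",
    "trienoic",
    "tetraenoic",
    "pentaenoic",
    "hexaenoic",
)


class FAParseError(ValueError):
    """A fatty-acid name does not conform to the shorthand grammar."""


class UnsupportedEnoicClassError(ValueError):
    """More than six double bonds: no enoic class (or peroxidability weight)
    is defined."""


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Parsed identity of one fatty acid.

    Attributes
    ----------
    name:
        Canonical shorthand (round-trips through :func:`parse_fa_name`).
    carbons:
        Chain length (> 0).
    double_bonds:
        Number of double bonds (>= 0).
    family:
        Omega family ``n-3``/``n-6``/``n-4`` or ``None`` — position of the
        first double bond counted from the methyl end.
    isomer_positions:
        Ordered ``(geometry, position)`` pairs, e.g. ``(("cis", 9),)``.
    branch:
        ``"anteiso"`` for branched-chain acids, else ``None``.
    alias:
        Trivial name stripped during parsing (``EPA``/``DHA``/``DPA``), if any.
    """

    name: str
    carbons: int
    double_bonds: int
    family: str | None = None
    isomer_positions: tuple[tuple[str, int], ...] = ()
    branch: str | None = None
    alias: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise FAParseError(f"carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise FAParseError("double_bonds must be non-negative")
        if self.double_bonds == 0 and (self.family or self.isomer_positions):
            raise FAParseError(
                f"saturated acid {self.name!r} cannot carry a family or "
                "double-bond positions"
            )
        if len(self.isomer_positions) > self.double_bonds:
            raise FAParseError(
                f"{self.name!r}: {len(self.isomer_positions)} double-bond "
                f"positions exceed {self.double_bonds} double bonds"
            )
        if self.family is not None and self.family not in _FAMILIES:
            raise FAParseError(f"unknown family {self.family!r}")


_GRAMMAR = re.compile(
    r"""^
    (?P<branch>anteiso-)?
    C(?P<carbons>\d+)
    (?::(?P<db>\d+))?
    (?P<isomers>(?:\ cis-\d+(?:,\d+)*)*)
    (?:\ (?P<family>n-\d+))?
    (?:\ \((?P<alias>[A-Za-z0-9]+)\))?
    $""",
    re.VERBOSE,
)


def _normalize(name: str) -> str:
    # strip markdown/italic asterisks and collapse runs of whitespace
    return re.sub(r"\s+", " ", name.replace("*", "").strip())


def parse_fa_name(name: str) -> FattyAcidDescriptor:
    """Parse a fatty-acid shorthand string.

    Accepts the table-label grammar
    ``[anteiso-]C<carbons>[:<double_bonds>][ cis-<pos>[,…]][ n-<k>][ (<alias>)]``
    including typographic variants (``C16:1 *cis*-9``). A bare ``C18`` is read
    as the saturated ``C18:0``, matching its abbreviated appearance in
    published coefficient tables.

    Raises
    ------
    FAParseError
        If the string contains tokens outside the grammar, an inconsistent
        alias, or an impossible carbon/double-bond combination.
    """
    if not isinstance(name, str):
        raise FAParseError(f"fatty-acid name must be a string, got {type(name)!r}")
    cleaned = _normalize(name)
    m = _GRAMMAR.match(cleaned)
    if m is None:
        # best effort at naming the offending token for the error message
        tokens = cleaned.split(" ")
        bad = next(
            (
                t
                for t in tokens
                if not re.fullmatch(
                    r"(anteiso-)?C\d+(:\d+)?|cis-\d+(,\d+)*|n-\d+|\([A-Za-z0-9]+\)",
                    t,
                )
            ),
            cleaned,
        )
        raise FAParseError(f"cannot parse fatty-acid name {name!r}: bad token {bad!r}")

    carbons = int(m.group("carbons"))
    if carbons == 0:
        raise FAParseError(f"{name!r}: zero carbons")
    double_bonds = int(m.group("db")) if m.group("db") is not None else 0
    positions: list[tuple[str, int]] = []
    for grp in (m.group("isomers") or "").split():
        geometry, _, tail = grp.partition("-")
        positions.extend((geometry, int(p)) for p in tail.split(","))
    family = m.group("family")
    alias = m.group("alias")
    if alias is not None:
        key = alias.upper()
        if key not in ALIASES:
            raise FAParseError(f"{name!r}: unknown alias {alias!r}")
        ac, adb, afam = ALIASES[key]
        if (carbons, double_bonds) != (ac, adb) or (family or afam) != afam:
            raise FAParseError(
                f"{name!r}: alias {alias!r} denotes C{ac}:{adb} {afam}, "
                f"inconsistent with the explicit shorthand"
            )
        family = family or afam
        alias = key
    if family is not None and family not in _FAMILIES:
        raise FAParseError(
            f"{name!r}: unknown family {family!r} (supported: {', '.join(_FAMILIES)})"
        )

    desc = FattyAcidDescriptor(
        name="",  # placeholder, replaced below
        carbons=carbons,
        double_bonds=double_bonds,
        family=family,
        isomer_positions=tuple(positions),
        branch="anteiso" if m.group("branch") else None,
        alias=alias,
    )
    canonical = format_fa_name(desc)
    object.__setattr__(desc, "name", canonical)
    return desc


def format_fa_name(d: FattyAcidDescriptor) -> str:
    """Canonical spelling of a descriptor (inverse of :func:`parse_fa_name`)."""
    parts = [f"{'anteiso-' if d.branch == 'anteiso' else ''}C{d.carbons}:{d.double_bonds}"]
    if d.isomer_positions:
        by_geom: dict[str, list[int]] = {}
        order: list[str] = []
        for geom, pos in d.isomer_positions:
            if geom not in by_geom:
                by_geom[geom] = []
                order.append(geom)
            by_geom[geom].append(pos)
        for geom in order:
            parts.append(f"{geom}-" + ",".join(str(p) for p in by_geom[geom]))
    if d.family:
        parts.append(d.family)
    return " ".join(parts)


def canonical_name(name: str) -> str:
    """Normalize any accepted spelling to the canonical one."""
    return parse_fa_name(name).name


def saturation_class(d: FattyAcidDescriptor) -> str:
    """``SFA`` (0 double bonds), ``MUFA`` (1) or ``PUFA`` (>= 2).

    Branching does not affect the class: anteiso-C16:0 counts with the
    saturated acids exactly as it does in the published partial sums.
    """
    if d.double_bonds == 0:
        return "SFA"
    if d.double_bonds == 1:
        return "MUFA"
    return "PUFA"


def enoic_class(d: FattyAcidDescriptor) -> str:
    """Enoic class by double-bond count: saturated, monoenoic … hexaenoic.

    The peroxidability index assigns one weight per enoic class, so acids
    with more than six double bonds have no defined class and raise
    :class:`UnsupportedEnoicClassError`.
    """
    if d.double_bonds > 6:
        raise UnsupportedEnoicClassError(
            f"{d.name!r}: {d.double_bonds} double bonds — no enoic class "
            "(or peroxidability weight) is defined beyond hexaenoic"
        )
    return ENOIC_NAMES[d.double_bonds]
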