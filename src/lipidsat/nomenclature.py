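"""Lipid shorthand parsing and saturation classification.

Targeted lipidomics platforms report species in the C:n shorthand, where the
number before the colon is the acyl-chain carbon count and the number after
it the count of C=C double bonds; ``PC(18:0/20:4)`` is a phosphatidylcholine
with a fully saturated 18-carbon chain at sn-1 and arachidonate at sn-2.
Saturation classes follow the standard convention: zero double bonds is a
saturated fatty acid (SFA), one is monounsaturated (MUFA) and two or more
polyunsaturated (PUFA).  A species is *highly unsaturated* when its most
unsaturated chain carries four or more double bonds — the binning that drives
the downstream differential and unsaturation-index analyses.

Two name dialects are accepted, ``PC(18:0/20:4)`` and ``PC 18:0_20:4``.  The
separator carries meaning: ``/`` asserts that sn-positions are resolved,
``_`` that the chain order is arbitrary.  O-/P- ether linkage prefixes and
omega-position suffixes (``18:3ω-3``, ``18:3n-3``) are parsed and preserved
but play no role in saturation arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "SaturationAnnotation",
    "LipidParseError",
    "DEFAULT_PHOSPHOLIPID_CLASSES",
    "parse_species",
    "annotate_saturation",
    "format_species",
]

#: Lipid classes counted as phospholipids unless the caller overrides the set.
#: Lyso species (one chain) are included by default.
DEFAULT_PHOSPHOLIPID_CLASSES = frozenset({"PC", "PE", "PS", "PI", "PG", "LPC", "LPE"})

#: Number of acyl chains a fully chain-resolved name of each class carries.
#: Used to recognise total-composition names such as "PC 38:4", where a
#: multi-chain class is reported with a single summed C:n token.
EXPECTED_CHAIN_COUNT = {
    "FFA": 1, "CE": 1, "MAG": 1,
    "LPC": 1, "LPE": 1, "LPS": 1, "LPI": 1, "LPG": 1,
    "PC": 2, "PE": 2, "PS": 2, "PI": 2, "PG": 2, "PA": 2,
    "SM": 2, "DAG": 2,
    "TAG": 3,
}


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be interpreted."""


@dataclass(frozen=True)
class AcylChain:
    """One fatty acyl chain: carbon count, double bonds, optional decorations."""

    carbons: int
    double_bonds: int
    ether_link: str = "none"  # one of {"none", "O", "P"}
    omega: int | None = None  # position of the last double bond, if annotated

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ValueError(f"carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double_bonds must be >= 0, got {self.double_bonds}")
        if self.double_bonds >= self.carbons:
            raise ValueError(
                f"double_bonds ({self.double_bonds}) must be < carbons ({self.carbons})"
            )
        if self.ether_link not in ("none", "O", "P"):
            raise ValueError(f"ether_link must be none/O/P, got {self.ether_link!r}")

    def __str__(self) -> str:
        prefix = "" if self.ether_link == "none" else f"{self.ether_link}-"
        suffix = "" if self.omega is None else f"ω-{self.omega}"
        return f"{prefix}{self.carbons}:{self.double_bonds}{suffix}"


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of one lipid species.

    ``raw_name`` keeps the input string for reporting but is excluded from
    equality so that parse -> format -> parse round-trips compare equal.
    ``total_composition`` marks names like ``PC(38:4)`` where a multi-chain
    class is reported as a single summed pseudo-chain; for those the
    pseudo-chain's double-bond count is the species total.
    """

    raw_name: str = field(compare=False)
    class_code: str = ""
    chains: tuple[AcylChain, ...] = ()
    sn_resolved: bool = False
    total_composition: bool = False

    def __post_init__(self) -> None:
        if not self.class_code:
            raise ValueError("class_code must be non-empty")
        if not self.chains:
            raise ValueError("a species needs at least one chain")

    @property
    def max_double_bonds(self) -> int:
        return max(c.double_bonds for c in self.chains)

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    def __str__(self) -> str:
        return format_species(self)


@dataclass(frozen=True)
class SaturationAnnotation:
    """Saturation classification of a species by its most unsaturated chain."""

    max_double_bonds: int
    saturation_class: str  # SFA / MUFA / PUFA
    highly_unsaturated: bool  # max_double_bonds >= 4
    contains_20_4: bool  # arachidonic acid chain present
    contains_18_2: bool  # linoleic acid chain present
    contains_18_3: bool  # alpha-linolenic acid chain present
    is_phospholipid: bool


_NAME_PAREN_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\s*\((?P<body>[^()]+)\)\s*$")
_NAME_SPACE_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\s+(?P<body>\S.*)$")
_CHAIN_RE = re.compile(
    r"^(?:(?P<ether>[OP])-)?(?P<c>\d+):(?P<n>\d+)"
    r"(?:\(?(?:ω|w|n)-?(?P<omega>\d+)\)?)?$"
)


def _parse_chain(fragment: str, name: str) -> AcylChain:
    m = _CHAIN_RE.match(fragment.strip())
    if m is None:
        raise LipidParseError(f"malformed chain token {fragment!r} in {name!r}")
    carbons = int(m.group("c"))
    double_bonds = int(m.group("n"))
    if double_bonds >= carbons:
        raise LipidParseError(
            f"chain {fragment!r} in {name!r}: {double_bonds} double bonds "
            f"is not possible with {carbons} carbons"
        )
    ether = m.group("ether") or "none"
    omega = int(m.group("omega")) if m.group("omega") else None
    return AcylChain(carbons, double_bonds, ether_link=ether, omega=omega)


def parse_species(name: str) -> LipidSpecies:
    """Parse a lipid shorthand name into a :class:`LipidSpecies`.

    Both the parenthesised (``PC(18:0/20:4)``) and space-separated
    (``PC 18:0_20:4``) dialects are accepted.  ``sn_resolved`` is true only
    when chains are separated by ``/``.

    Raises
    ------
    LipidParseError
        On an empty name, an unrecognisable class token, a malformed C:n
        fragment, mixed chain separators, or double bonds >= carbons.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    stripped = name.strip()
    m = _NAME_PAREN_RE.match(stripped) or _NAME_SPACE_RE.match(stripped)
    if m is None:
        raise LipidParseError(f"cannot split {name!r} into class and chains")
    class_code = m.group("cls")
    body = m.group("body").strip()

    has_slash = "/" in body
    has_underscore = "_" in body
    if has_slash and has_underscore:
        raise LipidParseError(f"mixed chain separators '/' and '_' in {name!r}")
    if has_slash:
        fragments, sn_resolved = body.split("/"), True
    elif has_underscore:
        fragments, sn_resolved = body.split("_"), False
    else:
        fragments, sn_resolved = [body], False

    chains = tuple(_parse_chain(f, name) for f in fragments)
    expected = EXPECTED_CHAIN_COUNT.get(class_code, len(chains))
    total_composition = len(chains) == 1 and expected > 1
    return LipidSpecies(
        raw_name=name,
        class_code=class_code,
        chains=chains,
        sn_resolved=sn_resolved,
        total_composition=total_composition,
    )


def format_species(species: LipidSpecies) -> str:
    """Serialise a species to the canonical ``CLASS(C:n_C:n)`` dialect.

    ``/`` is used when sn positions are resolved.  ``parse_species`` applied
    to the output reproduces an equivalent record.
    """
    sep = "/" if species.sn_resolved else "_"
    return f"{species.class_code}({sep.join(str(c) for c in species.chains)})"


def annotate_saturation(
    species: LipidSpecies,
    phospholipid_classes: frozenset[str] | set[str] = DEFAULT_PHOSPHOLIPID_CLASSES,
) -> SaturationAnnotation:
    """Classify a species by the double-bond count of its most unsaturated chain.

    SFA = 0 double bonds, MUFA = 1, PUFA >= 2; *highly unsaturated* means
    >= 4.  For total-composition names the summed double-bond count stands in
    for the per-chain maximum (a conservative reading that never understates
    unsaturation).  The ``contains_X_Y`` flags require an exact chain match,
    so they are never set on total-composition pseudo-chains.
    """
    max_db = species.max_double_bonds
    if max_db == 0:
        sat = "SFA"
    elif max_db == 1:
        sat = "MUFA"
    else:
        sat = "PUFA"

    def _contains(carbons: int, double_bonds: int) -> bool:
        if species.total_composition:
            return False
        return any(
            c.carbons == carbons and c.double_bonds == double_bonds
            for c in species.chains
        )

    return SaturationAnnotation(
        max_double_bonds=max_db,
        saturation_class=sat,
        highly_unsaturated=max_db >= 4,
        contains_20_4=_contains(20, 4),
        contains_18_2=_contains(18, 2),
        contains_18_3=_contains(18, 3),
        is_phospholipid=species.class_code in phospholipid_classes,
    )
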