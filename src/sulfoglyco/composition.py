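"""Glycan composition data types, string grammar, classification and
in-silico enzymatic transforms.

A composition is the unit of MS1 annotation: counts of the four residue
classes distinguishable by mass in a permethylated N-glycan (Hex, HexNAc,
dHex written ``Fuc``, NeuAc) plus the number of sulfate esters (``Sulf``).

The composition-string grammar is::

    ("Hex" INT)? ("HexNAc" INT)? ("Fuc" INT)? ("NeuAc" INT)? ("Sulf" INT)?

with at least one clause, e.g. ``Hex5HexNAc4Fuc1NeuAc2`` or
``Hex5HexNAc4Fuc1Sulf1``.  Clause order in the canonical rendering is
Hex, HexNAc, Fuc, NeuAc, Sulf; zero counts are omitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum


class CompositionError(ValueError):
    """Malformed composition string or invalid residue counts."""


class ClassificationError(ValueError):
    """Composition cannot be interpreted as an N-glycan."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue counts of a (possibly sulfated) N-glycan.

    Parameters
    ----------
    hex, hexnac, dhex, neuac : int
        Counts of hexose, N-acetylhexosamine, deoxyhexose (fucose) and
        N-acetylneuraminic acid residues.
    sulfo : int
        Number of sulfate esters.  Sulfated sites escape methylation
        during mild (sulfate-preserving) permethylation, which is why
        sulfation enters the mass calculus as ``+SO3 - CH2`` per site.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0
    sulfo: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac", "sulfo"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise CompositionError(
                    f"residue count {name}={v!r} must be a non-negative integer"
                )
        if self.total_residues == 0 and self.sulfo == 0:
            raise CompositionError("empty composition: at least one residue required")
        if self.total_residues == 0:
            raise CompositionError("sulfate without any residue is not a glycan")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac

    @property
    def is_n_glycan(self) -> bool:
        """True if the composition can carry the trimannosyl-chitobiose core."""
        return self.hexnac >= 2 and self.hex >= 3

    def render(self) -> str:
        """Canonical composition string (clause order Hex, HexNAc, Fuc, NeuAc, Sulf)."""
        parts = []
        for label, count in (
            ("Hex", self.hex),
            ("HexNAc", self.hexnac),
            ("Fuc", self.dhex),
            ("NeuAc", self.neuac),
            ("Sulf", self.sulfo),
        ):
            if count:
                parts.append(f"{label}{count}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.render()

    def with_sulfo(self, n: int) -> "GlycanComposition":
        return replace(self, sulfo=n)


# Clause order matters: "HexNAc" must be tried before "Hex", "NeuAc" is
# unambiguous.  Any residue name not in this table is a parse error.
_TOKEN_FIELD = (("HexNAc", "hexnac"), ("Hex", "hex"),
                ("Fuc", "dhex"), ("NeuAc", "neuac"), ("Sulf", "sulfo"))
_CANONICAL_ORDER = ("hex", "hexnac", "dhex", "neuac", "sulfo")
_CLAUSE_RE = re.compile(r"([A-Za-z]+)(\d+)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``Hex5HexNAc4Fuc1NeuAc1``.

    Raises
    ------
    CompositionError
        On an unknown residue token, a repeated clause, a zero count, or
        text that is not fully consumed by the grammar.
    """
    if not isinstance(text, str) or not text.strip():
        raise CompositionError("empty composition string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _CLAUSE_RE.finditer(text):
        if m.start() != pos:
            raise CompositionError(
                f"unparseable text {text[pos:m.start()]!r} in {text!r}"
            )
        token, number = m.group(1), int(m.group(2))
        for tok, field in _TOKEN_FIELD:
            if token == tok:
                break
        else:
            raise CompositionError(f"unknown residue token {token!r} in {text!r}")
        if field in counts:
            raise CompositionError(f"repeated clause {token!r} in {text!r}")
        if number == 0:
            raise CompositionError(f"zero count for {token!r}: omit the clause instead")
        counts[field] = number
        pos = m.end()
    if pos != len(text):
        raise CompositionError(f"unparseable trailing text {text[pos:]!r} in {text!r}")
    if not counts:
        raise CompositionError(f"no clauses found in {text!r}")
    return GlycanComposition(**counts)


class GlycanCategory(str, Enum):
    OLIGOMANNOSE = "oligomannose"
    PAUCIMANNOSE = "paucimannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"


@dataclass(frozen=True)
class GlycanClass:
    """Composition-level structural reading of an N-glycan.

    ``bisect_candidate`` flags a HexNAc surplus over what the antennae can
    carry galactose for (hexnac - 2 > hex - 3); a bisecting GlcNAc cannot
    be proven from composition alone, so this is a candidate flag, never a
    claim.  Likewise ``core_fucosylated`` maps any dHex to the core, the
    dominant placement in thyroid tissue; topology-level fragment evidence
    may override.
    """

    category: GlycanCategory
    antennarity: int
    bisect_candidate: bool
    core_fucosylated: bool
    sialylation_count: int
    sulfation_count: int


def classify(comp: GlycanComposition) -> GlycanClass:
    """Classify an N-glycan composition into the profiled feature classes.

    oligomannose: hexnac == 2, hex >= 5;  paucimannose: hexnac == 2, hex <= 4;
    hybrid: hexnac == 3, hex >= 5;  otherwise complex.
    Antennarity counts HexNAc beyond the chitobiose core, capped at 4 and
    discounting one HexNAc when the surplus flags a bisect candidate — a
    bisecting GlcNAc raises the HexNAc count without adding an antenna,
    which is how a bisected biantennary (HexNAc 5) stays biantennary.
    Mannose-only categories have antennarity 0; hybrid and complex at
    least 1.

    Raises
    ------
    ClassificationError
        If the composition lacks the trimannosyl-chitobiose core.
    """
    if not comp.is_n_glycan:
        raise ClassificationError(
            f"{comp} is not an N-glycan composition (needs HexNAc>=2 and Hex>=3)"
        )
    bisect_candidate = (comp.hexnac - 2) > (comp.hex - 3)
    if comp.hexnac == 2:
        category = (GlycanCategory.OLIGOMANNOSE if comp.hex >= 5
                    else GlycanCategory.PAUCIMANNOSE)
        antennarity = 0
    elif comp.hexnac == 3 and comp.hex >= 5:
        category = GlycanCategory.HYBRID
        antennarity = 1
    else:
        category = GlycanCategory.COMPLEX
        antennarity = comp.hexnac - 2 - (1 if bisect_candidate else 0)
        antennarity = min(max(antennarity, 1), 4)
    return GlycanClass(
        category=category,
        antennarity=antennarity,
        bisect_candidate=bisect_candidate,
        core_fucosylated=comp.dhex >= 1,
        sialylation_count=comp.neuac,
        sulfation_count=comp.sulfo,
    )


class Sialidase(str, Enum):
    """Broad-spectrum (A) vs alpha2-3-specific (S) exosialidase."""

    A = "sialidaseA"
    S = "sialidaseS"


def desialylate(
    comp: GlycanComposition,
    enzyme: Sialidase | str = Sialidase.A,
    alpha23_fraction: float = 0.0,
) -> GlycanComposition:
    """In-silico exosialidase treatment of a composition.

    Sialidase A releases alpha2-3/6/8/9-linked sialic acids and removes all
    NeuAc.  Sialidase S releases only the alpha2-3-linked share, given by
    ``alpha23_fraction`` of the NeuAc count (rounded); the default of 0
    reflects thyroid N-glycans, whose sialylation is alpha2-6-dominant, so
    sialidase S leaves the composition unchanged.  Sialidase A is
    idempotent; a composition carries no linkage information, so repeated
    sialidase-S calls with a fractional profile act on the remainder.
    """
    enzyme = Sialidase(enzyme)
    if not 0.0 <= alpha23_fraction <= 1.0:
        raise ValueError(f"alpha23_fraction {alpha23_fraction} outside [0, 1]")
    if comp.neuac == 0:
        return comp
    if enzyme is Sialidase.A:
        return replace(comp, neuac=0)
    removed = round(comp.neuac * alpha23_fraction)
    return replace(comp, neuac=comp.neuac - removed)
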