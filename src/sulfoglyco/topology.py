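"""Rooted glycan topologies for fragment enumeration.

A topology is a rooted tree of monosaccharides with the reducing end at
the root.  The text grammar is nested parentheses::

    node     := NAME sulfo? linkage? child*
    child    := "(" node ")"
    sulfo    := "[S" INT "]"          e.g. [S3] = 3-O-sulfate
    linkage  := "{" LABEL "}"         e.g. {a2-6}, {b1-4}

Example (core-fucosylated biantennary with one 3-O-sulfated terminal
galactose)::

    GlcNAc(Fuc)(GlcNAc(Man(Man(GlcNAc(Gal[S3])))(Man(GlcNAc(Gal)))))

Residue names map to mass classes: Man/Gal/Glc/Hex -> Hex,
GlcNAc/GalNAc/HexNAc -> HexNAc, Fuc -> dHex, NeuAc -> NeuAc.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from sulfoglyco.composition import GlycanComposition

_RESIDUE_CLASS = {
    "Man": "hex", "Gal": "hex", "Glc": "hex", "Hex": "hex",
    "GlcNAc": "hexnac", "GalNAc": "hexnac", "HexNAc": "hexnac",
    "Fuc": "dhex",
    "NeuAc": "neuac", "Neu5Ac": "neuac",
}


class TopologyError(ValueError):
    """Malformed topology text or an inconsistent tree."""


@dataclass
class TopologyNode:
    """One monosaccharide in a rooted glycan tree."""

    name: str
    residue_class: str
    sulfo_site: int | None = None   # e.g. 3 for a 3-O-sulfate
    linkage: str | None = None      # label of the bond to the parent
    children: list["TopologyNode"] = field(default_factory=list)

    @property
    def is_sulfated(self) -> bool:
        return self.sulfo_site is not None

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GlycanTopology:
    """Rooted tree of monosaccharides; the root carries the reducing end."""

    root: TopologyNode

    def nodes(self) -> list[TopologyNode]:
        return list(self.root.walk())

    def edges(self) -> list[tuple[TopologyNode, TopologyNode]]:
        """(parent, child) pairs; each is one glycosidic bond."""
        out = []
        for node in self.root.walk():
            for child in node.children:
                out.append((node, child))
        return out

    @property
    def n_bonds(self) -> int:
        return len(self.edges())

    def composition(self) -> GlycanComposition:
        """Derived residue-count composition, sulfates included."""
        counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
        sulfo = 0
        for node in self.root.walk():
            counts[node.residue_class] += 1
            if node.is_sulfated:
                sulfo += 1
        return GlycanComposition(sulfo=sulfo, **counts)

    @property
    def is_n_glycan(self) -> bool:
        return (
            self.root.residue_class == "hexnac"
            and self.composition().is_n_glycan
        )

    def __str__(self) -> str:
        return render_topology(self)


_NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*")


def parse_topology(text: str) -> GlycanTopology:
    """Parse the nested-parenthesis topology grammar.

    Raises
    ------
    TopologyError
        On unknown residue names, unbalanced parentheses or trailing text.
    """
    text = text.strip()
    if not text:
        raise TopologyError("empty topology text")
    node, pos = _parse_node(text, 0)
    if pos != len(text):
        raise TopologyError(f"trailing text {text[pos:]!r} after topology")
    return GlycanTopology(root=node)


def _parse_node(text: str, pos: int) -> tuple[TopologyNode, int]:
    m = _NAME_RE.match(text, pos)
    if not m:
        raise TopologyError(f"expected residue name at position {pos} in {text!r}")
    name = m.group(0)
    if name not in _RESIDUE_CLASS:
        raise TopologyError(f"unknown residue name {name!r} at position {pos}")
    pos = m.end()
    sulfo_site = None
    linkage = None
    if pos < len(text) and text[pos] == "[":
        end = text.find("]", pos)
        if end < 0:
            raise TopologyError(f"unterminated '[' at position {pos}")
        tag = text[pos + 1:end]
        if not re.fullmatch(r"S\d+", tag):
            raise TopologyError(f"bad sulfo tag {tag!r}; expected e.g. [S3]")
        sulfo_site = int(tag[1:])
        pos = end + 1
    if pos < len(text) and text[pos] == "{":
        end = text.find("}", pos)
        if end < 0:
            raise TopologyError(f"unterminated '{{' at position {pos}")
        linkage = text[pos + 1:end]
        pos = end + 1
    node = TopologyNode(
        name=name, residue_class=_RESIDUE_CLASS[name],
        sulfo_site=sulfo_site, linkage=linkage,
    )
    while pos < len(text) and text[pos] == "(":
        child, pos = _parse_node(text, pos + 1)
        if pos >= len(text) or text[pos] != ")":
            raise TopologyError(f"expected ')' at position {pos} in {text!r}")
        pos += 1
        node.children.append(child)
    return node, pos


def render_topology(topology: GlycanTopology) -> str:
    """Inverse of :func:`parse_topology` (canonical child order preserved)."""

    def render(node: TopologyNode) -> str:
        s = node.name
        if node.sulfo_site is not None:
            s += f"[S{node.sulfo_site}]"
        if node.linkage is not None:
            s += f"{{{node.linkage}}}"
        for child in node.children:
            s += f"({render(child)})"
        return s

    return render(topology.root)
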