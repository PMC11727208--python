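"""Glycosidic fragment enumeration for permethylated (sulfo-)glycans and
the diagnostic-ion logic that assigns 3-O-sulfated galactose.

Fragment nomenclature follows the Domon-Costello scheme: B/C ions carry
the non-reducing side of a cleaved glycosidic bond, Y/Z ions the
reducing side.  Masses obey the permethylation-aware end-group
conventions (validated against the printed MS/MS ions of the
core-fucosylated mono-sulfated biantennary precursor before freezing):

* positive B of a fragment subtree carrying k sulfates:
  sum(residues) + 15.0229 + (1 + k) * (Na - H)   -- every fragment is
  sodiated once, and each sulfate travels as its sodium salt;
* positive Y after loss of a subtree with k sulfates:
  precursor_mz - sum(lost residues) - 14.0157 - k * (Na - H);
* negative (sulfate-retaining) B: the positive oxocarbenium minus 2 H;
* negative Y: precursor_mz - sum(lost residues) - 14.0157, defined only
  when the lost subtree carries no sulfate (the charge stays on the
  retained sulfate);
* C = B + H2O, Z = Y - H2O.

General cross-ring (A/X) enumeration is not implemented.  The three
linkage-diagnostic cross-ring/elimination masses for 3-O-sulfo-galactose
(m/z 153, 181, 253) are curated constants with citations: E-ion
chemistry of permethylated glycans is an empirical signature, not a
desk-derivable mass rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from sulfoglyco.composition import GlycanComposition
from sulfoglyco.masses import (
    H,
    NA,
    O,
    PROTON,
    RESIDUE_MASSES,
    S,
    SULFO_DELTA,
    Polarity,
    ion_mz,
)
from sulfoglyco.topology import GlycanTopology, TopologyNode

B_END = 15.0229          # oxocarbenium end-group adjustment for B ions
Y_LOSS = 14.0157         # extra neutral loss per glycosidic cleavage on Y ions
WATER = 18.0106
NA_MINUS_H = NA - H      # 21.98194, one sodiation
SULFO_GAL_RESIDUE = RESIDUE_MASSES["hex"] + SULFO_DELTA  # 270.0410


class FragmentKind(str, Enum):
    B = "B"
    C = "C"
    Y = "Y"
    Z = "Z"
    BY = "BY"    # internal fragment: B cut with an inner Y loss
    YY = "YY"    # double Y loss on disjoint branches
    DIAGNOSTIC = "diagnostic"


@dataclass(frozen=True)
class FragmentIon:
    """One predicted fragment ion of a topology."""

    kind: FragmentKind
    label: str                      # e.g. "B5", "Y1", "Y1Y2"
    cleaved_edges: tuple[int, ...]  # indices into GlycanTopology.edges()
    polarity: Polarity
    sodiation: int
    mz: float
    composition: GlycanComposition | None  # residues of the charged fragment

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


class FragmentError(ValueError):
    pass


def _subtree_sum(node: TopologyNode) -> tuple[float, int, dict]:
    """(residue-mass sum incl. sulfo deltas, sulfate count, residue counts)."""
    total = 0.0
    sulfo = 0
    counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
    for n in node.walk():
        total += RESIDUE_MASSES[n.residue_class]
        counts[n.residue_class] += 1
        if n.is_sulfated:
            total += SULFO_DELTA
            sulfo += 1
    return total, sulfo, counts


def _depth(node: TopologyNode) -> int:
    if not node.children:
        return 1
    return 1 + max(_depth(c) for c in node.children)


def _b_mz(res_sum: float, k_sulfo: int, polarity: Polarity) -> float | None:
    oxo = res_sum + B_END
    if polarity is Polarity.POSITIVE:
        return oxo + (1 + k_sulfo) * NA_MINUS_H
    if k_sulfo < 1:
        return None  # no charge carrier on the non-reducing side
    return oxo - 2 * PROTON + (k_sulfo - 1) * NA_MINUS_H


def _y_mz(
    precursor_mz: float, lost_sum: float, lost_sulfo: int,
    retained_sulfo: int, polarity: Polarity, n_cuts: int = 1,
) -> float | None:
    if polarity is Polarity.NEGATIVE and (retained_sulfo < 1 or lost_sulfo > 0):
        return None
    mz = precursor_mz - lost_sum - n_cuts * Y_LOSS
    if polarity is Polarity.POSITIVE:
        mz -= lost_sulfo * NA_MINUS_H
    return mz


def enumerate_glycosidic_fragments(
    topology: GlycanTopology,
    polarity: Polarity | str,
    max_cleavages: int = 2,
    precursor_mz: float | None = None,
) -> list[FragmentIon]:
    """All B/C/Y/Z ions from single (and optionally double) glycosidic
    cleavages of a rooted topology.

    In positive mode every edge yields four ions (B, C, Y, Z); in
    negative mode only sulfate-retaining fragments survive the polarity
    filter.  Double cleavages produce internal BY fragments (nested cuts)
    and YY double losses (disjoint branches).

    Raises
    ------
    FragmentError
        For negative mode on an unsulfated topology.
    """
    polarity = Polarity(polarity)
    comp = topology.composition()
    if polarity is Polarity.NEGATIVE and comp.sulfo == 0:
        raise FragmentError(
            "negative-mode fragmentation requires a sulfated topology"
        )
    if precursor_mz is None:
        precursor_mz = ion_mz(comp, polarity)
    total_sum, total_sulfo, total_counts = _subtree_sum(topology.root)
    edges = topology.edges()

    ions: list[FragmentIon] = []

    def add(kind, label, cut, mz, counts, k_sulfo, sodiation):
        if mz is None or mz <= 0:
            return
        frag_comp = None
        if any(counts.values()):
            frag_comp = GlycanComposition(sulfo=k_sulfo, **counts)
        ions.append(FragmentIon(
            kind=kind, label=label, cleaved_edges=cut, polarity=polarity,
            sodiation=sodiation, mz=round(mz, 4), composition=frag_comp,
        ))

    subtree = {}
    for idx, (_, child) in enumerate(edges):
        subtree[idx] = (_subtree_sum(child), _depth(child), child)

    for idx, (_, child) in enumerate(edges):
        (res_sum, k_sulfo, counts), depth, _ = subtree[idx]
        lost_sulfo = k_sulfo
        retained_sulfo = total_sulfo - k_sulfo
        n_lost = sum(counts.values())
        retained_counts = {
            k: total_counts[k] - counts[k] for k in counts
        }
        sod = (1 + k_sulfo) if polarity is Polarity.POSITIVE else 0
        b = _b_mz(res_sum, k_sulfo, polarity)
        add(FragmentKind.B, f"B{depth}", (idx,), b, counts, k_sulfo, sod)
        add(FragmentKind.C, f"C{depth}", (idx,),
            None if b is None else b + WATER, counts, k_sulfo, sod)
        y = _y_mz(precursor_mz, res_sum, lost_sulfo, retained_sulfo, polarity)
        add(FragmentKind.Y, f"Y{n_lost}", (idx,), y,
            retained_counts, retained_sulfo, 1 if polarity is Polarity.POSITIVE else 0)
        add(FragmentKind.Z, f"Z{n_lost}", (idx,),
            None if y is None else y - WATER, retained_counts, retained_sulfo,
            1 if polarity is Polarity.POSITIVE else 0)

    if max_cleavages >= 2:
        node_sets = {
            idx: frozenset(id(n) for n in subtree[idx][2].walk())
            for idx in range(len(edges))
        }
        for i in range(len(edges)):
            (sum_i, sulfo_i, counts_i), depth_i, child_i = subtree[i]
            for j in range(i + 1, len(edges)):
                (sum_j, sulfo_j, counts_j), depth_j, child_j = subtree[j]
                nested_ij = node_sets[j] <= node_sets[i]
                nested_ji = node_sets[i] <= node_sets[j]
                if nested_ij or nested_ji:
                    # internal BY fragment: outer B cut minus inner Y loss
                    outer, inner = (i, j) if nested_ij else (j, i)
                    (sum_o, sulfo_o, counts_o), depth_o, _ = subtree[outer]
                    (sum_n, sulfo_n, counts_n), _, _ = subtree[inner]
                    k = sulfo_o - sulfo_n
                    frag_counts = {
                        key: counts_o[key] - counts_n[key] for key in counts_o
                    }
                    mz = _b_mz(sum_o - sum_n, k, polarity)
                    if mz is not None:
                        if polarity is Polarity.POSITIVE and sulfo_n:
                            mz -= sulfo_n * NA_MINUS_H
                        mz -= Y_LOSS
                    add(FragmentKind.BY, f"B{depth_o}Y", (outer, inner), mz,
                        frag_counts, k,
                        (1 + k) if polarity is Polarity.POSITIVE else 0)
                else:
                    # disjoint double Y loss
                    lost_sulfo = sulfo_i + sulfo_j
                    retained = total_sulfo - lost_sulfo
                    frag_counts = {
                        key: total_counts[key] - counts_i[key] - counts_j[key]
                        for key in counts_i
                    }
                    mz = _y_mz(
                        precursor_mz, sum_i + sum_j, lost_sulfo, retained,
                        polarity, n_cuts=2,
                    )
                    n_lost = sum(counts_i.values()) + sum(counts_j.values())
                    add(FragmentKind.YY, f"YY{n_lost}", (i, j), mz,
                        frag_counts, retained,
                        1 if polarity is Polarity.POSITIVE else 0)
    return ions


# --- diagnostic ions -------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticIon:
    mz: float
    name: str
    inference: str
    citation: str
    derived: bool  # True if recomputed from the mass table, False if curated


@dataclass(frozen=True)
class DiagnosticTable:
    entries: tuple[DiagnosticIon, ...]

    def match(self, peaks, tolerance_da: float = 0.5) -> dict[int, float]:
        """Map nearest-integer diagnostic m/z -> observed peak m/z."""
        hits: dict[int, float] = {}
        for entry in self.entries:
            for mz in peaks:
                if abs(mz - entry.mz) <= tolerance_da:
                    hits.setdefault(round(entry.mz), float(mz))
        return hits


def diagnostic_ions() -> DiagnosticTable:
    """The curated negative-mode diagnostic table for sulfated N-glycans.

    The sulfate anion (97), B-type sulfo-Gal (283) and B-type sulfo-LacNAc
    (528) masses are recomputed from the residue/atom table; the
    cross-ring 2,4A1 (153) and E-type (181, 253) masses of 3-O-sulfated
    galactose are curated literature values.
    """
    hso4 = H + S + 4 * O                       # 96.9601
    sulfo_gal_b = SULFO_GAL_RESIDUE + B_END - 2 * PROTON          # 283.048
    sulfo_lacnac_b = sulfo_gal_b + RESIDUE_MASSES["hexnac"]       # 528.174
    return DiagnosticTable(entries=(
        DiagnosticIon(round(hso4, 4), "sulfate_anion",
                      "a sulfate ester is present on the precursor",
                      "HSO4- ion, nominal m/z 97", True),
        DiagnosticIon(153.0, "A24_sulfo_gal",
                      "2,4A1 cross-ring of 3-O-sulfated galactose",
                      "cross-ring signature of 3-O-sulfo-Gal, nominal m/z 153",
                      False),
        DiagnosticIon(181.0, "E1_sulfo_gal_181",
                      "E-type elimination ion of 3-O-sulfated galactose",
                      "E-ion signature of permethylated 3-O-sulfo-Gal, "
                      "nominal m/z 181", False),
        DiagnosticIon(253.1, "E1_sulfo_gal_253",
                      "E-type elimination ion of 3-O-sulfated galactose",
                      "E-ion signature of permethylated 3-O-sulfo-Gal, "
                      "nominal m/z 253", False),
        DiagnosticIon(round(sulfo_gal_b, 4), "B_sulfo_gal",
                      "the sulfate sits on a terminal galactose "
                      "(not the internal GlcNAc)",
                      "B-type terminal sulfo-Gal, nominal m/z 283 "
                      "(labelled B2 in source spectra despite spanning one "
                      "residue)", True),
        DiagnosticIon(round(sulfo_lacnac_b, 4), "B2_sulfo_lacnac",
                      "a sulfo-LacNAc motif caps an antenna",
                      "B2-type sulfo-Gal-GlcNAc, nominal m/z 528", True),
    ))


class SulfoPosition(str, Enum):
    TERMINAL_GAL = "terminal_Gal"
    INTERNAL_GLCNAC = "internal_GlcNAc"
    INDETERMINATE = "indeterminate"


class SulfoLinkage(str, Enum):
    THREE_O_GAL = "3-O-Gal"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LinkageVerdict:
    """Outcome of the diagnostic-ion decision chain.

    The chain: m/z 97 establishes a sulfate; 97 + 528 a sulfo-LacNAc
    antenna; 283 places the sulfate on the terminal galactose; any of the
    cross-ring/E ions 153/181/253 (given 97) licenses the 3-O linkage on
    galactose.  Anything not positively established stays indeterminate.
    """

    sulfate_present: bool
    sulfo_on_lacnac: bool
    sulfo_position: SulfoPosition
    linkage: SulfoLinkage
    matched_diagnostics: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.linkage is SulfoLinkage.THREE_O_GAL:
            assert self.sulfate_present
            assert any(m in self.matched_diagnostics for m in (153, 181, 253))


def assign_sulfo_linkage(
    msms_peaks,
    polarity: Polarity | str = Polarity.NEGATIVE,
    tolerance_da: float = 0.5,
) -> LinkageVerdict:
    """Run the diagnostic-ion decision logic on an MS/MS peak list.

    Sulfate-retaining diagnostics appear only in negative mode; a
    positive-mode peak list therefore yields an all-indeterminate verdict
    (positive spectra contribute complementary B/Y confirmation only).
    """
    polarity = Polarity(polarity)
    if polarity is not Polarity.NEGATIVE:
        return LinkageVerdict(
            sulfate_present=False, sulfo_on_lacnac=False,
            sulfo_position=SulfoPosition.INDETERMINATE,
            linkage=SulfoLinkage.INDETERMINATE, matched_diagnostics=(),
        )
    hits = diagnostic_ions().match(msms_peaks, tolerance_da)
    matched = tuple(sorted(hits))
    sulfate = 97 in hits
    lacnac = sulfate and 528 in hits
    position = (
        SulfoPosition.TERMINAL_GAL if 283 in hits
        else SulfoPosition.INDETERMINATE
    )
    linkage = (
        SulfoLinkage.THREE_O_GAL
        if sulfate and any(m in hits for m in (153, 181, 253))
        else SulfoLinkage.INDETERMINATE
    )
    return LinkageVerdict(
        sulfate_present=sulfate, sulfo_on_lacnac=lacnac,
        sulfo_position=position, linkage=linkage,
        matched_diagnostics=matched,
    )


@dataclass(frozen=True)
class MsmsMatch:
    observed_mz: float
    fragment: FragmentIon
    error_da: float


@dataclass(frozen=True)
class MsmsAnnotation:
    matches: tuple[MsmsMatch, ...]
    diagnostics: tuple[int, ...]
    coverage: float          # matched glycosidic bonds / total bonds
    verdict: LinkageVerdict


def annotate_msms(
    topology: GlycanTopology,
    msms_peaks,
    polarity: Polarity | str,
    tolerance_da: float = 0.5,
    precursor_mz: float | None = None,
    max_cleavages: int = 2,
) -> MsmsAnnotation:
    """Match observed MS/MS peaks to enumerated fragments and diagnostics.

    Each observed peak is matched to at most one enumerated fragment (the
    smallest |error| wins); bond coverage is the fraction of glycosidic
    bonds cut by at least one matched fragment.  If ``precursor_mz`` is
    given it must agree with the topology's predicted precursor within
    tolerance.

    Raises
    ------
    FragmentError
        On a precursor mismatch.
    """
    polarity = Polarity(polarity)
    predicted = ion_mz(topology.composition(), polarity)
    if precursor_mz is not None and abs(precursor_mz - predicted) > max(
        tolerance_da, 1.0
    ):
        raise FragmentError(
            f"precursor m/z {precursor_mz:.2f} does not match the topology's "
            f"predicted {predicted:.2f}"
        )
    fragments = enumerate_glycosidic_fragments(
        topology, polarity, max_cleavages=max_cleavages,
        precursor_mz=precursor_mz,
    )
    matches = []
    for mz in msms_peaks:
        best = None
        for frag in fragments:
            err = mz - frag.mz
            if abs(err) <= tolerance_da and (
                best is None or abs(err) < abs(best.error_da)
            ):
                best = MsmsMatch(float(mz), frag, float(err))
        if best is not None:
            matches.append(best)
    covered = set()
    for m in matches:
        covered.update(m.fragment.cleaved_edges)
    n_bonds = topology.n_bonds
    coverage = len(covered) / n_bonds if n_bonds else 0.0
    verdict = assign_sulfo_linkage(msms_peaks, polarity, tolerance_da)
    return MsmsAnnotation(
        matches=tuple(matches),
        diagnostics=verdict.matched_diagnostics,
        coverage=coverage,
        verdict=verdict,
    )
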