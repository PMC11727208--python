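"""Monoisotopic mass calculus for fully permethylated, optionally sulfated
N-glycans and their singly charged MALDI ions.

All masses are monoisotopic Daltons.  A permethylated glycan of free
reducing end is summed as::

    M = sum(count_r * residue_mass_r) + CLOSURE + n_sulfo * SULFO_DELTA

where the residue masses are those of the *permethylated* glycosyl
residues (e.g. permethylated Hex = C9H16O5 = 204.0998 Da), CLOSURE
(C2H6O = 46.0419 Da) closes the free reducing end plus the non-reducing
termini, and SULFO_DELTA = SO3 - CH2 = +65.9412 Da per sulfate ester:
a sulfated hydroxyl escapes methylation, so installing the sulfate both
adds SO3 and removes one methylene relative to the fully methylated
residue.

Ion conventions (all singly charged, reflector MALDI-TOF):

* neutral/sialylated pool, positive mode: [M+Na]+.
* sulfated pool, negative mode, n sulfates: all sulfates deprotonated
  with n-1 sodium counterions, M - nH + (n-1)Na; for n=1 this is plain
  [M-H]-.
* sulfated pool, positive mode: the sodium-salt form M - nH + (n+1)Na
  (for n=1, the conventional "[M+2Na-2H]+" label).

The negative-mode formula is deliberately M - nH + (n-1)Na on the free
acid: this reproduces the printed mono- and di-sulfated peak labels and
their +88 Da spacing, whereas adding the (n-1) sodiums without removing
the matching protons would sit 1 Da high for di-sulfated species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum

from sulfoglyco.composition import CompositionError, GlycanComposition

# --- atomic constants (monoisotopic, Da) -----------------------------------
PROTON = 1.00783          # 1H (electron mass ignored; < 1 mDa, absorbed by tolerance)
NA = 22.98977
CH2 = 14.01565
SO3 = 79.95682
H = 1.00783
O = 15.99491
S = 31.97207

# Permethylated glycosyl residue masses.
RESIDUE_MASSES: dict[str, float] = {
    "hex": 204.0998,      # C9H16O5
    "hexnac": 245.1263,   # C11H19NO5
    "dhex": 174.0892,     # C8H14O4
    "neuac": 361.1737,    # C16H27NO8
}

# Free reducing end + non-reducing termini of a permethylated glycan (C2H6O).
CLOSURE_MASS = 46.0419

# Per-sulfate mass shift on a permethylated glycan: +SO3 - CH2.
SULFO_DELTA = SO3 - CH2  # 65.94117

# Satellite species seen beside assigned peaks (see satellite_offsets).
UNDER_PERMETHYLATION = -CH2           # one missing methyl: -14.0157
EXTRA_SULFO_SALT = SO3 - CH2 + NA - H  # next sulfation state, same charge: +87.9231


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class IonSpeciesError(ValueError):
    """Ion species inconsistent with the composition or polarity."""


@dataclass(frozen=True)
class IonSpecies:
    """Singly charged MALDI adduct species.

    ``n_sulfo`` is the sulfate count of the composition the species
    applies to; it selects between the plain sodiated form (positive,
    no sulfate), the deprotonated/sodium-counterion negative form and
    the positive sodium-salt form.
    """

    polarity: Polarity
    n_sulfo: int = 0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise IonSpeciesError("only singly charged ions are modelled")
        if self.polarity is Polarity.NEGATIVE and self.n_sulfo < 1:
            raise IonSpeciesError(
                "negative-mode species require at least one sulfate "
                "(the sulfated pool is the only one profiled in negative mode)"
            )

    @classmethod
    def for_composition(
        cls, comp: GlycanComposition, polarity: Polarity | str
    ) -> "IonSpecies":
        return cls(Polarity(polarity), n_sulfo=comp.sulfo)

    @property
    def adduct_shift(self) -> float:
        """Mass shift from the neutral free-acid M to the observed m/z."""
        n = self.n_sulfo
        if self.polarity is Polarity.POSITIVE:
            if n == 0:
                return NA
            return -n * PROTON + (n + 1) * NA
        return -n * PROTON + (n - 1) * NA

    @property
    def label(self) -> str:
        n = self.n_sulfo
        if self.polarity is Polarity.POSITIVE:
            if n == 0:
                return "[M+Na]+"
            return f"[M+{n + 1}Na-{n + 1}H]+" if n > 1 else "[M+2Na-2H]+"
        if n == 1:
            return "[M-H]-"
        return f"[M-{n}H+{n - 1}Na]-"


def neutral_mass(comp: GlycanComposition) -> float:
    """Neutral monoisotopic mass (free-acid form) of a permethylated glycan."""
    if comp.total_residues == 0:
        raise CompositionError("cannot compute the mass of an empty composition")
    return (
        comp.hex * RESIDUE_MASSES["hex"]
        + comp.hexnac * RESIDUE_MASSES["hexnac"]
        + comp.dhex * RESIDUE_MASSES["dhex"]
        + comp.neuac * RESIDUE_MASSES["neuac"]
        + CLOSURE_MASS
        + comp.sulfo * SULFO_DELTA
    )


def ion_mz(
    comp: GlycanComposition,
    species: IonSpecies | Polarity | str,
) -> float:
    """Observed singly charged m/z of a composition under the adduct rules.

    ``species`` may be a full :class:`IonSpecies` (its ``n_sulfo`` must
    match the composition) or just a polarity, in which case the species
    is derived from the composition's sulfate count.

    Raises
    ------
    IonSpeciesError
        For negative mode with an unsulfated composition, or a species
        whose sulfate count disagrees with the composition.
    """
    if not isinstance(species, IonSpecies):
        species = IonSpecies.for_composition(comp, species)
    elif species.n_sulfo != comp.sulfo:
        raise IonSpeciesError(
            f"species sulfate count {species.n_sulfo} != composition {comp.sulfo}"
        )
    return neutral_mass(comp) + species.adduct_shift


def satellite_offsets() -> dict[str, float]:
    """m/z offsets of the satellite peaks flagged next to assigned ions.

    ``under_permethylation``: -14.0157 Da per missing methyl group (sulfate
    loss during workup/ionization leaves one unmethylated hydroxyl).
    ``extra_sulfo_salt``: +87.9231 Da, the spacing from an n-sulfated
    negative ion to the (n+1)-sulfated ion of the same base composition
    under the sodium-salt convention (SO3 - CH2 + Na - H); its nearest
    integer is the +88 Da adduct spacing used to spot di-sulfation.
    """
    return {
        "under_permethylation": UNDER_PERMETHYLATION,
        "extra_sulfo_salt": EXTRA_SULFO_SALT,
    }


def mass_table_csv() -> str:
    """The residue/constant table as CSV text, for audit and export."""
    buf = io.StringIO()
    buf.write("name,mass_da,note\n")
    for name, mass in RESIDUE_MASSES.items():
        buf.write(f"{name},{mass:.4f},permethylated residue\n")
    buf.write(f"closure,{CLOSURE_MASS:.4f},free reducing end + termini (C2H6O)\n")
    buf.write(f"sulfo_delta,{SULFO_DELTA:.4f},per sulfate (+SO3 -CH2)\n")
    buf.write(f"proton,{PROTON:.5f},1H\n")
    buf.write(f"sodium,{NA:.5f},Na\n")
    buf.write(f"ch2,{CH2:.5f},methylene\n")
    buf.write(f"so3,{SO3:.5f},sulfo\n")
    return buf.getvalue()
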