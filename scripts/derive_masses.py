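"""Derive the permethylated-residue mass table from atomic masses and
validate the frozen ion/fragment conventions against printed peak labels.

Run from the repository root::

    python scripts/derive_masses.py

This is the audit trail for every constant in ``sulfoglyco.masses``: each
residue mass is rebuilt from IUPAC monoisotopic atomic masses and the
elemental formula of the permethylated glycosyl residue, then the full
set of published peak and fragment labels is recomputed through the
package and compared at the +/-1 Da integer-label policy.
"""

from __future__ import annotations

import sys

# IUPAC monoisotopic atomic masses (Da).
ATOM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
        "O": 15.9949146221, "Na": 22.98976928, "S": 31.97207069}


def formula_mass(formula: dict[str, int]) -> float:
    return sum(ATOM[el] * n for el, n in formula.items())


# Elemental formulas of permethylated glycosyl residues (the repeating
# unit inside a chain, i.e. the residue after loss of water on
# glycosidic-bond formation, fully O/N-methylated).
RESIDUE_FORMULAS = {
    "hex": {"C": 9, "H": 16, "O": 5},
    "hexnac": {"C": 11, "H": 19, "N": 1, "O": 5},
    "dhex": {"C": 8, "H": 14, "O": 4},
    # Neu5Ac residue C11H17NO8 plus 5 CH2 (4 O-methyls + methyl ester).
    "neuac": {"C": 16, "H": 27, "N": 1, "O": 8},
}
CLOSURE_FORMULA = {"C": 2, "H": 6, "O": 1}   # free reducing end + termini


def main() -> int:
    from sulfoglyco import ion_mz, parse_composition, parse_topology
    from sulfoglyco.fragments import enumerate_glycosidic_fragments
    from sulfoglyco.masses import CLOSURE_MASS, RESIDUE_MASSES, SULFO_DELTA

    failures = 0

    def check(label, computed, expected, tol):
        nonlocal failures
        ok = abs(computed - expected) <= tol
        failures += 0 if ok else 1
        print(f"  {'ok ' if ok else 'FAIL'} {label}: computed {computed:.4f} "
              f"vs {expected} (tol {tol})")

    print("residue masses from atomic composition:")
    for name, formula in RESIDUE_FORMULAS.items():
        check(name, formula_mass(formula), RESIDUE_MASSES[name], 5e-4)
    check("closure", formula_mass(CLOSURE_FORMULA), CLOSURE_MASS, 5e-4)
    check("sulfo delta (SO3 - CH2)",
          formula_mass({"S": 1, "O": 3}) - formula_mass({"C": 1, "H": 2}),
          SULFO_DELTA, 5e-4)

    print("printed MS1 peak labels (integer policy, +/-1 Da):")
    for text, polarity, printed in [
        ("Hex5HexNAc2", "positive", 1579),
        ("Hex6HexNAc2", "positive", 1783),
        ("Hex7HexNAc2", "positive", 1987),
        ("Hex8HexNAc2", "positive", 2192),
        ("Hex9HexNAc2", "positive", 2396),
        ("Hex5HexNAc4Fuc1NeuAc1", "positive", 2605),
        ("Hex5HexNAc4Fuc1NeuAc2", "positive", 2966),
        ("Hex6HexNAc5Fuc1NeuAc1", "positive", 3054),
        ("Hex5HexNAc5Fuc1NeuAc2", "positive", 3211),
        ("Hex5HexNAc4Sulf1", "negative", 2112),
        ("Hex5HexNAc4Fuc1Sulf1", "negative", 2286),
        ("Hex5HexNAc4Fuc1NeuAc1Sulf1", "negative", 2647),
        ("Hex6HexNAc5Fuc1Sulf1", "negative", 2735),
        ("Hex6HexNAc5Fuc1NeuAc1Sulf1", "negative", 3096),
        ("Hex4HexNAc3Sulf1", "negative", 1662),
        ("Hex4HexNAc3Fuc1Sulf1", "negative", 1836),
        ("Hex5HexNAc3Sulf1", "negative", 1866),
        ("Hex5HexNAc3Fuc1Sulf1", "negative", 2041),
        ("Hex5HexNAc4Fuc1Sulf2", "negative", 2374),
        ("Hex5HexNAc4Fuc1Sulf1", "positive", 2332),
        ("Hex5HexNAc4Fuc1NeuAc1Sulf1", "positive", 2693),
    ]:
        check(f"{text} {polarity}", ion_mz(parse_composition(text), polarity),
              printed, 1.0)

    print("printed MS/MS fragment labels of the sulfated biantennary:")
    topo = parse_topology(
        "GlcNAc(Fuc)(GlcNAc(Man(Man(GlcNAc(Gal[S3])))(Man(GlcNAc(Gal)))))"
    )
    for polarity, printed_set in [
        ("negative", (283, 528, 1834, 2067, 1822)),
        ("positive", (474, 486, 574, 1781, 1869, 1881, 2026)),
    ]:
        mzs = [f.mz for f in enumerate_glycosidic_fragments(topo, polarity)]
        for printed in printed_set:
            nearest = min(mzs, key=lambda m: abs(m - printed))
            check(f"{polarity} fragment {printed}", nearest, printed, 1.0)

    print(f"{failures} failures")
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
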