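"""Physical constants for mass and isotope arithmetic.

Atomic isotope masses and natural abundances come from the NIST reference
table shipped with :mod:`pyteomics` (``pyteomics.mass.nist_mass``), restricted
to the five elements present in unmodified peptides (C, H, N, O, S).  The
table can be exported to TSV for audit with :func:`write_isotope_table`.
"""

from __future__ import annotations

import csv

from pyteomics.mass import nist_mass

#: Elements supported in peptide elemental formulas, fixed order.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")

#: Mass of a proton in Da, used for m/z <-> neutral-mass conversion.
PROTON_MASS = 1.007276

#: Natural abundance of 13C (atom fraction).
NATURAL_C13 = 0.0107

#: Mass difference between 13C and 12C in Da — the nucleon-offset spacing of
#: carbon isotopologue envelopes, and the spacing assumed for integer parent
#: mass offsets (deisotoping errors move the reported precursor by multiples
#: of this).
C13_DELTA = nist_mass["C"][13][0] - nist_mass["C"][12][0]


def _natural_isotopes(element: str) -> tuple[tuple[int, float, float], ...]:
    """(nucleon offset from lightest stable isotope, mass Da, abundance)."""
    present = [
        (a, m, ab) for a, (m, ab) in nist_mass[element].items() if a > 0 and ab > 0.0
    ]
    present.sort()
    lightest = present[0][0]
    return tuple((a - lightest, m, ab) for a, m, ab in present)


#: element -> ((offset, mass, natural abundance), ...), offsets relative to
#: the lightest stable isotope.
NATURAL_ISOTOPES: dict[str, tuple[tuple[int, float, float], ...]] = {
    el: _natural_isotopes(el) for el in ELEMENTS
}

#: Monoisotopic (lightest stable isotope) mass per element, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    el: NATURAL_ISOTOPES[el][0][1] for el in ELEMENTS
}

#: Monoisotopic mass of water, Da.
WATER_MONO = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]


def write_isotope_table(path) -> None:
    """Dump the isotope constants to a TSV file for audit."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["element", "nucleon_offset", "mass_da", "natural_abundance"])
        for element in ELEMENTS:
            for offset, mass, abundance in NATURAL_ISOTOPES[element]:
                writer.writerow([element, offset, f"{mass:.10f}", f"{abundance:.6f}"])
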