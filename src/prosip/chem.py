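"""Peptide chemistry: tryptic digestion, elemental composition, masses.

Residue elemental compositions are taken from pyteomics' standard amino-acid
table.  Digestion is fully specific trypsin (cleave C-terminal to K/R, not
before P) with a bounded number of missed cleavages, matching the search
settings used throughout the package.  The only variable modification
supported is methionine oxidation (+O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from pyteomics.mass import std_aa_comp

from .constants import ELEMENTS, MONOISOTOPIC_MASS, WATER_MONO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Supported variable modification ids and their composition deltas.
MODIFICATIONS: dict[str, dict[str, int]] = {
    "Oxidation": {"O": 1},
}


@dataclass(frozen=True)
class ElementalFormula:
    """Counts of C, H, N, O, S atoms in a neutral molecule."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        counts = self.as_tuple()
        if any(c < 0 for c in counts):
            raise ValueError(f"negative element count in {self}")
        if not any(counts):
            raise ValueError("formula must contain at least one atom")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.C, self.H, self.N, self.O, self.S)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            *(a + b for a, b in zip(self.as_tuple(), other.as_tuple()))
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            *(a - b for a, b in zip(self.as_tuple(), other.as_tuple()))
        )

    def monoisotopic_mass(self) -> float:
        """Neutral mass with every atom as its lightest stable isotope, Da."""
        return sum(
            count * MONOISOTOPIC_MASS[el] for el, count in zip(ELEMENTS, self.as_tuple())
        )


WATER = ElementalFormula(H=2, O=1)


def _residue_formulas() -> dict[str, ElementalFormula]:
    table = {}
    for residue in AMINO_ACIDS:
        comp = std_aa_comp[residue]
        table[residue] = ElementalFormula(
            **{el: int(comp.get(el, 0)) for el in ELEMENTS}
        )
    return table


#: Residue (amino acid minus water) elemental formulas.
RESIDUE_FORMULAS: dict[str, ElementalFormula] = _residue_formulas()


@dataclass(frozen=True)
class Peptide:
    """A fully tryptic peptide with optional modifications.

    ``mods`` holds (zero-based residue position, modification id) pairs;
    ``protein_ids`` the accessions of the source proteins (possibly empty for
    free-standing peptides).
    """

    sequence: str
    missed_cleavages: int = 0
    mods: tuple[tuple[int, str], ...] = ()
    protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-residue characters in peptide: {sorted(bad)!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        for pos, mod in self.mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"mod position {pos} outside peptide bounds")
            if mod not in MODIFICATIONS:
                raise ValueError(f"unknown modification id {mod!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, tuple[tuple[int, str], ...]]:
        """Identity of the (sequence, modifications) analyte."""
        return (self.sequence, self.mods)


def cleavage_sites(sequence: str) -> list[int]:
    """Trypsin cut positions: after K or R, unless the next residue is P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    max_missed: int = 3,
    enzyme: str = "trypsin",
    min_length: int = 6,
    max_length: int = 50,
    protein_id: str | None = None,
) -> list[Peptide]:
    """Fully-specific in-silico digestion.

    Returns every peptide delimited by cleavage sites (or the protein
    termini) containing 0..``max_missed`` internal missed cleavage sites and
    whose length lies in [``min_length``, ``max_length``].  Order is
    deterministic: by start position, then by missed-cleavage count.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if not 0 <= max_missed <= 3:
        raise ValueError("max_missed must be in [0, 3]")
    bad = set(protein_sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"non-residue characters in protein sequence: {sorted(bad)!r}"
        )
    bounds = [0] + cleavage_sites(protein_sequence) + [len(protein_sequence)]
    ids = (protein_id,) if protein_id else ()
    peptides = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            frag = protein_sequence[bounds[i]: bounds[j]]
            if min_length <= len(frag) <= max_length:
                peptides.append(
                    Peptide(frag, missed_cleavages=missed, protein_ids=ids)
                )
    return peptides


def elemental_composition(peptide: Peptide | str) -> ElementalFormula:
    """Elemental formula of a neutral peptide: residue sum + one water.

    Methionine oxidation adds one oxygen per modified residue.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    formula = WATER
    for residue in peptide.sequence:
        formula = formula + RESIDUE_FORMULAS[residue]
    for _pos, mod in peptide.mods:
        formula = formula + ElementalFormula(**MODIFICATIONS[mod])
    return formula


def neutral_mass(
    formula: ElementalFormula,
    mode: str = "monoisotopic",
    enrichment=None,
) -> float:
    """Neutral mass of a formula in Da.

    ``monoisotopic``: all atoms as their lightest stable isotope.
    ``most_abundant``: centroid mass of the maximal peak of the isotopologue
    envelope under ``enrichment`` (an :class:`~prosip.isotopes.EnrichmentSpec`,
    natural abundance when omitted).
    """
    if mode == "monoisotopic":
        return formula.monoisotopic_mass()
    if mode == "most_abundant":
        from .isotopes import formula_envelope, most_abundant_offset

        env = formula_envelope(formula, spec=enrichment)
        return float(env.centroid_masses[most_abundant_offset(env)])
    raise ValueError(f"unknown mass mode {mode!r}")


def mass_to_mz(neutral: float, charge: int) -> float:
    """m/z of an ion carrying ``charge`` protons."""
    from .constants import PROTON_MASS

    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral + charge * PROTON_MASS) / charge


def mz_to_mass(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge."""
    from .constants import PROTON_MASS

    return mz * charge - charge * PROTON_MASS


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein FASTA; accession is the first whitespace-delimited token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as handle:
        for accession, seq in records:
            handle.write(f">{accession}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i: i + 70] + "\n")
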