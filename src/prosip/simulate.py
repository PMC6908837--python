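"""Ground-truth synthetic communities, proteomes, and spectra.

The generator emulates the statistical structure the pipeline assumes, at
desk scale: multi-genome communities whose genomes differ in k-mer
composition (per-genome dinucleotide Markov bias) and in per-sample
abundance series; tryptic proteomes with a labeled subset at chosen
:sup:`13`\\ C atom%; and centroided spectra whose precursor and b/y fragment
envelopes follow the enrichment model, perturbed by multiplicative intensity
noise and peak dropout.  Every generator is deterministic given its seed,
and a :class:`TruthManifest` records the ground truth for every stage.

Coverage noise is Poisson on mean depth rather than read-level simulation,
and spectra are envelope-level centroid peak lists; chromatography, charge
states beyond 3+, and profile peaks are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import Gene, Scaffold
from .chem import Peptide, digest, elemental_composition, mass_to_mz
from .constants import NATURAL_C13, PROTON_MASS
from .isotopes import EnrichmentSpec, formula_envelope, most_abundant_offset
from .search import Spectrum, fragment_formulas

_DNA = np.array(list("ACGT"))
# residues used for random proteins; no P (avoids cleavage suppression) and
# no M (keeps the unmodified/oxidized search space identical)
_PROTEIN_ALPHABET = list("ADEFGHILNQSTVWY")


@dataclass
class TruthManifest:
    """Ground truth of a synthetic scene, keyed for every pipeline stage."""

    genome_sequences: dict[str, str] = field(default_factory=dict)
    genome_abundance: pd.DataFrame | None = None  # genome x sample
    scaffold_genome: dict[str, str] = field(default_factory=dict)
    protein_genome: dict[str, str] = field(default_factory=dict)
    protein_sequences: dict[str, str] = field(default_factory=dict)
    labeled_atom_fraction: dict[str, float] = field(default_factory=dict)
    spectrum_truth: dict[str, tuple[str, float, bool]] = field(
        default_factory=dict
    )  # spectrum_id -> (peptide sequence, atom fraction, matchable)
    genome_markers: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for protein in self.labeled_atom_fraction:
            if protein not in self.protein_genome:
                raise ValueError(f"labeled protein {protein} has no genome")
        if self.genome_abundance is not None and (
            self.genome_abundance.values < 0
        ).any():
            raise ValueError("abundance vectors must be >= 0")


# ---------------------------------------------------------------------------
# community


def _biased_sequence(length: int, rng: np.random.Generator) -> str:
    """Random DNA with a genome-specific dinucleotide transition bias."""
    transition = rng.dirichlet(np.full(4, 0.5), size=4)
    cumulative = np.cumsum(transition, axis=1)
    uniforms = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    state = int(rng.integers(4))
    for i in range(length):
        states[i] = state
        state = int(np.searchsorted(cumulative[state], uniforms[i]))
    return "".join(_DNA[states])


def generate_community(
    n_genomes: int = 8,
    genome_length: int = 25_000,
    n_samples: int = 14,
    abundance_sigma: float = 1.5,
    depth: float = 30.0,
    scaffold_log_mean: float = np.log(6000.0),
    scaffold_log_sigma: float = 0.25,
    min_scaffold: int = 1000,
    seed: int = 0,
) -> tuple[list[Scaffold], pd.DataFrame, TruthManifest]:
    """Genomes, fragmented scaffolds, and a per-sample coverage table.

    Genome abundances are iid lognormal per sample (distinct abundance
    series per genome); scaffold coverage is Poisson around abundance x
    ``depth``.  Scaffold lengths are lognormal with a 1 kbp floor.
    """
    if n_genomes < 2:
        raise ValueError("need at least two genomes")
    if genome_length < 2 * min_scaffold:
        raise ValueError("genome too short to fragment")
    rng = np.random.default_rng(seed)
    truth = TruthManifest()
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    abundance = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=abundance_sigma, size=(n_genomes, n_samples)),
        index=[f"genome_{g + 1:02d}" for g in range(n_genomes)],
        columns=samples,
    )
    scaffolds: list[Scaffold] = []
    coverage_rows = {}
    for g, genome_id in enumerate(abundance.index):
        sequence = _biased_sequence(genome_length, rng)
        truth.genome_sequences[genome_id] = sequence
        pos = 0
        i = 0
        while pos < len(sequence):
            length = int(
                max(min_scaffold, rng.lognormal(scaffold_log_mean, scaffold_log_sigma))
            )
            if len(sequence) - (pos + length) < min_scaffold:
                length = len(sequence) - pos
            sid = f"{genome_id}_scaf{i:03d}"
            lam = abundance.loc[genome_id].values * depth
            cov = rng.poisson(lam).astype(float)
            scaffolds.append(
                Scaffold(scaffold_id=sid, sequence=sequence[pos: pos + length],
                         coverage=cov)
            )
            coverage_rows[sid] = cov
            truth.scaffold_genome[sid] = genome_id
            pos += length
            i += 1
    truth.genome_abundance = abundance
    coverage = pd.DataFrame.from_dict(
        coverage_rows, orient="index", columns=samples
    )
    truth.validate()
    return scaffolds, coverage, truth


# ---------------------------------------------------------------------------
# proteome and labels


def _random_protein(
    rng: np.random.Generator, n_peptides: int = 8, pep_len=(6, 12)
) -> str:
    """Random protein made of tryptic segments ending in K/R."""
    parts = []
    for _ in range(n_peptides):
        length = int(rng.integers(pep_len[0], pep_len[1] + 1)) - 1
        body = "".join(rng.choice(_PROTEIN_ALPHABET, size=length))
        parts.append(body + ("K" if rng.random() < 0.5 else "R"))
    return "".join(parts)


def generate_proteome_and_labels(
    scaffolds: list[Scaffold],
    truth: TruthManifest,
    genes_per_genome: int = 12,
    labeled_proteins: dict[str, float] | None = None,
    labeled_fraction: float = 0.0,
    atom_percent_range: tuple[float, float] = (15.0, 46.0),
    n_markers: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthManifest]:
    """Random tryptic proteins placed as genes on scaffolds, plus labels.

    Genes are laid out left-to-right without overlap across each genome's
    scaffolds.  The labeled subset is either given explicitly (protein index
    within genome -> atom%) or drawn as ``labeled_fraction`` of all proteins
    with true atom% uniform in ``atom_percent_range``.  Single-copy markers
    (one full set per genome) are scattered over each genome's scaffolds
    with the genome id as taxonomy label.
    """
    rng = np.random.default_rng(seed)
    by_genome: dict[str, list[Scaffold]] = {}
    for scaffold in scaffolds:
        genome = truth.scaffold_genome[scaffold.scaffold_id]
        by_genome.setdefault(genome, []).append(scaffold)
    proteins: list[tuple[str, str]] = []
    marker_ids = [f"marker_{m:02d}" for m in range(n_markers)]
    for genome_id in sorted(by_genome):
        # longest scaffolds first so early genes and markers sit on
        # scaffolds that survive the binning length threshold
        members = sorted(
            by_genome[genome_id], key=lambda s: (-s.length, s.scaffold_id)
        )
        cursors = {s.scaffold_id: 1 for s in members}
        placed = 0
        attempt = 0
        while placed < genes_per_genome:
            scaffold = members[attempt % len(members)]
            attempt += 1
            if attempt > 10 * genes_per_genome:
                raise ValueError(
                    f"genome {genome_id} too short for {genes_per_genome} genes"
                )
            seq = _random_protein(rng)
            gene_len = 3 * len(seq) + 3
            start = cursors[scaffold.scaffold_id]
            if start + gene_len >= scaffold.length:
                continue
            protein_id = f"{genome_id}_p{placed:02d}"
            scaffold.genes.append(
                Gene(
                    gene_id=f"{protein_id}_gene",
                    protein_id=protein_id,
                    start=start,
                    end=start + gene_len - 1,
                )
            )
            cursors[scaffold.scaffold_id] = start + gene_len + 50
            proteins.append((protein_id, seq))
            truth.protein_genome[protein_id] = genome_id
            truth.protein_sequences[protein_id] = seq
            placed += 1
        # one full single-copy marker set per genome
        truth.genome_markers[genome_id] = marker_ids
        for m, marker in enumerate(marker_ids):
            scaffold = members[m % len(members)]
            scaffold.marker_hits.append((marker, genome_id))
    if labeled_proteins:
        for protein_id, atom_percent in labeled_proteins.items():
            if protein_id not in truth.protein_genome:
                raise KeyError(f"unknown protein {protein_id}")
            truth.labeled_atom_fraction[protein_id] = atom_percent / 100.0
    elif labeled_fraction > 0:
        ids = sorted(truth.protein_genome)
        n_label = int(round(labeled_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_label, replace=False)
        lo, hi = atom_percent_range
        for i in sorted(chosen):
            truth.labeled_atom_fraction[ids[i]] = (
                rng.uniform(lo, hi) / 100.0
            )
    truth.validate()
    return proteins, truth


# ---------------------------------------------------------------------------
# spectra


def synthetic_spectrum(
    peptide: Peptide | str,
    atom_fraction: float = NATURAL_C13,
    charge: int = 2,
    noise_sd: float = 0.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "spec",
    sample_id: str = "",
    replicate_id: str = "",
    precursor_intensity: float = 1000.0,
) -> Spectrum:
    """One centroided spectrum of a peptide at a true enrichment.

    The peak list holds the precursor isotopologue envelope at ``charge``
    plus singly-charged b/y fragment envelopes, each scaled by a random base
    intensity, multiplied by lognormal noise of sd ``noise_sd`` (so
    signal-to-noise ~ 1/``noise_sd``), with peaks dropped at probability
    ``dropout``.  The reported precursor m/z is the most abundant envelope
    peak.
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    spec = EnrichmentSpec("C", atom_fraction)
    formula = elemental_composition(peptide)
    env = formula_envelope(formula, spec)
    mode_off = most_abundant_offset(env)
    mode_mass = float(env.centroid_masses[mode_off - int(env.offsets[0])])
    mz_list = []
    int_list = []
    prec_mz = (env.centroid_masses + charge * PROTON_MASS) / charge
    for mz, ab in zip(prec_mz, env.abundances):
        mz_list.append(mz)
        int_list.append(precursor_intensity * ab)
    for _label, f_formula in fragment_formulas(peptide):
        f_env = formula_envelope(f_formula, spec)
        base = float(rng.uniform(200.0, 800.0))
        for mz, ab in zip(f_env.centroid_masses + PROTON_MASS, f_env.abundances):
            mz_list.append(mz)
            int_list.append(base * ab)
    mz_arr = np.array(mz_list)
    int_arr = np.array(int_list)
    if noise_sd > 0:
        int_arr = int_arr * np.exp(rng.normal(0.0, noise_sd, size=len(int_arr)))
    if dropout > 0:
        keep = rng.random(len(mz_arr)) >= dropout
        mz_arr, int_arr = mz_arr[keep], int_arr[keep]
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=mass_to_mz(mode_mass, charge),
        precursor_charge=charge,
        peaks=np.column_stack([mz_arr, int_arr]),
        sample_id=sample_id,
        replicate_id=replicate_id,
    )


def generate_spectra(
    peptide_assignments: list[tuple[Peptide | str, float, str, str]],
    noise_sd: float = 0.05,
    dropout: float = 0.0,
    decoy_rate: float = 0.0,
    charges: tuple[int, ...] = (2, 3),
    seed: int = 0,
    truth: TruthManifest | None = None,
) -> list[Spectrum]:
    """Spectra for (peptide, true atom fraction, sample, replicate) tuples.

    A ``decoy_rate`` fraction of spectra is generated from shuffled peptide
    sequences instead, making them unmatchable; the truth manifest marks
    them so.
    """
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else TruthManifest()
    n = len(peptide_assignments)
    n_decoy = int(round(decoy_rate * n))
    decoy_idx = set(
        rng.choice(n, size=n_decoy, replace=False).tolist()
    ) if n_decoy else set()
    spectra = []
    for i, (pep, atom_fraction, sample, replicate) in enumerate(
        peptide_assignments
    ):
        if isinstance(pep, str):
            pep = Peptide(pep)
        matchable = True
        if i in decoy_idx:
            # shuffle all but the C-terminal residue; unmatchable by design
            body = list(pep.sequence[:-1])
            rng.shuffle(body)
            pep = Peptide("".join(body) + pep.sequence[-1])
            matchable = False
        charge = int(charges[int(rng.integers(len(charges)))])
        sid = f"spec_{i:05d}"
        spectra.append(
            synthetic_spectrum(
                pep,
                atom_fraction=atom_fraction,
                charge=charge,
                noise_sd=noise_sd,
                dropout=dropout,
                rng=rng,
                spectrum_id=sid,
                sample_id=sample,
                replicate_id=replicate,
            )
        )
        truth.spectrum_truth[sid] = (pep.sequence, atom_fraction, matchable)
    return spectra


# ---------------------------------------------------------------------------
# a complete scene


@dataclass
class SyntheticScene:
    scaffolds: list[Scaffold]
    coverage: pd.DataFrame
    proteins: list[tuple[str, str]]
    spectra: list[Spectrum]
    truth: TruthManifest
    sample_blocks: dict[str, str]
    marker_set: list[str]


def default_scene(
    seed: int = 0,
    n_genomes: int = 8,
    labeled_atom_percents: tuple[float, ...] = (20.0, 50.0, 95.0),
    n_samples: int = 14,
    peptides_per_protein: int = 2,
    noise_sd: float = 0.05,
    n_unlabeled_spectra: int = 24,
) -> SyntheticScene:
    """The default end-to-end test scene.

    ``n_genomes`` genomes over ``n_samples`` samples; the first
    ``len(labeled_atom_percents)`` genomes each carry one labeled protein at
    the given atom%.  Labeled proteins get ``peptides_per_protein`` tryptic
    peptides measured twice in each of two samples of one plant block
    (satisfying the two-peptide rule); unlabeled spectra are drawn from the
    remaining proteome at natural abundance.
    """
    scaffolds, coverage, truth = generate_community(
        n_genomes=n_genomes, n_samples=n_samples, seed=seed
    )
    genome_ids = sorted(truth.genome_sequences)
    labeled = {}
    for g, atom_percent in enumerate(labeled_atom_percents):
        labeled[f"{genome_ids[g]}_p00"] = atom_percent
    proteins, truth = generate_proteome_and_labels(
        scaffolds, truth, labeled_proteins=labeled, seed=seed + 1
    )
    samples = list(coverage.columns)
    # first 12 samples: 3 plant blocks x (2 timepoints x 2 replicates);
    # last 2 are unplanted initial-soil controls
    blocks = {}
    plants = ["plantA", "plantB", "plantC"]
    for i, sample in enumerate(samples[:12]):
        blocks[sample] = plants[i // 4]
    for sample in samples[12:]:
        blocks[sample] = "initial"
    assignments: list[tuple[Peptide | str, float, str, str]] = []
    for g, (protein_id, atom_percent) in enumerate(sorted(labeled.items())):
        block_samples = [s for s in samples if blocks[s] == plants[g % 3]][:2]
        seq = truth.protein_sequences[protein_id]
        peps = [
            p
            for p in digest(seq, max_missed=0)
            if elemental_composition(p).C >= 20
        ][:peptides_per_protein]
        for sample in block_samples:
            for pep in peps:
                assignments.append(
                    (pep.sequence, atom_percent / 100.0, sample, "r1")
                )
    rng = np.random.default_rng(seed + 2)
    unlabeled = [p for p in sorted(truth.protein_sequences) if p not in labeled]
    for i in range(n_unlabeled_spectra):
        protein_id = unlabeled[int(rng.integers(len(unlabeled)))]
        peps = digest(truth.protein_sequences[protein_id], max_missed=0)
        pep = peps[int(rng.integers(len(peps)))]
        sample = samples[int(rng.integers(12))]
        assignments.append((pep.sequence, NATURAL_C13, sample, "r1"))
    spectra = generate_spectra(
        assignments, noise_sd=noise_sd, seed=seed + 3, truth=truth
    )
    marker_set = truth.genome_markers[genome_ids[0]]
    return SyntheticScene(
        scaffolds=scaffolds,
        coverage=coverage,
        proteins=proteins,
        spectra=spectra,
        truth=truth,
        sample_blocks=blocks,
        marker_set=list(marker_set),
    )
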