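"""Enrichment-resolved peptide-spectrum matching and target-decoy FDR.

A SIP database search scores each spectrum against candidate peptides over a
grid of :sup:`13`\\ C enrichment hypotheses.  For every grid point the
precursor isotopologue envelope and the b/y fragment envelopes are computed
from the peptide's elemental composition, aligned against the observed peak
list, and scored with a cosine-normalized weighted dot product; the
enrichment estimate is the grid argmax.  Integer parent-mass offsets (in
units of the 13C-12C spacing) absorb precursor deisotoping errors.  The
regular (unlabeled) search is the same machinery with offsets -1..3 and the
grid pinned to natural abundance.

False-discovery control follows the concatenated target-decoy approach:
every target protein contributes a full-sequence-reversed decoy, and
identifications are filtered to a peptide-level FDR by score thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import (
    ElementalFormula,
    Peptide,
    RESIDUE_FORMULAS,
    WATER,
    digest,
    elemental_composition,
    mass_to_mz,
    mz_to_mass,
)
from .constants import C13_DELTA, NATURAL_C13, PROTON_MASS
from .isotopes import (
    EnrichmentSpec,
    Envelope,
    formula_envelope,
    most_abundant_offset,
)

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"


# ---------------------------------------------------------------------------
# spectra


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with its precursor and sample labels."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # (n, 2) array of (m/z, intensity), sorted by m/z
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if not 1 <= self.precursor_charge <= 6:
            raise ValueError("precursor charge must lie in [1, 6]")
        if not np.all(np.isfinite(self.peaks)):
            raise ValueError("peaks must be finite")
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def precursor_neutral_mass(self) -> float:
        return mz_to_mass(self.precursor_mz, self.precursor_charge)


# ---------------------------------------------------------------------------
# configuration


def sip_enrichment_grid(
    step: float = 0.01, start: float = 0.02, stop: float = 0.99
) -> tuple[float, ...]:
    """SIP enrichment grid: the natural-abundance point plus ``step``
    increments from ``start`` to ``stop`` atom fraction (default 1 atom%
    steps from 2% to 99%)."""
    points = [NATURAL_C13]
    value = start
    while value <= stop + 1e-12:
        if value > NATURAL_C13 + 1e-12:
            points.append(round(value, 10))
        value += step
    return tuple(points)


@dataclass(frozen=True)
class SearchConfig:
    """Tolerances, offsets, and the enrichment grid for one search mode."""

    parent_offsets: tuple[int, ...] = tuple(range(-4, 5))
    parent_tol_da: float = 0.03
    fragment_tol_da: float = 0.01
    enrichment_grid: tuple[float, ...] = field(default_factory=sip_enrichment_grid)
    max_missed: int = 3
    variable_mods: tuple[str, ...] = ()
    min_peptide_length: int = 6
    max_peptide_length: int = 50

    def __post_init__(self) -> None:
        if self.parent_tol_da <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be > 0")
        grid = tuple(self.enrichment_grid)
        if list(grid) != sorted(grid):
            raise ValueError("enrichment grid must be sorted ascending")
        if grid[0] < 0 or grid[-1] > 1:
            raise ValueError("enrichment grid must lie in [0, 1]")


def sip_config(**overrides) -> SearchConfig:
    """SIP search: parent offsets -4..4, full enrichment grid, no mods."""
    return SearchConfig(**overrides)


def regular_config(**overrides) -> SearchConfig:
    """Regular (unlabeled) search: offsets -1..3, natural-abundance grid,
    methionine oxidation as the only variable modification."""
    defaults = dict(
        parent_offsets=(-1, 0, 1, 2, 3),
        enrichment_grid=(NATURAL_C13,),
        variable_mods=("Oxidation",),
    )
    defaults.update(overrides)
    return SearchConfig(**defaults)


# ---------------------------------------------------------------------------
# decoy database


def make_decoy_db(
    records: Sequence[tuple[str, str]], prefix: str = DECOY_PREFIX
) -> list[tuple[str, str]]:
    """Concatenated target+decoy database: one full-sequence-reversed decoy
    per target, accession prefixed with ``prefix``."""
    if not records:
        raise ValueError("empty protein database")
    for accession, _seq in records:
        if accession.startswith(prefix):
            raise ValueError(
                f"accession {accession!r} collides with decoy prefix {prefix!r}"
            )
    decoys = [(prefix + acc, seq[::-1]) for acc, seq in records]
    return list(records) + decoys


def is_decoy(accession: str, prefix: str = DECOY_PREFIX) -> bool:
    return accession.startswith(prefix)


# ---------------------------------------------------------------------------
# peptide index


@dataclass
class IndexedPeptide:
    peptide: Peptide
    protein_ids: tuple[str, ...]
    formula: ElementalFormula
    mono_mass: float
    fragments: tuple[tuple[str, ElementalFormula], ...] | None = None

    @property
    def is_decoy(self) -> bool:
        return all(is_decoy(p) for p in self.protein_ids)


def fragment_formulas(
    peptide: Peptide,
) -> tuple[tuple[str, ElementalFormula], ...]:
    """Elemental formulas of singly-protonated b and y ions (charge 1).

    The neutral-species convention: a b_i fragment is the sum of the first i
    residue formulas, a y_i fragment the last i residues plus water; the
    proton is added at m/z conversion time.  b1/y1 ions are omitted.
    """
    from .chem import MODIFICATIONS

    seq = peptide.sequence
    mods = dict(peptide.mods)
    prefixes: list[ElementalFormula] = []
    acc: ElementalFormula | None = None
    for pos, residue in enumerate(seq):
        res = RESIDUE_FORMULAS[residue]
        if pos in mods:
            res = res + ElementalFormula(**MODIFICATIONS[mods[pos]])
        acc = res if acc is None else acc + res
        prefixes.append(acc)
    total = elemental_composition(peptide)
    ions = []
    for i in range(2, len(seq)):
        ions.append((f"b{i}", prefixes[i - 1]))
    for i in range(2, len(seq)):
        # y_i = total - b-type prefix of length L-i; water stays on y
        ions.append((f"y{i}", total - prefixes[len(seq) - i - 1]))
    return tuple(ions)


class PeptideIndex:
    """Digested target+decoy peptide index supporting precursor lookup."""

    def __init__(self, entries: dict[tuple, IndexedPeptide]):
        if not entries:
            raise ValueError("empty peptide index")
        self.entries = entries
        self._keys = sorted(entries)
        self._mono = np.array([entries[k].mono_mass for k in self._keys])
        self._ncarbon = np.array([entries[k].formula.C for k in self._keys])

    @classmethod
    def build(
        cls,
        database: Sequence[tuple[str, str]],
        config: SearchConfig,
    ) -> "PeptideIndex":
        """Digest a (target+decoy) protein database into a peptide index.

        At most one oxidized methionine per peptide is enumerated when
        oxidation is among the configured variable modifications.
        """
        entries: dict[tuple, IndexedPeptide] = {}
        proteins: dict[tuple, set[str]] = {}
        peptide_obj: dict[tuple, Peptide] = {}
        for accession, sequence in database:
            for pep in digest(
                sequence,
                max_missed=config.max_missed,
                min_length=config.min_peptide_length,
                max_length=config.max_peptide_length,
            ):
                variants = [pep]
                if "Oxidation" in config.variable_mods:
                    for pos, residue in enumerate(pep.sequence):
                        if residue == "M":
                            variants.append(
                                replace(pep, mods=((pos, "Oxidation"),))
                            )
                for variant in variants:
                    proteins.setdefault(variant.key, set()).add(accession)
                    peptide_obj.setdefault(variant.key, variant)
        for key, pep in peptide_obj.items():
            ids = tuple(sorted(proteins[key]))
            formula = elemental_composition(pep)
            entries[key] = IndexedPeptide(
                peptide=replace(pep, protein_ids=ids),
                protein_ids=ids,
                formula=formula,
                mono_mass=formula.monoisotopic_mass(),
            )
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def candidates(
        self, neutral_mass: float, config: SearchConfig
    ) -> list[IndexedPeptide]:
        """Peptides whose envelope could match ``neutral_mass`` at some grid
        point after an allowed integer parent offset (coarse prefilter)."""
        k = (neutral_mass - self._mono) / C13_DELTA
        k_round = np.round(k)
        residual = np.abs(neutral_mass - self._mono - k_round * C13_DELTA)
        lo = min(config.parent_offsets)
        hi = max(config.parent_offsets)
        max_heavy = np.ceil(self._ncarbon * config.enrichment_grid[-1]) + 3
        ok = (
            (residual <= config.parent_tol_da + 0.01)
            & (k_round >= lo - 1)
            & (k_round <= max_heavy + hi + 1)
        )
        return [self.entries[self._keys[i]] for i in np.flatnonzero(ok)]

    def fragments_of(self, entry: IndexedPeptide):
        if entry.fragments is None:
            entry.fragments = fragment_formulas(entry.peptide)
        return entry.fragments


# ---------------------------------------------------------------------------
# scoring


def matched_intensities(
    peaks: np.ndarray, mz_values: np.ndarray, tol: float
) -> np.ndarray:
    """Observed intensity aligned to theoretical m/z positions.

    For each theoretical m/z, the intensity of the nearest observed peak
    within ``tol`` Da, else 0.
    """
    if len(peaks) == 0:
        return np.zeros(len(mz_values))
    mz = peaks[:, 0]
    idx = np.searchsorted(mz, mz_values)
    left = np.clip(idx - 1, 0, len(mz) - 1)
    right = np.clip(idx, 0, len(mz) - 1)
    d_left = np.abs(mz_values - mz[left])
    d_right = np.abs(mz_values - mz[right])
    best = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    out = np.where(dist <= tol, peaks[best, 1], 0.0)
    return out


def score_envelope(observed: np.ndarray, theoretical: Envelope) -> float:
    """Cosine-normalized weighted dot product of an observed intensity
    vector against theoretical envelope abundances; 0 for all-zero input."""
    obs = np.asarray(observed, dtype=float)
    theo = theoretical.abundances
    n_obs = np.linalg.norm(obs)
    if n_obs == 0:
        return 0.0
    return float(np.dot(obs, theo) / (n_obs * np.linalg.norm(theo)))


@dataclass(frozen=True)
class AtomPercentEstimate:
    atom_fraction: float
    score: float
    parent_offset: int
    precursor_score: float
    fragment_score: float
    n_fragments_matched: int
    peak_area: float

    @property
    def atom_percent(self) -> float:
        return 100.0 * self.atom_fraction


def _approx_mode(n_carbon: int, p: float) -> int:
    return int(np.floor((n_carbon + 1) * p))


def estimate_atom_percent(
    spectrum: Spectrum,
    peptide: Peptide | IndexedPeptide,
    config: SearchConfig,
    index: PeptideIndex | None = None,
    fragment_top_k: int = 7,
    precursor_only: bool = False,
) -> AtomPercentEstimate | None:
    """Grid search over enrichment hypotheses for one peptide candidate.

    Per grid point, the combined score is 0.5 x precursor-envelope score +
    0.5 x mean fragment-envelope score over the b/y ion series (a fragment
    with no peak within the fragment tolerance scores 0).  Only grid points
    where the precursor envelope's most abundant peak matches the reported
    precursor within the parent tolerance — after one allowed integer
    parent offset — are scored; fragment envelopes are evaluated for the
    ``fragment_top_k`` best grid points by precursor score.  Ties break
    toward the lower enrichment.  Returns ``None`` when no grid point
    yields a precursor match.
    """
    if isinstance(peptide, Peptide):
        formula = elemental_composition(peptide)
        entry = IndexedPeptide(
            peptide=peptide,
            protein_ids=peptide.protein_ids,
            formula=formula,
            mono_mass=formula.monoisotopic_mass(),
        )
    else:
        entry = peptide
    z = spectrum.precursor_charge
    obs_neutral = spectrum.precursor_neutral_mass
    k_star = int(round((obs_neutral - entry.mono_mass) / C13_DELTA))
    if abs(obs_neutral - entry.mono_mass - k_star * C13_DELTA) > (
        config.parent_tol_da + 0.01
    ):
        return None
    offsets = config.parent_offsets
    k_lo = k_star - max(offsets)
    k_hi = k_star - min(offsets)
    n_c = entry.formula.C
    # pass 1: precursor-envelope match and score per admissible grid point
    precursor_pass: list[tuple[float, int, float, float]] = []
    for p in config.enrichment_grid:
        approx = _approx_mode(n_c, p)
        if approx < k_lo - 2 or approx > k_hi + 2:
            continue
        env = formula_envelope(entry.formula, EnrichmentSpec("C", p))
        mode_offset = most_abundant_offset(env)
        mode_mass = float(
            env.centroid_masses[mode_offset - int(env.offsets[0])]
        )
        offset = None
        for o in offsets:
            if abs(obs_neutral - (mode_mass + o * C13_DELTA)) <= config.parent_tol_da:
                offset = o
                break
        if offset is None:
            continue
        prec_mz = (env.centroid_masses + z * PROTON_MASS) / z
        prec_obs = matched_intensities(
            spectrum.peaks, prec_mz, config.parent_tol_da
        )
        prec_score = score_envelope(prec_obs, env)
        precursor_pass.append((p, offset, prec_score, float(prec_obs.sum())))
    if not precursor_pass:
        return None
    if precursor_only:
        p, offset, prec_score, prec_area = min(
            precursor_pass, key=lambda t: (-t[2], t[0])
        )
        return AtomPercentEstimate(
            atom_fraction=p,
            score=prec_score,
            parent_offset=offset,
            precursor_score=prec_score,
            fragment_score=0.0,
            n_fragments_matched=0,
            peak_area=prec_area,
        )
    # pass 2: fragment envelopes for the strongest precursor hypotheses
    shortlist = sorted(precursor_pass, key=lambda t: (-t[2], t[0]))[
        : max(1, fragment_top_k)
    ]
    shortlist.sort(key=lambda t: t[0])  # ascending p: ties -> lower enrichment
    fragments = (
        index.fragments_of(entry)
        if index is not None
        else fragment_formulas(entry.peptide)
    )
    best: AtomPercentEstimate | None = None
    for p, offset, prec_score, prec_area in shortlist:
        frag_scores = []
        for _label, f_formula in fragments:
            f_env = formula_envelope(f_formula, EnrichmentSpec("C", p))
            f_mz = f_env.centroid_masses + PROTON_MASS
            f_obs = matched_intensities(
                spectrum.peaks, f_mz, config.fragment_tol_da
            )
            frag_scores.append(score_envelope(f_obs, f_env))
        frag_score = float(np.mean(frag_scores)) if frag_scores else 0.0
        combined = 0.5 * prec_score + 0.5 * frag_score
        if best is None or combined > best.score + 1e-12:
            best = AtomPercentEstimate(
                atom_fraction=p,
                score=combined,
                parent_offset=offset,
                precursor_score=prec_score,
                fragment_score=frag_score,
                n_fragments_matched=int(np.sum(np.asarray(frag_scores) > 0)),
                peak_area=prec_area,
            )
    return best


# ---------------------------------------------------------------------------
# search and FDR


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    spectrum_id: str
    sample_id: str
    replicate_id: str
    sequence: str
    mods: tuple[tuple[int, str], ...]
    protein_ids: tuple[str, ...]
    is_decoy: bool
    atom_percent: float
    score: float
    parent_offset_da: int
    precursor_charge: int
    peak_area: float

    @property
    def peptide_key(self) -> tuple:
        return (self.sequence, self.mods)


def search_sample(
    spectra: Iterable[Spectrum],
    index: PeptideIndex,
    config: SearchConfig,
    candidate_top_k: int = 5,
) -> list[PeptideSpectrumMatch]:
    """Search spectra against a digested target+decoy index.

    Candidates passing the precursor prefilter are triaged by their
    precursor-envelope score, and the ``candidate_top_k`` strongest receive
    full fragment-envelope scoring.  Per spectrum, only the best-scoring
    (peptide x enrichment x offset) candidate is retained.  Malformed
    spectra are skipped and counted.
    """
    psms: list[PeptideSpectrumMatch] = []
    skipped = 0
    for spectrum in spectra:
        try:
            neutral = spectrum.precursor_neutral_mass
        except Exception:
            skipped += 1
            continue
        if len(spectrum.peaks) == 0:
            skipped += 1
            continue
        triage: list[tuple[float, str, tuple, IndexedPeptide]] = []
        for entry in index.candidates(neutral, config):
            quick = estimate_atom_percent(
                spectrum, entry, config, index=index, precursor_only=True
            )
            if quick is None:
                continue
            triage.append(
                (
                    -quick.precursor_score,
                    entry.peptide.sequence,
                    entry.peptide.mods,
                    entry,
                )
            )
        triage.sort(key=lambda t: t[:3])
        best: tuple | None = None
        for _negscore, _seq, _mods, entry in triage[: max(1, candidate_top_k)]:
            est = estimate_atom_percent(spectrum, entry, config, index=index)
            if est is None:
                continue
            # deterministic ordering: higher score, then lower enrichment,
            # then target before decoy, then lexicographic peptide
            rank = (
                -est.score,
                est.atom_fraction,
                entry.is_decoy,
                entry.peptide.sequence,
                entry.peptide.mods,
            )
            if best is None or rank < best[0]:
                best = (rank, entry, est)
        if best is None:
            continue
        _rank, entry, est = best
        psms.append(
            PeptideSpectrumMatch(
                spectrum_id=spectrum.spectrum_id,
                sample_id=spectrum.sample_id,
                replicate_id=spectrum.replicate_id,
                sequence=entry.peptide.sequence,
                mods=entry.peptide.mods,
                protein_ids=entry.protein_ids,
                is_decoy=entry.is_decoy,
                atom_percent=est.atom_percent,
                score=est.score,
                parent_offset_da=est.parent_offset,
                precursor_charge=spectrum.precursor_charge,
                peak_area=est.peak_area,
            )
        )
    if skipped:
        logger.warning("skipped %d malformed spectra", skipped)
    return psms


def fdr_filter(
    psms: Sequence[PeptideSpectrumMatch], level: float = 0.01
) -> list[PeptideSpectrumMatch]:
    """Peptide-level target-decoy FDR filtering.

    PSMs are collapsed to the best per peptide, sorted by score descending
    (decoys first at ties, conservatively), and the largest prefix with
    #decoy/#target <= ``level`` is retained.  Decoys are excluded from the
    returned identifications.
    """
    if not 0 < level < 1:
        raise ValueError("FDR level must lie in (0, 1)")
    best: dict[tuple, PeptideSpectrumMatch] = {}
    for psm in psms:
        key = (psm.peptide_key, psm.is_decoy)
        if key not in best or psm.score > best[key].score:
            best[key] = psm
    ranked = sorted(
        best.values(), key=lambda m: (-m.score, not m.is_decoy, m.sequence, m.mods)
    )
    n_target = n_decoy = 0
    cut = -1
    for i, psm in enumerate(ranked):
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if n_target > 0 and n_decoy / n_target <= level:
            cut = i
    if cut < 0:
        return []
    return [m for m in ranked[: cut + 1] if not m.is_decoy]


# ---------------------------------------------------------------------------
# MGF I/O


def write_mgf(spectra: Sequence[Spectrum], path, manifest_path=None) -> None:
    """Write spectra to MGF; TITLE carries the spectrum id.  Sample and
    replicate labels go to a sidecar TSV manifest when requested."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
    if manifest_path is not None:
        with open(manifest_path, "w") as handle:
            handle.write("spectrum_id\tsample_id\treplicate_id\n")
            for s in spectra:
                handle.write(f"{s.spectrum_id}\t{s.sample_id}\t{s.replicate_id}\n")


def read_mgf(path, manifest_path=None) -> list[Spectrum]:
    """Read MGF spectra, attaching sample/replicate labels from a sidecar
    manifest TSV when given."""
    labels: dict[str, tuple[str, str]] = {}
    if manifest_path is not None:
        with open(manifest_path) as handle:
            header = handle.readline()
            for line in handle:
                sid, sample, rep = line.rstrip("\n").split("\t")
                labels[sid] = (sample, rep)
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            title = entry["params"]["title"]
            charge = int(entry["params"]["charge"][0])
            sample, rep = labels.get(title, ("", ""))
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(entry["params"]["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=np.column_stack(
                        [entry["m/z array"], entry["intensity array"]]
                    ),
                    sample_id=sample,
                    replicate_id=rep,
                )
            )
    return spectra
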