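"""Scaffold binning, MAG quality, acceptance rules, and taxonomy voting.

Scaffolds are embedded in a feature space combining the log of their
per-sample coverage series with canonical tetranucleotide composition, and
clustered with a seeded Gaussian mixture.  Untargeted MAGs are clusters
passing completeness/contamination thresholds; targeted MAGs are built
around *anchor* scaffolds — scaffolds carrying genes whose proteins were
called :sup:`13`\\ C-labeled — by keeping cluster members within a
feature-distance radius of the anchor centroid.

Completeness and contamination come from a user-supplied universal
single-copy marker table: completeness is the fraction of markers present at
least once, contamination the excess copies beyond one per marker.  Taxonomy
is assigned by marker concordance voting and a 2-of-3 phylum agreement rule
across independent tool lineages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

# ---------------------------------------------------------------------------
# scaffolds


@dataclass
class Gene:
    gene_id: str
    protein_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class Scaffold:
    """An assembly scaffold with its abundance series and annotations."""

    scaffold_id: str
    sequence: str = ""
    length: int = 0
    coverage: np.ndarray | None = None  # per-sample mean depth
    genes: list[Gene] = field(default_factory=list)
    anchor_flag: bool = False
    marker_hits: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence and not self.length:
            self.length = len(self.sequence)
        if self.length <= 0:
            raise ValueError("scaffold length must be > 0")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
            if np.any(self.coverage < 0):
                raise ValueError("coverage must be >= 0")


# canonical tetranucleotides: reverse-complement-collapsed, 136 classes
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical_kmers(k: int = 4) -> dict[str, int]:
    index: dict[str, int] = {}
    for kmer in itertools.product("ACGT", repeat=k):
        kmer = "".join(kmer)
        rc = kmer.translate(_COMPLEMENT)[::-1]
        canon = min(kmer, rc)
        if canon not in index:
            index[canon] = len(index)
    full = {}
    for kmer in itertools.product("ACGT", repeat=k):
        kmer = "".join(kmer)
        rc = kmer.translate(_COMPLEMENT)[::-1]
        full[kmer] = index[min(kmer, rc)]
    return full


_KMER_INDEX = _canonical_kmers()
N_TNF = len(set(_KMER_INDEX.values()))  # 136


def tetranucleotide_frequencies(sequence: str) -> np.ndarray:
    """Canonical (reverse-complement-collapsed) tetranucleotide frequency
    vector, normalized to sum 1."""
    counts = np.zeros(N_TNF)
    seq = sequence.upper()
    for i in range(len(seq) - 3):
        idx = _KMER_INDEX.get(seq[i: i + 4])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return np.full(N_TNF, 1.0 / N_TNF)
    return counts / total


def scaffold_features(
    scaffolds: Sequence[Scaffold],
    min_length: int = 5000,
    pseudocount_factor: float = 0.01,
) -> tuple[list[str], np.ndarray]:
    """Feature matrix for binnable scaffolds (length >= ``min_length``).

    Features are log(coverage + pseudocount) per sample concatenated with the
    canonical tetranucleotide composition, each block standardized per
    column.  The pseudocount is ``pseudocount_factor`` x the global mean
    coverage (floor 1e-3), keeping zero-coverage scaffolds finite.
    """
    kept = [s for s in scaffolds if s.length >= min_length]
    if not kept:
        return [], np.zeros((0, 0))
    for s in kept:
        if s.coverage is None:
            raise ValueError(f"scaffold {s.scaffold_id} lacks a coverage vector")
    cov = np.vstack([s.coverage for s in kept])
    pseudo = max(pseudocount_factor * float(cov.mean()), 1e-3)
    log_cov = np.log(cov + pseudo)
    tnf = np.vstack([tetranucleotide_frequencies(s.sequence) for s in kept])

    def _standardize(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        return (block - mu) / sd

    features = np.hstack([_standardize(log_cov), _standardize(tnf)])
    return [s.scaffold_id for s in kept], features


def cluster_scaffolds(
    features: np.ndarray, k: int = 10, seed: int = 0
) -> np.ndarray:
    """Gaussian-mixture clustering of scaffold features, seeded.

    Features are first projected to the principal components explaining 90%
    of variance (capped by the data rank), then fit with a ``k``-component
    diagonal-covariance Gaussian mixture.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = features.shape[0]
    if n < k:
        raise ValueError(f"fewer scaffolds ({n}) than clusters ({k})")
    max_comp = min(n - 1, features.shape[1])
    pca = PCA(n_components=max_comp, random_state=seed)
    projected = pca.fit_transform(features)
    explained = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(explained, 0.90)) + 1
    projected = projected[:, :n_comp]
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        random_state=seed,
        reg_covar=1e-4,
        n_init=3,
        max_iter=500,
    )
    return gmm.fit_predict(projected)


# ---------------------------------------------------------------------------
# targeted refinement


def refine_bin(
    member_features: np.ndarray,
    anchor_mask: np.ndarray | Sequence[bool],
    radius_quantile: float = 0.90,
    reference_distances: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Candidate MAG scaffold sets for one cluster.

    Untargeted mode (no anchors): the cluster is returned unchanged as a
    single candidate.  Targeted mode: anchors closer than the radius are
    merged into one anchor group; each group's candidate set is the anchors
    plus the cluster members within the radius of the anchor centroid.  The
    radius is the ``radius_quantile`` quantile of ``reference_distances`` —
    the dataset-wide distribution of scaffold-to-own-cluster-centroid
    distances — falling back to this cluster's centroid distances when no
    reference is given.  Returns index arrays into the cluster's rows; each
    anchor appears in exactly one candidate set.
    """
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    n = member_features.shape[0]
    if anchor_mask.shape[0] != n:
        raise ValueError("anchor mask length must match feature rows")
    anchor_idx = np.flatnonzero(anchor_mask)
    if len(anchor_idx) == 0:
        return [np.arange(n)]
    if reference_distances is None:
        centroid = member_features.mean(axis=0)
        reference_distances = np.linalg.norm(
            member_features - centroid, axis=1
        )
    radius = float(np.quantile(reference_distances, radius_quantile))
    # single-linkage merge of anchors within the radius
    groups: list[list[int]] = []
    assigned = {}
    for a in anchor_idx:
        merged_into = None
        for gi, group in enumerate(groups):
            if any(
                np.linalg.norm(member_features[a] - member_features[b]) <= radius
                for b in group
            ):
                if merged_into is None:
                    group.append(a)
                    merged_into = gi
                else:
                    groups[merged_into].extend(group)
                    groups[gi] = []
        if merged_into is None:
            groups.append([a])
    groups = [g for g in groups if g]
    candidates = []
    for group in groups:
        centroid = member_features[group].mean(axis=0)
        dist = np.linalg.norm(member_features - centroid, axis=1)
        members = np.flatnonzero(dist <= radius)
        candidates.append(np.unique(np.concatenate([members, group])))
    return candidates


# ---------------------------------------------------------------------------
# quality and acceptance


def estimate_quality(
    scaffolds: Iterable[Scaffold], marker_set: Sequence[str]
) -> tuple[float, float]:
    """Completeness/contamination from single-copy marker counts.

    completeness = 100 x (markers present at least once) / |marker set|;
    contamination = 100 x sum(max(0, count_i - 1)) / |marker set|.
    """
    markers = list(marker_set)
    if not markers:
        raise ValueError("empty marker set")
    counts = {m: 0 for m in markers}
    for scaffold in scaffolds:
        for marker_id, _taxon in scaffold.marker_hits:
            if marker_id in counts:
                counts[marker_id] += 1
    present = sum(1 for c in counts.values() if c >= 1)
    excess = sum(max(0, c - 1) for c in counts.values())
    n = len(markers)
    return 100.0 * present / n, 100.0 * excess / n


#: Acceptance thresholds.  Targeted contamination is compared inclusively at
#: 5 because quality values are reported at integer precision.
UNTARGETED_MIN_COMPLETENESS = 70.0
UNTARGETED_MAX_CONTAMINATION = 10.0
TARGETED_MAX_CONTAMINATION = 5.0
MIN_LABELED_SUPPORT_CO2 = 2


@dataclass
class MAGRecord:
    """A candidate metagenome-assembled genome and its verdict inputs."""

    mag_id: str
    scaffold_ids: tuple[str, ...] = ()
    completeness: float = float("nan")
    contamination: float = float("nan")
    mode: str = "untargeted"
    n_labeled_identifications: int = 0
    replicate_support: Mapping[str, frozenset] = field(default_factory=dict)
    taxonomy: str = "Unclassified"
    taxonomy_confidence: str = "unclassified"
    genome_size: int = 0
    accepted: bool | None = None
    quality_class: str = ""
    failed_rules: tuple[str, ...] = ()


def quality_class(completeness: float, contamination: float) -> str:
    """``medium`` at >=50% completeness and <10% contamination, else
    ``low``; ``no-marker`` when completeness is unknown."""
    if np.isnan(completeness):
        return "no-marker"
    if completeness >= 50.0 and contamination < 10.0:
        return "medium"
    return "low"


def accept_mag(mag: MAGRecord, mode: str | None = None) -> MAGRecord:
    """Apply the mode's acceptance rule and record failed rules.

    untargeted: completeness > 70 and contamination < 10.
    targeted_co2: contamination <= 5 and at least two labeled-protein
    identifications.  targeted_methanol: contamination <= 5 and one labeled
    protein seen in at least two replicates of one incubation triplicate.
    """
    mode = mode or mag.mode
    failed: list[str] = []
    if mode == "untargeted":
        if not mag.completeness > UNTARGETED_MIN_COMPLETENESS:
            failed.append(f"completeness <= {UNTARGETED_MIN_COMPLETENESS:g}")
        if not mag.contamination < UNTARGETED_MAX_CONTAMINATION:
            failed.append(f"contamination >= {UNTARGETED_MAX_CONTAMINATION:g}")
    elif mode in ("targeted_co2", "targeted_methanol"):
        if not mag.contamination <= TARGETED_MAX_CONTAMINATION:
            failed.append(f"contamination > {TARGETED_MAX_CONTAMINATION:g}")
        if mode == "targeted_co2":
            if mag.n_labeled_identifications < MIN_LABELED_SUPPORT_CO2:
                failed.append("fewer than 2 labeled-protein identifications")
        else:
            ok = any(
                len(reps) >= 2 for reps in mag.replicate_support.values()
            )
            if not ok:
                failed.append(
                    "no triplicate with labeled support in >=2 replicates"
                )
    else:
        raise ValueError(f"unknown MAG mode {mode!r}")
    mag.mode = mode
    mag.accepted = not failed
    mag.failed_rules = tuple(failed)
    mag.quality_class = (
        quality_class(mag.completeness, mag.contamination)
        if mag.accepted
        else mag.quality_class
    )
    return mag


# ---------------------------------------------------------------------------
# taxonomy


def marker_vote(labels: Sequence[str]) -> tuple[str, str]:
    """Concordance vote over per-marker taxonomy labels.

    The most common label with fraction f is ``assigned`` at f >= 0.75,
    ``putative`` at 0.5 < f < 0.75, else the MAG stays ``unclassified``.
    """
    if not labels:
        return "Unclassified", "unclassified"
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    order = np.lexsort((values.astype(str), -counts))
    top = order[0]
    fraction = counts[top] / len(labels)
    taxon = str(values[top])
    if fraction >= 0.75:
        return taxon, "assigned"
    if fraction > 0.5:
        return taxon, "putative"
    return "Unclassified", "unclassified"


def lineage_consensus(
    lineages: Sequence[Sequence[str]],
) -> tuple[str, ...] | None:
    """2-of-3 phylum agreement: the lowest common ancestor of the agreeing
    lineages, or None.  The phylum is the first rank of a lineage path."""
    lineages = [tuple(l) for l in lineages if l]
    by_phylum: dict[str, list[tuple[str, ...]]] = {}
    for lineage in lineages:
        by_phylum.setdefault(lineage[0], []).append(lineage)
    agreeing = [group for group in by_phylum.values() if len(group) >= 2]
    if not agreeing:
        return None
    group = max(agreeing, key=len)
    lca: list[str] = []
    for ranks in zip(*group):
        if all(r == ranks[0] for r in ranks):
            lca.append(ranks[0])
        else:
            break
    return tuple(lca) if lca else None


def assign_taxonomy(
    marker_taxonomies: Sequence[str],
    tool_assignments: Sequence[Sequence[str]] = (),
) -> tuple[str, str]:
    """Combined taxonomy call for a MAG.

    The per-marker concordance vote yields the confidence class; when at
    least two of the three tool lineages agree at the phylum level, their
    lowest common ancestor overrides the voted taxon.
    """
    taxon, confidence = marker_vote(marker_taxonomies)
    consensus = lineage_consensus(tool_assignments) if tool_assignments else None
    if consensus:
        return consensus[-1], confidence if confidence != "unclassified" else "assigned"
    return taxon, confidence


def bin_purity(
    scaffold_ids: Iterable[str],
    scaffold_genome: Mapping[str, str],
    scaffold_length: Mapping[str, int],
) -> float:
    """Fraction of a MAG's base pairs originating from its plurality
    genome (ground-truth diagnostic for synthetic scenes)."""
    bp: dict[str, int] = {}
    for sid in scaffold_ids:
        genome = scaffold_genome[sid]
        bp[genome] = bp.get(genome, 0) + scaffold_length[sid]
    total = sum(bp.values())
    if total == 0:
        return float("nan")
    return max(bp.values()) / total
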