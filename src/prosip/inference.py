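"""Protein inference, labeled-protein filtering, and summary statistics.

Proteins are inferred from filtered peptide identifications by the parsimony
rule (greedy minimal set cover); indistinguishable proteins — identical
peptide sets — are combined into a protein group, and every group must keep
at least one unique peptide.  A protein group is called :sup:`13`\\ C-labeled
only if its supporting identifications clear the experiment-specific
filters: in the CO2 (rhizosphere) design, >10 atom% enrichment on every
supporting peptide plus at least two labeled peptides in one sample of the
plant-species block; in the methanol (microcosm) design, labeled
identifications in at least two replicates of one incubation triplicate.

Also here: agglomerative clustering of labeled-peptide atom% values into
protein isotopologues, an exact Mann-Whitney U timepoint comparison, the
protein-level FDR estimate, and flat GO/EC functional abundance aggregation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# identifications and designs


@dataclass(frozen=True)
class Identification:
    """One filtered peptide identification with its quantitative context."""

    peptide: str
    sample_id: str
    replicate_id: str = ""
    atom_percent: float = float("nan")
    peak_area: float = 0.0
    charge: int = 2


@dataclass(frozen=True)
class CO2Design:
    """Rhizosphere design: sample -> (plant-species block, timepoint)."""

    blocks: Mapping[str, str]
    timepoints: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class MethanolDesign:
    """Microcosm design: sample -> incubation triplicate id; the replicate
    id distinguishes members of a triplicate."""

    triplicates: Mapping[str, str]


# ---------------------------------------------------------------------------
# parsimony inference


@dataclass
class ProteinGroup:
    group_id: str
    member_protein_ids: tuple[str, ...]
    unique_peptides: frozenset[str]
    shared_peptides: frozenset[str]
    identifications: list[Identification] = field(default_factory=list)

    @property
    def peptides(self) -> frozenset[str]:
        return self.unique_peptides | self.shared_peptides


def infer_proteins(
    peptide_to_proteins: Mapping[str, Iterable[str]],
) -> list[ProteinGroup]:
    """Parsimony protein inference by greedy minimal set cover.

    Proteins with identical peptide sets are merged into one group first;
    then the group explaining the most unexplained peptides is selected
    repeatedly (ties broken by accession order of the first member).  After
    selection, a peptide is unique if it occurs in exactly one selected
    group; groups left without a unique peptide are discarded.
    """
    protein_to_peptides: dict[str, set[str]] = {}
    for peptide, proteins in peptide_to_proteins.items():
        for protein in proteins:
            protein_to_peptides.setdefault(protein, set()).add(peptide)
    # merge indistinguishable proteins
    by_peptide_set: dict[frozenset[str], list[str]] = {}
    for protein, peptides in protein_to_peptides.items():
        by_peptide_set.setdefault(frozenset(peptides), []).append(protein)
    candidates = [
        (tuple(sorted(members)), peptides)
        for peptides, members in by_peptide_set.items()
    ]
    candidates.sort(key=lambda c: c[0])
    unexplained = set(peptide_to_proteins)
    selected: list[tuple[tuple[str, ...], frozenset[str]]] = []
    while unexplained:
        best = min(
            candidates,
            key=lambda c: (-len(c[1] & unexplained), c[0]),
        )
        gain = best[1] & unexplained
        if not gain:
            break
        selected.append(best)
        unexplained -= gain
    # peptide uniqueness across the selected set
    peptide_count: dict[str, int] = {}
    for _members, peptides in selected:
        for peptide in peptides:
            peptide_count[peptide] = peptide_count.get(peptide, 0) + 1
    groups = []
    for i, (members, peptides) in enumerate(selected):
        unique = frozenset(p for p in peptides if peptide_count[p] == 1)
        if not unique:
            continue
        groups.append(
            ProteinGroup(
                group_id=f"group_{members[0]}",
                member_protein_ids=members,
                unique_peptides=unique,
                shared_peptides=frozenset(peptides) - unique,
            )
        )
    return groups


def protein_fdr(
    target_groups: Sequence[ProteinGroup], decoy_groups: Sequence[ProteinGroup]
) -> float:
    """Protein-level FDR estimate: #decoy groups / #target groups."""
    if not target_groups:
        raise ValueError("zero target protein groups")
    return len(decoy_groups) / len(target_groups)


# ---------------------------------------------------------------------------
# isotopologue clustering


def cluster_isotopologues(
    atom_values: Sequence[float], min_gap: float = 10.0
) -> list[list[float]]:
    """Cluster labeled-peptide atom% values into protein isotopologues.

    Agglomerative single pass on cluster means: the two clusters with the
    closest means are merged while that distance is <= ``min_gap``; the
    final partition has all pairwise mean differences > ``min_gap``.
    """
    if not atom_values:
        raise ValueError("empty atom% input")
    clusters = [[v] for v in sorted(atom_values)]
    while len(clusters) > 1:
        means = [sum(c) / len(c) for c in clusters]
        gaps = [means[i + 1] - means[i] for i in range(len(means) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] > min_gap:
            break
        clusters[i: i + 2] = [clusters[i] + clusters[i + 1]]
    return clusters


# ---------------------------------------------------------------------------
# labeled-protein filtering


@dataclass(frozen=True)
class LabeledProteinCall:
    group_id: str
    experiment_mode: str
    passing: bool
    atom_percents: tuple[float, ...]
    isotopologue_clusters: tuple[tuple[float, ...], ...]
    reasons: tuple[str, ...] = ()


MIN_LABELED_ATOM_PERCENT = 10.0


def filter_labeled_proteins(
    group: ProteinGroup,
    mode: str,
    design: CO2Design | MethanolDesign,
    min_atom_percent: float = MIN_LABELED_ATOM_PERCENT,
) -> LabeledProteinCall:
    """Apply the labeled-protein acceptance filter to one protein group.

    ``co2``: every supporting atom% must exceed ``min_atom_percent`` and at
    least one sample of the group's plant-species block must hold two or
    more distinct labeled peptides.  ``methanol``: labeled identifications
    must appear in at least two replicates of one incubation triplicate.
    An identification counts once per (sample, peptide, charge).
    """
    idents = [
        i for i in group.identifications if not math.isnan(i.atom_percent)
    ]
    seen = set()
    unique_idents = []
    for ident in idents:
        key = (ident.sample_id, ident.peptide, ident.charge)
        if key not in seen:
            seen.add(key)
            unique_idents.append(ident)
    labeled = [
        i for i in unique_idents if i.atom_percent > min_atom_percent
    ]
    values = tuple(i.atom_percent for i in labeled)
    reasons: list[str] = []
    all_above = bool(idents) and all(
        i.atom_percent > min_atom_percent for i in unique_idents
    )
    if mode == "co2":
        if not isinstance(design, CO2Design):
            raise ValueError("co2 mode requires a CO2Design")
        per_sample: dict[str, set[str]] = {}
        for ident in labeled:
            per_sample.setdefault(ident.sample_id, set()).add(ident.peptide)
        two_in_one_sample = any(len(peps) >= 2 for peps in per_sample.values())
        if not two_in_one_sample:
            reasons.append("no sample with >=2 labeled peptides")
        if not all_above:
            reasons.append(
                f"supporting atom% not all > {min_atom_percent:g}"
            )
        passing = two_in_one_sample and all_above
    elif mode == "methanol":
        if not isinstance(design, MethanolDesign):
            raise ValueError("methanol mode requires a MethanolDesign")
        per_triplicate: dict[str, set[str]] = {}
        for ident in labeled:
            trip = design.triplicates.get(ident.sample_id)
            if trip is None:
                continue
            per_triplicate.setdefault(trip, set()).add(ident.replicate_id)
        passing = any(len(reps) >= 2 for reps in per_triplicate.values())
        if not passing:
            reasons.append(
                "no triplicate with labeled identifications in >=2 replicates"
            )
    else:
        raise ValueError(f"unknown experiment mode {mode!r}")
    clusters = (
        tuple(tuple(c) for c in cluster_isotopologues(values))
        if values
        else ()
    )
    return LabeledProteinCall(
        group_id=group.group_id,
        experiment_mode=mode,
        passing=passing,
        atom_percents=values,
        isotopologue_clusters=clusters,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# timepoint statistics


def _u_statistic(t1: Sequence[float], t2: Sequence[float]) -> float:
    """Mann-Whitney U of the first sample: wins of t1 over t2, ties half."""
    u = 0.0
    for x in t1:
        for y in t2:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def compare_timepoints(
    t1_values: Sequence[float],
    t2_values: Sequence[float],
    alternative: str = "greater",
    exact_limit: int = 20,
) -> tuple[float, float]:
    """Mann-Whitney U test between two timepoints.

    Returns (U statistic of the first sample, p value).  ``alternative``
    refers to the second sample: ``greater`` tests t2 > t1 (small U),
    ``two-sided`` doubles the smaller tail.  The null is evaluated by exact
    permutation enumeration when n1+n2 <= ``exact_limit`` (ties handled
    exactly), else by the normal approximation with tie correction.
    """
    if len(t1_values) == 0 or len(t2_values) == 0:
        raise ValueError("both value lists must be non-empty")
    n1, n2 = len(t1_values), len(t2_values)
    u_obs = _u_statistic(t1_values, t2_values)
    if n1 + n2 <= exact_limit:
        pooled = list(t1_values) + list(t2_values)
        n_total = len(pooled)
        count_le = count_ge = total = 0
        for first_idx in itertools.combinations(range(n_total), n1):
            mask = set(first_idx)
            a = [pooled[i] for i in first_idx]
            b = [pooled[i] for i in range(n_total) if i not in mask]
            u = _u_statistic(a, b)
            total += 1
            if u <= u_obs + 1e-12:
                count_le += 1
            if u >= u_obs - 1e-12:
                count_ge += 1
        p_greater = count_le / total  # t2 > t1  <=>  small U1
        p_less = count_ge / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_greater, p_less))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return u_obs, p
    scipy_alt = {"greater": "less", "less": "greater", "two-sided": "two-sided"}[
        alternative
    ]
    res = stats.mannwhitneyu(
        t1_values, t2_values, alternative=scipy_alt, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# functional aggregation


def aggregate_functional_abundance(
    protein_abundance: Mapping[str, float],
    annotation: Mapping[str, Iterable[str]],
    normalize: bool = True,
) -> pd.DataFrame:
    """Aggregate per-protein abundances into flat functional terms (GO/EC).

    Proteins without annotation are counted under ``unannotated``.  Returns
    a DataFrame indexed by term with columns ``abundance`` and ``fraction``
    (share of the total identified abundance; a protein carrying several
    terms contributes its full abundance to each).
    """
    total = float(sum(protein_abundance.values()))
    rows: dict[str, float] = {}
    for protein, abundance in protein_abundance.items():
        terms = list(annotation.get(protein, [])) or ["unannotated"]
        for term in terms:
            rows[term] = rows.get(term, 0.0) + abundance
    table = pd.DataFrame(
        {"abundance": pd.Series(rows, dtype=float)}
    ).sort_index()
    table["fraction"] = (
        table["abundance"] / total if total > 0 and normalize else np.nan
    )
    return table
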