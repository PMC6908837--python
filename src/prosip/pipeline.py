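"""End-to-end orchestration of the SIP analysis stages.

In-memory functions chaining search -> FDR -> inference -> labeled-protein
calls -> targeted binning; the CLI stages in :mod:`prosip.cli` wrap these
with file I/O.  Reports use the labeled-protein table layout of the
reference studies: one row per identification with protein, sample context,
integer atom%, and the MAG the protein was binned into.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binning, inference, search
from .binning import MAGRecord, Scaffold
from .inference import (
    CO2Design,
    Identification,
    LabeledProteinCall,
    MethanolDesign,
    ProteinGroup,
)
from .search import PeptideSpectrumMatch, SearchConfig, Spectrum

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# search + FDR


@dataclass
class SearchResult:
    psms: list[PeptideSpectrumMatch]
    retained: list[PeptideSpectrumMatch]
    retained_decoys: list[PeptideSpectrumMatch]
    counts: dict[str, int] = field(default_factory=dict)


def fdr_partition(
    psms: Sequence[PeptideSpectrumMatch], level: float = 0.01
) -> tuple[list[PeptideSpectrumMatch], list[PeptideSpectrumMatch]]:
    """Targets and decoys above the peptide-level FDR score threshold.

    Same thresholding as :func:`prosip.search.fdr_filter`; the retained
    decoys feed the protein-level FDR estimate.
    """
    retained_targets = search.fdr_filter(psms, level)
    if not retained_targets:
        return [], []
    threshold = min(m.score for m in retained_targets)
    best: dict[tuple, PeptideSpectrumMatch] = {}
    for psm in psms:
        if not psm.is_decoy:
            continue
        key = psm.peptide_key
        if key not in best or psm.score > best[key].score:
            best[key] = psm
    retained_decoys = [m for m in best.values() if m.score >= threshold]
    return retained_targets, retained_decoys


def run_search(
    spectra: Sequence[Spectrum],
    database: Sequence[tuple[str, str]],
    config: SearchConfig,
    fdr_level: float = 0.01,
    decoys_included: bool = False,
) -> SearchResult:
    """Search spectra against a protein database with target-decoy FDR.

    ``database`` holds target records; reversed decoys are concatenated
    here unless ``decoys_included``.
    """
    db = list(database) if decoys_included else search.make_decoy_db(database)
    index = search.PeptideIndex.build(db, config)
    psms = search.search_sample(spectra, index, config)
    retained, retained_decoys = fdr_partition(psms, fdr_level)
    counts = {
        "spectra": len(spectra),
        "database_proteins": len(db),
        "indexed_peptides": len(index),
        "psms": len(psms),
        "peptides_post_fdr": len(retained),
        "decoy_peptides_post_fdr": len(retained_decoys),
    }
    logger.info("search counts: %s", counts)
    return SearchResult(psms, retained, retained_decoys, counts)


# ---------------------------------------------------------------------------
# inference of labeled proteins


def psms_to_identifications(
    psms: Sequence[PeptideSpectrumMatch],
) -> list[Identification]:
    return [
        Identification(
            peptide=m.sequence,
            sample_id=m.sample_id,
            replicate_id=m.replicate_id,
            atom_percent=m.atom_percent,
            peak_area=m.peak_area,
            charge=m.precursor_charge,
        )
        for m in psms
    ]


@dataclass
class LabeledProteinResult:
    groups: list[ProteinGroup]
    decoy_groups: list[ProteinGroup]
    protein_fdr: float
    calls: list[LabeledProteinCall]

    @property
    def passing(self) -> list[LabeledProteinCall]:
        return [c for c in self.calls if c.passing]


def call_labeled_proteins(
    retained: Sequence[PeptideSpectrumMatch],
    retained_decoys: Sequence[PeptideSpectrumMatch],
    all_psms: Sequence[PeptideSpectrumMatch],
    mode: str,
    design: CO2Design | MethanolDesign,
) -> LabeledProteinResult:
    """Parsimony inference plus labeled-protein filtering.

    Groups are inferred from the FDR-retained peptides; every retained
    peptide's PSMs across samples (from ``all_psms``) supply the per-sample
    atom% identifications the filters operate on.
    """
    peptide_map = {m.sequence: set(m.protein_ids) for m in retained}
    groups = inference.infer_proteins(peptide_map)
    decoy_map = {m.sequence: set(m.protein_ids) for m in retained_decoys}
    decoy_groups = inference.infer_proteins(decoy_map) if decoy_map else []
    fdr = inference.protein_fdr(groups, decoy_groups) if groups else float("nan")
    retained_keys = {m.peptide_key for m in retained}
    by_peptide: dict[str, list[PeptideSpectrumMatch]] = {}
    for psm in all_psms:
        if psm.peptide_key in retained_keys and not psm.is_decoy:
            by_peptide.setdefault(psm.sequence, []).append(psm)
    calls = []
    for group in groups:
        idents = []
        for peptide in sorted(group.peptides):
            idents.extend(psms_to_identifications(by_peptide.get(peptide, [])))
        group.identifications = idents
        calls.append(inference.filter_labeled_proteins(group, mode, design))
    return LabeledProteinResult(groups, decoy_groups, fdr, calls)


# ---------------------------------------------------------------------------
# binning


@dataclass
class BinningResult:
    mags: list[MAGRecord]
    cluster_labels: dict[str, int]
    mag_members: dict[str, list[str]]


def _protein_scaffold_map(scaffolds: Sequence[Scaffold]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for scaffold in scaffolds:
        for gene in scaffold.genes:
            mapping[gene.protein_id] = scaffold.scaffold_id
    return mapping


def run_binning(
    scaffolds: Sequence[Scaffold],
    mode: str = "untargeted",
    labeled_result: LabeledProteinResult | None = None,
    design: CO2Design | MethanolDesign | None = None,
    marker_set: Sequence[str] = (),
    k: int = 10,
    min_length: int = 5000,
    radius_quantile: float = 0.90,
    seed: int = 0,
) -> BinningResult:
    """Untargeted or labeled-anchor targeted binning with acceptance.

    Targeted modes require labeled-protein calls; scaffolds carrying genes
    for passing labeled proteins become anchors, and candidate MAGs are the
    anchor neighborhoods inside each mixture cluster.  Every MAG gets
    marker-based quality, a taxonomy vote, and the mode's verdict.
    """
    ids, features = binning.scaffold_features(scaffolds, min_length=min_length)
    if len(ids) == 0:
        raise ValueError("no scaffolds pass the binning length threshold")
    row_of = {sid: i for i, sid in enumerate(ids)}
    labels = binning.cluster_scaffolds(
        features, k=min(k, len(ids)), seed=seed
    )
    by_scaffold = {s.scaffold_id: s for s in scaffolds}
    centroid_dist = np.empty(len(ids))
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        centroid = features[rows].mean(axis=0)
        centroid_dist[rows] = np.linalg.norm(features[rows] - centroid, axis=1)

    anchor_proteins: dict[str, list[str]] = {}  # scaffold -> labeled proteins
    if mode in ("targeted_co2", "targeted_methanol"):
        if labeled_result is None:
            raise ValueError("targeted binning requires labeled-protein calls")
        protein_scaffold = _protein_scaffold_map(scaffolds)
        group_by_id = {g.group_id: g for g in labeled_result.groups}
        for call in labeled_result.passing:
            group = group_by_id[call.group_id]
            for protein_id in group.member_protein_ids:
                sid = protein_scaffold.get(protein_id)
                if sid is None:
                    continue
                anchor_proteins.setdefault(sid, []).append(call.group_id)
        missing = [s for s in anchor_proteins if s not in row_of]
        if missing:
            raise ValueError(
                f"anchor scaffolds not in any cluster: {sorted(missing)}"
            )
        if not anchor_proteins:
            return BinningResult([], dict(zip(ids, labels.tolist())), {})

    mags: list[MAGRecord] = []
    mag_members: dict[str, list[str]] = {}
    mag_counter = 1
    for c in sorted(np.unique(labels)):
        rows = np.flatnonzero(labels == c)
        cluster_ids = [ids[i] for i in rows]
        if mode == "untargeted":
            candidates = [np.arange(len(rows))]
        else:
            anchor_mask = np.array(
                [sid in anchor_proteins for sid in cluster_ids]
            )
            if not anchor_mask.any():
                continue
            candidates = binning.refine_bin(
                features[rows],
                anchor_mask,
                radius_quantile=radius_quantile,
                reference_distances=centroid_dist,
            )
        for candidate in candidates:
            member_ids = [cluster_ids[i] for i in candidate]
            members = [by_scaffold[sid] for sid in member_ids]
            completeness, contamination = (
                binning.estimate_quality(members, marker_set)
                if marker_set
                else (float("nan"), float("nan"))
            )
            marker_labels = [
                taxon for s in members for _m, taxon in s.marker_hits
            ]
            taxon, confidence = binning.assign_taxonomy(marker_labels)
            mag = MAGRecord(
                mag_id=f"MAG{mag_counter:02d}",
                scaffold_ids=tuple(member_ids),
                completeness=completeness,
                contamination=contamination,
                mode=mode,
                taxonomy=taxon,
                taxonomy_confidence=confidence,
                genome_size=sum(s.length for s in members),
            )
            if mode in ("targeted_co2", "targeted_methanol"):
                _attach_labeled_support(
                    mag, member_ids, anchor_proteins, labeled_result, design
                )
            binning.accept_mag(mag, mode)
            mags.append(mag)
            mag_members[mag.mag_id] = member_ids
            mag_counter += 1
    return BinningResult(mags, dict(zip(ids, labels.tolist())), mag_members)


def _attach_labeled_support(
    mag: MAGRecord,
    member_ids: Sequence[str],
    anchor_proteins: Mapping[str, list[str]],
    labeled_result: LabeledProteinResult,
    design: CO2Design | MethanolDesign | None,
) -> None:
    group_by_id = {g.group_id: g for g in labeled_result.groups}
    group_ids = {
        gid for sid in member_ids for gid in anchor_proteins.get(sid, [])
    }
    n_idents = 0
    replicate_support: dict[str, set] = {}
    for gid in sorted(group_ids):
        group = group_by_id[gid]
        seen = set()
        for ident in group.identifications:
            if ident.atom_percent <= inference.MIN_LABELED_ATOM_PERCENT:
                continue
            key = (ident.sample_id, ident.peptide)
            if key in seen:
                continue
            seen.add(key)
            n_idents += 1
            if isinstance(design, MethanolDesign):
                trip = design.triplicates.get(ident.sample_id)
                if trip is not None:
                    replicate_support.setdefault(trip, set()).add(
                        ident.replicate_id
                    )
    mag.n_labeled_identifications = n_idents
    mag.replicate_support = {
        k: frozenset(v) for k, v in replicate_support.items()
    }


# ---------------------------------------------------------------------------
# reports


def labeled_report(
    labeled_result: LabeledProteinResult,
    binning_result: BinningResult | None = None,
    design: CO2Design | None = None,
    protein_scaffold: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Labeled-protein report, one row per supporting identification.

    Columns mirror the reference study layout: protein (group) id, sample
    and timepoint context, integer atom%, and MAG id placeholder.
    """
    mag_of_scaffold: dict[str, str] = {}
    if binning_result is not None:
        for mag_id, members in binning_result.mag_members.items():
            for sid in members:
                mag_of_scaffold[sid] = mag_id
    rows = []
    for call in labeled_result.passing:
        group = next(
            g for g in labeled_result.groups if g.group_id == call.group_id
        )
        mag_id = ""
        if protein_scaffold:
            for pid in group.member_protein_ids:
                sid = protein_scaffold.get(pid)
                if sid in mag_of_scaffold:
                    mag_id = mag_of_scaffold[sid]
                    break
        seen = set()
        for ident in group.identifications:
            if ident.atom_percent <= inference.MIN_LABELED_ATOM_PERCENT:
                continue
            key = (ident.sample_id, ident.peptide)
            if key in seen:
                continue
            seen.add(key)
            timepoint = (
                design.timepoints.get(ident.sample_id, "")
                if design is not None
                else ""
            )
            rows.append(
                {
                    "protein_id": "|".join(group.member_protein_ids),
                    "sample_id": ident.sample_id,
                    "replicate_id": ident.replicate_id,
                    "timepoint": timepoint,
                    "atom_percent": int(round(ident.atom_percent)),
                    "mag_id": mag_id,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "sample_id",
            "replicate_id",
            "timepoint",
            "atom_percent",
            "mag_id",
        ],
    )
    return table.sort_values(list(table.columns)).reset_index(drop=True)


def mag_report(binning_result: BinningResult) -> pd.DataFrame:
    rows = []
    for mag in binning_result.mags:
        rows.append(
            {
                "mag_id": mag.mag_id,
                "mode": mag.mode,
                "completeness": round(mag.completeness, 4),
                "contamination": round(mag.contamination, 4),
                "n_labeled_identifications": mag.n_labeled_identifications,
                "taxonomy": mag.taxonomy,
                "taxonomy_confidence": mag.taxonomy_confidence,
                "genome_size_bp": mag.genome_size,
                "n_scaffolds": len(mag.scaffold_ids),
                "accepted": mag.accepted,
                "quality_class": mag.quality_class,
                "failed_rules": ";".join(mag.failed_rules),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "mode",
            "completeness",
            "contamination",
            "n_labeled_identifications",
            "taxonomy",
            "taxonomy_confidence",
            "genome_size_bp",
            "n_scaffolds",
            "accepted",
            "quality_class",
            "failed_rules",
        ],
    )


def summarize_labeling(
    labeled_table: pd.DataFrame,
    mag_table: pd.DataFrame | None = None,
    timepoint_pair: tuple[str, str] = ("T1", "T2"),
) -> dict:
    """Summary block: counts, atom% range, timepoint test, MAG tallies.

    Order-invariant over input rows; empty input yields an empty summary.
    """
    summary: dict = {}
    if len(labeled_table) == 0:
        return summary
    values = labeled_table["atom_percent"].astype(float)
    summary["n_identifications"] = int(len(labeled_table))
    summary["n_proteins"] = int(labeled_table["protein_id"].nunique())
    summary["atom_percent_min"] = float(values.min())
    summary["atom_percent_mean"] = float(values.mean())
    summary["atom_percent_max"] = float(values.max())
    if "timepoint" in labeled_table.columns:
        t1 = values[labeled_table["timepoint"] == timepoint_pair[0]]
        t2 = values[labeled_table["timepoint"] == timepoint_pair[1]]
        if len(t1) and len(t2):
            u, p = inference.compare_timepoints(list(t1), list(t2))
            summary["timepoint_u"] = float(u)
            summary["timepoint_p"] = float(p)
    if mag_table is not None and len(mag_table):
        summary["mags_total"] = int(len(mag_table))
        summary["mags_accepted"] = int(mag_table["accepted"].sum())
        summary["mags_medium_quality"] = int(
            (mag_table.loc[mag_table["accepted"], "quality_class"] == "medium").sum()
        )
    return summary
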