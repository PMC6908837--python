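"""Seeded benchmark experiments exercising the pipeline end to end.

Each routine builds its own synthetic inputs, runs the package's public
machinery, and measures a performance figure: atom% recovery error, the
enrichment detection limit, empirical false-discovery proportion under an
entrapment design, targeted-binning purity, and the acceptance-rule
reproduction on the bundled reference reports.  All sizes are chosen to run
on one CPU in seconds to a few minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import binning, pipeline, reference, search, simulate
from .chem import Peptide, digest, elemental_composition
from .constants import NATURAL_C13
from .inference import CO2Design, compare_timepoints
from .search import SearchConfig, sip_config, sip_enrichment_grid

#: Reference peptide for enrichment-recovery simulations: a tryptic
#: peptide with >= 20 carbons (the regime where envelope shifts resolve
#: 1-2 atom% differences).
RECOVERY_PEPTIDE = "LVDEFGHSTWAK"


def _check_recovery_peptide() -> Peptide:
    pep = Peptide(RECOVERY_PEPTIDE)
    if elemental_composition(pep).C < 20:
        raise AssertionError("recovery peptide must have >= 20 carbons")
    return pep


def atom_percent_recovery(
    true_atom_percents: tuple[float, ...] = (30.0,),
    n_spectra: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    config: SearchConfig | None = None,
) -> dict[float, dict]:
    """Estimate atom% on noisy synthetic spectra of a known peptide.

    ``noise_sd`` is the multiplicative intensity noise (signal-to-noise ~
    1/``noise_sd``).  Returns, per true atom%, the per-spectrum estimates
    and the mean absolute error in atom% units.
    """
    pep = _check_recovery_peptide()
    config = config or sip_config()
    rng = np.random.default_rng(seed)
    results: dict[float, dict] = {}
    for true_pct in true_atom_percents:
        estimates = []
        for i in range(n_spectra):
            spectrum = simulate.synthetic_spectrum(
                pep,
                atom_fraction=true_pct / 100.0,
                charge=2,
                noise_sd=noise_sd,
                rng=rng,
                spectrum_id=f"rec_{true_pct}_{i}",
            )
            est = search.estimate_atom_percent(spectrum, pep, config)
            if est is not None:
                estimates.append(est.atom_percent)
        estimates = np.asarray(estimates)
        results[true_pct] = {
            "estimates": estimates,
            "n_matched": int(len(estimates)),
            "mean_abs_error": float(np.mean(np.abs(estimates - true_pct)))
            if len(estimates)
            else float("nan"),
        }
    return results


def detection_limit(
    levels_atom_percent: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0, 5.0),
    n_spectra: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    alpha: float = 0.01,
    grid_step: float = 0.001,
) -> dict:
    """Smallest true enrichment distinguishable from natural abundance.

    Estimates atom% on ``n_spectra`` noisy spectra per level using a fine
    (``grid_step`` atom fraction) enrichment grid, then asks — per level —
    whether the estimates are stochastically larger than those of
    natural-abundance spectra (one-sided Mann-Whitney at ``alpha``).
    Returns the per-level p values and the smallest significant level.
    """
    pep = _check_recovery_peptide()
    fine = sip_enrichment_grid(
        step=grid_step,
        start=NATURAL_C13 + grid_step,
        stop=max(levels_atom_percent) / 100.0 + 0.03,
    )
    config = sip_config(enrichment_grid=fine)
    rng = np.random.default_rng(seed)

    def _estimates(atom_fraction: float, tag: str) -> list[float]:
        out = []
        for i in range(n_spectra):
            spectrum = simulate.synthetic_spectrum(
                pep,
                atom_fraction=atom_fraction,
                charge=2,
                noise_sd=noise_sd,
                rng=rng,
                spectrum_id=f"det_{tag}_{i}",
            )
            est = search.estimate_atom_percent(spectrum, pep, config)
            if est is not None:
                out.append(est.atom_percent)
        return out

    natural = _estimates(NATURAL_C13, "nat")
    p_values: dict[float, float] = {}
    limit = float("nan")
    for level in sorted(levels_atom_percent):
        ests = _estimates(level / 100.0, f"{level}")
        _u, p = compare_timepoints(natural, ests, alternative="greater")
        p_values[level] = p
        if np.isnan(limit) and p < alpha:
            limit = level
    return {
        "p_values": p_values,
        "detection_limit_atom_percent": limit,
        "natural_estimates": natural,
    }


def fdr_entrapment(
    n_seeds: int = 20,
    n_true_proteins: int = 25,
    n_entrapment_proteins: int = 100,
    spectra_per_seed: int = 40,
    noise_sd: float = 0.1,
    dropout: float = 0.1,
    level: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Empirical false-discovery proportion under an entrapment design.

    Spectra are generated only from the true proteins; the database adds
    entrapment proteins (never measured) plus reversed decoys.  Any
    FDR-retained peptide not among the generating peptides is a false
    discovery.  Returns pooled and per-seed FDP at the nominal level.
    """
    total_retained = 0
    total_false = 0
    per_seed = []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + 1000 * s)
        true_db = [
            (f"true_{i:03d}", simulate._random_protein(rng))
            for i in range(n_true_proteins)
        ]
        entrap_db = [
            (f"entrap_{i:03d}", simulate._random_protein(rng))
            for i in range(n_entrapment_proteins)
        ]
        generating: list[str] = []
        assignments = []
        for i in range(spectra_per_seed):
            acc, seq = true_db[int(rng.integers(len(true_db)))]
            peps = digest(seq, max_missed=0)
            pep = peps[int(rng.integers(len(peps)))]
            generating.append(pep.sequence)
            assignments.append((pep.sequence, NATURAL_C13, "s1", "r1"))
        spectra = simulate.generate_spectra(
            assignments,
            noise_sd=noise_sd,
            dropout=dropout,
            seed=base_seed + 1000 * s + 1,
        )
        result = pipeline.run_search(
            spectra, true_db + entrap_db, search.regular_config(), fdr_level=level
        )
        generating_set = set(generating)
        false = [
            m for m in result.retained if m.sequence not in generating_set
        ]
        per_seed.append(
            {
                "retained": len(result.retained),
                "false": len(false),
            }
        )
        total_retained += len(result.retained)
        total_false += len(false)
    pooled_fdp = total_false / total_retained if total_retained else 0.0
    return {
        "pooled_fdp": pooled_fdp,
        "total_retained": total_retained,
        "total_false": total_false,
        "per_seed": per_seed,
        "nominal_level": level,
    }


@dataclass
class BinningRecovery:
    purities: list[float]
    anchor_containment: list[float]
    n_accepted: list[int]


def binning_recovery(
    n_seeds: int = 5, base_seed: int = 0, full_search: bool = True
) -> BinningRecovery:
    """Targeted-binning purity and anchor containment on default scenes.

    Runs the whole pipeline (search -> labeled calls -> targeted binning)
    on the default synthetic scene for ``n_seeds`` seeds; reports, per
    seed, the minimum MAG purity (fraction of base pairs from the
    plurality genome) and the fraction of anchor scaffolds contained in
    exactly one candidate MAG.
    """
    purities = []
    containment = []
    n_accepted = []
    for s in range(n_seeds):
        seed = base_seed + 17 * s
        scene = simulate.default_scene(seed=seed)
        design = CO2Design(blocks=scene.sample_blocks)
        if full_search:
            result = pipeline.run_search(
                scene.spectra, scene.proteins, sip_config()
            )
            labeled = pipeline.call_labeled_proteins(
                result.retained,
                result.retained_decoys,
                result.psms,
                "co2",
                design,
            )
        else:  # truth-derived calls, exercising binning in isolation
            labeled = _labeled_result_from_truth(scene)
        bres = pipeline.run_binning(
            scene.scaffolds,
            mode="targeted_co2",
            labeled_result=labeled,
            design=design,
            marker_set=scene.marker_set,
            seed=seed,
        )
        lengths = {s_.scaffold_id: s_.length for s_ in scene.scaffolds}
        seed_purities = [
            binning.bin_purity(
                mag.scaffold_ids, scene.truth.scaffold_genome, lengths
            )
            for mag in bres.mags
        ]
        purities.append(min(seed_purities) if seed_purities else float("nan"))
        anchors = _anchor_scaffolds(scene, labeled)
        counts = [
            sum(1 for mag in bres.mags if a in mag.scaffold_ids)
            for a in anchors
        ]
        containment.append(
            sum(1 for c in counts if c == 1) / len(counts) if counts else 0.0
        )
        n_accepted.append(sum(1 for m in bres.mags if m.accepted))
    return BinningRecovery(purities, containment, n_accepted)


def _anchor_scaffolds(scene, labeled) -> list[str]:
    protein_scaffold = {}
    for scaffold in scene.scaffolds:
        for gene in scaffold.genes:
            protein_scaffold[gene.protein_id] = scaffold.scaffold_id
    group_by_id = {g.group_id: g for g in labeled.groups}
    out = set()
    for call in labeled.passing:
        for pid in group_by_id[call.group_id].member_protein_ids:
            if pid in protein_scaffold:
                out.add(protein_scaffold[pid])
    return sorted(out)


def _labeled_result_from_truth(scene) -> pipeline.LabeledProteinResult:
    from .inference import Identification, ProteinGroup, LabeledProteinCall

    groups = []
    calls = []
    for pid, frac in sorted(scene.truth.labeled_atom_fraction.items()):
        seqs = [
            p.sequence
            for p in digest(scene.truth.protein_sequences[pid], max_missed=0)
        ][:2]
        group = ProteinGroup(
            group_id=f"group_{pid}",
            member_protein_ids=(pid,),
            unique_peptides=frozenset(seqs),
            shared_peptides=frozenset(),
            identifications=[
                Identification(
                    peptide=s, sample_id="s01", atom_percent=100.0 * frac
                )
                for s in seqs
            ],
        )
        groups.append(group)
        calls.append(
            LabeledProteinCall(
                group_id=group.group_id,
                experiment_mode="co2",
                passing=True,
                atom_percents=tuple(100.0 * frac for _ in seqs),
                isotopologue_clusters=(),
            )
        )
    return pipeline.LabeledProteinResult(groups, [], 0.0, calls)


def reference_rule_reproduction() -> dict:
    """Acceptance rules applied to the bundled printed reports."""
    co2 = [binning.accept_mag(m) for m in reference.co2_mag_records()]
    methanol = [binning.accept_mag(m) for m in reference.methanol_mag_records()]
    idents, _quality = reference.co2_reference()
    co2_accepted = [m for m in co2 if m.accepted]
    methanol_accepted = [m for m in methanol if m.accepted]
    return {
        "co2_mags_accepted": len(co2_accepted),
        "methanol_mags_accepted": len(methanol_accepted),
        "co2_quality_classes": sorted(m.quality_class for m in co2_accepted),
        "methanol_quality_classes": sorted(
            m.quality_class for m in methanol_accepted
        ),
        "co2_atom_percent_min": float(idents["atom_percent"].min()),
        "co2_atom_percent_max": float(idents["atom_percent"].max()),
    }
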