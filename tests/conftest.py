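"""Shared fixtures: a fully-run synthetic scene and an isotopologue oracle."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pytest

from prosip import pipeline, search, simulate
from prosip.constants import NATURAL_ISOTOPES
from prosip.inference import CO2Design


def exhaustive_envelope(counts: dict[str, int], p_c13: float | None = None):
    """Independent isotopologue oracle: enumerate every per-atom isotope
    assignment of a small formula, group by total nucleon offset.

    Returns (offsets, abundances, centroid masses) without truncation.
    Only feasible for formulas with a handful of atoms.
    """
    atoms: list[list[tuple[int, float, float]]] = []
    for element, n in counts.items():
        iso = NATURAL_ISOTOPES[element]
        if element == "C" and p_c13 is not None:
            iso = [
                (iso[0][0], iso[0][1], 1.0 - p_c13),
                (iso[1][0], iso[1][1], p_c13),
            ]
        atoms.extend([list(iso)] * n)
    weights: dict[int, float] = {}
    moments: dict[int, float] = {}
    for combo in itertools.product(*atoms):
        offset = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        prob = float(np.prod([c[2] for c in combo]))
        weights[offset] = weights.get(offset, 0.0) + prob
        moments[offset] = moments.get(offset, 0.0) + prob * mass
    offsets = sorted(o for o in weights if weights[o] > 0)
    abund = np.array([weights[o] for o in offsets])
    centroid = np.array([moments[o] / weights[o] for o in offsets])
    return np.array(offsets), abund, centroid


@dataclass
class SceneRun:
    scene: simulate.SyntheticScene
    design: CO2Design
    search_result: pipeline.SearchResult
    labeled: pipeline.LabeledProteinResult
    binning: pipeline.BinningResult


@pytest.fixture(scope="session")
def scene_run() -> SceneRun:
    """Default synthetic scene pushed through the full pipeline once."""
    scene = simulate.default_scene(seed=5)
    design = CO2Design(blocks=scene.sample_blocks)
    result = pipeline.run_search(
        scene.spectra, scene.proteins, search.sip_config()
    )
    labeled = pipeline.call_labeled_proteins(
        result.retained, result.retained_decoys, result.psms, "co2", design
    )
    bres = pipeline.run_binning(
        scene.scaffolds,
        mode="targeted_co2",
        labeled_result=labeled,
        design=design,
        marker_set=scene.marker_set,
        seed=5,
    )
    return SceneRun(scene, design, result, labeled, bres)
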