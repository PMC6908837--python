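"""Scaffold features, clustering, targeted refinement, quality, taxonomy."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from prosip import simulate
from prosip.binning import (
    MAGRecord,
    Scaffold,
    accept_mag,
    assign_taxonomy,
    bin_purity,
    cluster_scaffolds,
    estimate_quality,
    lineage_consensus,
    marker_vote,
    quality_class,
    refine_bin,
    scaffold_features,
    tetranucleotide_frequencies,
)


def _scaffold(sid, seq, cov):
    return Scaffold(scaffold_id=sid, sequence=seq, coverage=np.asarray(cov, float))


class TestScaffoldFeatures:
    def test_short_scaffolds_excluded(self):
        short = _scaffold("s1", "ACGT" * 100, [1.0, 2.0])
        long = _scaffold("s2", "ACGT" * 2000, [1.0, 2.0])
        ids, features = scaffold_features([short, long])
        assert ids == ["s2"]
        assert features.shape[0] == 1

    def test_zero_coverage_stays_finite(self):
        scaffolds = [
            _scaffold("s1", "ACGT" * 2000, [0.0, 0.0]),
            _scaffold("s2", "AACG" * 2000, [5.0, 1.0]),
        ]
        _ids, features = scaffold_features(scaffolds)
        assert np.all(np.isfinite(features))

    def test_missing_coverage_raises(self):
        scaffold = Scaffold(scaffold_id="s1", sequence="ACGT" * 2000)
        with pytest.raises(ValueError, match="s1"):
            scaffold_features([scaffold])

    def test_tnf_normalized_canonical(self):
        tnf = tetranucleotide_frequencies("ACGTACGTAAACCC")
        assert tnf.shape == (136,)
        assert tnf.sum() == pytest.approx(1.0)

    def test_same_genome_scaffolds_closer_than_cross_genome(self):
        scaffolds, _cov, truth = simulate.generate_community(
            n_genomes=2, seed=3
        )
        ids, features = scaffold_features(scaffolds)
        genome = [truth.scaffold_genome[sid] for sid in ids]
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = np.linalg.norm(features[i] - features[j])
                (within if genome[i] == genome[j] else between).append(d)
        assert np.median(within) < np.median(between)


class TestClusterScaffolds:
    def test_two_separated_genomes_fully_recovered(self):
        scaffolds, _cov, truth = simulate.generate_community(
            n_genomes=2, seed=3
        )
        ids, features = scaffold_features(scaffolds)
        labels = cluster_scaffolds(features, k=2, seed=0)
        truth_labels = [truth.scaffold_genome[sid] for sid in ids]
        assert adjusted_rand_score(truth_labels, labels) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        scaffolds, _cov, _truth = simulate.generate_community(seed=4)
        _ids, features = scaffold_features(scaffolds)
        first = cluster_scaffolds(features, k=5, seed=9)
        second = cluster_scaffolds(features, k=5, seed=9)
        assert np.array_equal(first, second)

    def test_identical_rows_collapse_to_one_effective_cluster(self):
        features = np.zeros((12, 6))
        labels = cluster_scaffolds(features, k=3, seed=0)
        assert len(set(labels.tolist())) == 1

    def test_fewer_rows_than_clusters(self):
        with pytest.raises(ValueError):
            cluster_scaffolds(np.zeros((3, 4)), k=5)


class TestRefineBin:
    def test_tight_neighborhood_excludes_outliers(self):
        rng = np.random.default_rng(0)
        anchor = np.zeros((1, 3))
        tight = rng.normal(scale=0.05, size=(10, 3))
        outliers = rng.normal(scale=0.05, size=(5, 3)) + 10.0
        features = np.vstack([anchor, tight, outliers])
        mask = np.zeros(16, dtype=bool)
        mask[0] = True
        # reference scale: typical within-cluster centroid distances
        reference = np.linalg.norm(
            np.vstack([tight, rng.normal(scale=0.1, size=(40, 3))]), axis=1
        )
        candidates = refine_bin(features, mask, 0.90, reference)
        assert len(candidates) == 1
        assert len(candidates[0]) == 11

    def test_untargeted_returns_cluster_unchanged(self):
        features = np.arange(12.0).reshape(4, 3)
        (candidate,) = refine_bin(features, [False] * 4)
        assert np.array_equal(candidate, np.arange(4))

    def test_nearby_anchors_merge(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(scale=0.1, size=(12, 3))
        mask = np.zeros(12, dtype=bool)
        mask[[0, 1]] = True
        reference = np.linalg.norm(rng.normal(scale=0.1, size=(50, 3)), axis=1)
        candidates = refine_bin(cloud, mask, 0.90, reference)
        assert len(candidates) == 1
        assert {0, 1} <= set(candidates[0].tolist())


class TestEstimateQuality:
    def _scaffold_with(self, hits):
        s = Scaffold(scaffold_id="s", length=10)
        s.marker_hits = hits
        return s

    def test_complete_and_clean(self):
        markers = [f"m{i}" for i in range(100)]
        scaffold = self._scaffold_with([(m, "tax") for m in markers])
        assert estimate_quality([scaffold], markers) == (100.0, 0.0)

    def test_partial_completeness(self):
        markers = [f"m{i}" for i in range(100)]
        scaffold = self._scaffold_with([(m, "tax") for m in markers[:54]])
        assert estimate_quality([scaffold], markers) == (54.0, 0.0)

    def test_duplicate_marker_counts_as_contamination(self):
        # 10-marker set: 7 present once, 1 present twice -> (80, 10)
        markers = [f"m{i}" for i in range(10)]
        hits = [(m, "t") for m in markers[:7]] + [("m7", "t"), ("m7", "t")]
        scaffold = self._scaffold_with(hits)
        assert estimate_quality([scaffold], markers) == (80.0, 10.0)

    def test_empty_marker_set(self):
        with pytest.raises(ValueError):
            estimate_quality([], [])


class TestAcceptMag:
    def test_targeted_co2_with_support_accepted(self):
        mag = MAGRecord(
            mag_id="m",
            completeness=54.0,
            contamination=0.3,
            n_labeled_identifications=2,
        )
        accept_mag(mag, "targeted_co2")
        assert mag.accepted and mag.quality_class == "medium"

    def test_untargeted_low_completeness_rejected(self):
        mag = MAGRecord(mag_id="m", completeness=65.0, contamination=2.0)
        accept_mag(mag, "untargeted")
        assert not mag.accepted
        assert any("completeness" in r for r in mag.failed_rules)

    def test_targeted_contamination_rejected_despite_support(self):
        mag = MAGRecord(
            mag_id="m",
            completeness=90.0,
            contamination=6.0,
            n_labeled_identifications=5,
        )
        accept_mag(mag, "targeted_co2")
        assert not mag.accepted

    def test_methanol_requires_two_replicates(self):
        mag = MAGRecord(
            mag_id="m",
            completeness=30.0,
            contamination=1.0,
            replicate_support={"day8": frozenset({"r2"})},
        )
        accept_mag(mag, "targeted_methanol")
        assert not mag.accepted
        mag.replicate_support = {"day8": frozenset({"r2", "r3"})}
        accept_mag(mag, "targeted_methanol")
        assert mag.accepted

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            accept_mag(MAGRecord(mag_id="m"), "untamed")

    def test_quality_class_boundaries(self):
        assert quality_class(50.0, 9.9) == "medium"
        assert quality_class(49.9, 0.0) == "low"
        assert quality_class(float("nan"), 0.0) == "no-marker"


class TestTaxonomy:
    def test_strong_marker_concordance_assigned(self):
        labels = ["Pseudomonas"] * 8 + ["Bacillus"] * 2
        assert marker_vote(labels) == ("Pseudomonas", "assigned")

    def test_partial_concordance_putative(self):
        labels = ["Pseudomonas"] * 6 + ["Bacillus"] * 4
        assert marker_vote(labels) == ("Pseudomonas", "putative")

    def test_no_concordance_unclassified(self):
        labels = ["A", "B", "C", "D"]
        assert marker_vote(labels) == ("Unclassified", "unclassified")

    def test_empty_markers(self):
        assert marker_vote([]) == ("Unclassified", "unclassified")

    def test_two_of_three_phylum_lca(self):
        lineages = [
            ("Proteobacteria", "Pseudomonadales", "Pseudomonas"),
            ("Proteobacteria", "Burkholderiales"),
            ("Actinobacteria", "Micrococcales"),
        ]
        assert lineage_consensus(lineages) == ("Proteobacteria",)

    def test_no_phylum_agreement(self):
        lineages = [("A",), ("B",), ("C",)]
        assert lineage_consensus(lineages) is None

    def test_combined_assignment_prefers_consensus(self):
        taxon, confidence = assign_taxonomy(
            ["Pseudomonas"] * 9 + ["Bacillus"],
            [
                ("Proteobacteria", "Pseudomonadales"),
                ("Proteobacteria", "Pseudomonadales"),
                ("Firmicutes",),
            ],
        )
        assert taxon == "Pseudomonadales"
        assert confidence == "assigned"


def test_bin_purity_plurality_fraction():
    purity = bin_purity(
        ["a", "b", "c"],
        {"a": "g1", "b": "g1", "c": "g2"},
        {"a": 6000, "b": 3000, "c": 1000},
    )
    assert purity == pytest.approx(0.9)
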