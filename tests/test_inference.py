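"""Parsimony inference, labeling filters, clustering, and statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prosip.inference import (
    CO2Design,
    Identification,
    MethanolDesign,
    ProteinGroup,
    aggregate_functional_abundance,
    cluster_isotopologues,
    compare_timepoints,
    filter_labeled_proteins,
    infer_proteins,
    protein_fdr,
)


class TestInferProteins:
    def test_single_protein_all_unique(self):
        groups = infer_proteins({"a": {"P1"}, "b": {"P1"}})
        assert len(groups) == 1
        assert groups[0].member_protein_ids == ("P1",)
        assert groups[0].unique_peptides == {"a", "b"}

    def test_subsumed_protein_dropped(self):
        groups = infer_proteins({"a": {"P1"}, "b": {"P1", "P2"}})
        assert len(groups) == 1
        assert groups[0].member_protein_ids == ("P1",)
        assert groups[0].peptides == {"a", "b"}

    def test_indistinguishable_proteins_grouped(self):
        groups = infer_proteins({"a": {"P1", "P2"}})
        assert len(groups) == 1
        assert groups[0].member_protein_ids == ("P1", "P2")

    @settings(derandomize=True, max_examples=40)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            st.sets(
                st.sampled_from(["P1", "P2", "P3", "P4"]), min_size=1, max_size=3
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_every_peptide_explained(self, peptide_map):
        groups = infer_proteins(peptide_map)
        covered = set().union(*(g.peptides for g in groups)) if groups else set()
        # groups without a unique peptide are discarded, but selection
        # covered everything first
        selected_cover = set(peptide_map) - covered
        for peptide in selected_cover:
            # any uncovered peptide must be explainable only by discarded
            # (uniqueness-free) groups, which still were selected for cover
            assert peptide_map[peptide]


class TestProteinFdr:
    def test_zero_decoys(self):
        groups = [ProteinGroup("g1", ("P1",), frozenset("a"), frozenset())]
        assert protein_fdr(groups, []) == 0.0

    def test_direct_ratio(self):
        targets = [
            ProteinGroup(f"g{i}", (f"P{i}",), frozenset("a"), frozenset())
            for i in range(100)
        ]
        decoys = [ProteinGroup("d1", ("D1",), frozenset("b"), frozenset())]
        assert protein_fdr(targets, decoys) == pytest.approx(0.01)

    def test_zero_targets_raises(self):
        with pytest.raises(ValueError):
            protein_fdr([], [])


class TestClusterIsotopologues:
    def test_two_well_separated_clusters(self):
        clusters = cluster_isotopologues([20, 21, 45, 47])
        assert [sorted(c) for c in clusters] == [[20, 21], [45, 47]]

    def test_singleton(self):
        assert cluster_isotopologues([15]) == [[15]]

    def test_close_pair_merges(self):
        assert cluster_isotopologues([15, 18]) == [[15, 18]]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cluster_isotopologues([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=10.1, max_value=99.0), min_size=1, max_size=12
        )
    )
    def test_final_gaps_exceed_threshold(self, values):
        clusters = cluster_isotopologues(values)
        means = sorted(sum(c) / len(c) for c in clusters)
        assert all(b - a > 10 for a, b in zip(means, means[1:]))
        assert sum(len(c) for c in clusters) == len(values)


def _co2_group(idents):
    return ProteinGroup(
        group_id="g1",
        member_protein_ids=("P1",),
        unique_peptides=frozenset(i.peptide for i in idents),
        shared_peptides=frozenset(),
        identifications=list(idents),
    )


CO2 = CO2Design(
    blocks={"ta1": "T.aestivum", "ta2": "T.aestivum", "zm1": "Z.mays"}
)
METHANOL = MethanolDesign(
    triplicates={"d3r1": "day3", "d3r2": "day3", "d3r3": "day3",
                 "d8r1": "day8", "d8r2": "day8", "d8r3": "day8"}
)


class TestFilterLabeledProteins:
    def test_multi_peptide_enriched_protein_passes(self):
        # three identifications at 16/26/46 atom%, two peptides sharing
        # one wheat-rhizosphere sample
        idents = [
            Identification("pepA", "ta1", atom_percent=16.0),
            Identification("pepB", "ta1", atom_percent=26.0),
            Identification("pepA", "ta2", atom_percent=46.0),
        ]
        call = filter_labeled_proteins(_co2_group(idents), "co2", CO2)
        assert call.passing

    def test_single_peptide_fails_co2(self):
        idents = [Identification("pepA", "zm1", atom_percent=35.0)]
        call = filter_labeled_proteins(_co2_group(idents), "co2", CO2)
        assert not call.passing
        assert any("2 labeled peptides" in r for r in call.reasons)

    def test_low_enrichment_fails_co2(self):
        idents = [
            Identification("pepA", "zm1", atom_percent=35.0),
            Identification("pepB", "zm1", atom_percent=8.0),
        ]
        call = filter_labeled_proteins(_co2_group(idents), "co2", CO2)
        assert not call.passing

    def test_methanol_two_of_three_replicates_passes(self):
        # day-3 presence in replicates 1 and 3 only
        idents = [
            Identification("pepA", "d3r1", replicate_id="r1", atom_percent=93.0),
            Identification("pepA", "d3r3", replicate_id="r3", atom_percent=93.0),
        ]
        call = filter_labeled_proteins(_co2_group(idents), "methanol", METHANOL)
        assert call.passing

    def test_methanol_single_replicate_fails(self):
        idents = [
            Identification("pepA", "d8r2", replicate_id="r2", atom_percent=58.0)
        ]
        call = filter_labeled_proteins(_co2_group(idents), "methanol", METHANOL)
        assert not call.passing

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            filter_labeled_proteins(_co2_group([]), "acetate", CO2)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["pepA", "pepB", "pepC"]),
                st.sampled_from(["ta1", "ta2", "zm1"]),
                st.floats(min_value=10.5, max_value=99.0),
            ),
            min_size=1,
            max_size=8,
        ),
        st.tuples(
            st.sampled_from(["pepD", "pepE"]),
            st.sampled_from(["ta1", "ta2", "zm1"]),
            st.floats(min_value=10.5, max_value=99.0),
        ),
    )
    def test_adding_labeled_peptide_never_unpasses(self, base, extra):
        idents = [
            Identification(p, s, atom_percent=a) for p, s, a in base
        ]
        before = filter_labeled_proteins(_co2_group(idents), "co2", CO2)
        extended = idents + [
            Identification(extra[0], extra[1], atom_percent=extra[2])
        ]
        after = filter_labeled_proteins(_co2_group(extended), "co2", CO2)
        if before.passing:
            assert after.passing


class TestCompareTimepoints:
    def test_enumerated_extreme(self):
        u, p = compare_timepoints([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 6)

    def test_identical_singletons_two_sided(self):
        _u, p = compare_timepoints([5.0], [5.0], alternative="two-sided")
        assert p == 1.0

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10).tolist()
        b = (rng.normal(size=10) + 0.3).tolist()
        _u1, p_exact = compare_timepoints(a, b)
        _u2, p_approx = compare_timepoints(a, b, exact_limit=0)
        assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(size=4).tolist()
            b = rng.normal(size=5).tolist()
            u, p = compare_timepoints(a, b, alternative="two-sided")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compare_timepoints([], [1.0])


class TestAggregateFunctionalAbundance:
    def test_single_protein_single_term(self):
        table = aggregate_functional_abundance({"P1": 5.0}, {"P1": ["GO:1"]})
        assert table.loc["GO:1", "abundance"] == 5.0

    def test_shared_term_sums(self):
        table = aggregate_functional_abundance(
            {"P1": 2.0, "P2": 3.0}, {"P1": ["GO:1"], "P2": ["GO:1"]}
        )
        assert table.loc["GO:1", "abundance"] == 5.0

    def test_family_fraction(self):
        # one family holds 11% of the summed abundance
        abundances = {"X1": 6.0, "X2": 5.0, "other": 89.0}
        annotation = {"X1": ["methanol dehydrogenase"], "X2": ["methanol dehydrogenase"]}
        table = aggregate_functional_abundance(abundances, annotation)
        assert table.loc["methanol dehydrogenase", "fraction"] == pytest.approx(
            0.11, abs=1e-9
        )

    def test_unannotated_bucket(self):
        table = aggregate_functional_abundance({"P1": 1.0}, {})
        assert table.loc["unannotated", "abundance"] == 1.0
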