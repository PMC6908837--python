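"""Decoy construction, envelope scoring, atom% estimation, search, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prosip import simulate
from prosip.chem import Peptide, digest
from prosip.constants import NATURAL_C13
from prosip.isotopes import EnrichmentSpec, formula_envelope
from prosip.chem import ElementalFormula
from prosip.search import (
    PeptideIndex,
    PeptideSpectrumMatch,
    estimate_atom_percent,
    fdr_filter,
    make_decoy_db,
    read_mgf,
    score_envelope,
    search_sample,
    sip_config,
    write_mgf,
)


class TestDecoyDb:
    def test_full_sequence_reversal(self):
        db = make_decoy_db([("p1", "PEPTIDE")])
        assert db == [("p1", "PEPTIDE"), ("DECOY_p1", "EDITPEP")]

    def test_doubles_cardinality(self):
        records = [(f"p{i}", "AAAK") for i in range(7)]
        assert len(make_decoy_db(records)) == 14

    def test_palindrome_decoy_equals_target(self):
        db = make_decoy_db([("p1", "ABA".replace("B", "C"))])
        assert db[1][1] == db[0][1]
        assert db[1][0].startswith("DECOY_")

    def test_prefix_collision(self):
        with pytest.raises(ValueError):
            make_decoy_db([("DECOY_p1", "AAAK")])

    def test_empty_database(self):
        with pytest.raises(ValueError):
            make_decoy_db([])


class TestScoreEnvelope:
    @pytest.fixture()
    def envelope(self):
        return formula_envelope(
            ElementalFormula(C=2), EnrichmentSpec("C", 0.5), truncate=1.0
        )

    def test_proportional_observation_scores_one(self, envelope):
        assert score_envelope(envelope.abundances * 7.3, envelope) == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self, envelope):
        assert score_envelope(np.zeros(3), envelope) == 0.0

    def test_closed_form_cosine(self):
        env = formula_envelope(
            ElementalFormula(C=1), EnrichmentSpec("C", 0.5), truncate=1.0
        )
        assert score_envelope(np.array([1.0, 0.0]), env) == pytest.approx(
            0.7071, abs=1e-4
        )

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_intensity_scale_invariance(self, scale):
        env = formula_envelope(
            ElementalFormula(C=3), EnrichmentSpec("C", 0.3), truncate=1.0
        )
        observed = np.array([0.2, 0.5, 0.1, 0.05])
        assert score_envelope(observed * scale, env) == pytest.approx(
            score_envelope(observed, env), rel=1e-9
        )


class TestEstimateAtomPercent:
    def test_noiseless_grid_identity(self):
        spectrum = simulate.synthetic_spectrum("LVDEFGHSTK", atom_fraction=0.30)
        est = estimate_atom_percent(spectrum, Peptide("LVDEFGHSTK"), sip_config())
        assert est is not None and est.atom_percent == pytest.approx(30.0)

    def test_natural_abundance_maps_to_natural_point(self):
        spectrum = simulate.synthetic_spectrum("LVDEFGHSTK")
        est = estimate_atom_percent(spectrum, Peptide("LVDEFGHSTK"), sip_config())
        assert est is not None and est.atom_fraction == pytest.approx(NATURAL_C13)

    def test_noisy_replicates_recover_mean(self):
        rng = np.random.default_rng(42)
        estimates = []
        config = sip_config()
        for i in range(50):
            spectrum = simulate.synthetic_spectrum(
                "LVDEFGHSTWAK",
                atom_fraction=0.30,
                noise_sd=0.05,
                rng=rng,
                spectrum_id=f"n{i}",
            )
            est = estimate_atom_percent(spectrum, Peptide("LVDEFGHSTWAK"), config)
            estimates.append(est.atom_percent)
        assert np.mean(estimates) == pytest.approx(30.0, abs=2.0)

    def test_no_precursor_match_returns_none(self):
        spectrum = simulate.synthetic_spectrum("LVDEFGHSTK", atom_fraction=0.30)
        other = Peptide("WWWWWWWWWWWWK")  # far heavier precursor
        assert estimate_atom_percent(spectrum, other, sip_config()) is None


@pytest.fixture(scope="module")
def tiny_index():
    rng = np.random.default_rng(9)
    proteins = [
        (f"prot_{i:02d}", simulate._random_protein(rng)) for i in range(20)
    ]
    config = sip_config()
    index = PeptideIndex.build(make_decoy_db(proteins), config)
    return proteins, index, config


class TestSearchSample:
    def test_generative_round_trip(self, tiny_index):
        proteins, index, config = tiny_index
        rng = np.random.default_rng(11)
        assignments = []
        for i in range(60):
            _acc, seq = proteins[int(rng.integers(len(proteins)))]
            peps = digest(seq, max_missed=0)
            pep = peps[int(rng.integers(len(peps)))]
            frac = [NATURAL_C13, 0.2, 0.5][i % 3]
            assignments.append((pep.sequence, frac, "s1", "r1"))
        spectra = simulate.generate_spectra(assignments, noise_sd=0.0, seed=12)
        psms = search_sample(spectra, index, config)
        assert len(psms) == len(spectra)
        correct = sum(
            1
            for m, (seq, _f, _s, _r) in zip(psms, assignments)
            if m.sequence == seq
        )
        assert correct / len(spectra) >= 0.99

    def test_unmatchable_precursor_absent(self, tiny_index):
        from prosip.search import Spectrum

        _proteins, index, config = tiny_index
        # precursor neutral mass ~238 Da: below every indexed peptide
        spectrum = Spectrum(
            spectrum_id="tiny",
            precursor_mz=120.0,
            precursor_charge=2,
            peaks=np.array([[120.0, 100.0], [121.0, 50.0]]),
        )
        assert search_sample([spectrum], index, config) == []

    def test_deterministic_repeat(self, tiny_index):
        proteins, index, config = tiny_index
        seq = digest(proteins[0][1], max_missed=0)[0].sequence
        spectra = simulate.generate_spectra(
            [(seq, 0.2, "s1", "r1")], noise_sd=0.05, seed=3
        )
        first = search_sample(spectra, index, config)
        second = search_sample(spectra, index, config)
        assert first == second


def _psm(seq, score, decoy=False):
    return PeptideSpectrumMatch(
        spectrum_id=f"s_{seq}_{score}",
        sample_id="s1",
        replicate_id="r1",
        sequence=seq,
        mods=(),
        protein_ids=("DECOY_p" if decoy else "p",),
        is_decoy=decoy,
        atom_percent=1.07,
        score=score,
        parent_offset_da=0,
        precursor_charge=2,
        peak_area=1.0,
    )


class TestFdrFilter:
    def test_no_decoys_keeps_everything(self):
        psms = [_psm(f"PEP{i}K", 0.9 - 0.01 * i) for i in range(10)]
        assert len(fdr_filter(psms, 0.01)) == 10

    def test_prefix_stops_before_first_decoy(self):
        psms = [_psm(f"AAA{i}K".replace(str(i), "ACDEG"[i]), 0.9 - 0.02 * i) for i in range(4)]
        psms += [_psm("DDDDK", 0.80, decoy=True)]
        psms += [_psm(f"EEE{c}K", 0.70 - 0.01 * i) for i, c in enumerate("ACD")]
        retained = fdr_filter(psms, 0.01)
        assert len(retained) == 4
        assert all(m.score >= 0.84 for m in retained)

    def test_all_decoys_on_top_yields_empty(self):
        psms = [_psm(f"DDD{c}K", 0.9, decoy=True) for c in "ACDEF"]
        psms += [_psm(f"TTT{c}K", 0.5) for c in "ACDEF"]
        assert fdr_filter(psms, 0.01) == []

    def test_collapses_to_best_psm_per_peptide(self):
        psms = [_psm("PEPTIDEK", 0.5), _psm("PEPTIDEK", 0.9)]
        retained = fdr_filter(psms, 0.5)
        assert len(retained) == 1 and retained[0].score == 0.9

    def test_level_validation(self):
        with pytest.raises(ValueError):
            fdr_filter([], 0.0)


def test_mgf_round_trip(tmp_path):
    spectra = [
        simulate.synthetic_spectrum(
            "LVDEFGHSTK",
            atom_fraction=0.2,
            spectrum_id="a1",
            sample_id="s1",
            replicate_id="r2",
        )
    ]
    mgf_path = tmp_path / "spectra.mgf"
    manifest = tmp_path / "manifest.tsv"
    write_mgf(spectra, mgf_path, manifest)
    back = read_mgf(mgf_path, manifest)
    assert len(back) == 1
    assert back[0].spectrum_id == "a1"
    assert back[0].sample_id == "s1" and back[0].replicate_id == "r2"
    assert back[0].precursor_charge == spectra[0].precursor_charge
    assert back[0].precursor_mz == pytest.approx(spectra[0].precursor_mz, abs=1e-4)
    assert back[0].peaks[:, 0] == pytest.approx(spectra[0].peaks[:, 0], abs=1e-4)
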