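import numpy as np
import pytest
from scipy import stats

from mampipe import ProteinRecord
from mampipe.abundance import fraction_enrichment, nsaf
from mampipe.peptidomics import coverage, length_distribution, map_peptides
from mampipe.simulate import (
    CountTableConfig,
    PeptidomeConfig,
    simulate_count_table,
    simulate_genomes,
    simulate_peptidome,
    triangular_length_law,
)

from .conftest import random_protein


@pytest.fixture
def substrate():
    rng = np.random.default_rng(42)
    return ProteinRecord(id="substrate", sequence=random_protein(rng, 135))


class TestLengthLaw:
    def test_bounds_normalisation_and_modes(self):
        law = triangular_length_law()
        assert min(law) == 5 and max(law) == 29
        assert sum(law.values()) == pytest.approx(1.0)
        top = max(law.values())
        assert [l for l, p in law.items() if p == top] == [12, 13]

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            triangular_length_law(10, 5)


class TestSimulatePeptidome:
    def test_determinism(self, substrate):
        c = PeptidomeConfig(protein=substrate, seed=7)
        a = simulate_peptidome(c)
        b = simulate_peptidome(PeptidomeConfig(protein=substrate, seed=7))
        assert a[0] == b[0] and a[1] == b[1]

    def test_different_seed_differs(self, substrate):
        a, *_ = simulate_peptidome(PeptidomeConfig(protein=substrate, seed=1))
        b, *_ = simulate_peptidome(PeptidomeConfig(protein=substrate, seed=2))
        assert a != b

    def test_zero_yield_gives_empty_peptidome(self, substrate):
        c = PeptidomeConfig(protein=substrate,
                            n_peptides={6.0: 0.0, 25.0: 0.0})
        obs, meta, _ = simulate_peptidome(c)
        assert obs == []
        assert len(meta) == 8  # metadata still describes the samples

    def test_no_peptide_touches_protected_prefix(self, substrate):
        c = PeptidomeConfig(protein=substrate, protected_prefix_len=21,
                            n_peptides={25.0: 120.0}, seed=3)
        obs, _, truth = simulate_peptidome(c)
        matches, unmapped = map_peptides(obs, substrate)
        assert not unmapped
        assert min(m.start for m in matches) > truth.protected_prefix_len

    @pytest.mark.parametrize("k", [0, 10, 21, 30])
    def test_uncovered_prefix_recovery(self, substrate, k):
        c = PeptidomeConfig(protein=substrate, protected_prefix_len=k,
                            n_peptides={25.0: 125.0}, seed=1)  # ~500 peptides
        obs, _, _ = simulate_peptidome(c)
        assert len(obs) >= 400
        matches, _ = map_peptides(obs, substrate)
        assert coverage(matches, substrate).uncovered_prefix_len == k

    def test_length_histogram_matches_law(self, substrate):
        """Chi-square GOF of 10k sampled lengths against the planted law."""
        c = PeptidomeConfig(protein=substrate, protected_prefix_len=0,
                            n_peptides={25.0: 2500.0}, seed=11)
        obs, _, truth = simulate_peptidome(c)
        lengths = [len(o.peptide) for o in obs]
        assert len(lengths) >= 9000
        ks = sorted(truth.length_law)
        observed = np.array([sum(1 for l in lengths if l == k) for k in ks])
        expected = np.array([truth.length_law[k] for k in ks]) * len(lengths)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_empirical_mode_is_planted_mode(self):
        # long substrate so distinct-sequence deduplication cannot saturate
        # any length class; 10k draws pins the mode at the planted peak
        rng = np.random.default_rng(99)
        big = ProteinRecord(id="big", sequence=random_protein(rng, 5000))
        c = PeptidomeConfig(protein=big, protected_prefix_len=0,
                            n_peptides={25.0: 2500.0}, seed=13)
        obs, *_ = simulate_peptidome(c)
        assert len(obs) >= 9000
        *_, modes = length_distribution([o.peptide for o in obs])
        assert set(modes) <= {12, 13} and modes

    def test_impossible_config_rejected(self, substrate):
        with pytest.raises(ValueError, match="unprotected"):
            PeptidomeConfig(protein=substrate, protected_prefix_len=132)


class TestSimulateCountTable:
    def test_determinism_and_shape(self):
        c = CountTableConfig(seed=5)
        t1, g1 = simulate_count_table(c)
        t2, g2 = simulate_count_table(CountTableConfig(seed=5))
        assert t1.counts.equals(t2.counts)
        assert g1 == g2
        assert t1.counts.shape == (20, 8)

    def test_single_protein_nsaf_is_one(self):
        t, _ = simulate_count_table(CountTableConfig(n_proteins=1, seed=1))
        assert np.allclose(nsaf(t).nsaf, 1.0)

    def test_planted_enrichment_recovered(self):
        hits = 0
        for seed in range(100):
            t, truth = simulate_count_table(
                CountTableConfig(enrichment_fold=5.0, seed=seed))
            r = nsaf(t)
            means = r.mean_by_fraction[truth.enriched_fraction]
            if means.idxmax() == truth.enriched_protein_id:
                hits += 1
        assert hits >= 95

    def test_null_fold_is_calibrated(self):
        """fold=1: Welch p-values show no systematic fraction difference."""
        ps = []
        for seed in range(100):
            t, truth = simulate_count_table(
                CountTableConfig(enrichment_fold=1.0, seed=seed))
            r = nsaf(t)
            e = fraction_enrichment(r, truth.enriched_protein_id,
                                    "envelope", "cytoplasm")
            ps.append(e.p)
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert 0.3 < ps.mean() < 0.7

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            CountTableConfig(n_proteins=5, enriched_protein_index=5)


class TestSimulateGenomes:
    def test_determinism(self):
        a, ta = simulate_genomes(8, p_both=0.5, seed=9)
        b, tb = simulate_genomes(8, p_both=0.5, seed=9)
        assert [(p.id, p.sequence) for p in a] == \
            [(p.id, p.sequence) for p in b]
        assert ta == tb

    def test_planted_bookkeeping(self):
        proteins, truth = simulate_genomes(10, p_both=1.0, seed=2)
        ids = {p.id for p in proteins}
        for mam_id, pcat_id in truth.planted.values():
            assert {mam_id, pcat_id} <= ids
        assert len(truth.planted) == 10
        assert len(truth.taxa) == 10

    def test_taxon_weights_respected(self):
        _, truth = simulate_genomes(
            300, p_both=0.0, seed=4,
            taxon_labels=("Faecalibacterium", "other"),
            taxon_weights=(0.9, 0.1))
        frac = np.mean([t == "Faecalibacterium"
                        for t in truth.taxa.values()])
        assert 0.84 < frac < 0.96

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            simulate_genomes(3, p_both=1.5)
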