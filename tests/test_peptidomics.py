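import numpy as np
import pytest

from mampipe import (
    PeptideObservation,
    ProteinRecord,
    SampleMetadata,
    apply_identification_filters,
    coverage,
    length_distribution,
    map_peptides,
    peptides_per_sample,
    phase_summary,
    top_peptides,
)
from mampipe.peptidomics import PeptideMatch, find_occurrences

from .conftest import random_protein


def obs(peptide, count=1, sample="s1", **kw):
    return PeptideObservation(peptide=peptide, spectral_count=count,
                              sample_id=sample, **kw)


class TestIdentificationFilters:
    def test_two_stage_filter(self):
        grouped = {
            "keep": [obs("AAAA", evalue=1e-5), obs("CCCC", evalue=1e-3)],
            "one_peptide_left": [obs("DDDD", evalue=1e-5),
                                 obs("EEEE", evalue=0.5)],
            "all_weak": [obs("FFFF", evalue=0.02), obs("GGGG", evalue=0.9)],
        }
        out = apply_identification_filters(grouped)
        assert set(out) == {"keep"}
        assert len(out["keep"]) == 2

    def test_boundary_evalue_is_excluded(self):
        # strict <: a peptide exactly at the threshold is removed
        grouped = {"p": [obs("AAAA", evalue=0.01), obs("CCCC", evalue=0.0099),
                         obs("DDDD", evalue=0.0001)]}
        out = apply_identification_filters(grouped)
        assert [o.peptide for o in out["p"]] == ["CCCC", "DDDD"]

    def test_distinct_sequences_not_observations_counted(self):
        # two observations of one sequence do not satisfy min_peptides=2
        grouped = {"p": [obs("AAAA", sample="s1", evalue=1e-5),
                         obs("AAAA", sample="s2", evalue=1e-5)]}
        assert apply_identification_filters(grouped) == {}

    def test_protein_level_evalue(self):
        grouped = {"p": [obs("AAAA", evalue=1e-5), obs("CCCC", evalue=1e-5)],
                   "q": [obs("DDDD", evalue=1e-5), obs("EEEE", evalue=1e-5)]}
        out = apply_identification_filters(
            grouped, protein_evalues={"p": 1e-6, "q": 1e-3})
        assert set(out) == {"p"}

    def test_missing_evalue_is_error(self):
        with pytest.raises(ValueError, match="E-value"):
            apply_identification_filters({"p": [obs("AAAA")]})


class TestMapPeptides:
    def test_published_peptide_maps_at_53_65(self, mam_like_135):
        # position is only meaningful on the real sequence; here we plant it
        seq = mam_like_135.sequence[:52] + "GNTFLQSTINRTI" + \
            mam_like_135.sequence[65:]
        prot = ProteinRecord(id="m", sequence=seq)
        matches, unmapped = map_peptides([obs("GNTFLQSTINRTI")], prot)
        assert not unmapped
        assert any((m.start, m.end) == (53, 65) for m in matches)

    def test_overlapping_occurrences_all_reported(self):
        prot = ProteinRecord(id="p", sequence="AAAA")
        matches, _ = map_peptides([obs("AAA")], prot)
        assert [(m.start, m.end) for m in matches] == [(1, 3), (2, 4)]

    def test_il_equivalence_policy(self):
        prot = ProteinRecord(id="p", sequence="LLL")
        with_il, _ = map_peptides([obs("III")], prot, il_equivalent=True)
        assert [(m.start, m.end) for m in with_il] == [(1, 3)]
        without, unmapped = map_peptides([obs("III")], prot)
        assert without == [] and len(unmapped) == 1

    def test_il_never_reduces_matches(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_protein(rng, 60, alphabet="AILV")
            pep = random_protein(rng, 4, alphabet="AILV")
            plain = len(find_occurrences(pep, seq))
            folded = len(find_occurrences(pep, seq, il_equivalent=True))
            assert folded >= plain


class TestCoverage:
    def tile(self, start, end, step=10, width=15):
        """Peptide matches tiling residues start..end (1-based)."""
        out = []
        s = start
        while s <= end:
            e = min(s + width - 1, end)
            out.append(PeptideMatch(peptide="A" * (e - s + 1), start=s, end=e,
                                    spectral_count=1, sample_id="s1"))
            s += step
        return out

    def test_tiling_cargo_gives_844_percent(self, mam_like_135):
        cov = coverage(self.tile(22, 135), mam_like_135)
        assert cov.covered_fraction == pytest.approx(114 / 135, abs=1e-9)
        assert round(100 * cov.covered_fraction, 1) == 84.4
        assert cov.uncovered_prefix_len == 21

    def test_no_matches(self, mam42):
        cov = coverage([], mam42)
        assert cov.covered_fraction == 0.0
        assert cov.uncovered_prefix_len == 42

    def test_full_length_peptide(self, mam42):
        m = PeptideMatch(peptide=mam42.sequence, start=1, end=42,
                         spectral_count=2, sample_id="s1")
        cov = coverage([m], mam42)
        assert cov.covered_fraction == 1.0
        assert cov.uncovered_prefix_len == 0
        assert (cov.depth == 2).all()

    def test_out_of_bounds_match_rejected(self, mam42):
        bad = PeptideMatch(peptide="AAAA", start=40, end=43,
                           spectral_count=1, sample_id="s1")
        with pytest.raises(ValueError, match="out of bounds"):
            coverage([bad], mam42)

    def test_against_set_union_oracle_and_additive_depth(self):
        rng = np.random.default_rng(17)
        prot = ProteinRecord(id="p", sequence=random_protein(rng, 80))
        for _ in range(20):
            matches = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(1, 75))
                e = int(rng.integers(s, min(s + 12, 80)))
                matches.append(PeptideMatch(
                    peptide=prot.sequence[s - 1:e], start=s, end=e,
                    spectral_count=int(rng.integers(1, 9)), sample_id="s1"))
            cov = coverage(matches, prot)
            covered = set()
            depth = [0] * 80
            for m in matches:
                covered |= set(range(m.start, m.end + 1))
                for i in range(m.start, m.end + 1):
                    depth[i - 1] += m.spectral_count
            assert cov.covered_fraction == pytest.approx(len(covered) / 80)
            assert list(cov.depth) == depth
            # monotone under adding one more match
            extra = matches + [PeptideMatch(peptide=prot.sequence[:5],
                                            start=1, end=5,
                                            spectral_count=1, sample_id="s1")]
            assert coverage(extra, prot).covered_fraction >= cov.covered_fraction


class TestLengthDistribution:
    def test_min_max_modes(self):
        peps = ["AAAAA", "CCCCC", "DDDDDDDDDDDD"]
        hist, lo, hi, modes = length_distribution(peps)
        assert (lo, hi) == (5, 12)
        assert hist == {5: 2, 12: 1}
        assert modes == [5]

    def test_distinct_sequences_only(self):
        hist, *_ = length_distribution(["AAAAA", "AAAAA", "CCC"])
        assert hist == {3: 1, 5: 1}

    def test_single_peptide(self):
        hist, lo, hi, modes = length_distribution(["AAAA"])
        assert (lo, hi, modes) == (4, 4, [4])

    def test_tied_modes_all_reported(self):
        _, _, _, modes = length_distribution(["AA", "CC", "AAA", "CCC"])
        assert modes == [2, 3]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            length_distribution([])


class TestTopPeptides:
    def test_printed_spectral_count_ordering(self):
        observations = [obs("GNTFLQSTINRTI", 28),
                        obs("VGNTFLQSTINRTI", 20),
                        obs("AAVYNLGVAPTKNTVKETEVKFTV", 25)]
        ranked = top_peptides(observations, k=3)
        assert [c for _, c in ranked] == [28, 25, 20]
        assert ranked[0][0] == "GNTFLQSTINRTI"

    def test_aggregation_over_samples_and_tie_break(self):
        observations = [obs("CCC", 2, "s1"), obs("CCC", 3, "s2"),
                        obs("AAA", 5, "s1"), obs("DDD", 5, "s1")]
        ranked = top_peptides(observations, k=10)
        assert ranked == [("AAA", 5), ("CCC", 5), ("DDD", 5)]

    def test_k_larger_than_population(self):
        assert len(top_peptides([obs("AAA")], k=99)) == 1


class TestPhaseSummary:
    def meta(self, counts_by_sample, od=2.0, t=18.0):
        return [SampleMetadata(sample_id=s, time_h=t, od600=od, replicate=s)
                for s in counts_by_sample]

    def test_mean_and_sample_sd(self):
        counts = {"a": 64, "b": 66, "c": 68, "d": 68}
        df = phase_summary(counts, self.meta(counts))
        row = df.loc[18.0]
        assert row["mean_peptides"] == pytest.approx(66.5)
        assert row["sd_peptides"] == pytest.approx(1.9149, abs=1e-4)

    def test_per_od_division(self):
        df = phase_summary({"a": 10}, self.meta({"a": 10}, od=2.0))
        assert df.loc[18.0, "per_od_mean"] == pytest.approx(5.0)

    def test_scaled_series_max_is_exactly_one(self):
        meta = (self.meta({"a": 2, "b": 4}, od=0.5, t=6.0)
                + self.meta({"c": 30, "d": 40}, od=1.6, t=25.0))
        counts = {"a": 2, "b": 4, "c": 30, "d": 40}
        df = phase_summary(counts, meta)
        assert df["scaled_peptides"].max() == 1.0
        assert df["scaled_od"].max() == 1.0
        assert df["scaled_per_od"].max() == 1.0
        assert df.loc[25.0, "scaled_peptides"] == 1.0

    def test_single_time_point_scales_to_one(self):
        df = phase_summary({"a": 7}, self.meta({"a": 7}))
        assert df["scaled_peptides"].tolist() == [1.0]

    def test_missing_samples_count_zero(self):
        df = phase_summary({}, self.meta({"a": 0, "b": 0}))
        assert df.loc[18.0, "mean_peptides"] == 0.0


def test_peptides_per_sample_counts_distinct():
    observations = [obs("AAA", 5, "s1"), obs("AAA", 2, "s1"),
                    obs("CCC", 1, "s1"), obs("AAA", 1, "s2")]
    assert peptides_per_sample(observations) == {"s1": 2, "s2": 1}
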