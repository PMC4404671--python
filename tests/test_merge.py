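"""Strand harmonization, merging and replicate concordance."""

import numpy as np
import pytest

from tomatopop.merge import (ACTION_AMBIGUOUS, ACTION_DROPPED, ACTION_FLIPPED,
                             deduplicate, harmonize_and_merge,
                             replicate_concordance)
from tomatopop.genotypes import MISSING

from conftest import make_matrix


def two_sets(alleles1, alleles2, calls1, calls2, acc1=None, acc2=None):
    m1 = make_matrix(calls1, alleles=alleles1, accessions=acc1 or ["a1", "a2"])
    m2 = make_matrix(calls2, alleles=alleles2, accessions=acc2 or ["b1", "b2"])
    return [m1, m2]


class TestHarmonize:
    def test_reverse_complement_flipped_dosage_preserved(self):
        # A/G in set 1 vs T/C in set 2: relabel only, dosages untouched
        ds = two_sets([("A", "G")], [("T", "C")], [[0], [2]], [[1], [2]])
        merged, rep = harmonize_and_merge(ds)
        assert rep.count(ACTION_FLIPPED) == 1
        assert merged.calls[:, 0].tolist() == [0, 2, 1, 2]
        assert (merged.markers.loc[0, "allele_a"],
                merged.markers.loc[0, "allele_b"]) == ("A", "G")

    def test_identical_pairs_pass_through(self):
        ds = two_sets([("A", "G")], [("A", "G")], [[0], [2]], [[1], [2]])
        merged, rep = harmonize_and_merge(ds)
        assert rep.count(ACTION_FLIPPED) == 0
        assert rep.count(ACTION_DROPPED) == 0
        assert merged.calls[:, 0].tolist() == [0, 2, 1, 2]

    def test_swapped_pair_recodes_dosage(self):
        # G/A counts the other allele: dosage must be recoded 2-d
        ds = two_sets([("A", "G")], [("G", "A")], [[0], [2]], [[0], [2]])
        merged, _ = harmonize_and_merge(ds)
        assert merged.calls[:, 0].tolist() == [0, 2, 2, 0]

    def test_incompatible_pairs_dropped(self):
        ds = two_sets([("A", "G")], [("A", "C")], [[0], [2]], [[1], [2]])
        merged, rep = harmonize_and_merge(ds)
        assert rep.count(ACTION_DROPPED) == 1
        assert merged.n_markers == 0

    def test_ambiguous_resolved_by_frequency_concordance(self):
        # A/T marker: set 2's as-is frequency is the mirror of set 1's, so
        # the flipped orientation maximizes concordance
        calls1 = [[2], [2], [2], [1]]   # p(ref) = 7/8
        calls2 = [[0], [0], [0], [1]]   # p = 1/8 as-is, 7/8 flipped
        ds = two_sets([("A", "T")], [("A", "T")], calls1, calls2,
                      acc1=list("abcd"), acc2=list("efgh"))
        merged, rep = harmonize_and_merge(ds)
        assert rep.count(ACTION_AMBIGUOUS) == 1
        assert merged.calls[:, 0].tolist() == [2, 2, 2, 1, 2, 2, 2, 1]

    def test_ambiguous_near_half_frequency_dropped(self):
        calls = [[1], [0], [2], [1]]    # p = 0.5: both orientations tie
        ds = two_sets([("C", "G")], [("C", "G")], calls, calls,
                      acc1=list("abcd"), acc2=list("efgh"))
        merged, rep = harmonize_and_merge(ds)
        assert rep.count(ACTION_DROPPED) == 1
        assert merged.n_markers == 0

    def test_merge_is_idempotent(self):
        ds = two_sets([("A", "G")], [("T", "C")], [[0], [2]], [[1], [2]])
        merged1, _ = harmonize_and_merge(ds)
        half1 = merged1.subset(accession_ids=merged1.accessions[:2])
        half2 = merged1.subset(accession_ids=merged1.accessions[2:])
        merged2, rep2 = harmonize_and_merge([half1, half2])
        assert rep2.count(ACTION_FLIPPED) == 0
        assert np.array_equal(merged2.calls, merged1.calls)

    def test_shared_accessions_tagged_per_dataset(self):
        ds = two_sets([("A", "G")], [("A", "G")], [[0], [1]], [[2], [1]],
                      acc1=["x", "y"], acc2=["x", "z"])
        merged, _ = harmonize_and_merge(ds)
        assert sorted(merged.accessions) == ["x@ds0", "x@ds1", "y", "z"]


class TestReplicates:
    def test_identical_duplicates_not_flagged(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]], accessions=["r1", "r2"])
        rep = replicate_concordance(m, {"acc": ["r1", "r2"]}, seed=0)
        assert rep.summary.loc[0, "mean_distance"] == 0.0
        assert rep.flagged == []

    def test_fully_discordant_duplicates_flagged(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]], accessions=["r1", "r2"])
        rep = replicate_concordance(m, {"acc": ["r1", "r2"]}, seed=0)
        assert rep.summary.loc[0, "mean_distance"] == 1.0
        assert rep.flagged == ["acc"]

    def test_two_percent_hom_het_discordance_below_threshold(self):
        # 100 loci, 2 differing hom-vs-het: mean distance 0.02 * 0.5 = 0.01
        g1 = np.zeros((100,), dtype=np.int8)
        g2 = g1.copy()
        g2[:2] = 1
        m = make_matrix(np.vstack([g1, g2]), positions=np.arange(100.0),
                        accessions=["r1", "r2"])
        rep = replicate_concordance(m, {"acc": ["r1", "r2"]},
                                    threshold=0.05, seed=0)
        assert rep.summary.loc[0, "mean_distance"] == pytest.approx(0.01)
        assert rep.flagged == []

    def test_singleton_group_distance_undefined(self):
        m = make_matrix([[0], [1]], accessions=["r1", "r2"])
        rep = replicate_concordance(m, {"acc": ["r1"]}, seed=0)
        assert np.isnan(rep.summary.loc[0, "mean_distance"])
        assert "undefined" in rep.summary.loc[0, "note"]

    def test_deduplicate_keeps_one_seeded_representative(self):
        m = make_matrix([[0], [0], [1]], accessions=["r1", "r2", "u"])
        out, rep = deduplicate(m, {"acc": ["r1", "r2"]}, seed=42)
        assert out.n_accessions == 2
        assert "u" in out.accessions
        assert rep.representatives["acc"] in {"r1", "r2"}
        out2, _ = deduplicate(m, {"acc": ["r1", "r2"]}, seed=42)
        assert out2.accessions == out.accessions  # seeded choice reproducible
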