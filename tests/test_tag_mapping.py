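"""Tag-to-gene assignment rules and count-matrix normalization."""

import numpy as np
import pandas as pd
import pytest

from sagescape.containers import (
    CPM_TOTAL,
    GeneCountMatrix,
    TagCountTable,
    TranscriptRecord,
    TranscriptSet,
)
from sagescape.reference_consensus import ConsensusTranscriptSet
from sagescape.tag_mapping_counts import (
    AMBIGUOUS,
    ASSIGNED,
    UNMATCHED,
    TagIndex,
    _match_tag_exhaustive,
    build_gene_counts,
    match_tag,
    normalize_cpm,
)

RNG = np.random.default_rng(17)
BASES = np.array(list("ACGT"))


def _random_seq(n):
    return "".join(BASES[RNG.integers(0, 4, n)])


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture()
def reference():
    tagged = "CATG" + _random_seq(22)
    seq_a = _random_seq(60) + tagged + _random_seq(30)
    seq_b = _random_seq(120)
    return ConsensusTranscriptSet(records=[
        TranscriptRecord("gA", "tA1", seq_a),
        TranscriptRecord("gA", "tA2", _random_seq(40) + tagged),
        TranscriptRecord("gB", "tB1", seq_b),
    ]), tagged, seq_b


class TestMatchRules:
    def test_exact_substring_assigned_zero_mismatches(self, reference):
        ref, tag, _ = reference
        a = match_tag(tag, ref)
        assert (a.status, a.gene_id, a.mismatches) == (ASSIGNED, "gA", 0)

    def test_single_mismatch_assigned(self, reference):
        ref, tag, _ = reference
        mutated = ("T" if tag[10] != "T" else "G").join([tag[:10], tag[11:]])
        a = match_tag(mutated, ref)
        assert a.status == ASSIGNED and a.mismatches == 1

    def test_two_mismatches_unmatched(self, reference):
        ref, tag, _ = reference
        t = list(tag)
        t[10] = "T" if t[10] != "T" else "G"
        t[15] = "T" if t[15] != "T" else "G"
        # guard against the mutated tag accidentally matching elsewhere
        a = match_tag("".join(t), ref)
        assert a.status == UNMATCHED

    def test_hit_in_two_genes_is_ambiguous(self):
        shared = "CATG" + _random_seq(22)
        ref = ConsensusTranscriptSet(records=[
            TranscriptRecord("g1", "t1", _random_seq(30) + shared),
            TranscriptRecord("g2", "t2", shared + _random_seq(30)),
        ])
        assert match_tag(shared, ref).status == AMBIGUOUS

    def test_splice_variants_collapse_to_one_gene(self, reference):
        ref, tag, _ = reference
        # the tag occurs in both tA1 and tA2 but they share gene gA
        a = match_tag(tag, ref)
        assert a.status == ASSIGNED and a.gene_id == "gA"

    def test_iupac_position_costs_one_for_both_alleles(self):
        stem = "CATG" + _random_seq(22)
        seq = _random_seq(20) + stem + _random_seq(20)
        pos = 20 + 10
        ref_seq = seq[:pos] + "R" + seq[pos + 1:]  # A/G polymorphic site
        ref = ConsensusTranscriptSet(
            records=[TranscriptRecord("g1", "t1", ref_seq)],
            ambiguity_positions={"t1": [(pos, "R")]})
        for allele in ("A", "G"):
            tag = stem[:10] + allele + stem[11:]
            a = match_tag(tag, ref, max_mismatch=1)
            assert (a.status, a.mismatches) == (ASSIGNED, 1)

    def test_reverse_complement_not_matched(self, reference):
        ref, tag, _ = reference
        assert match_tag(_revcomp(tag), ref).status == UNMATCHED

    def test_non_acgt_tag_rejected(self, reference):
        ref, _, _ = reference
        with pytest.raises(ValueError):
            match_tag("CATG" + "N" * 22, ref)

    def test_duplicating_a_transcript_never_changes_status(self, reference):
        ref, tag, _ = reference
        merged = ConsensusTranscriptSet(
            records=list(ref.records)
            + [TranscriptRecord("gA", "tA3", ref.records[0].sequence)])
        assert match_tag(tag, merged).status == match_tag(tag, ref).status


class TestIndexAgainstExhaustiveScan:
    def test_identical_results_on_random_tags(self):
        genes = []
        for g in range(8):
            seq = _random_seq(50) + "CATG" + _random_seq(40)
            genes.append(TranscriptRecord(f"g{g}", f"t{g}", seq))
        ref = ConsensusTranscriptSet(records=genes)
        index = TagIndex(ref, max_mismatch=1)
        tags = []
        for rec in genes:
            pos = rec.sequence.rfind("CATG")
            tag = rec.sequence[pos:pos + 26]
            if len(tag) == 26:
                tags.append(tag)
                mutated = list(tag)
                mutated[7] = "A" if tag[7] != "A" else "C"
                tags.append("".join(mutated))
        tags.extend("CATG" + _random_seq(22) for _ in range(30))
        for tag in tags:
            fast = index.match(tag)
            slow = _match_tag_exhaustive(tag, ref, max_mismatch=1)
            assert (fast.status, fast.gene_id, fast.mismatches) == \
                (slow.status, slow.gene_id, slow.mismatches)


class TestCountsAndNormalization:
    def test_counts_sum_per_gene(self, reference):
        ref, tag, seq_b = reference
        tag_b = seq_b[:26]
        assignments = [match_tag(tag, ref)]
        tables = [TagCountTable("L1", {tag: 3}), TagCountTable("L2", {tag: 4})]
        matrix, _ = build_gene_counts(assignments, tables)
        assert matrix.raw.loc["gA", "L1"] == 3
        assert matrix.raw.loc["gA", "L2"] == 4

    def test_ambiguous_tags_contribute_nothing(self):
        shared = "CATG" + _random_seq(22)
        ref = ConsensusTranscriptSet(records=[
            TranscriptRecord("g1", "t1", _random_seq(10) + shared),
            TranscriptRecord("g2", "t2", shared),
        ])
        assignments = [match_tag(shared, ref)]
        tables = [TagCountTable("L1", {shared: 1000})]
        matrix, log = build_gene_counts(assignments, tables,
                                        gene_ids=["g1", "g2"])
        assert (matrix.raw.to_numpy() == 0).all()
        assert log["n_ambiguous"] == 1

    def test_empty_assignments_zero_matrix(self):
        matrix, _ = build_gene_counts([], [TagCountTable("L1", {})],
                                      gene_ids=["g1"])
        assert (matrix.raw.to_numpy() == 0).all()

    def test_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                           index=[f"g{i}" for i in range(30)],
                           columns=list("ABCD"))
        matrix = normalize_cpm(GeneCountMatrix(raw=raw))
        np.testing.assert_allclose(matrix.normalized.sum(axis=0),
                                   CPM_TOTAL, rtol=1e-9)

    def test_cpm_identity_at_one_million_total(self):
        raw = pd.DataFrame({"A": [400_000, 600_000]}, index=["g1", "g2"])
        matrix = normalize_cpm(GeneCountMatrix(raw=raw))
        pd.testing.assert_frame_equal(matrix.normalized, raw.astype(float))

    def test_cpm_simple_arithmetic(self):
        raw = pd.DataFrame({"A": [464, 2_000_000 - 464]}, index=["g1", "g2"])
        matrix = normalize_cpm(GeneCountMatrix(raw=raw))
        assert matrix.normalized.loc["g1", "A"] == pytest.approx(232.0)

    def test_zero_total_library_named_in_error(self):
        raw = pd.DataFrame({"A": [5], "B": [0]}, index=["g1"])
        with pytest.raises(ValueError, match="B"):
            normalize_cpm(GeneCountMatrix(raw=raw))
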