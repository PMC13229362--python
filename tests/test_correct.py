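"""Edit application, placeholder resolution, acceptance, VCF output."""

import numpy as np
import pytest

from seedpolish.correct import (
    CorrectionResult,
    VcfRecord,
    apply_pattern,
    correct_region,
    emit_vcf,
    records_from_results,
    resolve_gap,
    resolve_placeholders,
    support_ratio,
)
from seedpolish.index import build_index_from_counts, count_kmer_multiplicities
from seedpolish.model import GAP_CHAR, ErrorPattern
from seedpolish.regions import find_error_regions, find_gap_regions
from seedpolish.synthetic import generate_genome

K = 21
W = 5

NOOP = ErrorPattern((0,) * W)


@pytest.fixture(scope="module")
def truth_index(seed_set_k21):
    genome = generate_genome(10_000, rng_seed=12)
    counts = count_kmer_multiplicities([genome], K)
    index = build_index_from_counts(counts, K, seed_set_k21, threshold=1, fpr=1e-6)
    return genome, index


class TestApplyPattern:
    def test_noop_leaves_sequence_unchanged(self):
        assert apply_pattern("AACCGG", NOOP, anchor=2) == "AACCGG"

    def test_deletion_removes_bases_at_anchor(self):
        pat = ErrorPattern((0,) * W, ("del", 2))
        assert apply_pattern("AACCGG", pat, anchor=2) == "AAGG"

    def test_insertion_introduces_placeholders(self):
        pat = ErrorPattern((0,) * W, ("ins", 1))
        out = apply_pattern("AACCGG", pat, anchor=2)
        assert out == "AA" + GAP_CHAR + "CCGG"

    def test_mask_positions_become_placeholders(self):
        pat = ErrorPattern((1, 0, 1, 0, 0))
        out = apply_pattern("AACCGGTT", pat, anchor=1)
        assert out == "A" + GAP_CHAR + "C" + GAP_CHAR + "GGTT"

    def test_pattern_past_sequence_end_rejected(self):
        pat = ErrorPattern((0,) * W, ("del", 3))
        assert apply_pattern("ACGT", pat, anchor=2) is None


class TestSupportRatio:
    def test_truth_substring_fully_supported(self, truth_index):
        genome, index = truth_index
        assert support_ratio(genome[100:200], index) == 1.0

    def test_central_substitution_window_arithmetic(self, truth_index):
        genome, index = truth_index
        seq = genome[500:600]
        pos = 50
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        mutated = seq[:pos] + alt + seq[pos + 1 :]
        n = len(seq) - K + 1
        # Exactly k windows cover the substitution.
        assert support_ratio(mutated, index) == pytest.approx((n - K) / n)

    def test_all_n_sequence_unsupported(self, truth_index):
        _, index = truth_index
        assert support_ratio("N" * 50, index) == 0.0

    def test_short_sequence_raises(self, truth_index):
        _, index = truth_index
        with pytest.raises(ValueError):
            support_ratio("ACGT", index)


class TestResolvePlaceholders:
    def test_no_placeholders_returns_input(self, truth_index):
        genome, index = truth_index
        seq = genome[300:380]
        assert resolve_placeholders(seq, index, 0.5) == (seq, 1.0)

    def test_unique_truth_base_recovered(self, truth_index):
        genome, index = truth_index
        seq = genome[1000:1080]
        broken = seq[:40] + GAP_CHAR + seq[41:]
        resolved, support = resolve_placeholders(broken, index, 0.5)
        assert resolved == seq
        assert support == 1.0

    def test_below_p_returns_none(self, truth_index):
        genome, index = truth_index
        seq = genome[2000:2080]
        # Two errors; a single placeholder can only fix one of them.
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        broken = (
            seq[:30] + GAP_CHAR + seq[31:60] + alt[seq[60]] + seq[61:]
        )
        assert resolve_placeholders(broken, index, p=0.8) is None

    def test_over_budget_rejected(self, truth_index):
        genome, index = truth_index
        seq = genome[3000:3080]
        broken = GAP_CHAR * 12 + seq[12:]
        assert resolve_placeholders(broken, index, 0.1) is None


def _one_region(draft, index):
    regions = find_error_regions({"c": draft}, index)
    assert len(regions) == 1
    return regions[0]


class TestCorrectRegion:
    def test_true_pattern_at_rank_one_restores_truth(self, truth_index):
        genome, index = truth_index
        pos = 5000
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[pos]]
        draft = genome[:pos] + alt + genome[pos + 1 :]
        region = _one_region(draft, index)
        true_pat = ErrorPattern((1, 0, 0, 0, 0))
        res = correct_region(region, [(true_pat, 0.9), (NOOP, 0.1)], index, p=0.5)
        assert res.status == "edited"
        assert res.applied.support == 1.0
        assert res.applied.ops == [(pos, "SUB", alt, genome[pos])]

    def test_all_candidates_below_p_filtered(self, truth_index):
        genome, index = truth_index
        pos = 6000
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[pos]]
        draft = genome[:pos] + alt + genome[pos + 1 :]
        region = _one_region(draft, index)
        # Offered only a hopeless pattern far from the real error.
        bad = ErrorPattern((0, 0, 0, 0, 1), ("del", 5))
        res = correct_region(region, [(bad, 0.9)], index, p=0.99)
        assert res.status == "filtered"
        assert res.applied is None

    def test_applied_edit_never_decreases_support(self, truth_index, rng):
        genome, index = truth_index
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for pos in (1500, 4500, 7500):
            draft = genome[:pos] + alt[genome[pos]] + genome[pos + 1 :]
            region = _one_region(draft, index)
            patterns = [(ErrorPattern((1, 0, 0, 0, 0)), 0.5), (NOOP, 0.3)]
            res = correct_region(region, patterns, index, p=0.5)
            if res.applied is not None:
                assert res.applied.support > res.base_support


class TestResolveGap:
    def test_two_base_gap_restored_from_flanks(self, truth_index):
        genome, index = truth_index
        pos = 4000
        draft = genome[:pos] + "NN" + genome[pos + 2 :]
        region = find_gap_regions({"c": draft}, max_gap=W, k=K)[0]
        res = resolve_gap(region, index, p=0.8, w=W)
        assert res.status == "gap_resolved"
        assert res.applied.ops == [(pos, "GAP", "NN", genome[pos : pos + 2])]

    def test_oversized_gap_not_reported_by_scanner(self):
        seq = "ACGT" + "N" * (W + 1) + "ACGT"
        assert find_gap_regions({"c": seq}, max_gap=W) == []

    def test_unresolvable_gap_filtered(self, truth_index, seed_set_k21):
        genome, index = truth_index
        # An index built from unrelated sequence cannot support any fill.
        other = generate_genome(5000, rng_seed=77)
        counts = count_kmer_multiplicities([other], K)
        foreign = build_index_from_counts(counts, K, seed_set_k21, 1, 1e-6)
        draft = genome[:4000] + "NN" + genome[4002:]
        region = find_gap_regions({"c": draft}, max_gap=W, k=K)[0]
        res = resolve_gap(region, foreign, p=0.8, w=W)
        assert res.status == "filtered"


class TestVcf:
    def test_header_only_vcf_is_valid(self, tmp_path):
        import pysam

        path = tmp_path / "empty.vcf"
        emit_vcf([], {"c": "ACGT"}, path)
        with pysam.VariantFile(str(path)) as vf:
            assert list(vf) == []

    def test_substitution_coordinate_convention(self, tmp_path):
        import pysam

        draft = {"c": "A" * 100 + "G" + "A" * 100}
        rec = VcfRecord("c", 101, "G", "T", info={"STAGE": "model"})
        path = tmp_path / "sub.vcf"
        emit_vcf([rec], draft, path)
        with pysam.VariantFile(str(path)) as vf:
            out = list(vf)
        assert out[0].pos == 101 and out[0].ref == "G" and out[0].alts == ("T",)

    def test_records_ref_verified_against_draft(self, truth_index, tmp_path):
        import pysam

        genome, index = truth_index
        pos = 5000
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[pos]]
        draft = genome[:pos] + alt + genome[pos + 1 :]
        region = _one_region(draft, index)
        res = correct_region(
            region, [(ErrorPattern((1, 0, 0, 0, 0)), 0.9)], index, p=0.5
        )
        records = records_from_results([res], {"c": draft})
        path = tmp_path / "out.vcf"
        emit_vcf(records, {"c": draft}, path)
        with pysam.VariantFile(str(path)) as vf:
            for r in vf:
                assert draft[r.pos - 1 : r.pos - 1 + len(r.ref)] == r.ref

    def test_ref_mismatch_is_internal_error(self):
        with pytest.raises(ValueError):
            records_from_results(
                [
                    CorrectionResult(
                        region=_FakeRegion(), status="edited",
                        applied=_FakeApplied(), base_support=0.0,
                    )
                ],
                {"c": "AAAA"},
            )

    def test_filtered_region_symbolic_record(self, tmp_path, truth_index):
        genome, _ = truth_index
        draft = {"c": genome[:200]}
        res = CorrectionResult(
            region=_region_stub("c", 50, 55), status="filtered"
        )
        records = records_from_results([res], draft)
        assert records[0].alt == "<REGION>"
        assert records[0].filter == "lowsupport"
        assert records[0].info["END"] == 55


def _region_stub(contig, start, end):
    from seedpolish.regions import ErrorRegion

    return ErrorRegion(contig, start, end, "", "", sequence="x" * (end - start))


class _FakeRegion:
    contig_id = "c"
    start = 0
    end = 1


class _FakeApplied:
    support = 1.0
    ops = [(0, "SUB", "G", "T")]  # draft has A at 0: REF mismatch


class TestDeterminism:
    def test_byte_identical_results(self, truth_index):
        genome, index = truth_index
        pos = 2500
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[pos]]
        draft = genome[:pos] + alt + genome[pos + 1 :]
        region = _one_region(draft, index)
        pats = [(ErrorPattern((1, 0, 0, 0, 0)), 0.9), (NOOP, 0.05)]
        a = correct_region(region, pats, index, p=0.5)
        b = correct_region(region, pats, index, p=0.5)
        assert a.applied.edited_context == b.applied.edited_context
        assert a.applied.ops == b.applied.ops
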