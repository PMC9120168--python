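"""Merging and the filtering cascade: rules, conservation, idempotence."""

import itertools

import numpy as np
import pytest

from oracles import (
    GT_CHOICES,
    oracle_background_subtraction,
    oracle_pass,
    oracle_shared_genotype_removed,
    oracle_sv_size_removed,
    random_variant_set,
)
from varscreen.filters import (
    CascadeConfig,
    FilterReport,
    filter_pass,
    filter_sv_size,
    merge_variant_sets,
    private_to_sample,
    remove_shared_genotype,
    run_cascade,
    subtract_background_svs,
)
from varscreen.model import (
    MISSING,
    GenomeIndex,
    Genotype,
    ModelError,
    VariantClass,
    VariantRecord,
    VariantSet,
)

SAMPLES = ("a", "b", "c", "d")


def snv(contig, pos, sample, genome_samples=None, alt="G", filt="PASS"):
    gts = {sample: Genotype((1, 1))}
    return VariantRecord(
        contig=contig, pos=pos, ref="A", alt=alt,
        variant_class=VariantClass.SNV, filter=filt, genotypes=gts,
    )


def single_sample_set(sample, records, genome):
    return VariantSet((sample,), records, genome)


def sv_del(pos, sample, svlen=-2000, caller="delly", filt="PASS"):
    return VariantRecord(
        contig="chr1", pos=pos, ref="N", alt="<DEL>",
        variant_class=VariantClass.SV_DEL, filter=filt,
        genotypes={sample: Genotype((1, 1))},
        info={"SVTYPE": "DEL", "SVLEN": svlen},
        origin_callers=(caller,),
    )


class TestMerge:
    def test_common_and_private_snvs(self, genome):
        sets = []
        for i, s in enumerate(SAMPLES):
            recs = [snv("chr1", 100, s), snv("chr1", 200 + i * 10, s)]
            sets.append(single_sample_set(s, recs, genome))
        merged = merge_variant_sets(sets, genome)
        assert len(merged) == 5
        common = next(r for r in merged if r.pos == 100)
        assert all(common.genotype(s) == Genotype((1, 1)) for s in SAMPLES)
        private = next(r for r in merged if r.pos == 210)
        assert private.genotype("b").carries_alt
        assert all(private.genotype(s) is MISSING for s in ("a", "c", "d"))

    def test_sv_calls_within_tolerance_collapse(self, genome):
        s1 = single_sample_set("a", [sv_del(1000, "a", caller="delly")], genome)
        s2 = single_sample_set("b", [sv_del(1004, "b", caller="sniffles")], genome)
        merged = merge_variant_sets([s1, s2], genome, sv_breakpoint_tolerance=10)
        assert len(merged) == 1
        rec = merged.records[0]
        assert rec.pos == 1000  # earliest position kept
        assert rec.origin_callers == ("delly", "sniffles")
        assert rec.genotype("a").carries_alt and rec.genotype("b").carries_alt

    def test_sv_calls_beyond_tolerance_stay_separate(self, genome):
        s1 = single_sample_set("a", [sv_del(1000, "a")], genome)
        s2 = single_sample_set("b", [sv_del(1100, "b")], genome)
        merged = merge_variant_sets([s1, s2], genome, sv_breakpoint_tolerance=10)
        assert len(merged) == 2

    def test_empty_inputs_merge_empty(self, genome):
        merged = merge_variant_sets(
            [single_sample_set(s, [], genome) for s in SAMPLES], genome
        )
        assert len(merged) == 0
        assert merged.samples == SAMPLES

    def test_duplicate_sample_names_rejected(self, genome):
        s = single_sample_set("a", [], genome)
        with pytest.raises(ModelError, match="duplicate sample"):
            merge_variant_sets([s, s], genome)

    def test_genome_mismatch_rejected(self, genome):
        other = GenomeIndex.from_pairs([("chr1", 999)])
        s = single_sample_set("a", [], genome)
        with pytest.raises(ModelError, match="genome"):
            merge_variant_sets([s], other)


class TestFilterPass:
    def test_counts_and_identity(self, genome):
        recs = [snv("chr1", 10 * (i + 1), "a", filt="PASS" if i < 7 else "lowq")
                for i in range(10)]
        vset = single_sample_set("a", recs, genome)
        out, rep = filter_pass(vset)
        assert len(out) == 7
        assert rep.removed_by_rule["not_pass"] == 3
        again, rep2 = filter_pass(out)
        assert len(again) == 7 and rep2.removed_by_rule["not_pass"] == 0

    def test_all_fail_gives_empty(self, genome):
        vset = single_sample_set(
            "a", [snv("chr1", 10, "a", filt="lowq")], genome
        )
        out, rep = filter_pass(vset)
        assert len(out) == 0 and rep.output_count == 0


class TestSharedGenotype:
    def _vset_for_patterns(self, patterns, genome):
        records = []
        for i, gts in enumerate(patterns):
            records.append(
                VariantRecord(
                    contig="chr1", pos=i + 1, ref="A", alt="G",
                    variant_class=VariantClass.SNV,
                    genotypes=dict(zip(SAMPLES, gts)),
                )
            )
        return VariantSet(SAMPLES, records, genome)

    def test_rule_on_exhaustive_genotype_patterns(self, genome):
        """Enumerate every 4-sample pattern over {0/0,0/1,1/0,1/1,1/.,./.}."""
        patterns = list(itertools.product(GT_CHOICES, repeat=4))
        vset = self._vset_for_patterns(patterns, genome)
        out, rep = remove_shared_genotype(vset)
        kept_keys = {r.key for r in out.records}
        for rec in vset.records:
            expected_removed = oracle_shared_genotype_removed(rec, SAMPLES)
            assert (rec.key not in kept_keys) == expected_removed
        assert rep.input_count == len(patterns)
        assert rep.output_count == len(out)

    @pytest.mark.parametrize(
        "gts,removed",
        [
            ([(1, 1)] * 4, True),
            ([(1, 1)] * 3 + [(0, 1)], False),
            ([(0, 1), (1, 0), (0, 1), (1, 0)], True),  # unphased equality
            ([(1, 1)] * 3 + [(None, None)], False),  # not all called
        ],
    )
    def test_quoted_examples(self, gts, removed, genome):
        vset = self._vset_for_patterns([[Genotype(g) for g in gts]], genome)
        out, _ = remove_shared_genotype(vset)
        assert (len(out) == 0) == removed

    def test_single_sample_is_undefined(self, genome):
        vset = single_sample_set("a", [], genome)
        with pytest.raises(ModelError):
            remove_shared_genotype(vset)


class TestSvSize:
    def test_boundary_is_strict(self, genome):
        vset = single_sample_set(
            "a",
            [
                sv_del(1000, "a", svlen=-15_000),
                sv_del(5000, "a", svlen=-10_000),
                snv("chr1", 50, "a"),
            ],
            genome,
        )
        out, rep = filter_sv_size(vset, max_sv_len=10_000)
        assert rep.removed_by_rule["sv_too_long"] == 1
        spans = {abs(r.svlen) for r in out.records if r.is_sv}
        assert spans == {10_000}

    def test_span_falls_back_to_end_minus_pos(self, genome):
        rec = VariantRecord(
            contig="chr1", pos=1000, ref="N", alt="<DUP>",
            variant_class=VariantClass.SV_DUP,
            genotypes={"a": Genotype((1, 1))},
            info={"SVTYPE": "DUP", "END": 13_000},
        )
        vset = single_sample_set("a", [rec], genome)
        out, rep = filter_sv_size(vset, max_sv_len=10_000)
        assert len(out) == 0 and rep.removed_by_rule["sv_too_long"] == 1

    def test_non_sv_records_never_removed(self, genome):
        vset = single_sample_set("a", [snv("chr1", i + 1, "a") for i in range(5)],
                                 genome)
        out, rep = filter_sv_size(vset, max_sv_len=1)
        assert len(out) == 5 and rep.removed_by_rule["sv_too_long"] == 0


class TestBackgroundSubtraction:
    def _merged(self, genome, rep_gt, test_gt):
        rec = VariantRecord(
            contig="chr1", pos=1000, ref="N", alt="<DEL>",
            variant_class=VariantClass.SV_DEL,
            genotypes={"a": rep_gt, "b": Genotype((0, 0)), "c": MISSING,
                       "d": test_gt},
            info={"SVTYPE": "DEL", "SVLEN": -2000},
        )
        return VariantSet(SAMPLES, [rec], genome)

    def test_sv_also_in_replicate_is_background(self, genome):
        vset = self._merged(genome, Genotype((1, 1)), Genotype((1, 1)))
        out, rep = subtract_background_svs(vset, "d", ("a", "b", "c"))
        assert len(out) == 0
        assert rep.removed_by_rule["background_sv"] == 1

    def test_sv_absent_from_replicates_is_test_specific(self, genome):
        vset = self._merged(genome, Genotype((0, 0)), Genotype((1, 1)))
        out, rep = subtract_background_svs(vset, "d", ("a", "b", "c"))
        assert len(out) == 1
        assert rep.removed_by_rule["background_sv"] == 0

    def test_no_svs_at_all(self, genome):
        vset = VariantSet(SAMPLES, [], genome)
        out, rep = subtract_background_svs(vset, "d", ("a", "b", "c"))
        assert len(out) == 0 and rep.input_count == 0

    def test_unknown_sample_rejected(self, genome):
        vset = VariantSet(SAMPLES, [], genome)
        with pytest.raises(ModelError):
            subtract_background_svs(vset, "zz", ("a",))


class TestCascade:
    def _random_inputs(self, seed, genome, n=40):
        rng = np.random.default_rng(seed)
        sets = []
        for s in SAMPLES:
            vset = random_variant_set(rng, [s], genome, n)
            sets.append(vset)
        return sets

    def test_conservation_across_the_chain(self, big_genome):
        sets = self._random_inputs(0, big_genome)
        out, reports = run_cascade(sets, big_genome, CascadeConfig("d", ("a", "b", "c")))
        total_removed = sum(
            sum(r.removed_by_rule.values()) for r in reports
        )
        assert reports[0].input_count == len(out) + total_removed

    def test_cascade_is_idempotent(self, big_genome):
        sets = self._random_inputs(1, big_genome)
        cfg = CascadeConfig("d", ("a", "b", "c"))
        once, _ = run_cascade(sets, big_genome, cfg)
        # feed the cascade its own output (as a single multi-sample set)
        twice, reports = run_cascade([once], big_genome, cfg)
        assert [r.key for r in twice.records] == [r.key for r in once.records]
        assert all(sum(r.removed_by_rule.values()) == 0 for r in reports)

    def test_result_invariant_to_input_order(self, big_genome):
        sets = self._random_inputs(2, big_genome)
        cfg = CascadeConfig("d", ("a", "b", "c"))
        out1, _ = run_cascade(sets, big_genome, cfg)
        out2, _ = run_cascade(list(reversed(sets)), big_genome, cfg)
        key1 = [(r.key, tuple(sorted((s, str(g)) for s, g in r.genotypes.items())))
                for r in out1.records]
        key2 = [(r.key, tuple(sorted((s, str(g)) for s, g in r.genotypes.items())))
                for r in out2.records]
        assert key1 == key2

    def test_clean_input_passes_through_unchanged(self, genome):
        sets = [
            single_sample_set("a", [snv("chr1", 10, "a")], genome),
            single_sample_set("b", [snv("chr1", 20, "b")], genome),
        ]
        out, reports = run_cascade(sets, genome, CascadeConfig("b", ("a",)))
        assert len(out) == 2
        assert all(sum(r.removed_by_rule.values()) == 0 for r in reports)


class TestOracleEquivalence:
    """Each filter agrees with a literal re-implementation on random sets."""

    @pytest.mark.parametrize("seed", range(5))
    def test_filters_match_brute_force(self, seed, big_genome):
        rng = np.random.default_rng(seed)
        vset = random_variant_set(rng, SAMPLES, big_genome, 200)

        out, _ = filter_pass(vset)
        assert [r.key for r in out.records] == [r.key for r in oracle_pass(vset)]

        out, _ = remove_shared_genotype(vset)
        expect = [r.key for r in vset.records
                  if not oracle_shared_genotype_removed(r, SAMPLES)]
        assert [r.key for r in out.records] == expect

        out, _ = filter_sv_size(vset, max_sv_len=10_000)
        expect = [r.key for r in vset.records
                  if not oracle_sv_size_removed(r, 10_000)]
        assert [r.key for r in out.records] == expect

        out, rep = subtract_background_svs(vset, "d", ("a", "b", "c"))
        kept, background = oracle_background_subtraction(vset, "d", ("a", "b", "c"))
        assert [r.key for r in out.records] == [r.key for r in kept]
        assert rep.removed_by_rule["background_sv"] == len(background)


class TestFilterReport:
    def test_conservation_violation_is_rejected(self):
        with pytest.raises(ModelError):
            FilterReport("x", 10, {"not_pass": 3}, 8)

    def test_unknown_rule_name_rejected(self):
        with pytest.raises(ModelError):
            FilterReport("x", 10, {"weird_rule": 0}, 10)


def test_private_to_sample(genome):
    shared = VariantRecord(
        contig="chr1", pos=10, ref="A", alt="G", variant_class=VariantClass.SNV,
        genotypes={"a": Genotype((1, 1)), "b": Genotype((0, 1))},
    )
    only_b = VariantRecord(
        contig="chr1", pos=20, ref="A", alt="G", variant_class=VariantClass.SNV,
        genotypes={"a": Genotype((0, 0)), "b": Genotype((1, 1))},
    )
    vset = VariantSet(("a", "b"), [shared, only_b], genome)
    assert [r.pos for r in private_to_sample(vset, "b")] == [20]
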