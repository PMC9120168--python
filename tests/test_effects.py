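"""ANN parsing, coding-effect splits, stop-gain and affected-gene sets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from varscreen.diversity import round_half_away
from varscreen.effects import (
    affected_gene_sets,
    coding_effect_percentages,
    parse_ann,
    stop_gain_report,
)
from varscreen.model import (
    Genotype,
    ModelError,
    VariantClass,
    VariantRecord,
    VariantSet,
)

SAMPLES = ("a", "b", "c", "d")


class TestParseAnn:
    def test_single_annotation(self):
        recs = parse_ann("G|missense_variant|MODERATE|geneA|geneA|transcript|t1")
        assert len(recs) == 1
        assert recs[0].effect_term == "missense_variant"
        assert recs[0].gene == "geneA"
        assert recs[0].primary

    def test_multiple_annotations_first_is_primary(self):
        recs = parse_ann(
            "G|stop_gained|HIGH|geneA|geneA,G|synonymous_variant|LOW|geneB|geneB"
        )
        assert [r.primary for r in recs] == [True, False]
        assert recs[1].effect_term == "synonymous_variant"

    def test_ampersand_joined_terms_take_first(self):
        recs = parse_ann("G|missense_variant&splice_region_variant|MODERATE|g|g")
        assert recs[0].effect_term == "missense_variant"

    def test_empty_string_gives_empty_list(self):
        assert parse_ann("") == []

    def test_too_few_fields_is_an_error(self):
        with pytest.raises(ModelError, match="pipe"):
            parse_ann("G|missense_variant|MODERATE")


def annotated_snv(pos, ann, carriers, samples=SAMPLES):
    gts = {
        s: Genotype((1, 1)) if s in carriers else Genotype((0, 0)) for s in samples
    }
    return VariantRecord(
        contig="chr1", pos=pos, ref="A", alt="G",
        variant_class=VariantClass.SNV, genotypes=gts, info={"ANN": ann},
    )


def build_set(records, genome, samples=SAMPLES):
    return VariantSet(samples, records, genome)


def syn(gene="g1"):
    return f"G|synonymous_variant|LOW|{gene}|{gene}"


def mis(gene="g1"):
    return f"G|missense_variant|MODERATE|{gene}|{gene}"


def stop(gene="g1"):
    return f"G|stop_gained|HIGH|{gene}|{gene}"


def inter():
    return "G|intergenic_region|MODIFIER||"


class TestCodingPercentages:
    def test_59_41_split(self, big_genome):
        recs = [annotated_snv(i + 1, syn(), ("a",)) for i in range(59)]
        recs += [annotated_snv(100 + i, mis(), ("a",)) for i in range(41)]
        recs += [annotated_snv(500 + i, inter(), ("a",)) for i in range(10)]
        summary = coding_effect_percentages(build_set(recs, big_genome), "a")
        assert (summary.pct_synonymous, summary.pct_nonsynonymous) == (59, 41)
        assert summary.n_coding == 100  # intergenic excluded from denominator

    def test_all_synonymous(self, big_genome):
        recs = [annotated_snv(i + 1, syn(), ("a",)) for i in range(5)]
        summary = coding_effect_percentages(build_set(recs, big_genome), "a")
        assert (summary.pct_synonymous, summary.pct_nonsynonymous) == (100, 0)

    def test_no_coding_variants_is_undefined(self, big_genome):
        recs = [annotated_snv(1, inter(), ("a",))]
        assert coding_effect_percentages(build_set(recs, big_genome), "a") is None

    def test_only_carried_variants_count(self, big_genome):
        recs = [annotated_snv(1, syn(), ("a",)), annotated_snv(2, mis(), ("b",))]
        summary = coding_effect_percentages(build_set(recs, big_genome), "a")
        assert summary.n_coding == 1 and summary.n_synonymous == 1

    @given(n_syn=st.integers(0, 200), n_mis=st.integers(0, 200))
    def test_percentages_rounded_independently(self, n_syn, n_mis):
        """Each percentage equals half-away rounding of its own raw fraction."""
        if n_syn + n_mis == 0:
            return
        total = n_syn + n_mis
        p_syn = round_half_away(100.0 * n_syn / total)
        p_non = round_half_away(100.0 * n_mis / total)
        assert p_syn + p_non in {99, 100, 101}


class TestStopGain:
    def test_singleton_and_empty(self, big_genome):
        recs = [
            annotated_snv(1, stop("geneX"), ("a",)),
            annotated_snv(2, syn(), ("a",)),
        ]
        df = stop_gain_report(build_set(recs, big_genome), "a")
        assert df["gene"].tolist() == ["geneX"]
        assert stop_gain_report(build_set(recs, big_genome), "b").empty

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, seed, big_genome):
        rng = np.random.default_rng(seed)
        anns = [syn, mis, stop, inter]
        recs = []
        for i in range(80):
            ann = anns[int(rng.integers(0, 4))]
            carriers = tuple(
                s for s in SAMPLES if rng.random() < 0.5
            )
            args = (f"gene{int(rng.integers(0, 10))}",) if ann is not inter else ()
            recs.append(annotated_snv(i + 1, ann(*args), carriers))
        vset = build_set(recs, big_genome)
        for s in SAMPLES:
            expected = [
                r.pos for r in vset.records
                if r.genotype(s).carries_alt
                and parse_ann(r.info["ANN"])[0].effect_term == "stop_gained"
            ]
            assert sorted(stop_gain_report(vset, s)["pos"].tolist()) == sorted(expected)


class TestGeneSets:
    def test_worked_example(self, big_genome):
        # replicate gene sets {a,b},{b,c},{b}; test {b,d}
        recs = [
            annotated_snv(1, syn("a"), ("a",)),
            annotated_snv(2, syn("b"), ("a", "b", "c", "d")),
            annotated_snv(3, syn("c"), ("b",)),
            annotated_snv(4, syn("d"), ("d",)),
        ]
        hits = affected_gene_sets(build_set(recs, big_genome), ("a", "b", "c"), "d")
        assert hits.all_shared == {"b"}
        assert hits.replicates_shared == {"b"}
        assert hits.test_only == {"d"}

    def test_disjoint_sets_have_empty_intersections(self, big_genome):
        recs = [annotated_snv(i + 1, syn(f"g{i}"), (s,))
                for i, s in enumerate(SAMPLES)]
        hits = affected_gene_sets(build_set(recs, big_genome), ("a", "b", "c"), "d")
        assert hits.all_shared == frozenset()
        assert hits.replicates_shared == frozenset()

    def test_intergenic_and_uncarried_excluded(self, big_genome):
        recs = [
            annotated_snv(1, inter(), ("a",)),
            annotated_snv(2, syn("gX"), ("b",)),
        ]
        hits = affected_gene_sets(build_set(recs, big_genome), ("a", "b", "c"), "d")
        assert hits.per_sample["a"] == frozenset()
        assert hits.per_sample["b"] == {"gX"}

    def test_multi_gene_annotation_contributes_to_every_gene(self, big_genome):
        ann = "G|missense_variant|MODERATE|g1|g1,G|upstream_gene_variant|MODIFIER|g2|g2"
        recs = [annotated_snv(1, ann, ("a",))]
        hits = affected_gene_sets(build_set(recs, big_genome), ("a", "b", "c"), "d")
        assert hits.per_sample["a"] == {"g1", "g2"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_set_algebra_oracle(self, seed, big_genome):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(120):
            gene = f"g{int(rng.integers(0, 25))}"
            carriers = tuple(s for s in SAMPLES if rng.random() < 0.4)
            recs.append(annotated_snv(i + 1, syn(gene), carriers))
        vset = build_set(recs, big_genome)
        hits = affected_gene_sets(vset, ("a", "b", "c"), "d")
        truth = {
            s: {
                parse_ann(r.info["ANN"])[0].gene
                for r in vset.records if r.genotype(s).carries_alt
            }
            for s in SAMPLES
        }
        assert hits.per_sample == {s: frozenset(g) for s, g in truth.items()}
        assert hits.all_shared == truth["a"] & truth["b"] & truth["c"] & truth["d"]
        assert hits.replicates_shared == truth["a"] & truth["b"] & truth["c"]
        assert hits.test_only == truth["d"] - (truth["a"] | truth["b"] | truth["c"])
        # structural invariants
        assert len(hits.all_shared) <= min(len(v) for v in truth.values())
        assert not hits.test_only & (truth["a"] | truth["b"] | truth["c"])
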