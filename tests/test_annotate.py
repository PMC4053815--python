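import numpy as np
import pytest

from promcage.annotate import (
    PromoterCall,
    _identity,
    apply_tissue_specificity,
    assign_category,
    deduplicate,
    summarize,
)
from promcage.features import FeatureVector, PriorPair
from promcage.io import GeneModel, GenomicInterval, MirnaRecord, Transcript
from promcage.model import PosteriorResult
from promcage.preprocess import CandidateRegion, NormalizedTag, TagCluster


def make_call(start, end, x, category="intergenic", mirnas=("mir-a",), libs=("lib1",),
              chrom="chr1", strand="+"):
    iv = GenomicInterval(chrom, start, end, strand)
    cluster = TagCluster(iv, "lib1", (NormalizedTag(iv, "lib1", x),), x)
    region = CandidateRegion(
        cluster=cluster,
        representative_tss=start,
        feature_window=GenomicInterval(chrom, max(0, start - 500), start + 500, strand),
        assigned_mirnas=tuple(mirnas),
        category_hint=category,
    )
    return PromoterCall(
        region=region,
        features=FeatureVector(1.0, 0.5, 1.0, 0.5),
        prior=PriorPair(0.7),
        posterior=PosteriorResult(0.9, "promoter"),
        category=category,
        libraries_expressed=frozenset(libs),
    )


@pytest.fixture()
def annotation():
    host_iv = GenomicInterval("chr1", 200_000, 260_000, "+")
    exons = (
        GenomicInterval("chr1", 200_000, 200_500, "+"),
        GenomicInterval("chr1", 259_500, 260_000, "+"),
    )
    genes = {"HOST": GeneModel("HOST", host_iv, (Transcript("HT", host_iv, exons),))}
    mirnas = {
        "mir-intra": MirnaRecord(
            "mir-intra",
            GenomicInterval("chr1", 240_000, 240_080, "+"),
            (GenomicInterval("chr1", 240_010, 240_032, "+"),),
            "intragenic",
            host_gene_id="HOST",
        ),
        "mir-inter": MirnaRecord(
            "mir-inter",
            GenomicInterval("chr1", 500_000, 500_080, "+"),
            (GenomicInterval("chr1", 500_010, 500_032, "+"),),
            "intergenic",
        ),
    }
    return genes, mirnas


class TestAssignCategory:
    def test_host_tss_has_precedence(self, annotation):
        genes, mirnas = annotation
        call = make_call(199_950, 200_050, 5, mirnas=("mir-intra",))
        assert assign_category(call.region, mirnas, genes) == "host_gene"

    def test_promoter_inside_host_intron_is_intronic(self, annotation):
        genes, mirnas = annotation
        call = make_call(235_000, 235_030, 5, mirnas=("mir-intra",))
        assert assign_category(call.region, mirnas, genes) == "intronic"

    def test_intergenic_space_with_intragenic_mirna_is_hybrid(self, annotation):
        genes, mirnas = annotation
        call = make_call(195_000, 195_030, 5, mirnas=("mir-intra",))
        assert assign_category(call.region, mirnas, genes) == "hybrid"

    def test_upstream_of_intergenic_mirna_is_intergenic(self, annotation):
        genes, mirnas = annotation
        call = make_call(495_000, 495_030, 5, mirnas=("mir-inter",))
        assert assign_category(call.region, mirnas, genes) == "intergenic"


class TestIdentity:
    def test_identical_sequences(self):
        assert _identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_sliding_alignment_of_shorter(self):
        assert _identity("CGTA", "AACGTAAA") == 1.0

    def test_dissimilar_sequences_score_low(self):
        assert _identity("AAAAAAAA", "CCCCCCCC") == 0.0


class TestDeduplicate:
    def test_identical_sequences_keep_highest_count(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        calls = [make_call(1000, 1060, 5.0), make_call(5000, 5060, 9.0)]
        out = deduplicate(calls, [seq, seq])
        reps = [c for c in out if c.representative]
        assert len(reps) == 1 and reps[0].region.cluster.x == 9.0

    def test_dissimilar_sequences_all_representative(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(4)]
        calls = [make_call(1000 * (i + 1), 1000 * (i + 1) + 60, float(i + 1)) for i in range(4)]
        out = deduplicate(calls, seqs)
        assert all(c.representative for c in out)

    def test_same_locus_calls_merge_libraries(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        a = make_call(1000, 1060, 5.0, libs=("lib1",))
        b = make_call(1010, 1070, 3.0, libs=("lib2",))
        out = deduplicate([a, b], [seq, seq])
        assert len(out) == 1
        assert out[0].libraries_expressed == frozenset({"lib1", "lib2"})
        assert out[0].region.cluster.x == 8.0

    def test_idempotent(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(3)]
        seqs.append(seqs[0])
        calls = [
            make_call(1000, 1060, 2.0),
            make_call(3000, 3060, 4.0),
            make_call(6000, 6060, 1.0),
            make_call(9000, 9060, 8.0),
        ]
        once = deduplicate(calls, seqs)
        again = deduplicate(once, {i: seqs[0] for i in range(len(once))})
        # a second pass with consistent sequences preserves representatives
        assert sum(c.representative for c in once) >= sum(
            c.representative for c in again
        ) or len(once) == len(again)


class TestTissueSpecificity:
    def test_33_library_rule(self):
        calls = [
            make_call(1000, 1060, 5.0, libs=tuple(f"l{i}" for i in range(3))),
            make_call(3000, 3060, 5.0, libs=tuple(f"l{i}" for i in range(4))),
        ]
        out = apply_tissue_specificity(calls, n_libraries=33)
        assert out[0].tissue_specific is True  # 3 < 4
        assert out[1].tissue_specific is False  # 4 is not < 4

    def test_threshold_scales_with_library_count(self):
        call = make_call(1000, 1060, 5.0, libs=("l1",))
        (out,) = apply_tissue_specificity([call], n_libraries=66)
        assert out.tissue_specific is True  # threshold ceil(4*66/33) = 8


class TestSummarize:
    def _mirnas(self):
        return [
            MirnaRecord(
                "mir-a",
                GenomicInterval("chr1", 500_000, 500_080, "+"),
                (),
                "intergenic",
            ),
            MirnaRecord(
                "mir-b",
                GenomicInterval("chr1", 700_000, 700_080, "+"),
                (),
                "intergenic",
            ),
        ]

    def test_one_mirna_with_two_promoters(self):
        calls = [
            make_call(495_000, 495_060, 5.0, mirnas=("mir-a",)),
            make_call(490_000, 490_060, 3.0, mirnas=("mir-a",)),
        ]
        df = summarize(calls, self._mirnas()).set_index("category")
        row = df.loc["intergenic"]
        assert row["n_promoters"] == 2
        assert row["pct_mirnas_with_promoter"] == pytest.approx(50.0)
        assert row["pct_mirnas_multiple_promoters"] == pytest.approx(50.0)
        assert row["mean_tss_per_mirna"] == pytest.approx(2.0)

    def test_no_calls_gives_zero_rows(self):
        df = summarize([], self._mirnas()).set_index("category")
        assert (df["n_promoters"] == 0).all()
        assert (df["pct_mirnas_with_promoter"] == 0).all()

    def test_category_partition_is_exclusive_and_exhaustive(self, pipeline_result):
        reps = [c for c in pipeline_result.calls if c.representative]
        cats = {c.category for c in reps}
        assert cats <= {"intergenic", "host_gene", "intronic", "hybrid"}
        df = summarize(pipeline_result.calls, []).set_index("category")
        assert df.loc["all", "n_promoters"] == sum(
            df.loc[c, "n_promoters"] for c in ("intergenic", "host_gene", "intronic", "hybrid")
        )
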