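"""Genome mapping, category cascade and summaries."""

import random

import pytest

from srnakit.annotate import (
    Feature,
    FeatureIndex,
    GenomicAlignment,
    brute_force_map,
    classify_tag,
    length_distribution,
    map_tags,
    read_gff3,
    summarize_categories,
    write_gff3,
)
from srnakit.cleaning import SmallRNATag
from srnakit.sequtils import revcomp


def _random_genome(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


GENOME = _random_genome(5000)


def test_exact_substring_maps_plus_strand():
    tag = GENOME[1000:1021]
    alns = map_tags([tag], GENOME, 0)[tag]
    plus = [a for a in alns if a.strand == "+"]
    assert any(a.start == 1000 and a.end == 1021 and a.mismatches == 0 for a in plus)


def test_reverse_complement_maps_minus_strand():
    tag = revcomp(GENOME[2000:2022])
    alns = map_tags([tag], GENOME, 0)[tag]
    assert any(a.strand == "-" and a.start == 2000 for a in alns)


def test_random_tag_unmapped():
    # a random 21-mer is absent from a 5 kb genome with probability ~1
    tag = "TGCTGCTAGCTAGCTTGACAT"
    assert brute_force_map(tag, GENOME, 0) == []
    assert tag not in map_tags([tag], GENOME, 0)


def test_mapping_agrees_with_bruteforce_scan():
    rng = random.Random(1)
    tags = []
    for _ in range(15):
        s = rng.randrange(0, len(GENOME) - 22)
        t = list(GENOME[s : s + 21])
        for _ in range(rng.randrange(0, 3)):  # up to 2 substitutions
            i = rng.randrange(21)
            t[i] = rng.choice([b for b in "ACGT" if b != t[i]])
        tag = "".join(t)
        tags.append(tag if rng.random() < 0.5 else revcomp(tag))
    tags.append("".join(rng.choice("ACGT") for _ in range(21)))
    for mm in (0, 1, 2):
        got = map_tags(tags, GENOME, mm)
        for tag in set(tags):
            expect = brute_force_map(tag, GENOME, mm)
            assert got.get(tag, []) == expect, (tag, mm)


def test_invalid_mismatch_count_rejected():
    with pytest.raises(ValueError):
        map_tags(["ACGT" * 5], GENOME, 3)
    with pytest.raises(ValueError):
        map_tags(["ACGT" * 5], "", 0)


FEATS = [
    Feature("chr1", 100, 200, "+", "rRNA", "r1"),
    Feature("chr1", 150, 260, "+", "exon", "e1"),
    Feature("chr1", 300, 400, "-", "exon", "e2"),
    Feature("chr1", 400, 500, "-", "intron", "i1"),
    Feature("chr1", 600, 700, "+", "repeat_region", "rep1"),
    Feature("chr1", 650, 800, "+", "exon", "e3"),
]
FIDX = FeatureIndex(FEATS)


def _aln(start, end, strand="+", mm=0):
    return GenomicAlignment("x" * (end - start), "chr1", start, end, strand, mm)


def test_known_mirna_beats_every_feature():
    assert classify_tag("t", [_aln(150, 171)], FIDX, known_mirna_hit=True) == "miRNA"


def test_rrna_beats_exon():
    assert classify_tag("t", [_aln(160, 181)], FIDX) == "rRNA"


def test_repeat_beats_exon():
    assert classify_tag("t", [_aln(655, 676)], FIDX) == "repeat"


def test_exon_strand_split():
    assert classify_tag("t", [_aln(210, 231, "+")], FIDX) == "exon_sense"
    assert classify_tag("t", [_aln(210, 231, "-")], FIDX) == "exon_antisense"
    assert classify_tag("t", [_aln(310, 331, "-")], FIDX) == "exon_sense"


def test_unmapped_and_unannotated_fallback():
    assert classify_tag("t", None, FIDX) == "unannotated"
    assert classify_tag("t", [_aln(2000, 2021)], FIDX) == "unannotated"


def test_best_alignment_fewest_mismatches_used():
    # perfect hit in unannotated space beats a 1-mismatch hit in rRNA
    alns = [_aln(2000, 2021, "+", 0), _aln(120, 141, "+", 1)]
    assert classify_tag("t", alns, FIDX) == "unannotated"


def test_classification_order_independent():
    alns = [_aln(160, 181), _aln(655, 676)]
    assert classify_tag("t", alns, FIDX) == classify_tag("t", list(reversed(alns)), FIDX)


def test_summary_reproduces_printed_library_percentages():
    # miRNA reads 1,985,940 of 18,179,025 total -> 10.92 %
    tags = [
        SmallRNATag("A" * 21, 1_985_940, 1_732_993),
        SmallRNATag("C" * 21, 16_193_085, 16_030_355),
    ]
    cats = {"A" * 21: "miRNA", "C" * 21: "unannotated"}
    sc = summarize_categories(tags, cats, "control")
    st = summarize_categories(tags, cats, "treatment")
    assert sc.percent("miRNA") == 10.92
    assert st.percent("miRNA") == 9.76
    assert sc.table.loc["Total", "total"] == 18_179_025


def test_single_category_is_100_percent():
    tags = [SmallRNATag("ACGTACGTACGTACGTA", 5, 0)]
    s = summarize_categories(tags, {tags[0].sequence: "rRNA"}, "control")
    assert s.percent("rRNA") == 100.0


def test_summary_partitions_library(small_results):
    for lib, total in (("control", small_results.n_clean_c), ("treatment", small_results.n_clean_t)):
        table = summarize_categories(small_results.tags, small_results.categories, lib).table
        assert table.loc["Total", "total"] == total
        assert table.drop("Total")["total"].sum() == total
        assert table.drop("Total")["unique"].sum() == table.loc["Total", "unique"]


def test_zero_total_library_raises():
    with pytest.raises(ValueError):
        summarize_categories([SmallRNATag("ACGTACGTACGTACGTA", 0, 1)], {"ACGTACGTACGTACGTA": "rRNA"}, "control")


def test_length_distribution_all_21():
    tags = [SmallRNATag("A" * 21, 3, 0), SmallRNATag("C" * 21, 2, 0)]
    df = length_distribution(tags)
    assert df.loc[21, "total_c_pct"] == 100.0
    assert df.loc[24, "total_c_pct"] == 0.0  # empty bins reported, not omitted
    assert set(df.index) == set(range(15, 31))


def test_length_distribution_mixture_shares(small_config, small_results):
    df = length_distribution(small_results.tags)
    # insert-length modes at 21 and 24 nt should dominate the read totals
    w = small_config.length_mode_weights
    assert abs(df.loc[24, "total_c_pct"] / 100 - w[24]) < 0.1
    assert df.loc[21, "total_c_pct"] > df.loc[18, "total_c_pct"]


def test_gff3_roundtrip(tmp_path):
    p = tmp_path / "f.gff3"
    write_gff3(p, FEATS)
    back = read_gff3(p)
    assert [(f.start, f.end, f.ftype, f.fid) for f in back] == [
        (f.start, f.end, f.ftype, f.fid) for f in FEATS
    ]
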