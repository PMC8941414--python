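"""Category-map construction: coordinate conventions, derivation rules,
residual semantics, and brute-force per-base equality."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orthoannot.annotation import (
    CATEGORIES,
    RESIDUAL_CATEGORIES,
    AnnotationConfig,
    GeneModel,
    build_category_map,
    classify_exonic,
    coverage_summary,
    derive_introns,
    derive_tad_boundaries,
    overlap_matrix,
    read_gene_models,
    read_regulatory_build,
    read_tad_domains,
    write_gtf,
)
from orthoannot.intervals import GenomicInterval, IntervalSet

from oracles import label_genome

CFG = AnnotationConfig(splice_window=10, tad_flank=25_000, autosomes=("1", "2"))


def iv(s, e, chrom="1"):
    return GenomicInterval(chrom, s, e)


# ----------------------------------------------------------------- readers
def test_gtf_one_based_inclusive_converts_to_half_open(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(
        'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "lncRNA";\n'
    )
    (model,) = read_gene_models(p, CFG)
    assert model.exons == [iv(100, 200)]
    assert model.chrom == "1"  # chr prefix stripped


def test_gene_rows_without_exons_yield_no_models(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text('1\t.\tgene\t1\t500\t.\t+\t.\tgene_id "g";\n')
    assert read_gene_models(p, CFG) == []


def test_exon_counts_match_text_scan_of_toy_gtf(tmp_path):
    lines = []
    expected = {"t1": 3, "t2": 2, "t3": 1}
    start = 100
    for tid, n in expected.items():
        for i in range(n):
            s, e = start + 200 * i, start + 200 * i + 100
            lines.append(
                f'1\t.\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g_{tid}"; transcript_id "{tid}"; '
                f'transcript_biotype "protein_coding";\n'
            )
        start += 2000
    p = tmp_path / "toy.gtf"
    p.write_text("".join(lines))
    models = read_gene_models(p, CFG)
    assert {m.transcript_id: len(m.exons) for m in models} == expected


def test_malformed_gtf_reports_line_number(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("1\t.\texon\t10\n")
    with pytest.raises(ValueError, match=r"bad\.gtf:1"):
        read_gene_models(p, CFG)


def test_cds_outside_exons_rejects_transcript(tmp_path, caplog):
    p = tmp_path / "toy.gtf"
    p.write_text(
        '1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";\n'
        '1\t.\tCDS\t150\t300\t.\t+\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";\n'
    )
    with caplog.at_level("WARNING"):
        assert read_gene_models(p, CFG) == []
    assert "CDS outside its exons" in caplog.text


def test_gtf_round_trip_preserves_coordinates(tmp_path, small_bundle):
    first = tmp_path / "a.gtf"
    second = tmp_path / "b.gtf"
    write_gtf(small_bundle.human_genes, first)
    models = read_gene_models(first, small_bundle.annotation_config())
    write_gtf(sorted(models, key=lambda m: m.transcript_id), second)
    rewritten = read_gene_models(second, small_bundle.annotation_config())
    key = lambda m: m.transcript_id
    for a, b in zip(sorted(models, key=key), sorted(rewritten, key=key)):
        assert (a.transcript_id, a.exons, a.cds) == (b.transcript_id, b.exons, b.cds)


# ---------------------------------------------------------------- exonic
def test_utr_is_exon_minus_cds():
    m = GeneModel("g", "t", "1", "+", "protein_coding", [iv(100, 200)], [iv(130, 170)])
    frags = classify_exonic([m])
    assert frags["ExonCDS"].array("1").tolist() == [[130, 170]]
    assert frags["ExonUTR"].array("1").tolist() == [[100, 130], [170, 200]]


def test_noncoding_exons_fall_into_exon_other():
    m = GeneModel("g", "t", "1", "+", "lncRNA", [iv(500, 600)])
    frags = classify_exonic([m])
    assert frags["ExonOther"].array("1").tolist() == [[500, 600]]
    assert not frags["ExonCDS"]


def test_overlapping_transcripts_match_per_base_labelling():
    """A base translated in one isoform and untranslated in another belongs
    to both ExonCDS and ExonUTR."""
    m1 = GeneModel("g", "t1", "1", "+", "protein_coding", [iv(100, 300)], [iv(150, 250)])
    m2 = GeneModel("g", "t2", "1", "+", "protein_coding", [iv(200, 400)], [iv(320, 380)])
    frags = classify_exonic([m1, m2])
    for pos in range(100, 400):
        in_cds = (150 <= pos < 250) or (320 <= pos < 380)
        in_utr = (100 <= pos < 150) or (250 <= pos < 300) or (200 <= pos < 320) or (380 <= pos < 400)
        assert frags["ExonCDS"].contains("1", pos) == in_cds
        assert frags["ExonUTR"].contains("1", pos) == in_utr


# ---------------------------------------------------------------- introns
def test_intron_windows_split_at_ten_bp():
    m = GeneModel("g", "t", "1", "+", "protein_coding", [iv(100, 200), iv(300, 400)])
    out = derive_introns([m], CFG)
    assert out["IntronProximal"].array("1").tolist() == [[200, 210], [290, 300]]
    assert out["IntronDistal"].array("1").tolist() == [[210, 290]]
    # agreement with a per-base distance-to-splice-site scan
    for pos in range(200, 300):
        dist = min(pos - 200, 299 - pos)
        assert out["IntronProximal"].contains("1", pos) == (dist < 10)
        assert out["IntronDistal"].contains("1", pos) == (dist >= 10)


@pytest.mark.parametrize("intron_len,distal_len", [(20, 0), (21, 1), (19, 0)])
def test_short_introns_are_entirely_proximal(intron_len, distal_len):
    m = GeneModel(
        "g", "t", "1", "+", "protein_coding", [iv(100, 200), iv(200 + intron_len, 300 + intron_len)]
    )
    out = derive_introns([m], CFG)
    assert out["IntronProximal"].total_length == intron_len - distal_len
    assert out["IntronDistal"].total_length == distal_len


def test_single_exon_transcripts_contribute_no_introns():
    m = GeneModel("g", "t", "1", "+", "lncRNA", [iv(100, 200)])
    out = derive_introns([m], CFG)
    assert out["IntronProximal"].total_length == 0
    assert out["IntronDistal"].total_length == 0


# ------------------------------------------------------------- regulatory
def test_regulatory_types_map_to_categories(tmp_path):
    p = tmp_path / "reg.gff"
    p.write_text(
        "1\trb\tpromoter\t1001\t2000\t.\t.\t.\tID=p1\n"
        "1\trb\tTF_binding_site\t3001\t3200\t.\t.\t.\tID=t1\n"
        "1\trb\topen_chromatin_region\t4001\t4200\t.\t.\t.\tID=o1\n"
        "1\trb\tenhancer\t5001\t5400\t.\t.\t.\tID=e1\n"
        "1\trb\tweird_type\t6001\t6100\t.\t.\t.\tID=w1\n"
    )
    frags, unknown = read_regulatory_build(p, config=CFG)
    assert frags["Promoter"].array("1").tolist() == [[1000, 2000]]
    # TF binding sites and open chromatin both collapse into Miscellaneous
    assert frags["Miscellaneous"].array("1").tolist() == [[3000, 3200], [4000, 4200]]
    assert frags["EnhancerDistal"].array("1").tolist() == [[5000, 5400]]
    assert unknown == {"weird_type": 1}


def test_regulatory_coverage_equals_per_row_length_sums(tmp_path):
    rows = [
        ("promoter", 100, 400), ("promoter_flanking_region", 600, 900),
        ("enhancer", 1000, 1800), ("CTCF_binding_site", 2000, 2100),
        ("TF_binding_site", 2500, 2600),
    ]
    p = tmp_path / "reg.gff"
    p.write_text("".join(f"1\trb\t{t}\t{s + 1}\t{e}\t.\t.\t.\tID=x\n" for t, s, e in rows))
    frags, _ = read_regulatory_build(p, config=CFG)
    assert sum(f.total_length for f in frags.values()) == sum(e - s for _, s, e in rows)


def test_unrecognized_regulatory_file_is_hard_error(tmp_path):
    p = tmp_path / "reg.gff"
    p.write_text("1\trb\tmystery\t1\t10\t.\t.\t.\tID=x\n")
    with pytest.raises(ValueError, match="no recognized regulatory feature types"):
        read_regulatory_build(p, config=CFG)


# ------------------------------------------------------------------- TADs
def test_tad_boundaries_flank_each_domain_edge():
    out = derive_tad_boundaries([iv(1_000_000, 2_000_000)], CFG)
    assert out.array("1").tolist() == [[975_000, 1_025_000], [1_975_000, 2_025_000]]


def test_adjacent_domains_share_one_merged_boundary():
    out = derive_tad_boundaries([iv(100_000, 200_000), iv(200_000, 300_000)], CFG)
    assert out.array("1").tolist() == [[75_000, 125_000], [175_000, 225_000], [275_000, 325_000]]


def test_boundaries_clip_at_chromosome_bounds():
    # left flank clips at 0; the two clipped boundaries abut and merge
    out = derive_tad_boundaries([iv(10_000, 60_000)], CFG, chrom_lengths={"1": 70_000})
    assert out.array("1").tolist() == [[0, 70_000]]
    out = derive_tad_boundaries([iv(10_000, 20_000)], CFG, chrom_lengths={"1": 200_000})
    assert out.array("1").tolist() == [[0, 45_000]]


def test_tad_reader_accepts_bed3_and_bedpe(tmp_path):
    bed = tmp_path / "d.bed"
    bed.write_text("1\t1000\t5000\n")
    bedpe = tmp_path / "d.bedpe"
    bedpe.write_text("1\t1000\t5000\t1\t1000\t5000\t.\t0\n")
    assert read_tad_domains(bed, CFG) == read_tad_domains(bedpe, CFG) == [iv(1000, 5000)]


# ----------------------------------------------------------------- builder
def test_empty_fragments_leave_everything_unannotated():
    cmap = build_category_map({}, {"1": 1000}, CFG)
    assert cmap["Unannotated"].array("1").tolist() == [[0, 1000]]
    for cat in CATEGORIES:
        if cat != "Unannotated":
            assert not cmap[cat]


def test_intron_distal_loses_bases_with_other_annotations():
    frags = {
        "IntronDistal": IntervalSet.from_pairs({"1": [(210, 290)]}),
        "EnhancerDistal": IntervalSet.from_pairs({"1": [(250, 260)]}),
    }
    cmap = build_category_map(frags, {"1": 1000}, CFG)
    assert cmap["IntronDistal"].array("1").tolist() == [[210, 250], [260, 290]]


def test_fragment_beyond_chromosome_length_is_hard_error():
    frags = {"Promoter": IntervalSet.from_pairs({"1": [(900, 1100)]})}
    with pytest.raises(ValueError, match="beyond chromosome"):
        build_category_map(frags, {"1": 1000}, CFG)


def test_build_is_idempotent_on_its_own_output(small_bundle):
    cmap = small_bundle.human_category_map()
    rebuilt = build_category_map(
        {c: cmap[c] for c in CATEGORIES},
        cmap.chrom_lengths,
        small_bundle.annotation_config(),
    )
    for cat in CATEGORIES:
        assert rebuilt[cat] == cmap[cat], cat


def test_category_map_matches_per_base_oracle(small_bundle):
    """Interval-arithmetic categories equal a literal per-base labelling."""
    cmap = small_bundle.human_category_map()
    tx = {
        m.transcript_id: {
            "chrom": m.chrom,
            "biotype": m.biotype,
            "exons": [(e.start, e.end) for e in m.exons],
            "cds": [(c.start, c.end) for c in m.cds],
        }
        for m in small_bundle.human_genes
    }
    labels = label_genome(
        tx,
        small_bundle.human_regulatory,
        [(d.chrom, d.start, d.end) for d in small_bundle.human_domains],
        small_bundle.chrom_lengths,
        splice_window=small_bundle.config.splice_window,
        tad_flank=small_bundle.config.tad_flank,
    )
    for chrom, lab in labels.items():
        want = {c: np.array([c in s for s in lab]) for c in CATEGORIES}
        pos = np.arange(len(lab))
        for cat in CATEGORIES:
            got = cmap[cat].contains_many(chrom, pos)
            assert np.array_equal(got, want[cat]), (chrom, cat)


def test_residual_categories_touch_no_other_category(small_maps):
    human_map, mouse_map, _ = small_maps
    for cmap in (human_map, mouse_map):
        cmap.validate()
        for resid in RESIDUAL_CATEGORIES:
            others = IntervalSet.union_all(cmap[c] for c in CATEGORIES if c != resid)
            assert (cmap[resid] & others).total_length == 0


def test_union_of_categories_covers_every_base(small_maps):
    human_map, _, _ = small_maps
    union = IntervalSet.union_all(human_map[c] for c in CATEGORIES)
    assert union.total_length == sum(human_map.chrom_lengths.values())


# --------------------------------------------------------------- summaries
def test_coverage_summary_single_full_category():
    frags = {"Promoter": IntervalSet.from_pairs({"1": [(0, 1000)]})}
    cmap = build_category_map(frags, {"1": 1000}, CFG)
    cov = coverage_summary(cmap).set_index("category")
    assert cov.loc["Promoter", "pct"] == 100.0
    assert cov.loc["Unannotated", "bp"] == 0


def test_coverage_and_overlap_match_per_base_counts(small_maps):
    human_map, _, _ = small_maps
    cov = coverage_summary(human_map).set_index("category")
    mat = overlap_matrix(human_map)
    # overlap allowed between non-residual categories: totals can pass 100%
    assert cov["bp"].sum() >= human_map.genome_length
    for ci in CATEGORIES:
        assert cov.loc[ci, "bp"] == human_map[ci].total_length
        assert mat.loc[ci, ci] == human_map[ci].total_length
        for cj in CATEGORIES:
            assert mat.loc[ci, cj] == (human_map[ci] & human_map[cj]).total_length
    assert np.array_equal(mat.values, mat.values.T)
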