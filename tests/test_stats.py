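"""Conservation tables and the pooled two-proportion z-test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orthoannot.alignment import AlignmentIndex, ChainBlock
from orthoannot.annotation import CATEGORIES, CategoryMap
from orthoannot.stats import (
    DEFAULT_COMPARISONS,
    annotation_conservation,
    background_comparisons,
    two_proportion_z,
    variant_conservation,
)
from orthoannot.variants import VariantSite

from oracles import pooled_z


# ------------------------------------------------------------------ z-test
def test_z_statistic_hand_computed_example():
    # 50/100 vs 30/100: diff 0.2, pooled 0.4, se sqrt(0.24*0.02)
    res = two_proportion_z(50, 100, 30, 100)
    assert res.z == pytest.approx(0.2 / np.sqrt(0.24 * 0.02), rel=1e-12)
    assert res.z == pytest.approx(2.886751, abs=1e-6)


def test_equal_proportions_give_z_zero_p_one():
    res = two_proportion_z(25, 100, 5, 20)
    assert res.z == 0.0
    assert res.p == pytest.approx(1.0)


def test_antisymmetry():
    a = two_proportion_z(40, 90, 10, 70)
    b = two_proportion_z(10, 70, 40, 90)
    assert a.z == pytest.approx(-b.z, rel=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


def test_degenerate_pooled_proportion_is_explicit():
    res = two_proportion_z(0, 50, 0, 80)
    assert res.degenerate
    assert res.z is None and res.p is None
    assert "undefined" in res.p_label
    res = two_proportion_z(50, 50, 80, 80)
    assert res.degenerate


def test_z_equals_independent_formula_on_large_counts():
    res = two_proportion_z(984, 1000, 288, 1000)
    assert res.z == pytest.approx(pooled_z(984, 1000, 288, 1000), rel=1e-12)
    assert 0 < res.p < 1e-200


def test_extreme_p_values_floor_with_inequality_label():
    # z ~ 323: the normal tail underflows any float, so the p-value is
    # reported as a bounded inequality rather than 0
    res = two_proportion_z(98_400, 100_000, 28_800, 100_000)
    assert res.z == pytest.approx(pooled_z(98_400, 100_000, 28_800, 100_000), rel=1e-12)
    assert res.p == 1e-300
    assert res.p_label.startswith("<")


def test_z_matches_statsmodels_over_grid():
    from statsmodels.stats.proportion import proportions_ztest

    rng = np.random.default_rng(0)
    for _ in range(300):
        n1, n2 = rng.integers(2, 500, size=2)
        x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        pooled = (x1 + x2) / (n1 + n2)
        res = two_proportion_z(int(x1), int(n1), int(x2), int(n2))
        if pooled in (0.0, 1.0):
            assert res.degenerate
            continue
        z_sm, p_sm = proportions_ztest([x1, x2], [n1, n2])
        assert res.z == pytest.approx(z_sm, rel=1e-10, abs=1e-12)
        if res.p > 1e-290:
            assert res.p == pytest.approx(p_sm, rel=1e-8, abs=1e-300)
        assert np.sign(res.z) == np.sign(res.p1 - res.p2)


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        two_proportion_z(5, 0, 1, 10)
    with pytest.raises(ValueError):
        two_proportion_z(11, 10, 1, 10)


# -------------------------------------------------- identity / relabel limits
def identity_setup(cmap: CategoryMap):
    """Mouse := copy of human under an identity chain."""
    blocks = [
        ChainBlock(c, 0, n, c, 0, "+", i + 1, 1e6)
        for i, (c, n) in enumerate(sorted(cmap.chrom_lengths.items()))
    ]
    index = AlignmentIndex.from_blocks(
        blocks, ref_sizes=cmap.chrom_lengths, qry_sizes=cmap.chrom_lengths,
        resolve_overlaps=False,
    )
    return index


def test_identity_fixture_gives_fraction_one_everywhere(small_maps):
    human_map, _, _ = small_maps
    index = identity_setup(human_map)
    table = annotation_conservation(human_map, human_map, index)
    present = table[table["denominator"] > 0]
    assert (present["fraction_aligned"] == 1.0).all()
    assert (present["fraction_common"] == 1.0).all()


def test_relabelled_promoters_lose_common_but_not_aligned(small_maps):
    human_map, _, _ = small_maps
    index = identity_setup(human_map)
    relabelled = CategoryMap(
        species="mouse",
        assembly=human_map.assembly,
        chrom_lengths=dict(human_map.chrom_lengths),
        maps={
            **{c: human_map[c] for c in CATEGORIES},
            "Promoter": human_map["EnhancerDistal"],
            "EnhancerDistal": human_map["Promoter"] | human_map["EnhancerDistal"],
        },
    )
    table = annotation_conservation(human_map, relabelled, index).set_index("category")
    assert table.loc["Promoter", "fraction_aligned"] == 1.0
    assert table.loc["Promoter", "fraction_common"] == 0.0
    assert table.loc["ExonCDS", "fraction_common"] == 1.0


def test_variant_identity_and_gap_cases(small_maps):
    human_map, _, _ = small_maps
    index = identity_setup(human_map)
    cds = human_map["ExonCDS"]
    chrom = cds.chroms[0]
    sites = [
        VariantSite(chrom, int(cds.array(chrom)[0, 0]) + k, "mendelian")
        for k in range(10)
    ]
    table, flagged = variant_conservation(sites, human_map, human_map, index)
    row = table.set_index(["source", "category"]).loc[("mendelian", "ExonCDS")]
    assert row["denominator"] == 10
    assert row["fraction_aligned"] == row["fraction_common"] == 1.0
    assert all(s.aligned and s.common for s in flagged)


def test_site_in_chain_gap_counts_unaligned(small_maps, small_bundle):
    human_map, mouse_map, index = small_maps
    gap_fate = next(f for f in small_bundle.fates if not f.aligned)
    site = VariantSite(gap_fate.chrom, gap_fate.start, "complex")
    _, flagged = variant_conservation([site], human_map, mouse_map, index)
    assert flagged[0].aligned is False and flagged[0].common is False


# ---------------------------------------------------------------- rows/pipes
def test_row_invariants_on_simulated_pair(small_maps):
    human_map, mouse_map, index = small_maps
    table = annotation_conservation(human_map, mouse_map, index)
    assert (table["n_common"] <= table["n_aligned"]).all()
    assert (table["n_aligned"] <= table["denominator"]).all()
    genome = table.set_index("category").loc["Genome"]
    per_cat_aligned = index.ref_mask.total_length
    assert genome["n_aligned"] == per_cat_aligned
    assert genome["denominator"] == human_map.genome_length


def test_genome_aligned_count_sums_over_chromosomes(small_maps):
    _, _, index = small_maps
    per_chrom = index.per_chrom_aligned_fractions()
    assert per_chrom["aligned_bp"].sum() == index.ref_mask.total_length


def test_comparing_a_row_with_itself_gives_z_zero(small_maps, small_bundle):
    human_map, mouse_map, index = small_maps
    ann = annotation_conservation(human_map, mouse_map, index)
    comp = background_comparisons(
        ann.assign(source="mendelian"),
        ann,
        [
            {
                "name": "self",
                "a": ("annotation", None, "Unannotated"),
                "b": ("annotation", None, "Unannotated"),
            }
        ],
    )
    assert comp.loc[0, "z"] == 0.0
    assert comp.loc[0, "p"] == pytest.approx(1.0)


def test_missing_comparison_row_raises_with_pair_name(small_maps):
    human_map, mouse_map, index = small_maps
    ann = annotation_conservation(human_map, mouse_map, index)
    with pytest.raises(KeyError, match="nonexistent_pair"):
        background_comparisons(
            pd.DataFrame(columns=["source", "category", "n_aligned", "denominator"]),
            ann,
            [{"name": "nonexistent_pair", "a": ("variant", "mendelian", "NonCoding"),
              "b": ("annotation", None, "NonCoding")}],
        )


def test_planted_enrichment_yields_positive_z(small_maps, small_bundle):
    """Sites drawn preferentially from aligned bases score z > 0 against
    the base-level background."""
    human_map, mouse_map, index = small_maps
    ann = annotation_conservation(human_map, mouse_map, index)
    rng = np.random.default_rng(5)
    fates = [f for f in small_bundle.fates if f.category == "Unannotated"]
    aligned = [f for f in fates if f.aligned]
    unaligned = [f for f in fates if not f.aligned]
    sites = {}
    for pool, n in ((aligned, 160), (unaligned, 40)):  # 80% from aligned bases
        for _ in range(n):
            f = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(f.start, f.end))
            sites[(f.chrom, pos)] = VariantSite(f.chrom, pos, "complex")
    var_table, _ = variant_conservation(list(sites.values()), human_map, mouse_map, index)
    comp = background_comparisons(
        var_table, ann,
        [c for c in DEFAULT_COMPARISONS if c["name"] == "complex_unannotated_vs_unannotated_bases"],
    )
    assert comp.loc[0, "z"] > 0
    assert comp.loc[0, "p"] < 1e-6


def test_noncoding_definition_flag_changes_the_aggregate(small_maps):
    human_map, mouse_map, index = small_maps
    cds_only = annotation_conservation(
        human_map, mouse_map, index, noncoding_definition="non-cds"
    ).set_index("category").loc["NonCoding"]
    non_exonic = annotation_conservation(
        human_map, mouse_map, index, noncoding_definition="non-exonic"
    ).set_index("category").loc["NonCoding"]
    assert non_exonic["denominator"] < cds_only["denominator"]
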