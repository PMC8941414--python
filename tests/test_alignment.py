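"""Chain parsing and coordinate projection, validated against a per-base
chain walker and exact round trips."""

from __future__ import annotations

import numpy as np
import pytest

from orthoannot.alignment import (
    UNALIGNED,
    AlignmentIndex,
    Chain,
    ChainBlock,
    read_chain,
    write_chain,
)
from orthoannot.intervals import IntervalSet

from oracles import walk_chain_file


def make_chain_file(path, text):
    path.write_text(text)
    return path


def test_single_plus_block(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 200 1 20000 + 500 600 1\n100\n\n",
    )
    index = read_chain(p)
    (block,) = index.blocks()
    assert (block.ref_start, block.ref_end) == (100, 200)
    assert (block.qry_start, block.qry_end) == (500, 600)
    assert index.map_position("1", 150) == ("1", 550)


def test_gap_triples_expand_to_two_blocks(tmp_path):
    # "50 10 0" then "50": second block starts 10 later on the reference
    # and immediately after the first on the query
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 210 1 20000 + 500 600 1\n50 10 0\n50\n\n",
    )
    blocks = read_chain(p).blocks()
    assert [(b.ref_start, b.ref_end, b.qry_start) for b in blocks] == [
        (100, 150, 500),
        (160, 210, 550),
    ]


def test_positions_in_chain_gaps_are_unaligned(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 210 1 20000 + 500 600 1\n50 10 0\n50\n\n",
    )
    index = read_chain(p)
    for pos in range(150, 160):
        assert index.map_position("1", pos) is UNALIGNED
    assert index.map_position("1", 99) is UNALIGNED


def test_unknown_chromosome_is_an_error_not_unaligned(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 200 1 20000 + 500 600 1\n100\n\n",
    )
    with pytest.raises(KeyError):
        read_chain(p).map_position("7", 50)


def test_identity_chain_maps_every_base_to_itself(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 99 1 5000 + 0 5000 1 5000 + 0 5000 1\n5000\n\n",
    )
    index = read_chain(p)
    for pos in (0, 1, 2499, 4999):
        assert index.map_position("1", pos) == ("1", pos)


def test_inconsistent_chain_body_is_rejected_with_id(tmp_path):
    p = make_chain_file(
        tmp_path / "bad.chain",
        "chain 1000 1 10000 + 100 300 1 20000 + 500 600 7\n50 10 0\n50\n\n",
    )
    with pytest.raises(ValueError, match="chain 7"):
        read_chain(p)


def test_minus_strand_chain_matches_per_base_walker(tmp_path):
    p = make_chain_file(
        tmp_path / "m.chain",
        "chain 500 1 10000 + 100 260 1 20000 - 19000 19150 3\n40 20 10\n100\n\n",
    )
    index = read_chain(p)
    oracle = walk_chain_file(p)
    for pos in range(90, 270):
        got = index.map_position("1", pos)
        want = oracle.get(("1", pos))
        assert (None if got is UNALIGNED else got) == want
    # strictly decreasing mouse forward coordinate within the chain
    images = [index.map_position("1", pos) for pos in range(100, 140)]
    coords = [q for _, q in images]
    assert all(a > b for a, b in zip(coords, coords[1:]))


def test_round_trip_on_both_strands(fixture_dir):
    index = read_chain(fixture_dir / "human_mouse.chain")
    strands = set()
    for block in index.blocks():
        strands.add(block.qry_strand)
        for pos in range(block.ref_start, block.ref_end):
            qc, qp = index.map_position(block.ref_chrom, pos)
            assert index.reverse_map_position(qc, qp) == (block.ref_chrom, pos)
    assert strands == {"+", "-"}  # the fixture exercises both


def test_block_lengths_conserved_and_sum_to_chain_sizes(fixture_dir):
    path = fixture_dir / "human_mouse.chain"
    index = read_chain(path)
    # each chain's body "size" fields must sum to its blocks' ref lengths
    sizes_in_body = 0
    for line in path.read_text().splitlines():
        parts = line.split()
        if parts and not line.startswith("chain"):
            sizes_in_body += int(parts[0])
    assert sizes_in_body == index.ref_mask.total_length


def test_map_interval_spanning_a_gap(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 210 1 20000 + 500 600 1\n50 10 0\n50\n\n",
    )
    index = read_chain(p)
    segments = index.map_interval("1", 120, 200)
    assert [(s[0], s[1]) for s in segments] == [(120, 150), (160, 200)]
    mapped = sum(s[1] - s[0] for s in segments)
    assert mapped == 70 < 80
    assert index.map_interval("1", 0, 50) == []


def test_aligned_mask_fraction_limits(tmp_path):
    p = make_chain_file(
        tmp_path / "a.chain",
        "chain 1000 1 10000 + 100 200 1 20000 + 500 600 1\n100\n\n",
    )
    index = read_chain(p)
    inside = IntervalSet.from_pairs({"1": [(110, 160)]})
    outside = IntervalSet.from_pairs({"1": [(300, 400)]})
    assert index.aligned_mask(inside) == inside
    assert index.aligned_fraction(inside) == 1.0
    assert not index.aligned_mask(outside)
    assert index.aligned_fraction(outside) == 0.0


def test_aligned_mask_matches_walker_on_fixture(fixture_dir, small_bundle):
    index = read_chain(fixture_dir / "human_mouse.chain")
    oracle = walk_chain_file(fixture_dir / "human_mouse.chain")
    rng = np.random.default_rng(7)
    for chrom, length in small_bundle.chrom_lengths.items():
        starts = rng.integers(0, length - 500, size=25)
        for s in starts:
            s = int(s)
            span = IntervalSet.from_pairs({chrom: [(s, s + 500)]})
            got = index.aligned_mask(span).total_length
            want = sum(1 for p in range(s, s + 500) if (chrom, p) in oracle)
            assert got == want


def test_genome_wide_fraction_is_length_weighted_chromosome_mean(fixture_dir, small_bundle):
    index = read_chain(fixture_dir / "human_mouse.chain")
    per = index.per_chrom_aligned_fractions()
    total_len = per["length"].sum()
    weighted = (per["fraction_aligned"] * per["length"]).sum() / total_len
    genome = index.ref_mask.total_length / total_len
    assert genome == pytest.approx(weighted, abs=0, rel=1e-12)


def test_overlapping_chains_resolve_by_score(tmp_path):
    # the low-score chain claims 100-300, the high-score chain 200-400:
    # the winner keeps its block, the loser is truncated to 100-200
    p = make_chain_file(
        tmp_path / "o.chain",
        "chain 100 1 10000 + 100 300 1 20000 + 1000 1200 1\n200\n\n"
        "chain 900 1 10000 + 200 400 1 20000 + 5000 5200 2\n200\n\n",
    )
    index = read_chain(p)
    assert index.map_position("1", 250) == ("1", 5050)
    assert index.map_position("1", 150) == ("1", 1050)
    mask = index.ref_mask.array("1")
    assert mask.tolist() == [[100, 400]]


def test_unresolved_overlap_is_hard_error():
    blocks = [
        ChainBlock("1", 0, 100, "1", 0, "+", 1, 10.0),
        ChainBlock("1", 50, 150, "1", 500, "+", 2, 10.0),
    ]
    with pytest.raises(ValueError, match="overlapping"):
        AlignmentIndex.from_blocks(blocks, resolve_overlaps=False)


def test_chain_writer_reader_round_trip(tmp_path):
    chains = [
        Chain(1000.0, "1", 10_000, "1", 20_000, "+", 1, [(100, 500, 50), (170, 580, 30)]),
        Chain(800.0, "1", 10_000, "2", 15_000, "-", 2, [(1000, 9000, 40), (1100, 8900, 60)]),
    ]
    path = tmp_path / "rt.chain"
    write_chain(chains, path)
    index = read_chain(path)
    got = {
        (b.ref_start, b.ref_end, b.qry_chrom, b.qry_start, b.qry_strand)
        for b in index.blocks()
    }
    assert got == {
        (100, 150, "1", 500, "+"),
        (170, 200, "1", 580, "+"),
        (1000, 1040, "2", 9000, "-"),
        (1100, 1160, "2", 8900, "-"),
    }
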