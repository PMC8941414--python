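from __future__ import annotations

import pytest

from orthoannot.simulate import DEFAULT_VARIANT_COUNTS, SimConfig, simulate_genome_pair, write_fixtures


def small_sim_config(seed: int, **overrides) -> SimConfig:
    """A fixture pair small enough for per-base brute-force comparison."""
    kwargs = dict(
        seed=seed,
        chrom_lengths=(30_000, 30_000),
        tad_flank=200,
        margin=150,
        variant_counts={k: max(1, v // 10) for k, v in DEFAULT_VARIANT_COUNTS.items()},
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_genome_pair(small_sim_config(seed=42))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_bundle):
    d = tmp_path_factory.mktemp("fixtures") / "pair"
    write_fixtures(small_bundle, d)
    return d


@pytest.fixture(scope="session")
def small_maps(small_bundle):
    return (
        small_bundle.human_category_map(),
        small_bundle.mouse_category_map(),
        small_bundle.alignment_index(),
    )
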