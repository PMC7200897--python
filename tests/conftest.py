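import numpy as np
import pytest

from exofold import GenomeLayout, SimConfig, simulate_signal, toy_layout


@pytest.fixture
def layout():
    """Two 200-kb chromosomes."""
    return toy_layout()


@pytest.fixture
def mini_layout():
    """One 10-kb chromosome for brute-force oracles."""
    return GenomeLayout({"chr1": 10_000})


@pytest.fixture
def clean_sim(layout):
    """A noiseless, jitterless simulation: every read 5' sits exactly on
    a planted border."""
    config = SimConfig(
        layout=layout,
        site_positions=[("chr1", 50_000), ("chr2", 120_000)],
        footprint_bp=19,
        reads_per_site=40,
        border_jitter_sd=0.0,
        background_fraction=0.0,
        seed=1,
    )
    return config, simulate_signal(config)


def random_pairs(rng, layout, n, max_mapq=60):
    """Random AlignedReadPairs, deliberately with key collisions."""
    from exofold import AlignedReadPair

    chroms = layout.chroms
    pairs = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        pairs.append(
            AlignedReadPair(
                name=f"r{i}",
                chrom=chrom,
                r1_strand="+" if rng.integers(2) else "-",
                r1_five_prime=int(rng.integers(100, 200)),  # narrow: collisions
                r2_five_prime=int(rng.integers(100, 210)),
                mapq=int(rng.integers(0, max_mapq)),
            )
        )
    return pairs
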