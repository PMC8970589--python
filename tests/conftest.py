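import numpy as np
import pandas as pd
import pytest

from nmpseq_tfprint import LesionTrack, SimConfig, simulate_experiment


@pytest.fixture
def tiny_genome():
    return {"chrT": "ACGTACGTGGATCCAA"}


@pytest.fixture
def small_config():
    return SimConfig(
        genome_length=30_000,
        n_sites=40,
        depth=80_000,
        min_gap=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic experiment shared across read-only tests."""
    config = SimConfig(genome_length=60_000, n_sites=60, depth=200_000, seed=7)
    return simulate_experiment(config)


def make_track(genome, entries, mode="nmp"):
    """LesionTrack from (chrom, pos, strand, count) tuples."""
    track = LesionTrack(genome, mode=mode)
    for chrom, pos, strand, count in entries:
        track.counts[chrom][0 if strand == "+" else 1, pos] += count
    return track


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "five_prime_pos", "strand"])
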