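import numpy as np
import pytest

from tfscribe import synthetic
from tfscribe.chip import CoverageTrack, TSSRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_truth():
    """A fast-to-generate truth with every feature planted."""
    return synthetic.SyntheticTruth(
        n_genes=200,
        n_tfs=6,
        conditions=("condA", "condB"),
        active_tfs=(0, 2),
        coefficients={0: 1.0, 2: 0.5},
        knots={0: 8.0},
        collinear_pairs=((2, 3, 0.9),),
        interaction_pair=(0, 2, 0.02),
        noise_sd=10.0,
        seed=11,
    )


@pytest.fixture
def small_bundle(small_truth):
    return synthetic.generate_bundle(small_truth)


@pytest.fixture
def flat_track():
    return CoverageTrack({"chr1": np.ones(5000)})


def random_track(rng, length=2000, n_chroms=1):
    return CoverageTrack(
        {f"chr{c}": rng.integers(0, 5, size=length).astype(float) for c in range(n_chroms)}
    )


def brute_force_promoter_sum(track, rec: TSSRecord, upstream: int, downstream: int,
                             mirror: bool = True) -> float:
    """Independent base-by-base oracle for windowed coverage sums."""
    vec = track.coverage[rec.chrom]
    total = 0.0
    for pos in range(1, len(vec) + 1):
        if rec.strand == "+" or not mirror:
            inside = rec.tss - upstream <= pos <= rec.tss + downstream
        else:
            inside = rec.tss - downstream <= pos <= rec.tss + upstream
        if inside:
            total += vec[pos - 1]
    return total
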