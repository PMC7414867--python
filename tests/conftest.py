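import numpy as np
import pytest

from hrdscar.cn_io import Segment, SegmentProfile
from hrdscar.genome_ref import GenomeBuild, load_build

MB = 1_000_000


@pytest.fixture(scope="session")
def grch37():
    return load_build("GRCh37")


@pytest.fixture(scope="session")
def toy_build():
    """Three autosome-like chromosomes, small enough for brute force."""
    return GenomeBuild(
        name="toy",
        lengths={"1": 200 * MB, "2": 150 * MB, "3": 120 * MB},
        centromeres={
            "1": (90 * MB, 95 * MB),
            "2": (60 * MB, 64 * MB),
            "3": (50 * MB, 53 * MB),
        },
    )


@pytest.fixture(scope="session")
def tiny_build():
    """A single 100 bp chromosome for exhaustive per-position checks."""
    return GenomeBuild(
        name="tiny", lengths={"1": 100}, centromeres={"1": (41, 60)}
    )


def make_profile(rows, sample_id="S1", purity=1.0, ploidy=2.0):
    """Profile from (chrom, start, end, n_major, n_minor) tuples."""
    return SegmentProfile(
        sample_id=sample_id,
        segments=[Segment(str(c), s, e, ma, mi) for c, s, e, ma, mi in rows],
        purity=purity,
        ploidy=ploidy,
    )


STATES = [(1, 1), (1, 1), (1, 1), (2, 1), (1, 0), (2, 2), (2, 0), (3, 1), (0, 0)]


def random_profile(rng, build, max_segments=12, gap_prob=0.15, sample_id="R"):
    """Random valid profile on ``build``: random breakpoints, states, gaps.

    Weighted toward the diploid heterozygous state, with occasional
    whole-chromosome single segments and occasional dropped segments
    (coverage gaps), to exercise every scoring code path.
    """
    segments = []
    for chrom, length in build.lengths.items():
        n = int(rng.integers(1, max_segments + 1))
        if n == 1 and rng.random() < 0.5:
            ma, mi = STATES[int(rng.integers(len(STATES)))]
            segments.append(Segment(chrom, 1, length, ma, mi))
            continue
        cuts = np.unique(rng.integers(2, length, size=n - 1))
        bounds = [1, *cuts.tolist(), length + 1]
        for lo, hi in zip(bounds, bounds[1:]):
            if rng.random() < gap_prob:
                continue
            ma, mi = STATES[int(rng.integers(len(STATES)))]
            segments.append(Segment(chrom, int(lo), int(hi) - 1, ma, mi))
    return SegmentProfile(sample_id=sample_id, segments=segments)
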