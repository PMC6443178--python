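import numpy as np
import pytest

from hervscan.model import GenomicInterval, HervElement, SnvRecord, Supergroup

NUC = "ACGT"


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def random_snvs(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, labels=(None,)):
    out = []
    for _ in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        out.append(
            SnvRecord(
                chrom=str(rng.choice(chroms)),
                pos=int(rng.integers(1, max_pos + 1)),
                ref_allele=NUC[ref],
                alt_allele=NUC[alt],
                cancer_label=rng.choice(labels),
            )
        )
    return out


def random_elements(rng, n, **kwargs):
    return [
        HervElement(
            element_id=f"R{i:04d}",
            interval=iv,
            group="HERV-H/LTR7",
            supergroup=Supergroup.GE,
            canonical=bool(i % 2),
        )
        for i, iv in enumerate(random_intervals(rng, n, **kwargs))
    ]


def brute_force_point_hits(intervals, chrom, pos0):
    """Linear-scan oracle for interval stabbing (normalized chrom names)."""
    from hervscan.intervals import normalize_chrom

    hits = [
        i
        for i, iv in enumerate(intervals)
        if normalize_chrom(iv.chrom) == normalize_chrom(chrom) and iv.start <= pos0 < iv.end
    ]
    hits.sort(key=lambda i: (intervals[i].start, i))
    return hits


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
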