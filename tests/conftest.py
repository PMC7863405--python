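import numpy as np
import pandas as pd
import pytest

from spikewin.genomic_io import ChromSizes, GenomicInterval


@pytest.fixture
def small_sizes() -> ChromSizes:
    return ChromSizes(
        sizes={"chr1": 10_000, "chr2": 5_000, "lambda": 48_502, "phiX": 5_386},
        spike_contigs=frozenset({"lambda", "phiX"}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_fragments(
    rng: np.random.Generator, chrom: str, length: int, n: int, max_len: int = 400
) -> pd.DataFrame:
    starts = rng.integers(0, length - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lens, length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def brute_force_counts(
    frags: pd.DataFrame, windows: list[GenomicInterval], max_fragment: int
) -> np.ndarray:
    """Quadratic oracle: a fragment adds 1 to every window it overlaps."""
    out = np.zeros(len(windows), dtype=np.int64)
    for _, row in frags.iterrows():
        if row.end - row.start > max_fragment:
            continue
        for i, w in enumerate(windows):
            if w.chrom == row.chrom and row.start < w.end and w.start < row.end:
                out[i] += 1
    return out
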