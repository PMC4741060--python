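import numpy as np
import pytest

from gjoin.sim import worked_example_fixtures
from gjoin.tables import GenomicTable, IntervalKey, Schema


@pytest.fixture(scope="session")
def fixtures():
    """The two-gene/three-read tables and the five-interval tree example."""
    return worked_example_fixtures()


def random_table(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2", "chrX"),
    max_pos: int = 10_000,
    max_len: int = 500,
    name: str = "t",
) -> GenomicTable:
    """A random interval table for join/property tests."""
    schema = Schema(
        columns=[("chrom", "string"), ("start", "integer"), ("end", "integer"),
                 ("label", "string")],
        interval_key=IntervalKey("chrom", "start", "end"),
    )
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, max_pos))
        end = start + int(rng.integers(0, max_len))
        rows.append((chrom, start, end, f"{name}{i}"))
    return GenomicTable(name=name, schema=schema, rows=rows)
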