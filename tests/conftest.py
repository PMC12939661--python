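import numpy as np
import pytest

from crossmex import generate_benchmark, preset_domains
from crossmex.manifests import BENCHMARK_COUNTS, LABELS, SampleRecord


@pytest.fixture(scope="session")
def toy_bench_dir(tmp_path_factory):
    """Two-domain toy benchmark written to disk (images + flow + tables)."""
    out = tmp_path_factory.mktemp("toy_bench")
    bench = generate_benchmark(preset_domains("toy2"), out_dir=out, seed=11, size=48)
    return out, bench


@pytest.fixture(scope="session")
def desk_bench():
    """Five-domain desk benchmark kept in memory (300 samples, 64x64)."""
    return generate_benchmark(preset_domains("desk"), seed=7, size=64,
                              return_arrays=True)


@pytest.fixture(scope="session")
def table1_records():
    """A manifest shaped like the five public benchmarks' count matrix."""
    records = []
    for d, row in zip(BENCHMARK_COUNTS.datasets, BENCHMARK_COUNTS.counts):
        for cat, n in zip(LABELS, row):
            for j in range(n):
                records.append(SampleRecord(
                    sample_id=f"{d}_{cat}_{j}", source_dataset=d, label=cat,
                    au=np.zeros(17), split="train"))
    return records
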