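import numpy as np
import pytest

from lfe.benchmark import BenchmarkConfig, run_benchmark
from lfe.countmap import CountMapConfig, make_count_map


@pytest.fixture()
def toy_delta():
    """5×5 location map with a single centered impulse and its 3×3 count map."""
    loc = np.zeros((5, 5))
    loc[2, 2] = 1.0
    cfg = CountMapConfig(3)
    return loc, make_count_map(loc, cfg), cfg


@pytest.fixture(scope="session")
def full_benchmark_result():
    """One full run of the packaged synthetic benchmark (48 train / 16 test,
    96×96, ~15 disks, 1 label per image, r=7, prior 0.1)."""
    return run_benchmark(seed=7)


@pytest.fixture(scope="session")
def small_benchmark_results():
    """Five seeds of the shrunken benchmark, for multi-seed stage-2 properties."""
    cfg = BenchmarkConfig.small()
    return [run_benchmark(seed=s, cfg=cfg) for s in range(5)]
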