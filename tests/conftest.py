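import warnings

import numpy as np
import pytest

from macroperm.chemdata import Label
from macroperm.macro_pp import _BundleCache
from macroperm.synthetic import SyntheticSpec, make_benchmark

warnings.filterwarnings("ignore", category=DeprecationWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="macroperm.featurize")


@pytest.fixture(scope="session")
def bundle_cache():
    """Shared featurization cache so molecules are featurized once per run."""
    return _BundleCache()


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small synthetic benchmark: ~240 multi-assay records + 100 PAMPA records."""
    spec = SyntheticSpec(n_large=120, n_task=100, seed=7)
    large, task, truth = make_benchmark(spec)
    return spec, large, task, truth


@pytest.fixture(scope="session")
def tiny_task_split(tiny_benchmark):
    """Kept (non-excluded) task records split deterministically into train/val."""
    _, _, task, _ = tiny_benchmark
    kept = [lr for lr in task if lr.label is not Label.EXCLUDED]
    rng = np.random.default_rng(0)
    order = rng.permutation(len(kept))
    n_val = len(kept) // 4
    val = [kept[i] for i in order[:n_val]]
    train = [kept[i] for i in order[n_val:]]
    return train, val
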