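import numpy as np
import pytest

from vesseltrace.local_segmentation import OracleSegmenter
from vesseltrace.phantom import make_standard_suite
from vesseltrace.tracer import Seed, TracerConfig, run_trace


@pytest.fixture(scope="session")
def suite():
    """The five reference phantoms, rendered once per session."""
    return {c.name: c for c in make_standard_suite()}


@pytest.fixture(scope="session")
def oracle_seg():
    return OracleSegmenter(threshold=0.5, smooth_sigma=0.5)


def _trace(case, seg, **cfg_kwargs):
    pt, d, r = case.seed_hint
    return run_trace(case.image, Seed(pt, d, r), seg, TracerConfig(**cfg_kwargs))


@pytest.fixture(scope="session")
def straight_trace(suite, oracle_seg):
    return _trace(suite["straight"], oracle_seg)


@pytest.fixture(scope="session")
def y_trace(suite, oracle_seg):
    return _trace(suite["y_bifurcation"], oracle_seg)


@pytest.fixture(scope="session")
def taper_trace(suite, oracle_seg):
    return _trace(suite["taper"], oracle_seg)


def step_log_plain(result):
    """Step log with arrays converted so logs can be compared for equality."""
    return [
        {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in e.items()}
        for e in result.step_log
    ]
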