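import numpy as np
import pytest

import vibhole as vh
from vibhole.pipeline import run_dd_vpt2, run_standard_vpt2


@pytest.fixture(scope="session")
def fixtures():
    """Session cache of built model systems."""
    cache = {}

    def get(name, params=None, seed=0):
        key = (name, tuple(sorted((params or {}).items())), seed)
        if key not in cache:
            cache[key] = vh.make_fixture(name, params, seed=seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def vpt2_runs(fixtures):
    """Session cache of standard-VPT2 pipeline runs on fixtures."""
    cache = {}

    def get(name, params=None, **kw):
        key = (name, tuple(sorted((params or {}).items())), tuple(sorted(kw.items())))
        if key not in cache:
            fix = fixtures(name, params)
            cache[key] = run_standard_vpt2(
                fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma, **kw
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def dd_runs(fixtures):
    """Session cache of DD-VPT2 pipeline runs on fixtures."""
    cache = {}

    def get(name, params=None, cutoff=0.0, **kw):
        key = (name, tuple(sorted((params or {}).items())), cutoff, tuple(sorted(kw.items())))
        if key not in cache:
            fix = fixtures(name, params)
            cache[key] = run_dd_vpt2(
                fix.system,
                fix.iso_light,
                fix.iso_heavy,
                fix.pes.hessian,
                fix.sigma,
                cutoff=cutoff,
                **kw,
            )
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
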