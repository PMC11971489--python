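"""Shared fixtures: schedules and dictionaries reused across the suite.

Full-resolution dictionaries (1001 entries, 101 isochromats) take ~20 s each
to simulate, so they are built once per session and shared; cheap unit tests
use coarse grids and few isochromats instead.
"""

import numpy as np
import pytest

from hpmrf.dictionary import DictionarySpec, generate_dictionary
from hpmrf.params import BolusParams, FieldConditions, KineticParams
from hpmrf.sequences import build_schedule


@pytest.fixture(scope="session")
def full_dict():
    """Factory returning the nominal full-resolution dictionary per design."""
    cache = {}

    def get(design_id: str):
        if design_id not in cache:
            cache[design_id] = generate_dictionary(
                DictionarySpec(schedule=build_schedule(design_id))
            )
        return cache[design_id]

    return get


@pytest.fixture(scope="session")
def coarse_dict():
    """MRF-Sigmoid dictionary on a 101-point grid (step 1e-3) — fast."""
    return generate_dictionary(
        DictionarySpec(schedule=build_schedule("mrf_sigmoid"), kpl_res=1e-3)
    )


@pytest.fixture(scope="session")
def coarse_dict_factory():
    """Per-design coarse dictionaries (step 1e-3)."""
    cache = {}

    def get(design_id: str):
        if design_id not in cache:
            cache[design_id] = generate_dictionary(
                DictionarySpec(schedule=build_schedule(design_id), kpl_res=1e-3)
            )
        return cache[design_id]

    return get


@pytest.fixture
def small_cond():
    """Few-isochromat field conditions for cheap single-fingerprint tests."""
    return FieldConditions(n_isochromats=5)


@pytest.fixture
def no_bolus():
    """Bolus with zero amplitude (for closed-form relaxation/exchange tests)."""
    return BolusParams(total_input=0.0)


@pytest.fixture
def short_schedule():
    """A reduced MRF-Constant schedule for fast end-to-end simulations."""
    return build_schedule("mrf_constant", total_duration=16.4, n_exc=32, n_cat=4)
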