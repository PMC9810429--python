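"""Shared fixtures: material cards, mean plants, and cached sweep results.

The limiting-speed sweeps are the most expensive computations in the suite;
they are session-scoped so the failure-criterion, localization and ordering
tests all share one sweep per crop.
"""

from __future__ import annotations

import numpy as np
import pytest

from lodgesim import micromech as mm
from lodgesim import stemfe as fe
from lodgesim.morphotypes import (
    OAT_TEMPLATE,
    WHEAT_TEMPLATE,
    generate_morphology,
)
from lodgesim.windload import WindCase, build_loadset

TEMPLATES = {"oat": OAT_TEMPLATE, "wheat": WHEAT_TEMPLATE}


@pytest.fixture(scope="session")
def cards():
    """Material cards for both crops from the homogenization cascade."""
    return {crop: mm.build_crop_cards(crop) for crop in ("oat", "wheat")}


@pytest.fixture(scope="session")
def mean_plants():
    """Template-mean (zero-variance) plant of each crop."""
    return {
        crop: generate_morphology(tpl.replace(cv=0.0), 1, 0)[0]
        for crop, tpl in TEMPLATES.items()
    }


@pytest.fixture(scope="session")
def sweeps(cards, mean_plants):
    """Limiting-wind-speed sweeps for both crops at the 0.5 m/s grid."""
    out = {}
    for crop in ("oat", "wheat"):
        pith, shell = cards[crop]
        out[crop] = fe.limiting_wind_speed(
            mean_plants[crop], pith, shell, threshold=0.3, grid=0.5, v_max=16.0
        )
    return out


@pytest.fixture(scope="session")
def limit_results(cards, mean_plants, sweeps):
    """Full load/unload simulation of each crop at its limiting speed."""
    out = {}
    for crop in ("oat", "wheat"):
        pith, shell = cards[crop]
        v = sweeps[crop].v_limit_m_s
        case = WindCase.from_m_s(v)
        model = fe.build_stem_model(
            mean_plants[crop], pith, shell, loadset=build_loadset(mean_plants[crop], case)
        )
        out[crop] = fe.simulate_load_unload(model, case)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
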