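"""Shared fixtures: small seeded cohorts run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ebiflow import preset_config
from ebiflow.pipeline import run_cohort

SINGLET_CLASSES = {"singlet_erythroblast", "singlet_myeloid",
                   "singlet_macrophage"}


def collapse_truth(true_class: str) -> str:
    """Truth labels use three singlet kinds; the classifier calls 'singlet'."""
    return "singlet" if true_class in SINGLET_CLASSES else true_class


@pytest.fixture(scope="session")
def bm_run():
    """Full pipeline over a 160-object mouse bone-marrow cohort (seeded)."""
    return run_cohort(preset_config("BM", n_objects=160, seed=5))


@pytest.fixture(scope="session")
def bm_merged(bm_run):
    """Calls joined 1:1 with truth on object_id."""
    m = bm_run["calls"].merge(bm_run["truth"], on="object_id",
                              suffixes=("", "_true"))
    m["truth_call"] = m["true_class"].map(collapse_truth)
    return m


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
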