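"""Shared fixtures: packaged compound set and a small simulated screen."""

from __future__ import annotations

import pandas as pd
import pytest

from stressdyn.annotation import load_packaged_annotations
from stressdyn.descriptors import compute_cytotox_summary, compute_descriptor_table
from stressdyn.simulate import EffectConfig, LayoutConfig, draw_screen_params, simulate_screen


@pytest.fixture(scope="session")
def annotations():
    return load_packaged_annotations()


@pytest.fixture(scope="session")
def drug_annotations(annotations):
    return [a for a in annotations if not a.is_control]


@pytest.fixture(scope="session")
def small_screen(drug_annotations):
    """A reduced screen (8 compounds, 2 replicates, 40 cells/well) with its
    latent truth, reused across tests that only need realistic structure."""
    anns = drug_annotations[:8]
    effect = EffectConfig()
    layout = LayoutConfig(n_replicates=2, n_cells_0=40, n_control_wells=2)
    cells, truth = simulate_screen(anns, effect, layout, rng_seed=3)
    params = draw_screen_params(anns, effect, 3)
    return {
        "annotations": anns,
        "effect": effect,
        "layout": layout,
        "cells": cells,
        "truth": truth,
        "params": params,
        "seed": 3,
    }


@pytest.fixture(scope="session")
def small_descriptors(small_screen) -> pd.DataFrame:
    return compute_descriptor_table(small_screen["cells"])


@pytest.fixture(scope="session")
def small_cytotox(small_screen) -> pd.DataFrame:
    return compute_cytotox_summary(small_screen["cells"])
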