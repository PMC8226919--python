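"""Shared fixtures: noise-free phantom cells and the study's printed cell means."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import kneestress as ks
from kneestress.phantom import ConditionEffect

# Published per-cell means of the fifteen measures (mm / deg) in cell order
# (intact d0, intact d1, partial d0, partial d1, complete d0, complete d1).
# They serve as *input data* for the delta-referencing stage.
PUBLISHED_CELL_MEANS: dict[str, list[float]] = {
    "length_ABI": [36.4, 37.2, 37.2, 43.1, 39.6, 41.8],
    "x_ABI": [-2.3, -1.8, -3.5, -5.4, -5.0, -2.0],
    "y_ABI": [-5.0, -3.0, -3.3, 3.1, -2.6, 7.6],
    "z_ABI": [34.0, 36.5, 36.5, 41.4, 37.3, 40.2],
    "length_landmarks": [110.9, 113.2, 109.7, 116.3, 112.4, 118.0],
    "x_landmarks": [7.3, 7.5, 5.2, 5.4, 7.3, 5.0],
    "y_landmarks": [32.5, 35.8, 39.5, 43.9, 40.5, 47.3],
    "z_landmarks": [105.5, 106.4, 102.0, 106.9, 103.9, 107.3],
    "xz_angle": [143.6, 140.7, 138.0, 130.8, 137.0, 117.5],
    "yz_angle": [109.5, 103.3, 108.8, 98.0, 101.5, 101.2],
    "xy_angle": [34.9, 29.5, 39.0, 25.5, 28.7, 26.2],
    "LMD": [4.1, 0.9, 4.0, 0.1, 2.7, -0.2],
    "LTP_LFC": [-3.0, -6.0, -4.0, -9.9, -5.4, -10.8],
    "MMD": [3.7, 1.8, 3.1, 0.3, 1.8, -0.3],
    "MTP_MFC": [1.2, -0.7, 0.3, -2.4, -1.4, -4.6],
}

CELL_ORDER = [("intact", "d0"), ("intact", "d1"), ("partial", "d0"),
              ("partial", "d1"), ("complete", "d0"), ("complete", "d1")]


@pytest.fixture(scope="session")
def published_means_table() -> pd.DataFrame:
    """The printed cell means as a one-specimen long-format study table."""
    rows = []
    for measure, values in PUBLISHED_CELL_MEANS.items():
        for (condition, configuration), value in zip(CELL_ORDER, values):
            rows.append({"specimen": "cohort_mean", "condition": condition,
                         "configuration": configuration, "measure": measure,
                         "value": value})
    return pd.DataFrame(rows)


def exact_effects(translation: dict[str, float] | None = None,
                  rotation: dict[str, float] | None = None) -> dict[str, ConditionEffect]:
    """Zero-SD condition effects with the given per-condition means."""
    translation = translation or {"intact": 0.0, "partial": 8.1, "complete": 12.6}
    rotation = rotation or {"intact": 0.0, "partial": 0.0, "complete": 0.0}
    return {c: ConditionEffect(translation[c], 0.0, rotation[c], 0.0)
            for c in ("intact", "partial", "complete")}


@pytest.fixture(scope="session")
def noise_free_spec() -> ks.PhantomSpec:
    return ks.PhantomSpec(n_specimens=1, seed=7, noise_sd_mm=0.0,
                          condition_effects=exact_effects())


@pytest.fixture(scope="session")
def intact_cell(noise_free_spec):
    """(volume, annotations, ground truth) of a noise-free intact unloaded cell."""
    return ks.synthesize_cell(noise_free_spec, 0, "intact", "d0")


@pytest.fixture(scope="session")
def cylinder_pair_volume():
    """A vertical 10 mm cylinder 'femur' above a small 'tibia' block, 1 mm voxels.

    The cylinder is capped at z = 50 mm; the block below defines the joint
    side for axis orientation.
    """
    from kneestress.phantom import Cylinder, rasterize

    femur = Cylinder(name="shaft", center=np.array([30.0, 30.0, 75.0]),
                     R=np.eye(3), radius=10.0, half_length=25.0)
    tibia = Cylinder(name="block", center=np.array([30.0, 30.0, 20.0]),
                     R=np.eye(3), radius=12.0, half_length=10.0)
    return rasterize([(femur, 1), (tibia, 2)], (1.0, 1.0, 1.0), (61, 61, 110))
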