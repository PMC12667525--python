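"""Shared fixtures: compact simulated organoids and screens.

Reduced image sizes keep the suite fast; noise parameters stay at the
simulator defaults wherever a test makes a claim about "default noise".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibroscreen.features import FEATURE_NAMES, FeatureMatrix
from fibroscreen.imaging import SegmentationParams
from fibroscreen.synthetic import OrganoidSpec, ScreenDesign, Treatment, simulate_organoid


# compact acquisition used where the claim under test does not depend on
# field size: same noise model, smaller frame
SMALL_SHAPE = (6, 160, 160)


def small_spec(**overrides) -> OrganoidSpec:
    base = dict(
        image_shape=SMALL_SHAPE,
        organoid_radius_px=55.0,
        n_nuclei_mean=40.0,
        filaments_per_effect=8.0,
        blobs_per_effect=3.0,
    )
    base.update(overrides)
    return OrganoidSpec(**base)


@pytest.fixture(scope="session")
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def rendered_organoid():
    """One full-size organoid at default settings, with its ground truth."""
    return simulate_organoid(OrganoidSpec(seed=20))


@pytest.fixture()
def two_phenotype_design() -> ScreenDesign:
    """Screen with an untreated-like and a strongly fibrotic group."""
    return ScreenDesign(
        treatments=[
            Treatment("NC", fibrosis_effect=0.3),
            Treatment("TGFB", fibrosis_effect=2.5),
        ],
        days=[21],
        n_batches=2,
        organoids_per_batch_per_treatment=6,
        base_spec=small_spec(),
        seed=5,
    )


def feature_matrix_from_arrays(
    values: np.ndarray,
    treatments: list[str],
    feature_names: list[str] | None = None,
    days: list[int] | None = None,
    batches: list[str] | None = None,
    scaled: bool = False,
) -> FeatureMatrix:
    """Wrap a plain array as a FeatureMatrix for profiling-level tests."""
    n = values.shape[0]
    names = feature_names or [f"f{i}" for i in range(values.shape[1])]
    index = pd.Index([f"org{i}" for i in range(n)], name="organoid_id")
    return FeatureMatrix(
        values=pd.DataFrame(values, index=index, columns=names),
        labels=pd.DataFrame(
            {
                "treatment": treatments,
                "day": days or [21] * n,
                "batch": batches or ["B1"] * n,
            },
            index=index,
        ),
        scaled=scaled,
    )


def full_feature_row(rng: np.random.Generator) -> dict[str, float]:
    """A random but valid 18-feature value dict."""
    return {name: float(rng.uniform(0.0, 10.0)) for name in FEATURE_NAMES}
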