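import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from larkscape.io import Landscape
from larkscape.synth import HabitatDynamics, SimulationTruth, generate_dataset
from larkscape.types import HabitatPatch


def small_truth(seed: int = 7, **overrides) -> SimulationTruth:
    """A fast, reduced-size study configuration for unit tests."""
    kw = dict(
        rng_seed=seed,
        landscape_size_m=1500.0,
        n_nests=10,
        n_nests_surveyed=10,
        flight_radius_m=350.0,
        flight_grid_m=10.0,
        mean_observation_days=4.0,
    )
    kw.update(overrides)
    return SimulationTruth(**kw)


def uniform_weights() -> dict:
    """Habitat attractiveness identical everywhere: distance-only behavior."""
    return {}


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_truth())


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default study (shared across modules; read-only)."""
    return generate_dataset(SimulationTruth(rng_seed=1))


def single_patch_landscape(size: float = 5000.0, habitat: str = "winter_wheat") -> Landscape:
    return Landscape(
        [HabitatPatch("big", habitat, 2018, box(-size, -size, size, size))]
    )


def half_plane_landscape(split_x: float = 0.0, size: float = 5000.0) -> Landscape:
    return Landscape(
        [
            HabitatPatch("west", "winter_wheat", 2018, box(-size, -size, split_x, size)),
            HabitatPatch("east", "sugar_beet", 2018, box(split_x, -size, size, size)),
        ]
    )


def nest_row(nest_id="n0", x=0.0, y=0.0, year=2018, hatch="2018-05-10", brood=3):
    return pd.Series(
        {
            "nest_id": nest_id,
            "x": x,
            "y": y,
            "year": year,
            "hatch_date": pd.Timestamp(hatch),
            "brood_size": brood,
            "fate": "success",
            "radio_tagged": False,
        }
    )


def points_frame(nest_id, xs, ys, safe=True, session_id="s0"):
    n = len(xs)
    return pd.DataFrame(
        {
            "point_id": [f"p{i}" for i in range(n)],
            "session_id": session_id,
            "nest_id": nest_id,
            "x": np.asarray(xs, float),
            "y": np.asarray(ys, float),
            "safe": np.full(n, safe) if np.isscalar(safe) else np.asarray(safe),
            "habitat_type_observed": "",
        }
    )
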