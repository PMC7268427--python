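import math
from pathlib import Path

import numpy as np
import pytest

from strokesim import (RegionSpec, ScenarioParams, StrokeTransportModel,
                       generate_missions, generate_region)

DATA = Path(__file__).parent / "data"
TWO_CITY = DATA / "two_city"

# independent haversine oracle used across test modules (R = IUGG mean radius)
R_KM = 6371.0088


def haversine_oracle(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    h = (math.sin((p2 - p1) / 2) ** 2
         + math.cos(p1) * math.cos(p2) * math.sin(math.radians(lon2 - lon1) / 2) ** 2)
    return 2 * R_KM * math.asin(math.sqrt(min(1.0, h)))


@pytest.fixture(scope="session")
def two_city_paths():
    return {
        "nodes": TWO_CITY / "nodes.csv",
        "edges": TWO_CITY / "edges.csv",
        "hospitals": TWO_CITY / "hospitals.geojson",
        "bases": TWO_CITY / "bases.geojson",
        "missions": TWO_CITY / "missions.csv",
        "golden": TWO_CITY / "golden",
    }


@pytest.fixture(scope="session")
def two_city_model(two_city_paths):
    p = two_city_paths
    return StrokeTransportModel.from_files(
        p["nodes"], p["edges"], p["hospitals"], p["bases"], p["missions"])


@pytest.fixture(scope="session")
def two_city_results(two_city_model):
    return two_city_model.fit()


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast synthetic region for structural tests."""
    return RegionSpec(seed=7, n_urban_centers=10, n_hospitals_thrombolysis=6,
                      n_hospitals_thrombectomy=2, n_bases=3, n_missions=1500)


@pytest.fixture(scope="session")
def small_world(small_spec):
    return generate_region(small_spec)


@pytest.fixture(scope="session")
def small_missions(small_spec, small_world):
    return generate_missions(small_spec, small_world)


@pytest.fixture(scope="session")
def small_results(small_missions, small_world):
    return StrokeTransportModel(small_missions, small_world).fit()


@pytest.fixture(scope="session")
def region10k_results():
    """10,000 seeded synthetic missions evaluated at default parameters."""
    spec = RegionSpec(seed=42, n_missions=10_000)
    world = generate_region(spec)
    missions = generate_missions(spec, world)
    return StrokeTransportModel(missions, world, ScenarioParams()).fit()


@pytest.fixture(scope="session")
def default_region_results():
    """The default synthetic region (20k missions, seed 0), fully evaluated."""
    spec = RegionSpec()
    world = generate_region(spec)
    missions = generate_missions(spec, world)
    return StrokeTransportModel(missions, world).fit()
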