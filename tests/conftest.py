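import pandas as pd
import pytest

from rsmp.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across the suite."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_root(default_dataset):
    from rsmp.clustering import fourth_root

    return fourth_root(default_dataset.table.abundance.to_numpy())


@pytest.fixture()
def toy_tables(tmp_path):
    """A 3-sample CSV trio with consistent ids."""
    ids = ["a", "b", "c"]
    matrix = pd.DataFrame(
        {"sample_id": ids, "FamA": [3, 0, 1], "FamB": [0, 2, 5]}
    )
    factors = pd.DataFrame(
        {
            "sample_id": ids,
            "survey_id": ["S1", "S1", "S2"],
            "lat": [51.0, 51.2, 52.0],
            "lon": [1.0, 1.1, -2.0],
            "gear": ["Hamon_0.1", "Day_0.1", "core"],
            "sieve_mm": [1.0, 1.0, 0.5],
            "date": ["2015-06-01", "2015-06-02", "2016-07-01"],
            "depth_m": [20.0, 22.0, 35.0],
            "treatment": ["reference", "reference", "unknown"],
            "colonials_recorded": [True, True, False],
            "same_deployment": [True, True, True],
        }
    )
    psd = pd.DataFrame(
        {
            "sample_id": ["a", "a", "b"],
            "aperture_mm": [0.125, 0.0, 0.25],
            "percent": [60.0, 40.0, 100.0],
        }
    )
    env = pd.DataFrame(
        {"sample_id": ids, "Sal": [34.0, 34.2, 33.9], "Depth": [20.0, 22.0, 35.0]}
    )
    paths = {}
    for name, frame in [("matrix", matrix), ("factors", factors),
                        ("psd", psd), ("env", env)]:
        p = tmp_path / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths
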