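import pandas as pd
import pytest

from livech4 import (
    SyntheticSpec,
    load_parameter_set,
    run_synthetic_pipeline,
)


@pytest.fixture(scope="session")
def params():
    return load_parameter_set()


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_cities=30, n_provinces=6, years=(2010, 2013), seed=7)


@pytest.fixture(scope="session")
def small_pipeline(small_spec, params):
    return run_synthetic_pipeline(small_spec, params)


def make_panel(rows):
    """Build an activity panel DataFrame from (city, prov, year, cat, sub,
    stock, slaughtered) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "city_id",
            "province_id",
            "year",
            "category",
            "subclass",
            "stock_head",
            "slaughtered_head",
        ],
    ).assign(source_flag="observed")
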