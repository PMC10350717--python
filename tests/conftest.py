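import numpy as np
import pandas as pd
import pytest

from prevcast.survey import SurveyTable, VariableSpec


@pytest.fixture
def minimal_schema():
    """Design variables plus one binary indicator."""
    return [
        VariableSpec("year", "design", "continuous"),
        VariableSpec("sex", "design", "categorical", levels=("male", "female")),
        VariableSpec("age", "design", "continuous"),
        VariableSpec("smoking", "outcome", "binary", imputable=True),
    ]


@pytest.fixture
def small_table(minimal_schema):
    """Three records, one missing smoking value."""
    df = pd.DataFrame(
        {
            "year": [1997.0, 1997.0, 2002.0],
            "sex": ["male", "female", "male"],
            "age": [30.0, 44.0, 61.0],
            "smoking": [1.0, np.nan, 0.0],
        }
    )
    return SurveyTable(df, minimal_schema)


def make_random_table(rng, n, schema, missing_rate=0.2):
    """Random valid table over a schema; only imputable cells go missing."""
    cols = {}
    for spec in schema:
        if spec.name == "year":
            cols["year"] = rng.choice([1997.0, 2002.0, 2007.0], size=n)
        elif spec.name == "sex":
            cols["sex"] = rng.choice(list(spec.levels), size=n)
        elif spec.name == "age":
            cols["age"] = rng.integers(25, 65, size=n).astype(float)
        elif spec.vtype == "binary":
            col = rng.integers(0, 2, size=n).astype(float)
            col[rng.random(n) < missing_rate] = np.nan
            cols[spec.name] = col
        elif spec.vtype == "categorical":
            col = rng.choice(list(spec.levels), size=n).astype(object)
            col[rng.random(n) < missing_rate] = np.nan
            cols[spec.name] = col
        else:
            cols[spec.name] = rng.normal(size=n)
    return SurveyTable(pd.DataFrame(cols), schema)
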