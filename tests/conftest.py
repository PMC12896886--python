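import numpy as np
import pandas as pd
import pytest

from csctargets import ExpressionStudy, StudyConfig, gen_expression_study


def make_study(values: dict[str, list[float]], classes: dict[str, str],
               platforms: dict[str, str] | None = None) -> ExpressionStudy:
    """Small hand-built study; values maps sample id -> column."""
    df = pd.DataFrame(values)
    df.index = [f"g{i + 1}" for i in range(len(df))]
    sheet = pd.DataFrame(
        {
            "sample_id": list(values),
            "dataset_id": "d1",
            "platform": [
                (platforms or {}).get(s, "HuGene1.0ST") for s in values
            ],
            "tissue_class": [classes[s] for s in values],
        }
    )
    return ExpressionStudy(df, sheet)


@pytest.fixture(scope="session")
def planted_study():
    """Default-condition synthetic study with planted targets and decoys."""
    config = StudyConfig(seed=42, n_planted_decoys=25)
    return gen_expression_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
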