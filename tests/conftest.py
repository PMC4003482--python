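import numpy as np
import pandas as pd
import pytest

import remodelome as rm


def make_table(values, diets=("standard",), ages=(3, 10), n_reps=None, normalized=False):
    """FeatureTable from a (features x samples) array laid out as
    diet-major, then age-major, then replicate."""
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    per_diet = n_samples // len(diets)
    n_reps = n_reps or per_diet // len(ages)
    cols, rows = [], []
    for diet in diets:
        for age in ages:
            for rep in range(1, n_reps + 1):
                name = f"{diet}_a{age}_r{rep}"
                cols.append(name)
                rows.append({"sample": name, "diet": diet, "age_days": age, "replicate": rep})
    mat = pd.DataFrame(values, index=[f"F{i}" for i in range(len(values))], columns=cols)
    meta = pd.DataFrame(rows).set_index("sample")
    return rm.FeatureTable(mat, meta, normalized)


@pytest.fixture(scope="session")
def small_study():
    cfg = rm.GeneratorConfig(n_features=400, n_damage=60, seed=7)
    return rm.generate_study(cfg)


@pytest.fixture(scope="session")
def default_run():
    """One fitted paper-default pipeline run."""
    return rm.RemodelingModel.from_synthetic(rm.RunConfig(seed=1)).fit()


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty fitted paper-default runs for planted-structure recovery."""
    return [
        rm.RemodelingModel.from_synthetic(rm.RunConfig(seed=s)).fit() for s in range(20)
    ]
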