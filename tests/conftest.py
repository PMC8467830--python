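import numpy as np
import pandas as pd
import pytest

from metapool.dataset import Code, LimitTable, MetabolomicsDataset
from metapool.cleaning import clean
from metapool.imputation import impute
from metapool.simulate import epic_like_preset, generate


def build_dataset(values, studies, batches, codes=None, limits=None, scale="raw", **meta_cols):
    """Small-dataset builder for unit tests.

    ``values``: 2-D array-like; NaN cells must have a non-OBSERVED code.
    """
    values = pd.DataFrame(np.asarray(values, dtype=float))
    values.index = [f"s{i}" for i in range(values.shape[0])]
    values.columns = [f"m{j}" for j in range(values.shape[1])]
    if codes is None:
        codes = pd.DataFrame(Code.OBSERVED.value, index=values.index,
                             columns=values.columns, dtype=object)
    else:
        codes = pd.DataFrame(np.asarray(codes, dtype=object),
                             index=values.index, columns=values.columns)
    meta = pd.DataFrame({"study": studies, "batch": batches, **meta_cols},
                        index=values.index)
    return MetabolomicsDataset(values, codes, meta, limits or LimitTable(), scale)


@pytest.fixture(scope="session")
def preset():
    """Seeded multi-study dataset plus ground truth (shared, read-only)."""
    return generate(epic_like_preset(seed=7))


@pytest.fixture(scope="session")
def imputed(preset):
    """Preset dataset after cleaning and imputation (log scale)."""
    data, _ = preset
    cleaned, _ = clean(data)
    imp, _ = impute(cleaned)
    return imp
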