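import numpy as np
import pandas as pd
import pytest

from lncnet import (PipelineConfig, SyntheticConfig, generate_cohort, run_all,
                    small_fixture_config)
from lncnet.types import Layer, OmicsMatrix, SampleMetadata, Scale


def make_matrix(values, layer=Layer.MRNA, scale=Scale.LOG2,
                feature_ids=None, sample_ids=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids),
                       layer, scale)


def make_meta(groups, batches=None, sample_ids=None) -> SampleMetadata:
    sample_ids = sample_ids or [f"s{j}" for j in range(len(groups))]
    table = pd.DataFrame({"group": list(groups)}, index=sample_ids)
    batch_cols = ()
    if batches is not None:
        table["batch"] = list(batches)
        batch_cols = ("batch",)
    return SampleMetadata(table, batch_cols=batch_cols)


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic cohort with ground truth (58 samples)."""
    return generate_cohort(small_fixture_config())


@pytest.fixture(scope="session")
def full_result():
    """Full cascade run on the default-size synthetic cohort."""
    return run_all(PipelineConfig(synthetic=SyntheticConfig(seed=11)))
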