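import numpy as np
import pandas as pd
import pytest

from opncombat import FeatureMatrix, SampleMetadata


@pytest.fixture
def toy_dataset():
    """Tiny 6-sample dataset with one 2-level batch and a binary covariate."""
    rng = np.random.default_rng(42)
    ids = [f"s{i}" for i in range(6)]
    feat = FeatureMatrix(
        pd.DataFrame(
            rng.normal(size=(6, 3)), index=ids, columns=["fa", "fb", "fc"]
        )
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"batch": ["a", "a", "a", "b", "b", "b"],
             "sex": ["m", "f", "m", "f", "m", "f"]},
            index=ids,
        ),
        batch_vars=["batch"],
        categorical_covariates=["sex"],
    )
    return feat, meta


def planted_dataset(
    n=200, p=50, shift=1.0, scale=1.0, seed=0, covariate_effect=0.0
):
    """Two balanced batches with a location/scale effect on every feature."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    batch = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    Y = rng.normal(size=(n, p))
    sel = batch == "b"
    Y[sel] = Y[sel] * scale + shift
    cov = rng.integers(0, 2, size=n)
    if covariate_effect:
        Y += covariate_effect * cov[:, None]
    feat = FeatureMatrix(
        pd.DataFrame(Y, index=ids, columns=[f"f{j}" for j in range(p)])
    )
    meta = SampleMetadata(
        pd.DataFrame({"batch": batch, "cov": cov.astype(str)}, index=ids),
        batch_vars=["batch"],
        categorical_covariates=["cov"],
    )
    return feat, meta
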