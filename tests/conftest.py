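import numpy as np
import pandas as pd
import pytest

from metabonet.io import FeatureTable, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture
def random_table(rng):
    """30 features x 20 samples of positive random abundances."""
    n, p = 20, 30
    values = np.exp(rng.normal(10, 1, (n, p)))
    ab = pd.DataFrame(values, index=[f"S{i:02d}" for i in range(n)],
                      columns=[f"F{j:03d}" for j in range(p)])
    return FeatureTable(ab, None)


@pytest.fixture
def block_table(rng):
    """Two planted correlated blocks (30 features each) + 20 background.

    24 samples; block features load ~0.9 on a shared factor, so
    within-block correlations are high and between-block near zero.
    """
    n = 24
    cols, names = [], []
    for b in range(2):
        factor = rng.standard_normal(n)
        for j in range(30):
            cols.append(0.9 * factor + 0.35 * rng.standard_normal(n))
            names.append(f"B{b}_{j:02d}")
    for j in range(20):
        cols.append(rng.standard_normal(n))
        names.append(f"N_{j:02d}")
    ab = pd.DataFrame(np.column_stack(cols),
                      index=[f"S{i:02d}" for i in range(n)], columns=names)
    truth = pd.Series(["block0"] * 30 + ["block1"] * 30 + ["grey"] * 20,
                      index=names)
    return FeatureTable(ab, None), truth


@pytest.fixture
def toy_feature_file(tmp_path):
    text = (
        "feature_id\tmz\trt\tannotation\tS1\tS2\tS3\tS4\n"
        "X816\t165.0587\t10.44\t2-coumaric acid\t10\t20\t30\t40\n"
        "X002\t201.1\t5.5\t\t1\t2\t3\t4\n"
        "X003\t310.2\t12.0\tunknown\t5\t\t15\t20\n"
    )
    path = tmp_path / "features.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def toy_trait_file(tmp_path):
    text = (
        "sample_id\tdiet\tgenotype\tweight\n"
        "S1\tchow\tcontrol\t21.5\n"
        "S2\tchow\tKO\t22.0\n"
        "S3\tHFD\tcontrol\t28.1\n"
        "S4\tHFD\tKO\t30.4\n"
    )
    path = tmp_path / "traits.tsv"
    path.write_text(text)
    return path
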