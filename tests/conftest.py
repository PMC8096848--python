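import numpy as np
import pytest

from gcsex.datatypes import ExpressionMatrix
from gcsex.preprocess import split_train_validation, zscale_genes
from gcsex.sexnet import DenseSexClassifier
from gcsex.simulate import CohortConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_cohort():
    """One small cohort with planted sex genes (deterministic)."""
    cfg = CohortConfig(n_samples=150, n_genes=300, n_y_linked=6, n_xist_like=3,
                       n_xci_escape=9, seed=11)
    mat, table, ann = generate_cohorts(cfg, n_cohorts=1, seed=11)[0]
    return cfg, mat, table, ann


@pytest.fixture(scope="session")
def trained_toy_model(small_cohort):
    """A small trained classifier plus its scaled data and labels."""
    cfg, mat, table, ann = small_cohort
    scaled = zscale_genes(mat)
    plan = split_train_validation(scaled.sample_ids, 0.1, seed=3,
                                  stratify_by_sex=list(table.sex))
    sex = dict(zip(scaled.sample_ids, table.sex))
    Xtr = scaled.subset_samples(plan.train_ids).samples_by_genes()
    ytr = np.array([1 if sex[s] == "male" else 0 for s in plan.train_ids])
    Xva = scaled.subset_samples(plan.validation_ids).samples_by_genes()
    yva = np.array([1 if sex[s] == "male" else 0 for s in plan.validation_ids])
    clf = DenseSexClassifier(total_layers=5, hidden_width=8, epochs=40,
                             random_state=0).fit(Xtr, ytr, Xva, yva)
    return clf, scaled, table, plan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, scale="log2", prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        scale=scale,
    )
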