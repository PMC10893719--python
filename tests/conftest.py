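import numpy as np
import pandas as pd
import pytest

import igansub as ig


@pytest.fixture(scope="session")
def cohort():
    """Planted 3-subtype cohort (90 cases / 12 controls, effect 3, noise 1)."""
    cfg = ig.SimConfig(n_case=90, n_ctrl=12, seed=1)
    expr, ann, truth = ig.generate_cohort(cfg)
    return cfg, expr, ann, truth


@pytest.fixture(scope="session")
def adjusted(cohort):
    _, expr, ann, _ = cohort
    return ig.adjust_batches(expr, ann)


@pytest.fixture(scope="session")
def global_degs(cohort, adjusted):
    _, _, ann, _ = cohort
    return ig.two_group_degs(adjusted, ann["group"], ig.DEGThresholds(0.05, 1.7),
                             group1="case", group2="control")


@pytest.fixture(scope="session")
def case_features(cohort, adjusted, global_degs):
    """z-scored DEG submatrix over case samples: the clustering substrate."""
    _, _, ann, _ = cohort
    cases = ann.loc[ann["group"] == "case", "sample_id"].tolist()
    z = ig.zscore_genes(adjusted)
    return z.loc[global_degs["gene_id"], cases]


@pytest.fixture(scope="session")
def clouds():
    """Three well-separated Gaussian clouds as a genes x samples frame."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [12.0, 0.0], [0.0, 12.0]])
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(c + rng.normal(0, 0.5, size=(15, 2)))
        labels += [i + 1] * 15
    X = np.vstack(pts)
    expr = pd.DataFrame(X.T, index=["f1", "f2"],
                        columns=[f"S{i:02d}" for i in range(len(labels))])
    return expr, np.array(labels)
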