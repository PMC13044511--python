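import numpy as np
import pytest

from shortcutaudit import (default_tcga_like_config, encode_design_matrix,
                           fit_multinomial_logit, generate_cohort)
from shortcutaudit.cohort import DesignMatrix
from shortcutaudit.model import FittedSubtypeModel

FIVE_CLASSES = ["LumA", "LumB", "Her2E", "Basal", "Normal"]


def toy_model(coefficients, column_names, class_labels):
    """FittedSubtypeModel with hand-set coefficients (diagnostic fields inert)."""
    B = np.asarray(coefficients, dtype=float)
    k = B.size
    return FittedSubtypeModel(
        coefficients=B, column_names=list(column_names),
        class_labels=list(class_labels), log_likelihood=0.0,
        null_log_likelihood=-1.0, covariance=np.eye(k), converged=True,
        n_iterations=0, n_obs=0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Complete synthetic cohort (n=800) from the default generator truth."""
    return generate_cohort(default_tcga_like_config(n=800, seed=0))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return encode_design_matrix(default_cohort)


@pytest.fixture(scope="session")
def default_fit(default_design):
    return fit_multinomial_logit(default_design)


@pytest.fixture
def tiny_design():
    """Deterministic 8-row, 2-feature, 3-class design for fast exact checks."""
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(8), rng.normal(size=8),
                         rng.integers(0, 2, size=8).astype(float)])
    y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
    return DesignMatrix(X, y, ["intercept", "x1", "b1"], ["A", "B", "C"],
                        np.arange(8).astype(str))
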