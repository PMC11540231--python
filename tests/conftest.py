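import numpy as np
import pytest

import subspace_fewshot as sf


@pytest.fixture
def toy_binary_dataset() -> sf.FeatureDataset:
    """Two classes of two points each: class 0 on y=0, class 1 on y=2.

    Hand-computable statistics: ȳ_1=(1,0), ȳ_2=(1,2), ȳ=(1,1),
    S_W=[[4,0],[0,0]], S_B=[[0,0],[0,2]], s_b=(0,−2), β=1/2.
    """
    feats = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    return sf.FeatureDataset(feats, np.array([0, 0, 1, 1]))


@pytest.fixture
def analytic_binary_stats() -> sf.BinaryScatterStats:
    """S̃_W = diag(1,2), s_b = (1,1): closed-form discriminant directions
    d_1=(2,1)/√5, d_2=±(−1,2)/√5 with γ_1=3/2, γ_2=1/9."""
    s_b = np.array([1.0, 1.0])
    return sf.BinaryScatterStats(
        s_b=s_b,
        S_tilde_B=np.outer(s_b, s_b),
        S_tilde_W=np.diag([1.0, 2.0]),
        beta=0.5,
        n_features=2,
    )


def random_binary_dataset(
    seed: int, n_per_class: int = 30, m: int = 8, gap: float = 1.5
) -> sf.FeatureDataset:
    """Well-conditioned two-class Gaussian problem (N ≫ M)."""
    rng = np.random.default_rng(seed)
    shift = rng.normal(0.0, gap, m)
    feats = np.vstack(
        [
            rng.normal(0.0, 1.0, (n_per_class, m)) + shift,
            rng.normal(0.0, 1.0, (n_per_class, m)),
        ]
    )
    return sf.FeatureDataset(feats, np.repeat([0, 1], n_per_class))


def random_multiclass_dataset(
    seed: int, c: int = 5, n_per_class: int = 12, m: int = 8
) -> sf.FeatureDataset:
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for j in range(c):
        rows.append(rng.normal(0.0, 1.0, (n_per_class, m)) + rng.normal(0.0, 2.0, m))
        labels.append(np.full(n_per_class, j))
    return sf.FeatureDataset(np.vstack(rows), np.concatenate(labels))


@pytest.fixture
def separable_dataset() -> sf.FeatureDataset:
    """Three classes whose mean separation dwarfs the within-class spread."""
    spec = sf.MixtureSpec(
        n_classes=3,
        n_features=6,
        per_class_n=(40, 40, 40),
        class_means=np.eye(3, 6) * 50.0,
        within_class_scales=np.full(6, 0.1),
        seed=7,
    )
    return sf.generate_mixture(spec)
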