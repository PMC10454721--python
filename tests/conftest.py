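import numpy as np
import pandas as pd
import pytest

from modulome import ExpressionCompendium


def make_metadata(samples, projects, conditions, references, groups=None):
    """Build a metadata frame from parallel lists."""
    groups = groups if groups is not None else conditions
    return pd.DataFrame(
        {
            "project_id": projects,
            "condition_id": conditions,
            "reference_condition_id": references,
            "replicate_group": groups,
        },
        index=pd.Index(samples, name="sample_id"),
    )


def make_compendium(values: np.ndarray, metadata: pd.DataFrame, genes=None):
    genes = genes if genes is not None else [f"g{i}" for i in range(values.shape[0])]
    return ExpressionCompendium(
        pd.DataFrame(values, index=genes, columns=metadata.index), metadata
    )


def correlated_pair(rho: float, n: int = 200, seed: int = 0):
    """Two vectors with Pearson correlation exactly `rho` (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / np.linalg.norm(x - x.mean())
    z = z - z.mean()
    z = z - (z @ x) * x  # orthogonal to x, zero mean
    z /= np.linalg.norm(z)
    y = rho * x + np.sqrt(1 - rho**2) * z
    return x, y


@pytest.fixture(scope="session")
def small_world():
    """A small planted compendium shared by fast integration tests."""
    from modulome import generate_compendium

    compendium, truth = generate_compendium(
        n_genes=400,
        n_conditions=12,
        replicates_per_condition=3,
        k_modules=6,
        genes_per_module=25,
        seed=123,
        planted_shifts={(m, c): 20.0 for m in (1, 2) for c in (10, 11)},
    )
    return compendium, truth
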