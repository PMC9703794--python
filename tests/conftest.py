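import numpy as np
import pandas as pd
import pytest

from conet.datasets import LESIONAL, NON_LESIONAL, ExpressionDataset
from conet.synthetic import CompendiumConfig, generate_compendium


def make_dataset(x: np.ndarray, n_case: int, dataset_id: str = "DS") -> ExpressionDataset:
    """Wrap a raw matrix (genes x samples) with the first n_case columns lesional."""
    n_genes, n_samples = x.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"{dataset_id}_s{i}" for i in range(n_samples)]
    cond = pd.Series(
        [LESIONAL] * n_case + [NON_LESIONAL] * (n_samples - n_case), index=samples
    )
    return ExpressionDataset(
        expr=pd.DataFrame(x, index=genes, columns=samples),
        condition=cond,
        dataset_id=dataset_id,
    )


@pytest.fixture(scope="session")
def small_compendium():
    """A light 3-dataset compendium with planted structure, reused read-only."""
    cfg = CompendiumConfig(
        n_datasets=3,
        n_genes=120,
        samples_per_arm=15,
        n_deg=16,
        module_spec=((20, 0.7), (20, 0.7)),
        n_hub_switch=4,
        n_bridge=4,
        seed=7,
    )
    datasets, truth = generate_compendium(cfg)
    return cfg, datasets, truth
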