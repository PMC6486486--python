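import numpy as np
import pandas as pd
import pytest

from synaptage import AbundanceTable, SimConfig, arcsinh_normalize, simulate_dataset


def make_table(cell_values, proteins, peptides=None, normalized=False):
    """Build an AbundanceTable from {(region, age): 2d array (proteins x reps)}."""
    columns, data, meta = [], [], []
    for (region, age), arr in cell_values.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for rep in range(arr.shape[1]):
            name = f"{region}_{age}_{rep + 1}"
            columns.append(name)
            data.append(arr[:, rep])
            meta.append((name, region, age, str(rep + 1)))
    values = pd.DataFrame(np.column_stack(data), index=proteins, columns=columns)
    samples = pd.DataFrame(meta, columns=["sample", "region", "age", "replicate"]).set_index(
        "sample"
    )
    if peptides is None:
        peptides = pd.Series(5, index=proteins)
    else:
        peptides = pd.Series(peptides, index=proteins)
    return AbundanceTable(
        values=values, samples=samples, unique_peptides=peptides, normalized=normalized
    )


def one_region_table(groups, region="HC", proteins=("P1",), normalized=True):
    """Table with one region and the three age groups; ``groups`` maps age -> rows."""
    cells = {(region, age): groups[age] for age in ("young", "mid", "old")}
    return make_table(cells, list(proteins), normalized=normalized)


@pytest.fixture
def small_dataset():
    """100-protein noisy dataset with 10 planted candidates, plus its truth."""
    cfg = SimConfig(n_proteins=100, n_candidates=10, seed=42)
    table, truth = simulate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture
def normalized_dataset(small_dataset):
    cfg, table, truth = small_dataset
    return cfg, arcsinh_normalize(table), truth
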