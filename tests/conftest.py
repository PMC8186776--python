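import numpy as np
import pandas as pd
import pytest

from mirstab import CpmMatrix, SimConfig, generate_dataset, to_cpm


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort shared by read-only tests."""
    counts, meta, truth = generate_dataset(SimConfig(seed=7))
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_cpm(small_cohort):
    counts, meta, truth = small_cohort
    return to_cpm(counts), meta, truth


def make_meta(n_pairs=6, n_tumor_only=6, subtypes=("A", "B"), seed=0):
    """Tiny handmade metadata table with complete clinical codes."""
    rng = np.random.default_rng(seed)
    rows = []
    n_pat = n_pairs + n_tumor_only
    for i in range(n_pat):
        pat = f"p{i:02d}"
        sub = subtypes[i % len(subtypes)]
        t = int(rng.integers(1, 5))
        n = int(rng.integers(0, 4))
        clin = dict(T=t, N=n, M=int(rng.integers(0, 2)), stage=min(7, t + n),
                    neoplasm_status=int(rng.integers(0, 2)))
        rows.append(dict(sample_id=f"{pat}-T", patient_id=pat, tissue="tumor",
                         subtype=sub, **clin))
        if i < n_pairs:
            rows.append(dict(sample_id=f"{pat}-N", patient_id=pat, tissue="normal",
                             subtype="", **clin))
    return pd.DataFrame(rows)


def make_cpm(values, sample_ids, gene_ids=None):
    """CpmMatrix straight from an array (rows genes, cols samples)."""
    arr = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"
    return CpmMatrix(df)
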