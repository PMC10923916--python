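import numpy as np
import pandas as pd
import pytest

import dspsig as ds


@pytest.fixture(scope="session")
def default_experiment():
    """The packaged default synthetic DSP experiment (seed 1)."""
    return ds.simulate_dsp_experiment(ds.SimParams(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_experiment):
    """(filtered experiment, Q3 matrix, harmonized log2 matrix, flags)."""
    return ds.run_preprocess(default_experiment)


@pytest.fixture(scope="session")
def dea_tables(preprocessed):
    exp_f, _, harmonized, _ = preprocessed
    return {
        c: ds.run_dea(harmonized, exp_f.annotations, c)
        for c in ("GC_vs_IF", "LZ_vs_DZ", "RLT_vs_DLBCL")
    }


@pytest.fixture(scope="session")
def macrosigs(preprocessed, dea_tables):
    exp_f, normalized, _, _ = preprocessed
    ranks = ds.percentile_ranks(
        normalized, exp_f.annotation_frame["mask"], which_masks=["CD68", "CD20"]
    )
    return ds.derive_all_macrosigs(dea_tables, ranks)


def random_expression(rng, n_genes=30, n_samples=8, scale=ds.Scale.LOG2):
    df = pd.DataFrame(
        rng.normal(5, 1, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ds.ExpressionMatrix(df, scale)


def toy_macrosig(genes, p, lfc, name="Sig", contrast="A_vs_B"):
    p = np.asarray(p, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    entries = pd.DataFrame(
        {
            "weight": -np.log10(p),
            "sign": np.where(lfc > 0, 1, -1),
            "log2fc": lfc,
            "p": p,
            "adj_p": np.minimum(p * 2, 1.0),
        },
        index=list(genes),
    )
    return ds.MacroSig(name, contrast, entries)
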