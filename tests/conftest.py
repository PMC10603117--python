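import numpy as np
import pandas as pd
import pytest

from stratanet.preprocess import ExpressionStudy, NormalizedExpression
from stratanet.simulate import PlantedModule, SimConfig, generate_study


def make_study(counts: np.ndarray, sex=None, phenotype=None, controls=()):
    """Small hand-built ExpressionStudy from a raw count array."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "sex": sex if sex is not None else ["male"] * n,
            "phenotype": phenotype if phenotype is not None else ["MDD"] * n,
        },
        index=samples,
    )
    return ExpressionStudy(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        metadata=meta,
        control_gene_ids=list(controls),
    )


def make_norm(logexpr: np.ndarray, metadata: pd.DataFrame | None = None, **kw):
    """NormalizedExpression straight from a log-expression array."""
    logexpr = np.asarray(logexpr, dtype=float)
    genes = [f"g{i}" for i in range(logexpr.shape[0])]
    samples = [f"s{j}" for j in range(logexpr.shape[1])]
    if metadata is None:
        metadata = pd.DataFrame(index=samples)
    else:
        metadata = metadata.set_axis(samples)
    return NormalizedExpression(
        logexpr=pd.DataFrame(logexpr, index=genes, columns=samples),
        metadata=metadata,
        **kw,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study with one planted module, DE genes and
    controls — shared by read-only tests."""
    cfg = SimConfig(
        n_genes=400,
        modules=(PlantedModule("m1", 60, 0.8),),
        n_de_genes=40,
        de_log2fc=1.0,
        n_control_genes=20,
        symptom_effects={("m1", "insomnia_hypersomnia", "male"): 2.0},
        seed=11,
    )
    return generate_study(cfg)


def factor_model_expr(
    rng, n_genes, n_samples, loading=0.8, noise_sd=0.6, gene_prefix="g"
):
    """Gene x sample matrix from a one-factor model (no counts)."""
    f = rng.standard_normal(n_samples)
    lam = np.full(n_genes, loading)
    X = lam[:, None] * f[None, :] + noise_sd * rng.standard_normal(
        (n_genes, n_samples)
    )
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(X, index=genes, columns=samples)
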