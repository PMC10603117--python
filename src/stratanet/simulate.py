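"""Synthetic RNA-seq study generator with planted network structure.

Emulates the statistical structure of a sex-stratified postmortem-brain
bulk RNA-seq cohort: negative-binomial counts over a log-scale latent
factor model, planted co-expression modules with sex-specific rewiring,
planted differential expression between phenotypes, spike-in control
genes carrying only unwanted (batch) variation, and binary clinical
symptoms driven by module latent factors in the patient group only.

The generative model for gene g in sample s is

    log2 q_gs = mu_g + lambda_g * rewire(sex_s) * f_{m(g)}(s)
                + delta_g * 1[phenotype_s = MDD] + b_g * 1[batch_s = B]
                + eps_gs,                       eps_gs ~ N(0, noise_sd^2)

    count_gs ~ NegBin(mean = L_s * 2^{log2 q_gs} / C,  dispersion = phi)

where f_m ~ N(0,1) is the latent factor of module m, lambda_g its loading,
delta_g the planted log2 fold change, L_s a log-normal library size and C
a fixed normalising constant.  Symptoms are Bernoulli in MDD samples with
logit equal to a linear combination of the sample's module factors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedModule",
    "GroundTruth",
    "SYMPTOM_IDS",
    "generate_study",
    "write_fixture",
    "read_fixture",
]

#: Binary symptom categories retained for association analysis (the four
#: categories expressed by every patient are uninformative and excluded).
SYMPTOM_IDS = (
    "appetite_weight",
    "insomnia_hypersomnia",
    "psychomotor",
    "low_self_esteem",
    "concentration_indecision",
)

DEFAULT_CELLS = {
    ("male", "MDD"): 25,
    ("female", "MDD"): 25,
    ("male", "CTRL"): 17,
    ("female", "CTRL"): 22,
}


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expressed gene module.

    Parameters
    ----------
    module_id : str
        Label used in the ground truth.
    size : int
        Number of member genes; at least 50, mirroring the smallest
        module size the method is expected to resolve.
    loading_mean : float
        Mean factor loading in (0, 1]; per-gene loadings are jittered
        uniformly within +/-10% of this value.
    rewire : dict
        Per-sex multiplier in [0, 1] applied to the loadings; 0 destroys
        the module's connectivity in that sex, 1 leaves it intact.
    """

    module_id: str
    size: int
    loading_mean: float
    rewire: dict = field(default_factory=lambda: {"male": 1.0, "female": 1.0})

    def __post_init__(self):
        if self.size < 50:
            raise ConfigurationError(
                f"module {self.module_id!r}: size {self.size} < 50"
            )
        if not (0.0 < self.loading_mean <= 1.0):
            raise ConfigurationError(
                f"module {self.module_id!r}: loading_mean must be in (0,1]"
            )
        for sex, mult in self.rewire.items():
            if not (0.0 <= mult <= 1.0):
                raise ConfigurationError(
                    f"module {self.module_id!r}: rewire[{sex}] outside [0,1]"
                )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic study.

    Defaults reproduce the cohort geometry the pipeline targets:
    25 male MDD, 25 female MDD, 17 male CTRL, 22 female CTRL samples.
    """

    n_genes: int = 2000
    n_samples_per_cell: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    modules: tuple = ()
    n_de_genes: int = 0
    de_log2fc: float = 1.0
    n_control_genes: int = 30
    batch_sd: float = 0.3
    library_size_mean: float = 2e6
    nb_dispersion: float = 0.1
    noise_sd: float = 0.5
    symptom_effects: dict = field(default_factory=dict)
    symptom_base_logit: float = 0.0
    n_outliers: int = 0
    outlier_shift_sd: float = 4.0
    region: str = "PFC"
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.n_samples_per_cell:
            raise ConfigurationError("n_samples_per_cell must be non-empty")
        for cell, n in self.n_samples_per_cell.items():
            if n <= 0:
                raise ConfigurationError(f"cell {cell} has {n} samples")
        if self.n_de_genes < 0 or self.n_control_genes < 0:
            raise ConfigurationError("gene counts must be >= 0")
        if self.batch_sd < 0:
            raise ConfigurationError("batch_sd must be >= 0")
        if self.library_size_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("library size and dispersion must be > 0")
        sizes = sum(m.size for m in self.modules)
        if sizes + self.n_control_genes > self.n_genes:
            raise ConfigurationError(
                "sum of module sizes plus control genes exceeds n_genes"
            )
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate module ids")


@dataclass
class GroundTruth:
    """Planted truth serialisable alongside a fixture."""

    gene_module: dict  # gene id -> module id (absent = background)
    de_genes: dict  # gene id -> true log2 fold change
    control_genes: list  # gene ids carrying only unwanted variation
    latent_factors: pd.DataFrame  # samples x modules
    symptom_truth: dict  # "module|symptom|sex" -> True (planted association)
    outlier_samples: list

    def to_json_dict(self) -> dict:
        return {
            "gene_module": self.gene_module,
            "de_genes": self.de_genes,
            "control_genes": list(self.control_genes),
            "latent_factors": {
                "index": list(self.latent_factors.index),
                "columns": list(self.latent_factors.columns),
                "values": self.latent_factors.to_numpy().tolist(),
            },
            "symptom_truth": {k: bool(v) for k, v in self.symptom_truth.items()},
            "outlier_samples": list(self.outlier_samples),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        lf = d["latent_factors"]
        return cls(
            gene_module=dict(d["gene_module"]),
            de_genes={k: float(v) for k, v in d["de_genes"].items()},
            control_genes=list(d["control_genes"]),
            latent_factors=pd.DataFrame(
                np.asarray(lf["values"], dtype=float),
                index=lf["index"],
                columns=lf["columns"],
            ),
            symptom_truth=dict(d["symptom_truth"]),
            outlier_samples=list(d["outlier_samples"]),
        )


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for (sex, phenotype), n in sorted(config.n_samples_per_cell.items()):
        for _ in range(n):
            i += 1
            rows.append({"sample_id": f"S{i:03d}", "sex": sex, "phenotype": phenotype})
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta.index.name = "sample_id"
    n = len(meta)
    meta["region"] = config.region
    meta["batch"] = np.where(rng.random(n) < 0.5, "B1", "B2")
    meta["age"] = np.round(rng.normal(50, 10, n), 1)
    meta["pmi"] = np.round(np.clip(rng.normal(40, 15, n), 5, None), 1)
    meta["ph"] = np.round(rng.normal(6.5, 0.25, n), 2)
    meta["rin"] = np.round(np.clip(rng.normal(7.0, 1.0, n), 3, 10), 1)
    return meta


def generate_study(config: SimConfig):
    """Draw a synthetic study from ``config``.

    Returns an (:class:`~stratanet.preprocess.ExpressionStudy`,
    :class:`GroundTruth`) pair.  Identical configs (including the seed)
    give byte-identical output.
    """
    from .preprocess import ExpressionStudy  # deferred to avoid cycle

    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config, rng)
    n_samples = len(meta)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]

    # gene role assignment: modules first, then controls, then DE from the
    # remaining background (keeps module / control / DE signals disjoint)
    cursor = 0
    gene_module: dict = {}
    module_members: dict = {}
    for m in config.modules:
        members = genes[cursor : cursor + m.size]
        cursor += m.size
        module_members[m.module_id] = members
        for g in members:
            gene_module[g] = m.module_id
    control_genes = genes[cursor : cursor + config.n_control_genes]
    cursor += config.n_control_genes
    background = genes[cursor:]
    if config.n_de_genes > len(background):
        raise ConfigurationError(
            f"n_de_genes={config.n_de_genes} exceeds available background "
            f"genes ({len(background)})"
        )
    de_ids = background[: config.n_de_genes]
    signs = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
    de_genes = {g: float(s * config.de_log2fc) for g, s in zip(de_ids, signs)}

    gene_idx = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    # latent module factors, one per module per sample
    factors = pd.DataFrame(
        rng.standard_normal((n_samples, len(config.modules))),
        index=meta.index,
        columns=[m.module_id for m in config.modules],
    )

    log2q = np.tile(mu[:, None], (1, n_samples))

    sex_arr = meta["sex"].to_numpy()
    phen_arr = meta["phenotype"].to_numpy()
    for m in config.modules:
        loadings = m.loading_mean * rng.uniform(0.9, 1.1, m.size)
        rewire = np.array([m.rewire.get(s, 1.0) for s in sex_arr])
        f = factors[m.module_id].to_numpy()
        rows = [gene_idx[g] for g in module_members[m.module_id]]
        log2q[rows, :] += loadings[:, None] * (rewire * f)[None, :]

    is_mdd = (phen_arr == "MDD").astype(float)
    for g, lfc in de_genes.items():
        log2q[gene_idx[g], :] += lfc * is_mdd

    batch_eff = rng.normal(0.0, config.batch_sd, config.n_genes)
    in_b2 = (meta["batch"].to_numpy() == "B2").astype(float)
    log2q += batch_eff[:, None] * in_b2[None, :]

    noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    # control genes: batch + measurement noise only — wipe any other signal
    ctrl_rows = [gene_idx[g] for g in control_genes]
    if ctrl_rows:
        log2q[ctrl_rows, :] = (
            mu[ctrl_rows][:, None] + batch_eff[ctrl_rows][:, None] * in_b2[None, :]
        )
    log2q += noise

    # outlier samples: global per-gene displacement
    n_out = min(config.n_outliers, n_samples)
    outlier_ids = list(rng.choice(meta.index.to_numpy(), size=n_out, replace=False))
    for s in outlier_ids:
        j = meta.index.get_loc(s)
        log2q[:, j] += rng.normal(0.0, config.outlier_shift_sd, config.n_genes)

    # library sizes and negative-binomial observation
    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    lib = config.library_size_mean * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, n_samples)
    )
    q = np.exp2(log2q)
    C = float(np.exp2(mu).sum())  # fixed normaliser: no induced correlation
    mean = lib[None, :] * q / C
    r = 1.0 / config.nb_dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    # symptoms: Bernoulli(logit = base + sum effects * factor), MDD only
    symptom_truth = {}
    for col in SYMPTOM_IDS:
        meta[f"symptom_{col}"] = pd.array([pd.NA] * n_samples, dtype="Int64")
    for sym in SYMPTOM_IDS:
        logit = np.full(n_samples, config.symptom_base_logit, dtype=float)
        for (module_id, symptom_id, sex), beta in config.symptom_effects.items():
            if symptom_id != sym:
                continue
            if module_id not in factors.columns:
                raise ConfigurationError(
                    f"symptom effect references unknown module {module_id!r}"
                )
            mask = sex_arr == sex
            logit[mask] += beta * factors[module_id].to_numpy()[mask]
            if beta != 0:
                symptom_truth[f"{module_id}|{symptom_id}|{sex}"] = True
        prob = 1.0 / (1.0 + np.exp(-logit))
        vals = (rng.random(n_samples) < prob).astype("int64")
        col = pd.array(vals, dtype="Int64")
        col[phen_arr != "MDD"] = pd.NA
        meta[f"symptom_{sym}"] = col

    meta["is_outlier_truth"] = meta.index.isin(outlier_ids).astype(int)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    counts_df.index.name = "gene_id"
    counts_df.columns.name = None
    study = ExpressionStudy(
        counts=counts_df, metadata=meta, control_gene_ids=list(control_genes)
    )
    truth = GroundTruth(
        gene_module=gene_module,
        de_genes=de_genes,
        control_genes=list(control_genes),
        latent_factors=factors,
        symptom_truth=symptom_truth,
        outlier_samples=outlier_ids,
    )
    return study, truth


def write_fixture(study, truth: GroundTruth, directory) -> dict:
    """Write a study to plain-text files; returns the paths written.

    Layout: ``counts.tsv`` (genes x samples, first column ``gene_id``),
    ``metadata.tsv`` (one row per sample) and ``truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    counts = study.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(paths["counts"], sep="\t")
    meta = study.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(paths["metadata"], sep="\t", na_rep="NA")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_fixture(directory):
    """Inverse of :func:`write_fixture`; exact round trip."""
    from .preprocess import ExpressionStudy

    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    counts = counts.astype(np.int64)
    meta = pd.read_csv(
        directory / "metadata.tsv", sep="\t", index_col=0, na_values=["NA"],
        keep_default_na=False,
    )
    for col in meta.columns:
        if col.startswith("symptom_"):
            meta[col] = meta[col].astype("Int64")
    with open(directory / "truth.json") as fh:
        truth = GroundTruth.from_json_dict(json.load(fh))
    study = ExpressionStudy(
        counts=counts, metadata=meta, control_gene_ids=list(truth.control_genes)
    )
    return study, truth


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference study: one rewired module, one symptom-linked
    module, planted DE and spike-in controls at the default cohort geometry."""
    modules = (
        PlantedModule("mod_rewired", 60, 0.8, {"male": 1.0, "female": 0.0}),
        PlantedModule("mod_symptom", 60, 0.8, {"male": 1.0, "female": 1.0}),
        PlantedModule("mod_stable", 80, 0.8, {"male": 1.0, "female": 1.0}),
    )
    cfg = dict(
        n_genes=2000,
        modules=modules,
        n_de_genes=100,
        de_log2fc=1.0,
        n_control_genes=30,
        symptom_effects={
            ("mod_symptom", "insomnia_hypersomnia", "male"): 2.0,
            ("mod_symptom", "insomnia_hypersomnia", "female"): 2.0,
        },
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
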