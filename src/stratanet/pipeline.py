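"""End-to-end orchestration of the sex-stratified analysis.

The pipeline reproduces the study's analysis graph on a count matrix and
sample metadata: preprocessing (filter, log-CPM, unwanted-variation
factor, outlier exclusion, covariate adjustment), per-sex differential
expression, an RRHO map between the male and female MDD signatures,
top-DEG clustering, co-expression networks (pooled and per sex),
module differential connectivity (MDD vs CTRL within each sex, and
male MDD vs female MDD), preservation of male modules in the female
data, and symptom association on the pooled-network eigengenes within
the MDD samples of each sex.  All artefacts are plain-text TSV/JSON and
every stage records its parameters and seed in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, diffexpr, module_stats, preprocess, rrho, symptom_assoc
from .coexpression import UNASSIGNED
from .simulate import SYMPTOM_IDS, default_study_config, generate_study, read_fixture

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "score_against_truth"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    input_dir: str | None = None  # fixture directory; None = simulate
    out_dir: str = "stratanet_out"
    seed: int = 0
    covariates: tuple = ("batch",)
    ruv_k: int = 1
    min_count: int = 5
    low_fraction: float = 0.20
    outlier_z: float = -3.5
    de_alpha: float = 0.05
    rrho_step: int | None = None
    min_module_size: int = 50
    beta: int | None = None  # None = pick per network by scale-free fit
    n_perm_mdc: int = 200
    n_perm_preservation: int = 100
    n_perm_symptoms: int = 1000
    n_top_degs: int = 200
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None):
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written
    to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(config), "stages": {}}

    # ---- input ----
    truth = None
    if config.input_dir is None:
        study, truth = generate_study(default_study_config(seed=config.seed))
    else:
        study, truth = read_fixture(config.input_dir)
    report["stages"]["input"] = {
        "n_genes": len(study.gene_ids), "n_samples": len(study.sample_ids),
        "n_control_genes": len(study.control_gene_ids),
    }

    # ---- preprocess ----
    study_f = preprocess.filter_low_expression(
        study, min_count=config.min_count, low_fraction=config.low_fraction
    )
    norm = preprocess.log_cpm(study_f)
    if len(study_f.control_gene_ids) > config.ruv_k:
        norm = preprocess.estimate_unwanted_factors(norm, k=config.ruv_k)
    outliers = preprocess.detect_outlier_samples(norm, z_threshold=config.outlier_z)
    keep = [s for s in norm.sample_ids if s not in set(outliers)]
    norm = norm.subset_samples(keep)
    adjusted = preprocess.adjust_covariates(norm, list(config.covariates))
    report["stages"]["preprocess"] = {
        "genes_removed": len(study_f.removed_genes),
        "genes_kept": len(study_f.gene_ids),
        "outlier_samples": outliers,
        "ruv_factors": 0 if norm.unwanted_factors is None
        else int(norm.unwanted_factors.shape[1]),
        "outlier_order_note": "outliers detected on normalized, unadjusted data",
    }
    qc = {
        "removed_genes": study_f.removed_genes,
        "removed_samples": outliers,
        "ruv_factor": None if norm.unwanted_factors is None
        else {s: float(v) for s, v in norm.unwanted_factors.iloc[:, 0].items()},
    }
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=1)

    # ---- differential expression per sex ----
    de = {}
    for sex in ("male", "female"):
        de[sex] = diffexpr.de_within_sex(norm, sex, covariates=config.covariates)
        tab = de[sex].table.copy()
        degs = diffexpr.call_degs(de[sex], alpha=config.de_alpha)
        tab["deg_flag"] = tab.index.isin(degs["up"] | degs["down"])
        tab["direction"] = np.where(
            tab.index.isin(degs["up"]), "up",
            np.where(tab.index.isin(degs["down"]), "down", "ns"),
        )
        _write_tsv(tab, out / f"de_{sex}.tsv", index_label="gene_id")
    degs_m = diffexpr.call_degs(de["male"], alpha=config.de_alpha)
    degs_f = diffexpr.call_degs(de["female"], alpha=config.de_alpha)
    set_m = degs_m["up"] | degs_m["down"]
    set_f = degs_f["up"] | degs_f["down"]
    ov = diffexpr.overlap_degs(set_m, set_f, background_size=len(norm.gene_ids))
    report["stages"]["diffexpr"] = {
        "n_deg_male": len(set_m), "n_deg_female": len(set_f),
        "overlap": ov.overlap, "jaccard_pct": ov.jaccard_pct,
        "fisher_p": ov.fisher_p,
    }

    # ---- RRHO male vs female ----
    sig_m = rrho.RankedSignature.from_de(de["male"])
    sig_f = rrho.RankedSignature.from_de(de["female"])
    rmap = rrho.compute_rrho(sig_m, sig_f, step=config.rrho_step)
    pd.DataFrame(
        rmap.adj_neglog_p, index=rmap.thresholds, columns=rmap.thresholds
    ).to_csv(out / "rrho_adj_neglog_p.tsv", sep="\t")
    mx, cell, quad = rmap.max_signal()
    with open(out / "rrho_summary.json", "w") as fh:
        json.dump(
            {"max_adj_neglog_p": mx, "at_thresholds": list(cell),
             "quadrant": quad, "n_universe": rmap.n_universe,
             "step": rmap.step}, fh, indent=1,
        )
    if config.make_plots:
        rrho.plot_rrho(rmap, out / "rrho_male_vs_female.png",
                       title="male vs female MDD signatures")
    report["stages"]["rrho"] = {
        "max_adj_neglog_p": mx, "quadrant": quad, "n_universe": rmap.n_universe,
    }

    # ---- top-DEG clustering ----
    sym_cols = [c for c in norm.metadata.columns if c.startswith("symptom_")]
    n_top = min(config.n_top_degs, len(norm.gene_ids))
    clust = diffexpr.cluster_top_degs(
        norm, de["male"], symptom_labels=norm.metadata[sym_cols], n_top=n_top
    )
    _write_tsv(clust.matrix, out / "top_deg_matrix.tsv", index_label="gene_id")
    report["stages"]["top_deg_clustering"] = {
        "n_top": n_top, "first_gene": clust.gene_order[0],
    }

    # ---- networks ----
    meta = norm.metadata
    strata = {"pooled": list(norm.sample_ids)}
    for sex in ("male", "female"):
        strata[sex] = [s for s in norm.sample_ids if meta.at[s, "sex"] == sex]
        for phen in ("MDD", "CTRL"):
            strata[f"{sex}_{phen}"] = [
                s for s in strata[sex] if meta.at[s, "phenotype"] == phen
            ]
    networks = {}
    for name in ("pooled", "male", "female"):
        expr = adjusted.logexpr[strata[name]]
        net = coexpression.build_network(
            expr, stratum=name, beta=config.beta,
            min_size=config.min_module_size,
        )
        networks[name] = net
        assign = pd.DataFrame({"module": net.modules, "kIM": net.kIM})
        assign["is_hub"] = [
            g in set(net.hubs.get(m, [])) for g, m in net.modules.items()
        ]
        _write_tsv(assign, out / f"network_{name}_modules.tsv", index_label="gene_id")
        _write_tsv(net.ME, out / f"network_{name}_ME.tsv", index_label="sample_id")
        _write_tsv(net.kME, out / f"network_{name}_kME.tsv", index_label="gene_id")
        report["stages"][f"network_{name}"] = {
            "beta": net.beta, "reached_target_r2": bool(net.reached_target_r2),
            "n_modules": int((net.module_sizes > 0).sum()),
            "module_sizes": {str(k): int(v) for k, v in net.module_sizes.items()},
            "n_unassigned": int((net.modules == UNASSIGNED).sum()),
        }

    # ---- module differential connectivity ----
    mdc_rows = []
    comparisons = [
        ("male", "male_MDD", "male_CTRL"),
        ("female", "female_MDD", "female_CTRL"),
        ("male", "male_MDD", "female_MDD"),
    ]
    for net_name, cond_a, cond_b in comparisons:
        net = networks[net_name]
        expr_a = adjusted.logexpr[strata[cond_a]]
        expr_b = adjusted.logexpr[strata[cond_b]]
        for mod in sorted(set(net.modules) - {UNASSIGNED}):
            genes = list(net.modules.index[net.modules == mod])
            res = module_stats.mdc_significance(
                genes, expr_a, expr_b, beta=net.beta,
                n_perm=config.n_perm_mdc, seed=config.seed,
                module_label=f"{net_name}:{mod}",
            )
            mdc_rows.append(
                {"network": net_name, "module": mod,
                 "comparison": f"{cond_a}_vs_{cond_b}", "mdc": res.mdc,
                 "class": res.mdc_class, "fdr": res.fdr,
                 "n_perm": config.n_perm_mdc, "seed": config.seed}
            )
    mdc_table = pd.DataFrame(mdc_rows)
    mdc_table.to_csv(out / "mdc.tsv", sep="\t", index=False)
    report["stages"]["mdc"] = {
        "n_tests": len(mdc_table),
        "n_goc": int((mdc_table["class"] == "GOC").sum()),
        "n_loc": int((mdc_table["class"] == "LOC").sum()),
    }

    # ---- preservation of male modules in female data ----
    male_net = networks["male"]
    pres = module_stats.preservation_z(
        male_net.modules,
        adjusted.logexpr[strata["male"]],
        adjusted.logexpr[strata["female"]],
        beta=male_net.beta,
        n_perm=config.n_perm_preservation,
        seed=config.seed,
    )
    _write_tsv(pres, out / "preservation_male_in_female.tsv", index_label="module")
    report["stages"]["preservation"] = {
        "n_modules": len(pres),
        "n_preserved": int(pres["preserved"].sum()),
        "z_summary": {str(k): float(v) for k, v in pres["z_summary"].items()},
    }

    # ---- symptom association (pooled-network MEs, per sex, MDD only) ----
    pooled = networks["pooled"]
    assoc_tables = []
    for sex in ("male", "female"):
        ids = [
            s for s in strata[sex]
            if meta.at[s, "phenotype"] == "MDD"
        ]
        symptoms = meta.loc[ids, sym_cols].rename(
            columns=lambda c: c.replace("symptom_", "")
        )
        if pooled.ME.shape[1] == 0:
            continue
        table, skipped = symptom_assoc.module_symptom_association(
            pooled.ME.loc[ids], symptoms, sex_stratum=sex,
            n_perm=config.n_perm_symptoms, seed=config.seed,
        )
        if len(table):
            assoc_tables.append(table)
        report["stages"].setdefault("symptom_assoc", {})[sex] = {
            "n_tested": len(table), "skipped": skipped,
        }
    assoc = (
        pd.concat(assoc_tables, ignore_index=True)
        if assoc_tables else pd.DataFrame(
            columns=["module", "symptom", "sex", "r_pb", "p_perm", "n_used"]
        )
    )
    assoc.to_csv(out / "symptom_association.tsv", sep="\t", index=False)

    # DEG-module enrichment on the pooled network
    module_sets = {
        m: list(pooled.modules.index[pooled.modules == m])
        for m in sorted(set(pooled.modules) - {UNASSIGNED})
    }
    enr = symptom_assoc.enrichment_table(
        module_sets,
        {"deg_male": set_m, "deg_female": set_f},
        background=norm.gene_ids,
    )
    enr.to_csv(out / "module_deg_enrichment.tsv", sep="\t", index=False)

    report["seed"] = config.seed
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _match_modules(detected: pd.Series, truth_map: dict) -> dict:
    """Map each planted module to the detected label holding the
    plurality of its genes."""
    out = {}
    planted = sorted(set(truth_map.values()))
    for pm in planted:
        genes = [g for g, m in truth_map.items() if m == pm and g in detected.index]
        if not genes:
            continue
        counts = detected.loc[genes].value_counts()
        out[pm] = counts.index[0]
    return out


def score_against_truth(out_dir, truth) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Reports the adjusted Rand index of pooled-network module labels on
    the planted module genes, DEG recall and false-positive rate, the
    MDC class of each planted module in the male-vs-female comparison,
    and whether the planted symptom-associated module is the top hit.
    """
    from sklearn.metrics import adjusted_rand_score

    out = Path(out_dir)
    scores: dict = {}

    assign = pd.read_csv(out / "network_pooled_modules.tsv", sep="\t", index_col=0)
    planted_genes = [g for g in truth.gene_module if g in assign.index]
    if planted_genes:
        true_labels = [truth.gene_module[g] for g in planted_genes]
        det_labels = assign.loc[planted_genes, "module"].tolist()
        scores["module_ari"] = float(adjusted_rand_score(true_labels, det_labels))

    de_m = pd.read_csv(out / "de_male.tsv", sep="\t", index_col=0)
    de_f = pd.read_csv(out / "de_female.tsv", sep="\t", index_col=0)
    called = set(de_m.index[de_m["deg_flag"]]) | set(de_f.index[de_f["deg_flag"]])
    true_de = set(truth.de_genes)
    present_de = true_de & (set(de_m.index) | set(de_f.index))
    if present_de:
        scores["deg_recall"] = len(called & present_de) / len(present_de)
    null_genes = (set(de_m.index) - true_de) - set(truth.gene_module)
    if null_genes:
        null_called_m = set(de_m.index[de_m["p"] <= 0.05]) & null_genes
        scores["deg_null_positive_rate_male"] = len(null_called_m) / len(null_genes)

    mdc_table = pd.read_csv(out / "mdc.tsv", sep="\t")
    sex_cmp = mdc_table[mdc_table["comparison"] == "male_MDD_vs_female_MDD"]
    if len(sex_cmp):
        male_assign = pd.read_csv(
            out / "network_male_modules.tsv", sep="\t", index_col=0
        )["module"]
        match = _match_modules(male_assign, truth.gene_module)
        mdc_by_mod = sex_cmp.set_index("module")
        scores["planted_mdc"] = {}
        for pm, det in match.items():
            if det in mdc_by_mod.index and det != UNASSIGNED:
                row = mdc_by_mod.loc[det]
                scores["planted_mdc"][pm] = {
                    "detected_as": det, "mdc": float(row["mdc"]),
                    "class": str(row["class"]),
                }

    assoc = pd.read_csv(out / "symptom_association.tsv", sep="\t")
    scores["symptom_hits"] = {}
    for key in truth.symptom_truth:
        pm, sym, sex = key.split("|")
        sub = assoc[(assoc["symptom"] == sym) & (assoc["sex"] == sex)]
        if not len(sub):
            continue
        top = sub.loc[sub["r_pb"].abs().idxmax()]
        match = _match_modules(assign["module"], truth.gene_module)
        scores["symptom_hits"][key] = {
            "top_module": str(top["module"]),
            "expected_module": str(match.get(pm, "?")),
            "hit": bool(match.get(pm) == top["module"]),
            "p_perm": float(top["p_perm"]),
        }
    return scores
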