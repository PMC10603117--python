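"""Generate a synthetic sex-stratified RNA-seq study and inspect it.

The generator plants co-expressed modules (with optional sex-specific
rewiring), differentially expressed genes, spike-in control genes and
binary symptoms driven by module activity in MDD samples.
"""
from stratanet import default_study_config, generate_study, write_fixture

config = default_study_config(seed=1)
study, truth = generate_study(config)

print(f"counts: {study.counts.shape[0]} genes x {study.counts.shape[1]} samples")
print(study.metadata.groupby(["sex", "phenotype"]).size())
print(f"planted modules: {sorted(set(truth.gene_module.values()))}")
print(f"planted DE genes: {len(truth.de_genes)}, controls: {len(truth.control_genes)}")
paths = write_fixture(study, truth, "scratch/example_fixture")
print("fixture written:", paths)
# The cohort geometry (25/25 MDD, 17/22 CTRL by sex) matches the study
# design the pipeline targets; truth.json lets downstream stages be scored.
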