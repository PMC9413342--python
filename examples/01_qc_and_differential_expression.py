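"""QC filtering and differential expression on a simulated two-group study.

Generates negative-binomial counts and log-normal metabolite peaks for six
pregnant (AI-P) and six nonpregnant (NP) heifers-scale samples, applies the
three count filters and the metabolite RSD filter, and calls differential
features with the Welch test (p <= 0.05, |log2FC| >= 0.5).
"""

from omicnet import (
    call_significant,
    differential_test,
    filter_counts,
    generate,
    log_normalize,
    metabolite_qc,
    planted_scenario,
)

genes, metabs, truth = generate(planted_scenario(seed=0, n_per_group=6))

kept, report = filter_counts(genes)
print("gene QC:", report.describe())

metab_log, metab_report = metabolite_qc(metabs)
print("metabolite QC:", metab_report.describe())
for group, ids in metab_report.group_retained_ids.items():
    print(f"  retained for {group}: {len(ids)} metabolites")

de = differential_test(kept)
degs = call_significant(de, alpha=0.05, lfc_min=0.5)
truth_de_genes = {f for f in truth.de_features if f.startswith("G")}
print(f"DEGs called: {len(degs)} (planted: {len(truth_de_genes)}, "
      f"recovered: {len(degs & truth_de_genes)})")
# log2FC > 0 means higher expression in the NP (reference) group.

dem = differential_test(log_normalize(metabs), transform="log2")
dems = call_significant(dem)
print(f"DEMs called: {len(dems)}")
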