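"""Relate the PLS1 genes to curated lists and post-mortem expression.

Overlaps the PLS1 gene sets with a curated disease-gene list inside the
background universe, correlates each overlapping gene's regional
expression with the MS change map, and correlates PLS weights with
signed differential-expression values within each selected set.
"""

import json

import pandas as pd

from common import RESULTS, WORKDIR, ensure

ensure("assoc")

report = json.loads((WORKDIR / "assoc" / "overlap_report.json").read_text())
corr = pd.read_csv(WORKDIR / "assoc" / "overlap_gene_map_corr.tsv", sep="\t", index_col=0)
battery = pd.read_csv(WORKDIR / "assoc" / "dge_correlations.tsv", sep="\t")
corr.round(5).to_csv(RESULTS / "06_overlap_gene_map_corr.tsv", sep="\t")
battery.round(5).to_csv(RESULTS / "06_dge_correlations.tsv", sep="\t", index=False)

print(f"{report['n_overlap']} of {report['n_pls1_genes']} PLS1 genes overlap the "
      f"curated disease list ({report['n_disease_genes_in_background']} in background)")
if len(corr):
    print("each overlapping gene's expression vs the MS change map:")
    print(corr[["r", "p", "q"]].round(3).to_string())
print("PLS weight vs differential-expression value, per selected set and direction:")
print(battery.to_string(index=False))
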