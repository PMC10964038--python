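"""Link the regional t-map to gene expression with PLS.

PLS1 is the linear combination of gene expression profiles maximally
covarying with the t-map. Its significance comes from a spherical-
rotation spin test (preserving spatial autocorrelation); per-gene
reliability from bootstrap Z-scores (region resampling, sign-aligned
replicates), thresholded into the PLS1+ / PLS1- gene sets.
"""

import json

import pandas as pd

from common import RESULTS, WORKDIR, ensure

ensure("pls")

result = json.loads((WORKDIR / "pls" / "pls_result.json").read_text())
ztab = pd.read_csv(WORKDIR / "pls" / "gene_z.tsv", sep="\t", index_col=0)
top = ztab.reindex(ztab["z"].abs().sort_values(ascending=False).index).head(20)
top.round(4).to_csv(RESULTS / "05_pls_top_genes.tsv", sep="\t")
(RESULTS / "05_pls_summary.json").write_text(json.dumps(result, indent=2) + "\n")

v1, v2 = result["component_variance"]
print(f"PLS1 explains {100 * v1:.1f}% of t-map variance (PLS2: {100 * v2:.1f}%)")
print(f"spin test ({result['n_rotations']} rotations): p = {result['spin_p']:.4g}")
print(f"PLS1 scores vs t-map: r = {result['r_scores_vs_t']:.2f}")
print(f"gene sets at |Z| > 5 and q < 0.05: {result['n_pls1_plus']} PLS1+, "
      f"{result['n_pls1_minus']} PLS1-")
print("top |Z| genes written to results/05_pls_top_genes.tsv")
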