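"""Characterize the PLS1 gene sets: cell types and pathways.

Cell-type assignment uses the permutation test (random same-size queries
from the background); pathway over-representation uses the one-sided
hypergeometric test, with the top terms of the PLS1- list compared
against those of the curated disease list.
"""

import pandas as pd

from common import RESULTS, WORKDIR, ensure

ensure("enrich")

for label in ("minus", "plus"):
    path = WORKDIR / "enrich" / f"celltype_pls1_{label}.tsv"
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.to_csv(RESULTS / f"07_celltype_pls1_{label}.tsv", sep="\t")
    if len(table):
        print(f"PLS1{'-' if label == 'minus' else '+'} cell-type assignment:")
        print(table[["overlap", "p", "q"]].round(4).to_string())

ora = pd.read_csv(WORKDIR / "enrich" / "ora_pls1_minus.tsv", sep="\t", index_col=0)
shared = pd.read_csv(WORKDIR / "enrich" / "shared_terms.tsv", sep="\t", index_col=0)
ora.to_csv(RESULTS / "07_ora_pls1_minus.tsv", sep="\t")
shared.to_csv(RESULTS / "07_shared_terms.tsv", sep="\t")
print(f"\n{len(shared)} of the top-10 ORA terms are shared between the PLS1- genes "
      "and the curated disease list")
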