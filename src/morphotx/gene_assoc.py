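"""Associations between PLS1 genes, curated disease lists and post-mortem
differential expression.

Gene symbols are matched exactly after uppercasing (no alias expansion);
all correlation batteries computed in one call share a single BH FDR
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .casecontrol import fdr_bh

logger = logging.getLogger(__name__)


def _upper(genes) -> list[str]:
    return [str(g).upper() for g in genes]


@dataclass
class OverlapReport:
    """Result of intersecting a query and reference list within a background."""

    query_name: str
    reference_name: str
    overlap: list[str]
    n_query_in_background: int
    n_reference_in_background: int


def overlap_genes(
    query,
    reference,
    background,
    query_name: str = "query",
    reference_name: str = "reference",
) -> OverlapReport:
    """Intersect two gene lists after restricting both to a background universe."""
    bg = set(_upper(background))
    if not bg:
        raise ValueError("background gene universe is empty")
    q = [g for g in dict.fromkeys(_upper(query)) if g in bg]
    ref = set(_upper(reference)) & bg
    overlap = sorted(g for g in q if g in ref)
    return OverlapReport(
        query_name=query_name,
        reference_name=reference_name,
        overlap=overlap,
        n_query_in_background=len(q),
        n_reference_in_background=len(ref),
    )


def gene_map_correlation(
    genes, expression: pd.DataFrame, delta_map: pd.Series, q_level: float = 0.05
) -> pd.DataFrame:
    """Correlate each gene's regional expression with the MS-change map.

    Pearson r per gene between its expression profile and ``delta_map``
    (aligned on regions); BH q computed jointly across the genes tested
    in this call. A gene absent from the matrix raises, naming it.
    """
    upper_cols = {str(c).upper(): c for c in expression.columns}
    delta = delta_map.reindex(expression.index)
    if delta.isna().any():
        raise ValueError("delta map and expression regions are not aligned")
    rows = []
    for g in genes:
        key = str(g).upper()
        if key not in upper_cols:
            raise KeyError(f"gene {g} absent from expression matrix")
        r, p = stats.pearsonr(expression[upper_cols[key]].to_numpy(), delta.to_numpy())
        rows.append({"gene_id": key, "r": r, "p": max(p, np.finfo(float).tiny)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"], out["significant"] = fdr_bh(out["p"].to_numpy(), q_level)
    return out.set_index("gene_id")


def weights_vs_dge(
    z_table: pd.DataFrame,
    deg: pd.DataFrame,
    direction: str | None = None,
    use_z: bool = True,
    min_overlap: int = 3,
) -> dict:
    """Correlate PLS1 gene weights with differential-expression values.

    ``deg`` carries columns gene_id, value and optionally direction
    ("up"/"down"); when ``direction`` is given the table is filtered to
    it first. The correlation uses bootstrap Z-scores by default
    (``use_z=False`` uses raw weights). Overlaps below ``min_overlap``
    are flagged without reporting a correlation.
    """
    table = deg
    if direction is not None:
        table = deg[deg["direction"] == direction]
    values = pd.Series(
        table["value"].to_numpy(), index=_upper(table["gene_id"])
    )
    weights = pd.Series(
        (z_table["z"] if use_z else z_table["weight"]).to_numpy(),
        index=_upper(z_table.index),
    )
    common = [g for g in weights.index if g in values.index]
    result = {"direction": direction, "n_overlap": len(common), "statistic": "z" if use_z else "weight"}
    if len(common) < min_overlap:
        result.update({"flag": "insufficient overlap", "r": None, "p": None})
        return result
    r, p = stats.pearsonr(weights.loc[common].to_numpy(), values.loc[common].to_numpy())
    result.update({"r": float(r), "p": float(p)})
    return result


def dge_battery(
    z_table: pd.DataFrame, deg_tables: dict[str, pd.DataFrame], q_level: float = 0.05, **kw
) -> pd.DataFrame:
    """Run weights_vs_dge over several (name, table) comparisons with joint FDR."""
    rows = []
    for name, table in deg_tables.items():
        for direction in ("up", "down"):
            res = weights_vs_dge(z_table, table, direction=direction, **kw)
            res["comparison"] = name
            rows.append(res)
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    if tested.any():
        q = np.full(len(out), np.nan)
        q[tested.to_numpy()], _ = fdr_bh(out.loc[tested, "p"].to_numpy(), q_level)
        out["q"] = q
    return out
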