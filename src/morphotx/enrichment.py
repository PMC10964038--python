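"""Gene-set enrichment: permutation cell-type assignment and hypergeometric
over-representation analysis (ORA).

The cell-type test follows the permutation scheme standard for cortical
cell-class assignment: the observed overlap of the query with each set is
compared against overlaps of random same-size queries drawn from the
background without replacement. The ORA is a one-sided hypergeometric
tail test with fold enrichment, applied to arbitrary GMT term sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .casecontrol import fdr_bh

logger = logging.getLogger(__name__)


def _upper(genes) -> list[str]:
    return [str(g).upper() for g in genes]


def celltype_enrichment(
    query,
    cell_sets: dict[str, list[str]],
    background,
    n_perm: int = 10000,
    seed: int = 0,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Permutation over-representation of a query in each cell-type set.

    Query genes absent from the background are dropped (logged). Each
    cell set is intersected with the background before testing. The null
    draws ``n_perm`` random gene sets of the query's size from the
    background without replacement; p = (1 + #{null >= observed}) /
    (1 + n_perm), BH-adjusted across sets.
    """
    bg = sorted(dict.fromkeys(_upper(background)))
    bg_index = {g: i for i, g in enumerate(bg)}
    q_all = list(dict.fromkeys(_upper(query)))
    q_in = [g for g in q_all if g in bg_index]
    dropped = len(q_all) - len(q_in)
    if dropped:
        logger.info("%d query genes absent from background were dropped", dropped)
    if len(q_in) > len(bg):
        raise ValueError("query larger than background")
    if not q_in:
        raise ValueError("no query genes remain within the background")

    membership = {}
    for name, genes in cell_sets.items():
        mask = np.zeros(len(bg), dtype=bool)
        for g in _upper(genes):
            if g in bg_index:
                mask[bg_index[g]] = True
        membership[name] = mask

    q_mask = np.zeros(len(bg), dtype=bool)
    for g in q_in:
        q_mask[bg_index[g]] = True

    rng = np.random.default_rng(seed)
    k = len(q_in)
    keys = rng.random((n_perm, len(bg)))
    null_idx = np.argpartition(keys, k - 1, axis=1)[:, :k]  # n_perm random k-subsets

    rows = []
    for name, mask in membership.items():
        observed = int(np.sum(q_mask & mask))
        null = mask[null_idx].sum(axis=1)
        p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
        overlapping = sorted(np.array(bg)[q_mask & mask])
        rows.append(
            {"cell_type": name, "n_set": int(mask.sum()), "overlap": observed,
             "p": p, "genes": ";".join(overlapping)}
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"], out["significant"] = fdr_bh(out["p"].to_numpy(), q_level)
    return out


def ora_hypergeometric(
    query,
    term_sets: dict[str, list[str]],
    background,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term set.

    p = P(overlap >= observed) under random sampling of |query| genes
    from the background; fold enrichment = (overlap/|query|) /
    (|term|/|background|). Terms disjoint from the background are
    skipped with a log entry; BH q across tested terms.
    """
    bg = set(_upper(background))
    if not bg:
        raise ValueError("background gene universe is empty")
    q = set(_upper(query)) & bg
    if not q:
        raise ValueError("no query genes remain within the background")
    m_total = len(bg)
    rows = []
    for name, genes in term_sets.items():
        term = set(_upper(genes)) & bg
        if not term:
            logger.warning("term %s is disjoint from the background; skipped", name)
            continue
        observed = len(q & term)
        p = float(stats.hypergeom.sf(observed - 1, m_total, len(term), len(q)))
        fold = (observed / len(q)) / (len(term) / m_total)
        rows.append(
            {"term": name, "n_term": len(term), "overlap": observed,
             "p": min(max(p, np.finfo(float).tiny), 1.0), "fold_enrichment": fold,
             "genes": ";".join(sorted(q & term))}
        )
    out = pd.DataFrame(rows).set_index("term")
    out["q"], out["significant"] = fdr_bh(out["p"].to_numpy(), q_level)
    return out


def multilist_shared_terms(
    results_a: pd.DataFrame, results_b: pd.DataFrame, top_k: int = 10
) -> pd.DataFrame:
    """Terms shared between the top-k (by p) of two ORA result tables.

    Both result sets must have been computed against the same term
    universe. Ties in p break by term name for determinism.
    """
    if set(results_a.index) != set(results_b.index):
        raise ValueError("ORA results come from different term universes")

    def top(res: pd.DataFrame) -> list[str]:
        ordered = res.assign(_name=res.index).sort_values(["p", "_name"])
        return list(ordered.index[:top_k])

    shared = sorted(set(top(results_a)) & set(top(results_b)))
    return pd.DataFrame(
        {
            "term": shared,
            "p_a": [results_a.loc[t, "p"] for t in shared],
            "p_b": [results_b.loc[t, "p"] for t in shared],
        }
    ).set_index("term")
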