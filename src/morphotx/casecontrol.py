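"""Case-control inference on regional MS.

Per region, ordinary least squares of regional MS on an intercept, sex,
age and group (case - control contrast); the group t-statistic with its
two-sided p-value forms the regional t-map, corrected across regions by
Benjamini-Hochberg FDR. Also provides the descriptive correlations used
alongside the t-map (mean control MS vs t; MS vs clinical scores).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_SEX_CODE = {"female": 0.0, "male": 1.0}
_GROUP_CODE = {"control": 0.0, "case": 1.0}


def design_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """[1, sex, age, group] design; sex coded female=0/male=1, group case=1."""
    sex = cohort["sex"].map(_SEX_CODE) if cohort["sex"].dtype == object else cohort["sex"]
    group = (
        cohort["group"].map(_GROUP_CODE) if cohort["group"].dtype == object else cohort["group"]
    )
    if sex.isna().any():
        raise ValueError("sex must be 'male'/'female' or numeric 0/1")
    if group.isna().any():
        raise ValueError("group must be 'case'/'control' or numeric 0/1")
    return np.column_stack(
        [np.ones(len(cohort)), sex.to_numpy(float), cohort["age"].to_numpy(float),
         group.to_numpy(float)]
    )


def fit_region_lrm(
    ms_matrix: pd.DataFrame, cohort: pd.DataFrame, q_level: float = 0.05
) -> pd.DataFrame:
    """Per-region linear model MS ~ intercept + sex + age + group.

    ``ms_matrix`` is subjects x regions, aligned to ``cohort.subject_id``.
    Returns a region table with the group coefficient (beta), t-statistic
    (contrast case - control), two-sided p, BH q and significance mask.
    A perfect (zero-residual) fit is reported with the smallest positive
    double as p rather than an infinite t.
    """
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns else cohort
    missing = [s for s in ms_matrix.index if s not in cohort.index]
    if missing:
        raise ValueError(f"subjects missing from cohort table: {missing[:3]}")
    cohort = cohort.loc[ms_matrix.index]
    counts = cohort["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects in each group")
    x = design_matrix(cohort.reset_index())
    n, k = x.shape
    if n <= k:
        raise ValueError(f"need more than {k} subjects, got {n}")
    if np.linalg.matrix_rank(x) < k:
        names = ["intercept", "sex", "age", "group"]
        for j in range(1, k):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
                raise ValueError(f"design matrix is rank deficient: column '{names[j]}' is collinear")
        raise ValueError("design matrix is rank deficient")

    y = ms_matrix.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # k x regions
    resid = y - x @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    tiny = np.finfo(float).tiny
    se = np.sqrt(np.maximum(sigma2, tiny) * xtx_inv[3, 3])
    t = beta[3] / se
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), tiny)
    q, mask = fdr_bh(p, q_level)
    return pd.DataFrame(
        {
            "region_id": ms_matrix.columns,
            "beta": beta[3],
            "t": t,
            "p": p,
            "q": q,
            "significant": mask,
        }
    ).set_index("region_id")


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; returns (q, mask at q_level)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    mask, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def ms_tmap_correlation(mean_control_ms: pd.Series, tmap: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) between mean control MS and the t-map."""
    t = tmap["t"].reindex(mean_control_ms.index)
    if t.isna().any():
        raise ValueError("t-map and control MS regions are not aligned")
    if len(t) < 3:
        raise ValueError("need at least 3 regions")
    r, p = stats.pearsonr(mean_control_ms.to_numpy(), t.to_numpy())
    return float(r), float(p)


def clinical_correlations(
    ms_values: pd.DataFrame, clinical: pd.DataFrame, q_level: float = 0.05
) -> pd.DataFrame:
    """Pearson correlations between regional MS and clinical scores.

    ``ms_values`` is subjects x selected regions, ``clinical`` subjects x
    scores (aligned on index). Constant or <3-complete-pair scores are
    skipped with a log entry; BH q is computed jointly across all tested
    (region, score) pairs.
    """
    clinical = clinical.reindex(ms_values.index)
    rows = []
    for score in clinical.columns:
        c = clinical[score]
        for region in ms_values.columns:
            pair = pd.concat([ms_values[region], c], axis=1).dropna()
            if len(pair) < 3:
                logger.warning("skipping %s vs %s: <3 complete pairs", region, score)
                continue
            if pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
                logger.warning("skipping %s vs %s: constant values", region, score)
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"region_id": region, "score": score, "r": r,
                         "p": max(p, np.finfo(float).tiny)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"], out["significant"] = fdr_bh(out["p"].to_numpy(), q_level)
    return out
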