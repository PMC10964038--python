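"""Individual morphometric similarity networks (MSN).

A subject's MSN is the region x region matrix of Pearson correlations
between z-normalized multi-feature anatomical profiles; a region's MS
strength is the mean of its off-diagonal similarities. No thresholding is
applied anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def znormalize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each feature column across regions (sample SD, ddof=1).

    Raises ``ValueError`` naming the feature if a column is constant.
    """
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    if len(features) < 3:
        raise ValueError("need at least 3 regions")
    sd = features.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant feature: {constant.index[0]}")
    return (features - features.mean(axis=0)) / sd


def build_msn(features: pd.DataFrame) -> pd.DataFrame:
    """Build a subject's MSN from a z-normalized region x feature table.

    Entry (i, j) is the Pearson correlation between region i's and region
    j's feature vectors; the diagonal is set to 1 and no thresholding is
    applied. A region whose normalized feature vector has zero variance
    (all features identical) has undefined similarity and raises.
    """
    values = features.to_numpy(dtype=float)
    row_sd = values.std(axis=1)
    degenerate = np.flatnonzero(row_sd == 0)
    if degenerate.size:
        raise ValueError(
            f"region {features.index[degenerate[0]]} has a zero-variance feature vector"
        )
    corr = np.corrcoef(values)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=features.index, columns=features.index)


def regional_ms(network: pd.DataFrame) -> pd.Series:
    """Regional MS strength: mean of each region's off-diagonal entries.

    The mean convention is used (sum / (n - 1)); the sum convention
    differs by the constant factor n - 1 and leaves every downstream
    t-statistic unchanged.
    """
    a = network.to_numpy(dtype=float)
    n = a.shape[0]
    strengths = (a.sum(axis=1) - np.diag(a)) / (n - 1)
    return pd.Series(strengths, index=network.index, name="ms")


def subject_ms_matrix(features: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Regional MS for a whole cohort: subjects x regions DataFrame."""
    rows = {}
    for sid, table in features.items():
        rows[sid] = regional_ms(build_msn(znormalize_features(table)))
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out
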