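"""Microarray-style expression preprocessing into a region x gene matrix.

Emulates the standard post-mortem atlas workflow on tabular input that is
already keyed by region: background filtering of probes, representative
probe selection per gene (best correlation with an RNA-seq-like
reference), scaled-robust-sigmoid normalization of each gene's regional
profile, and a differential-stability filter across donors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

from .synth import ProbeData

logger = logging.getLogger(__name__)


def filter_probes_background(probes: ProbeData, min_fraction: float = 0.5) -> ProbeData:
    """Keep probes whose above-background sample fraction >= min_fraction."""
    frac = probes.flags.mean(axis=1)
    keep = frac[frac >= min_fraction].index
    return ProbeData(
        intensities=probes.intensities.loc[keep],
        flags=probes.flags.loc[keep],
        gene_map=probes.gene_map.loc[keep],
    )


def select_representative_probe(probes: ProbeData, reference: pd.DataFrame) -> pd.DataFrame:
    """Pick, per gene, the probe best correlated with the gene's reference.

    ``reference`` is gene x sample (an RNA-seq stand-in on the same
    samples/regions). Ties break by lexicographic probe id. Genes with no
    surviving probes are dropped with a log entry. Returns region x gene.
    """
    samples = probes.intensities.columns
    ref = reference[samples]
    chosen: dict[str, str] = {}
    for gene, group in probes.gene_map.groupby(probes.gene_map):
        if gene not in ref.index:
            logger.warning("gene %s absent from reference; dropped", gene)
            continue
        r_vals = ref.loc[gene].to_numpy(dtype=float)
        best_pid, best_r = None, -np.inf
        for pid in sorted(group.index):  # lexicographic tie-break
            x = probes.intensities.loc[pid].to_numpy(dtype=float)
            if x.std() == 0 or r_vals.std() == 0:
                r = -np.inf
            else:
                r = float(np.corrcoef(x, r_vals)[0, 1])
            if r > best_r:
                best_pid, best_r = pid, r
        if best_pid is not None:
            chosen[gene] = best_pid
    dropped = set(reference.index) - set(chosen)
    if dropped:
        logger.info("%d genes had no surviving probes", len(dropped))
    matrix = probes.intensities.loc[[chosen[g] for g in sorted(chosen)]].T
    matrix.columns = sorted(chosen)
    matrix.index.name = "region_id"
    matrix.columns.name = "gene_id"
    return matrix


def srs_normalize(values) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median) / (IQR / 1.35)) -> [0, 1].

    IQR/1.35 approximates the SD for Gaussian data, making the transform
    robust to outliers while preserving order exactly. The sigmoid output
    is min-max rescaled to the unit interval. Raises for <3 values or
    zero IQR.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("zero IQR; cannot normalize")
    s = expit((x - np.median(x)) / (iqr / 1.35))
    return (s - s.min()) / (s.max() - s.min())


def srs_normalize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """SRS-normalize each gene column; zero-IQR genes dropped and logged."""
    cols = {}
    for gene in matrix.columns:
        try:
            cols[gene] = srs_normalize(matrix[gene].to_numpy())
        except ValueError:
            logger.warning("gene %s dropped during normalization (zero IQR)", gene)
    return pd.DataFrame(cols, index=matrix.index)


def filter_inconsistent_genes(
    donor_matrices: list[pd.DataFrame], stability_threshold: float = 0.3
) -> list[str]:
    """Differential-stability filter across donors.

    A gene's stability is the mean Pearson correlation of its regional
    profile across all donor pairs; genes at or above the threshold are
    retained. Requires >= 2 donor-level region x gene matrices sharing
    regions.
    """
    if len(donor_matrices) < 2:
        raise ValueError("need at least 2 donors for the stability filter")
    common = donor_matrices[0].columns
    for m in donor_matrices[1:]:
        common = common.intersection(m.columns)
    regions = donor_matrices[0].index
    kept = []
    arrs = [m.loc[regions, common].to_numpy(dtype=float) for m in donor_matrices]
    n_d = len(arrs)
    for j, gene in enumerate(common):
        rs = []
        for a in range(n_d):
            for b in range(a + 1, n_d):
                xa, xb = arrs[a][:, j], arrs[b][:, j]
                if xa.std() == 0 or xb.std() == 0:
                    rs.append(0.0)
                else:
                    rs.append(float(np.corrcoef(xa, xb)[0, 1]))
        if float(np.mean(rs)) >= stability_threshold:
            kept.append(gene)
    return kept


def preprocess_expression(
    donors: list[ProbeData],
    reference: pd.DataFrame,
    min_fraction: float = 0.5,
    stability_threshold: float = 0.3,
) -> tuple[pd.DataFrame, list[str]]:
    """Full probe-to-matrix preprocessing.

    Per donor: background-filter probes, select the representative probe
    per gene, SRS-normalize each gene's regional profile. Across donors:
    apply the differential-stability filter, then average donors. Returns
    (region x gene matrix in [0, 1], retained gene universe).
    """
    per_donor = []
    for d in donors:
        filtered = filter_probes_background(d, min_fraction)
        matrix = select_representative_probe(filtered, reference)
        per_donor.append(srs_normalize_matrix(matrix))
    universe = filter_inconsistent_genes(per_donor, stability_threshold)
    stacked = np.mean([m[universe].to_numpy() for m in per_donor], axis=0)
    combined = pd.DataFrame(stacked, index=per_donor[0].index, columns=universe)
    combined.index.name = "region_id"
    return combined, universe
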