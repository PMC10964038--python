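"""Synthetic data generator for the imaging-transcriptomics analysis.

Everything the pipeline consumes can be generated here with the statistical
structure the downstream methods assume: a two-group cohort with a planted
regional morphometric-similarity effect, spatially autocorrelated regional
gene expression with a causal gene subset tracking the effect map, parcel
centroids on a hemispheric sphere, microarray-like probe tables, and
cell-type / annotation gene sets with planted over-representation.

The generative model, briefly:

* Parcel centroids are a Fibonacci lattice on one hemisphere of the unit
  sphere.
* The regional mean feature matrix is a skewed "archetype gradient"
  plus smooth residual fields: ``M[r] = a_r * g + 0.6 * f_r`` where
  ``g`` is a fixed feature contrast, ``a`` a skewed smooth scalar field
  (scale ``hub_strength``), and each residual feature field a
  unit-variance Gaussian random field with squared-exponential
  covariance in great-circle distance (length scale
  ``spatial_smoothness``). The skewed low-rank term creates regions
  whose profiles resemble many others (positive regional MS) and
  differentiated regions with negative regional MS — the hub structure
  real morphometric similarity maps show. Subjects add i.i.d. feature
  noise of SD ``noise_sd``.
* Effect regions default to the regions most susceptible to the plant:
  those where a fixed-size profile rotation moves regional MS the most
  (rotation angle squared times baseline MS magnitude). Case subjects
  receive, in each effect region, a norm-preserving rotation of the
  region's profile (displacement ``effect_size * noise_sd``) toward a
  reserved "lesion axis" — a feature contrast projected out of all
  baseline profiles, with signs alternating across effect regions. The
  rotation makes each effect region's profile more idiosyncratic,
  shrinking all its correlations proportionally, so its regional MS
  moves toward zero: hubs lose similarity and anti-hubs gain it, which
  also reproduces the characteristic negative correlation between
  baseline regional MS and the case-control t-map. Sign balancing
  keeps lesion regions from becoming similar to each other and cancels
  column-mean artifacts of the z-normalization step.
* The planted per-region MS change is bookkept as the Monte-Carlo
  expectation of the case-minus-control regional MS difference under
  the full noisy model (a large virtual cohort drawn from an
  independent stream), not from the noiseless profiles, because noise
  attenuation is part of the generative distribution.
* Gene expression profiles are independent smooth fields; causal genes
  are ``sign * (alpha * z(effect_map) + sqrt(1 - alpha^2) * field)`` so
  their profile-map correlation is approximately ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CELL_TYPES, FEATURE_NAMES, SimulationConfig

logger = logging.getLogger(__name__)

#: Cell-type set planted with causal-gene over-representation.
ENRICHED_CELL_TYPE = "Excitatory_neurons"

_GP_JITTER = 1e-8


def region_ids(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Geometry


def hemisphere_centroids(n_regions: int) -> pd.DataFrame:
    """Parcel centroids on one hemisphere's inflated sphere.

    The spherical registration of a single cortical hemisphere covers a
    complete unit sphere, so one hemisphere's parcels tile the whole
    sphere (this closure is what makes rotation-based spatial
    permutations exact). Uses a Fibonacci lattice, which spreads points
    near-uniformly; each returned (x, y, z) has unit norm to within
    1e-12.
    """
    i = np.arange(n_regions)
    z = (2.0 * (i + 0.5) / n_regions) - 1.0
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    coords = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return pd.DataFrame(coords, columns=["x", "y", "z"], index=region_ids(n_regions)).rename_axis("region_id")


def great_circle_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    cosines = np.clip(coords @ coords.T, -1.0, 1.0)
    return np.arccos(cosines)


def gp_cholesky(distances: np.ndarray, length_scale: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential kernel on the sphere.

    ``length_scale`` -> 0 degenerates to the identity (white field).
    """
    if length_scale <= 1e-12:
        return np.eye(distances.shape[0])
    kernel = np.exp(-((distances / length_scale) ** 2))
    kernel[np.diag_indices_from(kernel)] += _GP_JITTER
    return np.linalg.cholesky(kernel)


def smooth_fields(chol: np.ndarray, n_fields: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_fields`` standardized smooth fields (regions x fields)."""
    fields = chol @ rng.standard_normal((chol.shape[0], n_fields))
    fields -= fields.mean(axis=0)
    sd = fields.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return fields / sd


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SimulatedCohort:
    """A simulated case/control anatomical dataset.

    Attributes
    ----------
    cohort
        subject_id, group ("case"/"control"), age (years), sex.
    features
        subject_id -> region x feature DataFrame.
    centroids
        region_id, x, y, z on the unit sphere.
    effect_regions
        0-based indices of the perturbed regions.
    planted_delta
        Noiseless case-minus-control regional MS difference at the effect
        regions, computed from the deterministic part of the model; its
        sign is the planted direction of the effect.
    clinical
        Case-only clinical scores (independent of MS by construction).
    """

    cohort: pd.DataFrame
    features: dict[str, pd.DataFrame]
    centroids: pd.DataFrame
    effect_regions: np.ndarray
    planted_delta: pd.Series
    clinical: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _susceptible_effect_regions(
    config: SimulationConfig,
    base_ms: np.ndarray,
    row_norms: np.ndarray,
    delta_norm: float,
) -> np.ndarray:
    """Regions most susceptible to the decorrelation plant.

    A fixed-size rotation of a region's profile shrinks its correlations
    by roughly ``delta^2 / (2 * |c|^2)``, so its expected regional MS
    change is that factor times the region's baseline MS; selecting the
    top regions by this product makes the planted direction strong and
    well defined, and mirrors the empirical pattern that strongly
    (anti-)connected regions show the largest case-control differences.
    """
    susceptibility = (delta_norm**2 / (2.0 * row_norms**2)) * np.abs(base_ms)
    order = np.argsort(-susceptibility)
    return np.sort(order[: config.n_effect_regions])


def _noiseless_regional_ms(profile: np.ndarray) -> np.ndarray:
    """Regional MS of a noiseless region x feature matrix (internal)."""
    z = (profile - profile.mean(axis=0)) / profile.std(axis=0, ddof=1)
    corr = np.corrcoef(z)
    n = corr.shape[0]
    return (corr.sum(axis=1) - np.diag(corr)) / (n - 1)


#: Virtual subjects per group used to bookkeep the planted MS change.
PLANTED_MC_REPS = 200


def _mc_regional_ms(
    profile: np.ndarray, noise_sd: float, n_reps: int, rng: np.random.Generator,
    chunk: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of regional MS under subject noise (vectorized MC)."""
    n, f = profile.shape
    total = np.zeros(n)
    total_sq = np.zeros(n)
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        x = profile[None, :, :] + rng.standard_normal((k, n, f)) * noise_sd
        x = x - x.mean(axis=1, keepdims=True)
        x = x / x.std(axis=1, ddof=1, keepdims=True)
        w = x - x.mean(axis=2, keepdims=True)
        w = w / np.linalg.norm(w, axis=2, keepdims=True)
        corr = np.einsum("kif,kjf->kij", w, w)
        ms = (corr.sum(axis=2) - 1.0) / (n - 1)
        total += ms.sum(axis=0)
        total_sq += (ms**2).sum(axis=0)
        done += k
    mean = total / n_reps
    var = np.maximum(total_sq / n_reps - mean**2, 0.0)
    return mean, np.sqrt(var)


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Simulate the anatomical arm of the study.

    Controls share a regional mean feature matrix (smooth fields) plus
    subject noise; cases are identical except that the effect regions'
    feature profiles are shifted by magnitude ``effect_size * noise_sd``
    along the direction that shrinks their z-scored profile toward the
    cortical mean. Ages and sexes are drawn from the same distributions
    in both groups (matched by construction). A small, regionally
    varying additive sex effect is included in all subjects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_regions
    centroids = hemisphere_centroids(n)
    coords = centroids.to_numpy()
    dist = great_circle_distances(coords)
    chol = gp_cholesky(dist, config.spatial_smoothness)

    # Skewed archetype gradient (hub structure) + smooth residual fields.
    archetype = rng.standard_normal(config.n_features)
    archetype -= archetype.mean()
    archetype /= np.linalg.norm(archetype)
    gradient = smooth_fields(chol, 1, rng)[:, 0]
    loading = config.hub_strength * (gradient + 0.8 * (gradient**2 - 1.0) / np.sqrt(2.0))
    fields = smooth_fields(chol, config.n_features, rng)
    mean_profile = np.outer(loading, archetype) + 0.6 * fields
    sex_profile = smooth_fields(chol, config.n_features, rng) * (
        config.sex_effect * config.noise_sd
    )

    # Reserved lesion axis: a fixed zero-mean feature contrast projected
    # out of all baseline profiles, so healthy cortex expresses no
    # covariance along it.
    axis = rng.standard_normal(config.n_features)
    axis -= axis.mean()
    axis /= np.linalg.norm(axis)
    for mat in (mean_profile, sex_profile):
        centered = mat - mat.mean(axis=1, keepdims=True)
        mat -= np.outer(centered @ axis, axis)

    delta_norm = config.effect_size * config.noise_sd
    centered = mean_profile - mean_profile.mean(axis=1, keepdims=True)
    row_norms = np.linalg.norm(centered, axis=1)

    base_ms = base_sd = None
    if config.effect_size > 0:
        mc_rng = np.random.default_rng((np.uint32(config.seed) ^ np.uint32(0x5EED)).item())
        base_ms, base_sd = _mc_regional_ms(
            mean_profile, config.noise_sd, PLANTED_MC_REPS, mc_rng
        )

    if config.effect_regions is not None:
        effect_idx = np.asarray(sorted(config.effect_regions), dtype=int)
        for idx in effect_idx:
            if not 0 <= idx < n:
                raise ValueError(f"effect region index {idx} out of range [0, {n})")
    elif config.effect_size > 0:
        effect_idx = _susceptible_effect_regions(config, base_ms, row_norms, delta_norm)
    else:
        # null simulation: no planted effect, any region set serves
        stride = max(1, n // config.n_effect_regions)
        effect_idx = np.arange(0, n, stride)[: config.n_effect_regions]

    # Decorrelation plant: rotate each effect region's row-centered
    # profile toward the lesion axis (signs alternating across effect
    # regions so lesions stay dissimilar from one another and the
    # feature column means are unchanged). The profile norm is
    # preserved, so noise attenuation is untouched; all of the region's
    # correlations shrink by the rotation cosine, moving its regional
    # MS toward zero.
    perturbation = np.zeros_like(mean_profile)
    if config.effect_size > 0:
        for pos, r in enumerate(effect_idx):
            sign = 1.0 if pos % 2 == 0 else -1.0
            c = centered[r]
            norm_c = row_norms[r]
            sin_phi = min(delta_norm / norm_c, 1.0)
            cos_phi = np.sqrt(1.0 - sin_phi**2)
            perturbation[r] = (cos_phi - 1.0) * c + sin_phi * norm_c * sign * axis

    rids = list(centroids.index)
    if len(effect_idx) and config.effect_size > 0:
        # Paired Monte Carlo (common noise draws) for the planted change.
        pair_seed = (np.uint32(config.seed) ^ np.uint32(0xACE5)).item()
        case_ms, _ = _mc_regional_ms(
            mean_profile + perturbation, config.noise_sd, PLANTED_MC_REPS,
            np.random.default_rng(pair_seed),
        )
        ctrl_ms, _ = _mc_regional_ms(
            mean_profile, config.noise_sd, PLANTED_MC_REPS,
            np.random.default_rng(pair_seed),
        )
        planted = (case_ms - ctrl_ms)[effect_idx]
    else:
        planted = np.zeros(len(effect_idx))
    planted_delta = pd.Series(
        planted, index=[rids[i] for i in effect_idx], name="planted_delta"
    )

    n_sub = config.n_pd + config.n_hc
    subject_ids = [f"sub-PD{i + 1:03d}" for i in range(config.n_pd)] + [
        f"sub-HC{i + 1:03d}" for i in range(config.n_hc)
    ]
    groups = ["case"] * config.n_pd + ["control"] * config.n_hc
    ages = np.clip(rng.normal(60.0, 8.0, n_sub), 40.0, 80.0)
    sexes = rng.integers(0, 2, n_sub)  # 0 female, 1 male

    features: dict[str, pd.DataFrame] = {}
    for k, sid in enumerate(subject_ids):
        profile = mean_profile + sexes[k] * sex_profile
        if groups[k] == "case":
            profile = profile + perturbation
        noise = rng.standard_normal((n, config.n_features)) * config.noise_sd
        features[sid] = pd.DataFrame(
            profile + noise, index=pd.Index(rids, name="region_id"),
            columns=list(FEATURE_NAMES[: config.n_features]),
        )

    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "age": ages,
            "sex": np.where(sexes == 1, "male", "female"),
        }
    )

    case_ids = [s for s, g in zip(subject_ids, groups) if g == "case"]
    clinical = pd.DataFrame(
        {
            "subject_id": case_ids,
            "UPDRS3": np.clip(rng.normal(25, 8, len(case_ids)), 5, 60),
            "HY": rng.choice([1.0, 1.5, 2.0, 2.5, 3.0], len(case_ids)),
            "MMSE": np.clip(rng.normal(28, 1.5, len(case_ids)), 20, 30),
            "MoCA": np.clip(rng.normal(26, 2.0, len(case_ids)), 18, 30),
            "HAMD": np.clip(rng.normal(8, 4, len(case_ids)), 0, 30),
            "HAMA": np.clip(rng.normal(7, 4, len(case_ids)), 0, 30),
        }
    )

    return SimulatedCohort(
        cohort=cohort,
        features=features,
        centroids=centroids,
        effect_regions=effect_idx,
        planted_delta=planted_delta,
        clinical=clinical,
        config=config,
    )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig,
    centroids: pd.DataFrame,
    effect_map: pd.Series | np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a region x gene expression matrix with causal genes.

    Each gene's profile is an independent standardized smooth field.
    Causal genes instead get ``sign * (alpha * z(effect_map) +
    sqrt(1 - alpha^2) * field)`` with ``alpha = config.causal_alpha``, so
    their expected correlation with the standardized effect map is
    ``sign * alpha``. Causal signs split half positive / half negative.

    Returns (expression regions x genes, causal table with columns
    gene_id, sign, alpha).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    effect = np.asarray(effect_map, dtype=float)
    if effect.shape[0] != config.n_regions:
        raise ValueError(
            f"effect_map length {effect.shape[0]} != n_regions {config.n_regions}"
        )
    if effect.std() == 0:
        raise ValueError("effect_map is constant; cannot standardize")
    z_map = (effect - effect.mean()) / effect.std(ddof=1)

    coords = centroids.to_numpy()
    dist = great_circle_distances(coords)
    chol = gp_cholesky(dist, config.spatial_smoothness)
    fields = smooth_fields(chol, config.n_genes, rng)

    gids = gene_ids(config.n_genes)
    causal_idx = rng.choice(config.n_genes, size=config.n_causal_genes, replace=False)
    causal_idx = np.sort(causal_idx)
    signs = np.ones(config.n_causal_genes)
    signs[config.n_causal_genes // 2:] = -1.0

    alpha = config.causal_alpha
    expr = fields.copy()
    for s, gi in zip(signs, causal_idx):
        expr[:, gi] = s * (alpha * z_map + np.sqrt(1.0 - alpha**2) * fields[:, gi])

    expression = pd.DataFrame(
        expr, index=pd.Index(list(centroids.index), name="region_id"), columns=gids
    )
    causal = pd.DataFrame(
        {
            "gene_id": [gids[i] for i in causal_idx],
            "sign": signs,
            "alpha": alpha,
        }
    )
    return expression, causal


def expression_distance_profile(
    expression: pd.DataFrame, centroids: pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Empirical spatial correlogram of an expression matrix.

    Bins region pairs by great-circle distance and averages, per bin, the
    across-gene correlation of the two regions' expression profiles. Used
    to assert that generated expression decays with distance.
    """
    coords = centroids.to_numpy()
    dist = great_circle_distances(coords)
    x = expression.to_numpy()
    xz = (x - x.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(xz, axis=1, keepdims=True)
    corr = (xz / norms) @ (xz / norms).T
    iu = np.triu_indices(dist.shape[0], k=1)
    d, c = dist[iu], corr[iu]
    edges = np.linspace(0, d.max() + 1e-9, n_bins + 1)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            rows.append({"bin": b, "distance": d[mask].mean(), "mean_corr": c[mask].mean()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probe-level (microarray-like) data


@dataclass
class ProbeData:
    """One donor's microarray-like probe data, keyed by region.

    ``intensities``: probe x region values; ``flags``: same-shape boolean
    above-background indicators; ``gene_map``: probe_id -> gene_id.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    gene_map: pd.Series


def simulate_probe_data(
    config: SimulationConfig,
    expression: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_donors: int = 2,
    max_probes: int = 3,
    probe_noise_sd: float = 0.2,
    donor_noise_sd: float = 0.2,
    bad_probe_rate: float = 0.15,
) -> tuple[list[ProbeData], pd.DataFrame]:
    """Emulate per-donor probe tables from a true expression matrix.

    Each gene gets 1..max_probes probes; a probe's intensity is the true
    regional profile plus donor- and probe-level noise. "Bad" probes have
    low above-background fractions and inflated noise; every gene keeps at
    least one good probe. Also returns a per-region reference profile per
    gene (an RNA-seq stand-in used for representative-probe selection).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = list(expression.columns)
    regions = expression.index
    n_regions = len(regions)

    probe_rows, gene_of_probe, is_bad = [], [], []
    pid = 0
    for g in genes:
        k = int(rng.integers(1, max_probes + 1))
        bad = rng.random(k) < bad_probe_rate
        bad[int(rng.integers(0, k))] = False  # keep >= 1 good probe
        for j in range(k):
            probe_rows.append(f"P{pid + 1:05d}")
            gene_of_probe.append(g)
            is_bad.append(bool(bad[j]))
            pid += 1
    gene_map = pd.Series(gene_of_probe, index=pd.Index(probe_rows, name="probe_id"),
                         name="gene_id")
    is_bad = np.asarray(is_bad)

    truth = expression.to_numpy()  # regions x genes
    gene_col = {g: i for i, g in enumerate(genes)}
    probe_truth = truth[:, [gene_col[g] for g in gene_of_probe]].T  # probes x regions

    donors = []
    for _ in range(n_donors):
        donor_shift = rng.standard_normal((1, n_regions)) * donor_noise_sd
        noise_scale = np.where(is_bad, 4.0 * probe_noise_sd, probe_noise_sd)[:, None]
        intens = probe_truth + donor_shift + rng.standard_normal(probe_truth.shape) * noise_scale
        frac = np.where(is_bad, rng.uniform(0.0, 0.45, len(is_bad)),
                        rng.uniform(0.6, 1.0, len(is_bad)))
        flags = rng.random(probe_truth.shape) < frac[:, None]
        donors.append(
            ProbeData(
                intensities=pd.DataFrame(intens, index=gene_map.index, columns=regions),
                flags=pd.DataFrame(flags, index=gene_map.index, columns=regions),
                gene_map=gene_map,
            )
        )

    reference = pd.DataFrame(
        (truth + rng.standard_normal(truth.shape) * probe_noise_sd).T,
        index=pd.Index(genes, name="gene_id"), columns=regions,
    )
    return donors, reference


# ---------------------------------------------------------------------------
# Gene sets, disease list, differential expression


def simulate_gene_sets(
    config: SimulationConfig,
    causal: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict:
    """Simulate cell-type sets, pathway sets, a disease list and DEG values.

    One cell-type set (:data:`ENRICHED_CELL_TYPE`) includes each causal
    gene with probability ``min(1, enrichment_ratio * set_size /
    n_genes)``; all other sets are uniform draws. The differential
    expression table carries signed values ``sign * alpha + noise`` with
    noise SD ``alpha / deg_snr`` so values correlate with the planted
    causal weights. The disease list is the causal genes plus random
    extras (a curated-disease-gene stand-in).

    Returns a dict with keys ``cell_sets``, ``pathway_sets`` (name ->
    gene list), ``disease_genes`` (list) and ``deg`` (DataFrame gene_id,
    value, direction).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    universe = np.array(gene_ids(config.n_genes))
    causal_genes = list(causal["gene_id"])
    causal_set = set(causal_genes)
    size = config.cell_set_size
    if size > len(universe):
        raise ValueError("cell set size exceeds gene universe")

    base_rate = size / len(universe)
    p_inc = min(1.0, config.enrichment_ratio * base_rate)

    cell_sets: dict[str, list[str]] = {}
    for name in CELL_TYPES:
        if name == ENRICHED_CELL_TYPE:
            members = [g for g in causal_genes if rng.random() < p_inc]
            pool = np.array([g for g in universe if g not in causal_set])
            fill = rng.choice(pool, size=size - len(members), replace=False)
            cell_sets[name] = sorted(members + list(fill))
        else:
            cell_sets[name] = sorted(rng.choice(universe, size=size, replace=False))

    lo = max(2, min(15, len(universe) // 3))
    hi = max(lo + 1, min(60, len(universe)))
    pathway_sets = {
        f"PATHWAY_{k + 1:02d}": sorted(
            rng.choice(universe, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        for k in range(config.n_pathway_sets)
    }

    pool = np.array([g for g in universe if g not in causal_set])
    n_extra = min(max(0, 30 - len(causal_genes)), len(pool))
    disease = sorted(causal_genes + list(rng.choice(pool, size=n_extra, replace=False)))

    alpha = float(causal["alpha"].iloc[0]) if len(causal) else config.causal_alpha
    noise_sd = alpha / config.deg_snr if config.deg_snr > 0 else 1.0
    values = rng.standard_normal(len(universe)) * noise_sd
    sign_of = dict(zip(causal["gene_id"], causal["sign"]))
    for i, g in enumerate(universe):
        if g in sign_of:
            values[i] += sign_of[g] * alpha
    deg = pd.DataFrame(
        {
            "gene_id": universe,
            "value": values,
            "direction": np.where(values > 0, "up", "down"),
        }
    )
    return {
        "cell_sets": cell_sets,
        "pathway_sets": pathway_sets,
        "disease_genes": disease,
        "deg": deg,
    }


def spatial_autocorrelation_rank(profile: pd.DataFrame) -> float:
    """Spearman rank correlation between distance bin and mean correlation."""
    rho, _ = stats.spearmanr(profile["distance"], profile["mean_corr"])
    return float(rho)
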