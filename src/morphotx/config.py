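"""Configuration objects for the synthetic study and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

#: Anatomical features extracted per cortical region: cortical thickness,
#: gray-matter volume, surface area, Gaussian (intrinsic) curvature, mean
#: curvature, curved index, folding index.
FEATURE_NAMES = ("CT", "GM", "SA", "IC", "MC", "CV", "FD")

#: Canonical cortical cell classes used for cell-type assignment.
CELL_TYPES = (
    "Astrocytes",
    "Endothelial",
    "Microglia",
    "Excitatory_neurons",
    "Inhibitory_neurons",
    "Oligodendrocytes",
    "OPCs",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic imaging-transcriptomics study.

    The defaults define the desk-scale study conditions: one cortical
    hemisphere of 180 parcels with 7 anatomical features per parcel, a
    case/control cohort of 85 + 62 subjects, a 500-gene expression matrix
    with 10 causal genes whose regional profiles track the planted
    morphometric effect at correlation ``causal_alpha``.

    Parameters
    ----------
    n_regions
        Number of cortical parcels (one hemisphere).
    n_features
        Anatomical features per parcel.
    n_pd, n_hc
        Case (patient) and control group sizes.
    n_genes
        Size of the gene expression universe.
    n_causal_genes
        Genes whose spatial profile tracks the planted effect map.
    n_effect_regions
        Size of the spatially contiguous cap of perturbed regions used
        when ``effect_regions`` is not given explicitly.
    effect_regions
        Explicit 0-based region indices to perturb (optional).
    effect_size
        Magnitude of the case-group feature-profile perturbation, in
        units of ``noise_sd`` (dimensionless).
    causal_alpha
        Target correlation between a causal gene's regional expression
        profile and the standardized effect map.
    spatial_smoothness
        Correlation length (radians of great-circle distance) of the
        spatially autocorrelated fields used for features and expression.
    hub_strength
        Scale of the archetype gradient that creates hub regions with
        strong positive (and differentiated regions with negative)
        baseline regional MS; 0 removes the hub structure.
    noise_sd
        Subject-level feature noise SD, relative to the unit-SD regional
        mean feature fields.
    sex_effect
        Scale of the additive, regionally varying sex effect on features
        (units of ``noise_sd``); makes covariate adjustment non-trivial.
    enrichment_ratio
        Over-representation factor of causal genes in the planted
        enriched cell-type set (1 = no enrichment).
    cell_set_size
        Genes per cell-type set.
    n_pathway_sets
        Number of generic annotation ("pathway") sets emitted for ORA.
    deg_snr
        Signal-to-noise ratio of the synthetic differential-expression
        values relative to the planted causal weights.
    seed
        Base random seed for the whole simulation.
    """

    n_regions: int = 180
    n_features: int = len(FEATURE_NAMES)
    n_pd: int = 85
    n_hc: int = 62
    n_genes: int = 500
    n_causal_genes: int = 10
    n_effect_regions: int = 40
    effect_regions: Sequence[int] | None = None
    effect_size: float = 2.0
    causal_alpha: float = 0.7
    spatial_smoothness: float = 0.5
    hub_strength: float = 2.0
    noise_sd: float = 0.5
    sex_effect: float = 0.2
    enrichment_ratio: float = 5.0
    cell_set_size: int = 50
    n_pathway_sets: int = 15
    deg_snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_features", "n_pd", "n_hc", "n_genes",
                     "n_causal_genes", "n_effect_regions", "cell_set_size",
                     "n_pathway_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes exceeds n_genes")
        if self.cell_set_size > self.n_genes:
            raise ValueError("cell_set_size exceeds gene universe")
        if self.noise_sd < 0 or self.spatial_smoothness < 0:
            raise ValueError("noise_sd and spatial_smoothness must be non-negative")
        if not 0.0 <= self.causal_alpha <= 1.0:
            raise ValueError("causal_alpha must be in [0, 1]")
        if self.effect_regions is not None:
            for idx in self.effect_regions:
                if not 0 <= idx < self.n_regions:
                    raise ValueError(
                        f"effect region index {idx} out of range [0, {self.n_regions})"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["effect_regions"] is not None:
            d["effect_regions"] = list(d["effect_regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration.

    Thresholds mirror the analysis defaults: FDR level ``q_level`` for the
    regional t-map and all gene-level batteries, bootstrap-Z cut
    ``z_threshold`` for the PLS1+/PLS1- sets, ``n_rotations`` spherical
    rotations for the spin test, ``n_boot`` bootstrap resamples and
    ``n_perm`` permutations for cell-type enrichment.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    q_level: float = 0.05
    z_threshold: float = 5.0
    n_rotations: int = 199
    n_boot: int = 200
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_level < 1:
            raise ValueError("q_level must be in (0, 1)")
        if self.n_rotations < 99:
            raise ValueError("n_rotations too small for inference (need >= 99)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig.from_dict(sim)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(simulation=sim, **{k: v for k, v in d.items() if k in known})
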