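"""Synthetic-data generator: determinism, planted structure, null fidelity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from morphotx.casecontrol import fit_region_lrm
from morphotx.config import CELL_TYPES, SimulationConfig
from morphotx.msn import subject_ms_matrix
from morphotx.synth import (
    ENRICHED_CELL_TYPE,
    expression_distance_profile,
    gene_ids,
    great_circle_distances,
    hemisphere_centroids,
    simulate_cohort,
    simulate_expression,
    simulate_gene_sets,
    simulate_probe_data,
    spatial_autocorrelation_rank,
)


class TestGeometry:
    def test_centroids_unit_norm_and_unique(self):
        cen = hemisphere_centroids(120)
        norms = np.linalg.norm(cen.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert len(np.unique(np.round(cen.to_numpy(), 6), axis=0)) == 120
        assert cen.index.is_unique

    def test_great_circle_distance_properties(self):
        cen = hemisphere_centroids(30).to_numpy()
        d = great_circle_distances(cen)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-6)
        np.testing.assert_allclose(d, d.T)
        assert d.max() <= np.pi + 1e-9


class TestCohort:
    def test_identical_seed_identical_output(self, tiny_config):
        a = simulate_cohort(tiny_config)
        b = simulate_cohort(tiny_config)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        for sid in a.features:
            pd.testing.assert_frame_equal(a.features[sid], b.features[sid])
        pd.testing.assert_series_equal(a.planted_delta, b.planted_delta)

    def test_structure_and_groups(self, tiny_config):
        sim = simulate_cohort(tiny_config)
        assert len(sim.features) == tiny_config.n_pd + tiny_config.n_hc
        counts = sim.cohort["group"].value_counts()
        assert counts["case"] == tiny_config.n_pd and counts["control"] == tiny_config.n_hc
        assert sim.cohort["subject_id"].is_unique
        assert sim.cohort["age"].between(40, 80).all()
        table = next(iter(sim.features.values()))
        assert table.shape == (tiny_config.n_regions, tiny_config.n_features)

    def test_out_of_range_effect_region_named(self, tiny_config):
        with pytest.raises(ValueError, match="99"):
            replace(tiny_config, effect_regions=(0, 99))

    def test_null_effect_gives_near_zero_discoveries(self, tiny_config):
        cfg = replace(tiny_config, effect_size=0.0, n_pd=15, n_hc=15, seed=21)
        sim = simulate_cohort(cfg)
        ms = subject_ms_matrix(sim.features)
        tmap = fit_region_lrm(ms, sim.cohort)
        assert tmap["significant"].sum() <= 2
        assert np.allclose(sim.planted_delta.to_numpy(), 0.0)

    def test_planted_effect_recovered_in_direction(self):
        cfg = SimulationConfig(n_pd=50, n_hc=50, seed=13)
        sim = simulate_cohort(cfg)
        ms = subject_ms_matrix(sim.features)
        case = sim.cohort.loc[sim.cohort.group == "case", "subject_id"]
        ctrl = sim.cohort.loc[sim.cohort.group == "control", "subject_id"]
        observed = (ms.loc[case].mean() - ms.loc[ctrl].mean())[sim.planted_delta.index]
        signs = np.sign(sim.planted_delta.to_numpy())
        agreement = (np.sign(observed.to_numpy()) == signs).mean()
        assert agreement >= 0.85
        # aggregate comparison in the planted direction
        assert float((observed.to_numpy() * signs).mean()) > 0


class TestExpression:
    def test_causal_profiles_track_effect_map(self, tiny_config, rng):
        cfg = replace(tiny_config, n_regions=180, n_genes=200, n_causal_genes=10)
        centroids = hemisphere_centroids(180)
        effect = rng.standard_normal(180)
        expr, causal = simulate_expression(cfg, centroids, effect, rng=rng)
        z_map = (effect - effect.mean()) / effect.std(ddof=1)
        for _, row in causal.iterrows():
            r = np.corrcoef(expr[row.gene_id], z_map)[0, 1]
            assert abs(r - row.sign * cfg.causal_alpha) < 0.17
        assert set(causal["sign"]) == {1.0, -1.0}

    def test_noncausal_profiles_independent_of_map(self, tiny_config, rng):
        centroids = hemisphere_centroids(tiny_config.n_regions)
        effect = rng.standard_normal(tiny_config.n_regions)
        expr, causal = simulate_expression(tiny_config, centroids, effect, rng=rng)
        others = [g for g in expr.columns if g not in set(causal.gene_id)]
        rs = [np.corrcoef(expr[g], effect)[0, 1] for g in others]
        assert abs(np.mean(rs)) < 0.15

    def test_spatial_autocorrelation_decays(self, rng):
        cfg = SimulationConfig(n_regions=120, n_genes=150, seed=5)
        centroids = hemisphere_centroids(120)
        expr, _ = simulate_expression(cfg, centroids, rng.standard_normal(120), rng=rng)
        profile = expression_distance_profile(expr, centroids)
        assert spatial_autocorrelation_rank(profile) < -0.5
        assert profile["mean_corr"].iloc[0] > 0.2

    def test_no_autocorrelation_limit(self, rng):
        cfg = SimulationConfig(n_regions=120, n_genes=150, spatial_smoothness=0.0, seed=5)
        centroids = hemisphere_centroids(120)
        expr, _ = simulate_expression(cfg, centroids, rng.standard_normal(120), rng=rng)
        profile = expression_distance_profile(expr, centroids)
        assert profile["mean_corr"].abs().max() < 0.1

    def test_input_validation(self, tiny_config, rng):
        centroids = hemisphere_centroids(tiny_config.n_regions)
        with pytest.raises(ValueError, match="length"):
            simulate_expression(tiny_config, centroids, np.ones(3), rng=rng)
        with pytest.raises(ValueError, match="constant"):
            simulate_expression(tiny_config, centroids,
                                np.ones(tiny_config.n_regions), rng=rng)


class TestProbeData:
    def test_probe_tables_consistent(self, tiny_config, rng):
        centroids = hemisphere_centroids(tiny_config.n_regions)
        expr, _ = simulate_expression(tiny_config, centroids,
                                      rng.standard_normal(tiny_config.n_regions), rng=rng)
        donors, reference = simulate_probe_data(tiny_config, expr, rng=rng)
        assert len(donors) == 2
        for d in donors:
            assert d.intensities.shape == d.flags.shape
            assert d.gene_map.index.equals(d.intensities.index)
            # each gene keeps at least one high-quality probe
            frac = d.flags.mean(axis=1)
            assert d.gene_map[frac >= 0.5].nunique() == tiny_config.n_genes
        assert reference.shape == (tiny_config.n_genes, tiny_config.n_regions)


class TestGeneSets:
    def _causal(self, cfg, rng):
        genes = sorted(rng.choice(gene_ids(cfg.n_genes), cfg.n_causal_genes, replace=False))
        signs = np.ones(len(genes))
        signs[len(genes) // 2:] = -1
        return pd.DataFrame({"gene_id": genes, "sign": signs, "alpha": cfg.causal_alpha})

    def test_set_inventory(self, tiny_config, rng):
        causal = self._causal(tiny_config, rng)
        sets = simulate_gene_sets(tiny_config, causal, rng=rng)
        assert set(sets["cell_sets"]) == set(CELL_TYPES)
        for genes in sets["cell_sets"].values():
            assert len(genes) == tiny_config.cell_set_size
            assert len(set(genes)) == len(genes)
        assert len(sets["deg"]) == tiny_config.n_genes
        assert set(causal["gene_id"]) <= set(sets["disease_genes"])

    def test_planted_enrichment_concentrates_causal_genes(self, rng):
        cfg = SimulationConfig(n_genes=500, n_causal_genes=40, cell_set_size=50,
                               enrichment_ratio=5.0, seed=3)
        causal = self._causal(cfg, rng)
        counts = []
        for rep in range(30):
            sets = simulate_gene_sets(cfg, causal, rng=np.random.default_rng(rep))
            enriched = len(set(sets["cell_sets"][ENRICHED_CELL_TYPE]) & set(causal.gene_id))
            others = np.mean([
                len(set(sets["cell_sets"][c]) & set(causal.gene_id))
                for c in CELL_TYPES if c != ENRICHED_CELL_TYPE
            ])
            counts.append((enriched, others))
        enriched_mean = np.mean([c[0] for c in counts])
        other_mean = np.mean([c[1] for c in counts])
        assert enriched_mean > 3.5 * other_mean  # ~5x planted over-representation

    def test_deg_values_track_planted_signs(self, tiny_config, rng):
        causal = self._causal(tiny_config, rng)
        sets = simulate_gene_sets(tiny_config, causal, rng=rng)
        deg = sets["deg"].set_index("gene_id")
        causal_vals = deg.loc[causal.gene_id, "value"].to_numpy()
        assert np.corrcoef(causal_vals, causal["sign"] * causal["alpha"])[0, 1] > 0.3
        assert set(deg["direction"]) <= {"up", "down"}

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError, match="cell_set_size"):
            SimulationConfig(n_genes=10, cell_set_size=20)
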