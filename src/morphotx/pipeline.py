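"""End-to-end orchestration of the synthetic imaging-transcriptomics run.

Stages run in dependency order, each reading its inputs from the files
the previous stage wrote (which makes every stage idempotent and the run
resumable), and a manifest records the seed, a config hash and a sha256
checksum of every artifact.

Stage order: simulate -> msn -> casecontrol -> expression -> pls ->
assoc -> enrich.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .casecontrol import (
    clinical_correlations,
    fdr_bh,
    fit_region_lrm,
    ms_tmap_correlation,
)
from .config import RunConfig
from .enrichment import celltype_enrichment, multilist_shared_terms, ora_hypergeometric
from .expression import preprocess_expression
from .gene_assoc import gene_map_correlation, overlap_genes, weights_vs_dge
from .msn import subject_ms_matrix
from .pls import (
    bootstrap_gene_z,
    extract_pls_gene_sets,
    pls_first_component,
    spin_test_pls,
    weights_tmap_correlation,
)
from .synth import (
    simulate_cohort,
    simulate_expression,
    simulate_gene_sets,
    simulate_probe_data,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "msn", "casecontrol", "expression", "pls", "assoc", "enrich")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    sim = config.simulation
    data = out / "data"
    feat_dir = data / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(sim)
    files = []
    for sid, table in cohort.features.items():
        path = feat_dir / f"{sid}.tsv"
        io.write_features_tsv(table, path)
        files.append(path)
    io.write_cohort_csv(cohort.cohort, data / "cohort.csv")
    io.write_centroids_csv(cohort.centroids, data / "centroids.csv")
    cohort.clinical.to_csv(data / "clinical.csv", index=False, float_format=io.FLOAT_FORMAT)
    io.write_json(
        {
            "seed": sim.seed,
            "effect_regions": [int(i) for i in cohort.effect_regions],
            "planted_delta": {k: float(v) for k, v in cohort.planted_delta.items()},
            "note": "synthetic ground truth (not an input to the analysis stages)",
        },
        data / "truth_cohort.json",
    )
    return files + [data / "cohort.csv", data / "centroids.csv", data / "clinical.csv",
                    data / "truth_cohort.json"]


def _stage_msn(config: RunConfig, out: Path) -> list[Path]:
    data = out / "data"
    feat_dir = data / "features"
    features = {
        p.stem: io.read_features_tsv(p) for p in sorted(feat_dir.glob("*.tsv"))
    }
    ms = subject_ms_matrix(features)
    msn_dir = out / "msn"
    msn_dir.mkdir(exist_ok=True)
    io.write_matrix_tsv(ms, msn_dir / "regional_ms.tsv")
    cohort = io.read_cohort_csv(data / "cohort.csv").set_index("subject_id")
    means = ms.groupby(cohort.loc[ms.index, "group"]).mean().T
    means.index.name = "region_id"
    io.write_matrix_tsv(means, msn_dir / "group_mean_ms.tsv")
    return [msn_dir / "regional_ms.tsv", msn_dir / "group_mean_ms.tsv"]


def _stage_casecontrol(config: RunConfig, out: Path) -> list[Path]:
    data = out / "data"
    ms = io.read_matrix_tsv(out / "msn" / "regional_ms.tsv")
    cohort = io.read_cohort_csv(data / "cohort.csv")
    tmap = fit_region_lrm(ms, cohort, q_level=config.q_level)
    cc_dir = out / "casecontrol"
    cc_dir.mkdir(exist_ok=True)
    io.write_tmap_tsv(tmap, cc_dir / "tmap.tsv")

    means = io.read_matrix_tsv(out / "msn" / "group_mean_ms.tsv")
    delta = (means["case"] - means["control"]).rename("delta_ms")
    io.write_matrix_tsv(delta.to_frame(), cc_dir / "delta_map.tsv")
    r, p = ms_tmap_correlation(means["control"], tmap)

    clinical = pd.read_csv(data / "clinical.csv").set_index("subject_id")
    sig_regions = list(tmap.index[tmap["significant"]])
    clin_table = pd.DataFrame()
    if sig_regions:
        case_ids = [s for s in ms.index if s in clinical.index]
        clin_table = clinical_correlations(
            ms.loc[case_ids, sig_regions], clinical.loc[case_ids], q_level=config.q_level
        )
    clin_table.to_csv(cc_dir / "clinical_correlations.tsv", sep="\t", index=False,
                      float_format=io.FLOAT_FORMAT)
    io.write_json(
        {
            "seed": config.seed,
            "n_regions": int(len(tmap)),
            "n_significant": int(tmap["significant"].sum()),
            "n_increased": int((tmap["significant"] & (tmap["t"] > 0)).sum()),
            "n_decreased": int((tmap["significant"] & (tmap["t"] < 0)).sum()),
            "r_control_ms_vs_t": r,
            "p_control_ms_vs_t": p,
            "n_significant_clinical": int(clin_table["significant"].sum()) if len(clin_table) else 0,
        },
        cc_dir / "summary.json",
    )
    return [cc_dir / "tmap.tsv", cc_dir / "delta_map.tsv",
            cc_dir / "clinical_correlations.tsv", cc_dir / "summary.json"]


def _stage_expression(config: RunConfig, out: Path) -> list[Path]:
    sim = config.simulation
    centroids = io.read_centroids_csv(out / "data" / "centroids.csv")
    delta = io.read_matrix_tsv(out / "casecontrol" / "delta_map.tsv")["delta_ms"]
    rng = np.random.default_rng(sim.seed + 1)
    truth, causal = simulate_expression(sim, centroids, delta.to_numpy(), rng=rng)
    donors, reference = simulate_probe_data(sim, truth, rng=rng)
    matrix, universe = preprocess_expression(donors, reference)
    ex_dir = out / "expression"
    ex_dir.mkdir(exist_ok=True)
    io.write_matrix_tsv(matrix, ex_dir / "expression.tsv")
    io.write_gene_list(universe, ex_dir / "universe.txt")
    causal.to_csv(ex_dir / "truth_causal_genes.tsv", sep="\t", index=False,
                  float_format=io.FLOAT_FORMAT)

    sets = simulate_gene_sets(sim, causal, rng=np.random.default_rng(sim.seed + 3))
    io.write_gmt(sets["cell_sets"], ex_dir / "cell_types.gmt")
    io.write_gmt(sets["pathway_sets"], ex_dir / "pathways.gmt")
    io.write_gene_list(sets["disease_genes"], ex_dir / "disease_genes.txt")
    io.write_deg_tsv(sets["deg"], ex_dir / "deg.tsv")
    return [ex_dir / p for p in (
        "expression.tsv", "universe.txt", "truth_causal_genes.tsv",
        "cell_types.gmt", "pathways.gmt", "disease_genes.txt", "deg.tsv",
    )]


def _stage_pls(config: RunConfig, out: Path) -> list[Path]:
    expr = io.read_matrix_tsv(out / "expression" / "expression.tsv")
    tmap = io.read_tmap_tsv(out / "casecontrol" / "tmap.tsv")
    centroids = io.read_centroids_csv(out / "data" / "centroids.csv")
    y = tmap["t"].reindex(expr.index)
    result = pls_first_component(expr, y, n_components=2)
    _, spin_p = spin_test_pls(
        expr, y, centroids, n_rotations=config.n_rotations, seed=config.seed + 11
    )
    ztab = bootstrap_gene_z(expr, y, n_boot=config.n_boot, seed=config.seed + 13,
                            q_level=config.q_level)
    plus, minus = extract_pls_gene_sets(ztab, config.z_threshold, config.q_level)
    r_scores, p_scores = weights_tmap_correlation(result.scores, tmap["t"])

    pls_dir = out / "pls"
    pls_dir.mkdir(exist_ok=True)
    ztab.to_csv(pls_dir / "gene_z.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
    io.write_gene_list(plus, pls_dir / "pls1_plus.txt")
    io.write_gene_list(minus, pls_dir / "pls1_minus.txt")
    io.write_gmt({"PLS1_plus": plus, "PLS1_minus": minus}, pls_dir / "pls1_sets.gmt")
    io.write_json(
        {
            "seed": config.seed,
            "n_rotations": config.n_rotations,
            "n_boot": config.n_boot,
            "component_variance": result.component_variance,
            "variance_explained": result.variance_explained,
            "spin_p": spin_p,
            "r_scores_vs_t": r_scores,
            "p_scores_vs_t": p_scores,
            "n_pls1_plus": len(plus),
            "n_pls1_minus": len(minus),
        },
        pls_dir / "pls_result.json",
    )
    return [pls_dir / p for p in ("gene_z.tsv", "pls1_plus.txt", "pls1_minus.txt",
                                  "pls1_sets.gmt", "pls_result.json")]


def _stage_assoc(config: RunConfig, out: Path) -> list[Path]:
    ex_dir, pls_dir = out / "expression", out / "pls"
    universe = io.read_gene_list(ex_dir / "universe.txt")
    disease = io.read_gene_list(ex_dir / "disease_genes.txt")
    plus = io.read_gene_list(pls_dir / "pls1_plus.txt")
    minus = io.read_gene_list(pls_dir / "pls1_minus.txt")
    pls1_genes = sorted(set(plus) | set(minus))
    report = overlap_genes(pls1_genes, disease, universe,
                           query_name="PLS1", reference_name="disease_list")

    expr = io.read_matrix_tsv(ex_dir / "expression.tsv")
    delta = io.read_matrix_tsv(out / "casecontrol" / "delta_map.tsv")["delta_ms"]
    corr = (
        gene_map_correlation(report.overlap, expr, delta, q_level=config.q_level)
        if report.overlap
        else pd.DataFrame(columns=["r", "p", "q", "significant"])
    )

    # Correlate weights with DEG values within each selected PLS1 set,
    # mirroring the design of the post-mortem comparison: the question
    # is whether, among the genes the PLS selected, stronger weights go
    # with stronger differential expression.
    ztab = pd.read_csv(pls_dir / "gene_z.tsv", sep="\t", index_col=0)
    deg = io.read_deg_tsv(ex_dir / "deg.tsv")
    rows = []
    for set_name, genes in (("pls1_minus", minus), ("pls1_plus", plus)):
        zsub = ztab.loc[[g for g in genes if g in ztab.index]]
        if not len(zsub):
            continue
        for direction in ("up", "down"):
            res = weights_vs_dge(zsub, deg, direction=direction)
            res["comparison"] = set_name
            rows.append(res)
    battery = pd.DataFrame(
        rows, columns=["comparison", "direction", "n_overlap", "statistic",
                       "r", "p", "flag"]
    )
    battery["q"] = np.nan
    tested = battery["p"].notna() if len(battery) else pd.Series(dtype=bool)
    if tested.any():
        q, _ = fdr_bh(battery.loc[tested, "p"].to_numpy(), config.q_level)
        battery.loc[tested, "q"] = q

    as_dir = out / "assoc"
    as_dir.mkdir(exist_ok=True)
    corr.to_csv(as_dir / "overlap_gene_map_corr.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
    battery.to_csv(as_dir / "dge_correlations.tsv", sep="\t", index=False,
                   float_format=io.FLOAT_FORMAT)
    io.write_json(
        {
            "seed": config.seed,
            "n_pls1_genes": len(pls1_genes),
            "n_disease_genes_in_background": report.n_reference_in_background,
            "n_overlap": len(report.overlap),
            "overlap": report.overlap,
        },
        as_dir / "overlap_report.json",
    )
    return [as_dir / p for p in ("overlap_gene_map_corr.tsv", "dge_correlations.tsv",
                                 "overlap_report.json")]


def _stage_enrich(config: RunConfig, out: Path) -> list[Path]:
    ex_dir, pls_dir = out / "expression", out / "pls"
    universe = io.read_gene_list(ex_dir / "universe.txt")
    cell_sets = io.read_gmt(ex_dir / "cell_types.gmt")
    pathways = io.read_gmt(ex_dir / "pathways.gmt")
    disease = io.read_gene_list(ex_dir / "disease_genes.txt")
    en_dir = out / "enrich"
    en_dir.mkdir(exist_ok=True)
    files = []
    for label in ("plus", "minus"):
        query = io.read_gene_list(pls_dir / f"pls1_{label}.txt")
        path = en_dir / f"celltype_pls1_{label}.tsv"
        if query:
            table = celltype_enrichment(query, cell_sets, universe,
                                        n_perm=config.n_perm, seed=config.seed + 17,
                                        q_level=config.q_level)
        else:
            logger.warning("PLS1 %s set is empty; cell-type enrichment skipped", label)
            table = pd.DataFrame()
        table.to_csv(path, sep="\t", float_format=io.FLOAT_FORMAT)
        files.append(path)

    minus = io.read_gene_list(pls_dir / "pls1_minus.txt")
    shared_path = en_dir / "shared_terms.tsv"
    ora_path = en_dir / "ora_pls1_minus.tsv"
    if minus:
        ora_minus = ora_hypergeometric(minus, pathways, universe, q_level=config.q_level)
        ora_disease = ora_hypergeometric(disease, pathways, universe, q_level=config.q_level)
        shared = multilist_shared_terms(ora_minus, ora_disease, top_k=10)
        ora_minus.to_csv(ora_path, sep="\t", float_format=io.FLOAT_FORMAT)
        shared.to_csv(shared_path, sep="\t", float_format=io.FLOAT_FORMAT)
    else:
        pd.DataFrame().to_csv(ora_path, sep="\t")
        pd.DataFrame().to_csv(shared_path, sep="\t")
    files += [ora_path, shared_path]
    return files


_STAGE_FN = {
    "simulate": _stage_simulate,
    "msn": _stage_msn,
    "casecontrol": _stage_casecontrol,
    "expression": _stage_expression,
    "pls": _stage_pls,
    "assoc": _stage_assoc,
    "enrich": _stage_enrich,
}


def run_pipeline(
    config: RunConfig, out_dir, resume: bool = False, through: str | None = None
) -> dict:
    """Run the stages in order and write ``manifest.json`` under ``out_dir``.

    With ``resume=True``, a stage whose artifacts are all present and
    whose checksums match the existing manifest is skipped. ``through``
    stops after the named stage (inclusive). Returns the manifest dict
    (seed, config hash, per-stage artifact checksums).
    """
    if through is not None and through not in STAGES:
        raise ValueError(f"unknown stage: {through}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    stages = STAGES if through is None else STAGES[: STAGES.index(through) + 1]
    manifest = {"seed": config.seed, "config_hash": config_hash(config), "stages": {}}
    for stage in stages:
        prior = previous.get(stage)
        if (
            resume
            and prior
            and all(Path(out / f).exists() and io.sha256_file(out / f) == h
                    for f, h in prior.items())
        ):
            logger.info("stage %s up to date; skipped", stage)
            manifest["stages"][stage] = prior
            continue
        logger.info("running stage %s", stage)
        try:
            files = _STAGE_FN[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed under {out}: {exc}") from exc
        manifest["stages"][stage] = {
            str(f.relative_to(out)): io.sha256_file(f) for f in files
        }
    io.write_json(manifest, manifest_path)
    return manifest
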