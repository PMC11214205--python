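"""End-to-end pipeline: synth -> enterotype -> quantgen -> simulate -> respond -> shotgun.

Each stage reads files and writes files (no in-memory state crosses stage
boundaries), so any stage can be re-run in isolation; a JSON manifest
records the config, seeds and checksums of every artifact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, enterotyping, metagenomics, reml, response, selection, synthdata
from .manifest import write_manifest
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "genus": {"n_pm": 80, "n_rt": 80},
    "rarefaction_depth": 7000,
    "enterotype": {"iterations": 25},
    "quantgen": {"trait": "prevotella", "trait_b": "adg"},
    "simulate": {"replicates": 5},
    "shotgun": {"n_mgs": 20, "markers_per_mgs": 40, "n_per_group": 15,
                "n_planted_pm": 6, "n_planted_rt": 6},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key in user:
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key: {key!r}")
    return _merge(DEFAULT_CONFIG, user)


def run_all(config: dict | None = None, out_dir: str | Path = "holosel_run") -> dict:
    """Execute the full stage DAG; returns the manifest dictionary."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    files: list[Path] = []

    # stage 1: synthetic genus table -> rarefied relative table
    gcfg = synthdata.GeneratorConfig(seed=seed, **{k: v for k, v in cfg["genus"].items()})
    table, truth = synthdata.generate_genus_table(gcfg)
    counts_path = out / "genus_counts.tsv"
    table.to_tsv(counts_path)
    truth.to_csv(out / "genus_truth.tsv", sep="\t")
    files += [counts_path, out / "genus_truth.tsv"]
    logger.info("stage synth: %d samples x %d taxa", *table.data.shape)

    counts = abundance.AbundanceTable.from_tsv(counts_path, kind="counts")
    rare = abundance.rarefy(counts, depth=int(cfg["rarefaction_depth"]), seed=seed)
    rel = rare.to_relative()
    rel_path = out / "genus_relative.tsv"
    rel.to_tsv(rel_path)
    div = abundance.diversity_frame(rare)
    div.to_csv(out / "alpha_diversity.tsv", sep="\t")
    files += [rel_path, out / "alpha_diversity.tsv"]

    # stage 2: enterotyping
    rel2 = abundance.AbundanceTable.from_tsv(rel_path, kind="relative")
    D = enterotyping.jsd_distance_matrix(rel2)
    D.to_csv(out / "jsd_distance.tsv", sep="\t")
    assigns = enterotyping.assign_enterotypes(
        rel2, iterations=int(cfg["enterotype"]["iterations"]), seed=seed)
    aframe = enterotyping.assignments_frame(assigns)
    aframe.to_csv(out / "enterotypes.tsv", sep="\t")
    coords, _ = enterotyping.pcoa(D, n_axes=2)
    coords.to_csv(out / "pcoa.tsv", sep="\t")
    files += [out / "jsd_distance.tsv", out / "enterotypes.tsv", out / "pcoa.tsv"]
    logger.info("stage enterotype: %d stable of %d samples",
                int((aframe["label"] != "unstable").sum()), len(aframe))

    # stage 3: study-design phenotypes + genetic parameters
    ped, data = synthdata.generate_study_phenotypes(seed=seed)
    ped.to_tsv(out / "pedigree.tsv")
    data.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    files += [out / "pedigree.tsv", out / "phenotypes.tsv"]
    ped2 = Pedigree.from_tsv(out / "pedigree.tsv")
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t", dtype={"animal": str})
    vc = reml.reml_fit(pheno, ped2, cfg["quantgen"]["trait"])
    bi = reml.bivariate_reml(pheno, ped2, cfg["quantgen"]["trait"], cfg["quantgen"]["trait_b"],
                             compute_se=False)
    pd.DataFrame([
        {"trait": cfg["quantgen"]["trait"], "h2": vc.h2, "c2": vc.c2,
         "h2_se": vc.se.get("h2"), "c2_se": vc.se.get("c2")},
    ]).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"trait_a": cfg["quantgen"]["trait"], "trait_b": cfg["quantgen"]["trait_b"], "rG": bi.rG},
    ]).to_csv(out / "genetic_correlations.tsv", sep="\t", index=False)
    files += [out / "variance_components.tsv", out / "genetic_correlations.tsv"]
    logger.info("stage quantgen: h2=%.3f c2=%.3f rG=%.3f", vc.h2, vc.c2, bi.rG)

    # stage 4: selection-scheme trajectories
    traj = selection.run_scheme(n_replicates=int(cfg["simulate"]["replicates"]), seed=seed)
    traj.to_csv(out / "trajectory.tsv", sep="\t", index=False)
    files.append(out / "trajectory.tsv")

    # stage 5: response contrasts on the simulated phenotypes
    resp_data = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    resp_data = resp_data[resp_data["line"].isin(["HPM", "HRT"])]
    resp = response.line_contrasts(resp_data, ["prevotella", "treponema", "adg"])
    order = response.rank_differences(resp, generation="G3")
    resp["feature"] = pd.Categorical(resp["feature"], categories=order, ordered=True)
    resp.sort_values(["feature", "generation"]).to_csv(out / "response.tsv", sep="\t", index=False)
    files.append(out / "response.tsv")

    # stage 6: shotgun layer
    genes, catalog, struth = synthdata.generate_shotgun_fixture(
        seed=seed, **{k: int(v) for k, v in cfg["shotgun"].items()})
    genes.to_tsv(out / "gene_counts.tsv")
    files.append(out / "gene_counts.tsv")
    genes2 = metagenomics.GeneCountMatrix.from_tsv(out / "gene_counts.tsv")
    mgs = metagenomics.mgs_abundance(genes2, catalog)
    diff = metagenomics.diff_abundance(mgs, struth["groups"])
    diff.to_csv(out / "mgs_differential.tsv", sep="\t", index=False)
    kos = metagenomics.ko_abundance(genes2, catalog)
    kdiff = metagenomics.diff_abundance(kos, struth["groups"])
    kdiff.to_csv(out / "ko_differential.tsv", sep="\t", index=False)
    hits = list(kdiff.loc[kdiff["enriched_in"] != "none", "feature"])
    background = list(kdiff["feature"])
    if hits:
        enr = metagenomics.enrich_pathways(hits, background, catalog.ko2pathway, p_max=1.0)
        enr.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
        files.append(out / "pathway_enrichment.tsv")
    files += [out / "mgs_differential.tsv", out / "ko_differential.tsv"]

    manifest = write_manifest(out / "manifest.json", cfg, seed, files)
    logger.info("pipeline complete: %d artifacts in %s", len(files), out)
    return manifest
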