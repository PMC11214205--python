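"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators cover the package's input space:

* :func:`generate_genus_table` -- a two-enterotype genus-level count table.
  Each enterotype has a mean composition on the percent scale (defaults are
  the shotgun-derived means of the focal genera: e.g. Prevotella 44.9% in PM
  vs 25.7% in RT animals) with multiplicative log-normal dispersion matched
  to the study-reported SDs, a power-law background flora (heavier-tailed in RT, so
  RT alpha diversity exceeds PM), and multinomial count sampling at a random
  sequencing depth.
* :func:`generate_shotgun_fixture` -- marker-gene count matrices with
  planted differentially abundant MGS, per-gene efficiency noise and
  dropout, plus toy KO and pathway annotations with planted enrichment.
* :func:`generate_study_phenotypes` -- the four-generation study pedigree
  under random mating with known heritabilities for parameter-recovery
  loops (a thin wrapper over the selection simulator with selection off).

All generators are reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .metagenomics import GeneCountMatrix, MGSCatalog
from .pedigree import Pedigree
from .selection import BreedingScheme, GeneticArchitecture, simulate_population

# focal genus groups: members, per-member share of the group mean, and
# (mean%, sd%) per enterotype
_FOCAL = {
    "Prevotella": {
        "members": {"Prevotella_9": 0.60, "Prevotella_7": 0.25, "Prevotella": 0.15},
        "PM": (44.9, 8.3), "RT": (25.7, 10.0),
    },
    "Mitsuokella": {
        "members": {"Mitsuokella": 1.0},
        "PM": (1.2, 1.2), "RT": (0.4, 0.5),
    },
    "Ruminococcus": {
        "members": {
            "Ruminococcus": 0.4, "Ruminococcus_gnavus_group": 0.3,
            "Ruminococcus_torques_group": 0.2, "Ruminococcus_gauvreauii_group": 0.1,
        },
        "PM": (0.5, 0.5), "RT": (1.3, 0.8),
    },
    "Treponema": {
        "members": {"Treponema": 1.0},
        "PM": (1.2, 1.4), "RT": (8.7, 6.5),
    },
    "Rikenellaceae_RC9": {
        "members": {"Rikenellaceae_RC9_gut_group": 1.0},
        "PM": (1.8, 1.1), "RT": (5.0, 2.3),
    },
}


@dataclass
class GeneratorConfig:
    """Parameters of the two-enterotype genus-table generator."""

    n_pm: int = 150
    n_rt: int = 150
    focal: dict = field(default_factory=lambda: copy.deepcopy(_FOCAL))
    n_background: int = 120
    # power-law exponent of the background flora; a flatter RT tail gives RT
    # the higher alpha diversity
    background_alpha: dict = field(default_factory=lambda: {"PM": 1.6, "RT": 1.0})
    background_cv: float = 1.0
    depth_range: tuple = (10000, 30000)
    seed: int = 0

    def focal_mass(self, ent: str) -> float:
        return sum(spec[ent][0] for spec in self.focal.values())


def generate_genus_table(cfg: GeneratorConfig | None = None) -> tuple[AbundanceTable, pd.Series]:
    """Draw a two-enterotype genus count table; returns (table, true labels).

    Per sample, each focal genus group receives a shared multiplicative
    log-normal factor calibrated to its study-reported mean and SD; background taxa
    get independent log-normal noise around a power-law profile filling the
    remaining mass.  The composition is renormalized and counts drawn
    multinomially at a uniform random depth.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    taxa: list[str] = []
    for spec in cfg.focal.values():
        taxa.extend(spec["members"])
    bg_names = [f"Genus_{i:03d}" for i in range(cfg.n_background)]
    taxa = taxa + bg_names

    rows = []
    labels = []
    sample_ids = []
    for ent, n in (("PM", cfg.n_pm), ("RT", cfg.n_rt)):
        for spec in cfg.focal.values():
            if spec[ent][0] <= 0:
                raise ValueError("focal means must be positive")
        if cfg.focal_mass(ent) > 100:
            raise ValueError(f"{ent} focal profile sums above 100%")
        bg_mass = 100.0 - cfg.focal_mass(ent)
        alpha = cfg.background_alpha[ent]
        bg_profile = (np.arange(1, cfg.n_background + 1, dtype=float)) ** (-alpha)
        bg_profile *= bg_mass / bg_profile.sum()
        sd_bg = np.sqrt(np.log(1 + cfg.background_cv**2))
        for i in range(n):
            comp = []
            for spec in cfg.focal.values():
                mean, sd = spec[ent]
                cv = sd / mean
                s = np.sqrt(np.log(1 + cv**2))
                factor = np.exp(rng.normal(-0.5 * s**2, s))
                for share in spec["members"].values():
                    comp.append(mean * share * factor)
            bg = bg_profile * np.exp(rng.normal(-0.5 * sd_bg**2, sd_bg, size=cfg.n_background))
            comp = np.concatenate([comp, bg])
            comp /= comp.sum()
            depth = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
            counts = rng.multinomial(depth, comp)
            rows.append(counts)
            labels.append(ent)
            sample_ids.append(f"{ent}{i:04d}")
    df = pd.DataFrame(np.array(rows), index=pd.Index(sample_ids, name="sample_id"), columns=taxa)
    table = AbundanceTable(df, kind="counts")
    truth = pd.Series(labels, index=df.index, name="enterotype")
    return table, truth


def generate_shotgun_fixture(
    n_mgs: int = 40,
    markers_per_mgs: int = 100,
    n_per_group: int = 15,
    n_planted_pm: int = 12,
    n_planted_rt: int = 12,
    fold: float = 4.0,
    dropout: float = 0.1,
    depth: float = 200.0,
    n_ko: int = 120,
    pathway_size: int = 12,
    seed: int = 0,
) -> tuple[GeneCountMatrix, MGSCatalog, dict]:
    """Marker-gene count fixture with planted group differences.

    The first ``n_planted_pm`` MGS are ``fold``-times more abundant in PM
    samples, the next ``n_planted_rt`` in RT samples; the rest have no group
    effect.  Marker counts are Poisson around truth x gene length x depth
    with per-gene efficiency noise and Bernoulli dropout.  Genes of the
    planted MGS draw their KO annotations from dedicated pathways so that KO
    enrichment is recoverable.  Returns (gene matrix, catalog, truth dict).
    """
    if n_planted_pm + n_planted_rt > n_mgs:
        raise ValueError("planted sets exceed the number of MGS")
    rng = np.random.default_rng(seed)
    samples = [f"PM{i:02d}" for i in range(n_per_group)] + [f"RT{i:02d}" for i in range(n_per_group)]
    group = np.array(["PM"] * n_per_group + ["RT"] * n_per_group)
    mgs_ids = [f"msp_{i:04d}" for i in range(n_mgs)]

    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_mgs)
    truth_ab = np.empty((n_mgs, 2 * n_per_group))
    for m in range(n_mgs):
        mult = np.ones(2 * n_per_group)
        if m < n_planted_pm:
            mult[group == "PM"] = fold
        elif m < n_planted_pm + n_planted_rt:
            mult[group == "RT"] = fold
        noise = rng.lognormal(mean=0.0, sigma=0.35, size=2 * n_per_group)
        truth_ab[m] = base[m] * mult * noise

    gene_ids, lengths, markers, counts = [], [], {}, []
    ko_assign = {}
    pathways: dict[str, list[str]] = {}
    n_pathways = max(n_ko // pathway_size, 3)
    ko_ids = [f"K{k:05d}" for k in range(n_ko)]
    for p in range(n_pathways):
        pathways[f"path{p:03d}"] = ko_ids[p * pathway_size:(p + 1) * pathway_size]
    pm_kos = pathways["path000"]
    rt_kos = pathways["path001"]

    for m, mgs in enumerate(mgs_ids):
        glist = [f"{mgs}_g{j:03d}" for j in range(markers_per_mgs)]
        markers[mgs] = glist
        for g in glist:
            gene_ids.append(g)
            lengths.append(int(rng.integers(500, 3000)))
            if m < n_planted_pm:
                ko_assign[g] = pm_kos[int(rng.integers(len(pm_kos)))]
            elif m < n_planted_pm + n_planted_rt:
                ko_assign[g] = rt_kos[int(rng.integers(len(rt_kos)))]
            else:
                ko_assign[g] = ko_ids[int(rng.integers(2 * pathway_size, n_ko))]
    lengths = np.array(lengths, dtype=float)

    eff = rng.lognormal(mean=0.0, sigma=0.3, size=len(gene_ids))
    count_mat = np.zeros((len(gene_ids), 2 * n_per_group), dtype=np.int64)
    row = 0
    for m in range(n_mgs):
        for j in range(markers_per_mgs):
            lam = truth_ab[m] * (lengths[row] / 1000.0) * depth * eff[row] / 100.0
            keep = rng.random(2 * n_per_group) >= dropout
            count_mat[row] = rng.poisson(lam) * keep
            row += 1

    genes = GeneCountMatrix(
        pd.DataFrame(count_mat, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        pd.Series(lengths, index=gene_ids, name="length_bp"),
    )
    lineage = pd.DataFrame(
        {"genus": [f"TaxGenus_{i % max(n_mgs // 3, 1):03d}" for i in range(n_mgs)]},
        index=pd.Index(mgs_ids, name="mgs_id"),
    )
    catalog = MGSCatalog(
        markers=markers,
        lineage=lineage,
        gene2ko=pd.Series(ko_assign, name="ko"),
        ko2pathway=pathways,
    )
    truth = {
        "groups": pd.Series(group, index=samples, name="group"),
        "planted_pm": mgs_ids[:n_planted_pm],
        "planted_rt": mgs_ids[n_planted_pm:n_planted_pm + n_planted_rt],
        "abundance": pd.DataFrame(truth_ab, index=mgs_ids, columns=samples),
        "pm_pathway": "path000",
        "rt_pathway": "path001",
    }
    return genes, catalog, truth


def generate_study_phenotypes(
    scheme: BreedingScheme | None = None,
    arch: GeneticArchitecture | None = None,
    seed: int = 0,
) -> tuple[Pedigree, pd.DataFrame]:
    """Random-mating phenotypes on the study's four-generation design.

    Same pedigree constraints as the selection experiment (one boar per sire
    family, 30 dams, balanced matings) but parents drawn at random, so
    estimated genetic parameters can be compared against the architecture's
    known values.
    """
    pop = simulate_population(scheme, arch, seed=seed, selection=False)
    return pop.pedigree, pop.data
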