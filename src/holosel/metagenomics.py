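"""Shotgun-layer quantification and differential-abundance testing.

Starting from a gene x sample raw-count matrix with gene lengths, abundances
are length-normalized; each metagenomic species (MGS) is quantified as the
mean abundance of its marker genes (zero unless at least 10% of markers are
detected); taxon abundances are sums of MGS, and KEGG-ortholog (KO)
abundances are sums of genes.  Group contrasts (PM vs RT) use two-sided
Wilcoxon-Mann-Whitney tests with Benjamini-Hochberg FDR control and Cliff's
Delta effect sizes; pathway over-representation uses the hypergeometric
tail against a user-supplied KO -> pathway map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable


@dataclass
class GeneCountMatrix:
    """Raw gene counts (genes x samples) with per-gene lengths in bp."""

    counts: pd.DataFrame       # index gene_id, columns sample_id
    lengths: pd.Series         # bp per gene_id

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()])[:5]
            raise ValueError(f"genes without length: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("gene counts must be non-negative")

    def normalized(self) -> pd.DataFrame:
        """Counts divided by gene length in kilobases."""
        return self.counts.div(self.lengths / 1000.0, axis=0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = df.pop("length_bp")
        return cls(df, lengths)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class MGSCatalog:
    """MGS -> marker genes, MGS -> lineage, gene -> KO and KO -> pathway maps."""

    markers: dict[str, list[str]]
    lineage: pd.DataFrame | None = None      # index mgs_id, columns = ranks
    gene2ko: pd.Series | None = None         # index gene_id -> KO
    ko2pathway: dict[str, list[str]] | None = None  # KO -> pathway ids

    def __post_init__(self) -> None:
        for mgs, genes in self.markers.items():
            if not genes:
                raise ValueError(f"MGS {mgs!r} has an empty marker list")


@dataclass
class DiffResult:
    feature: str
    median_a: float
    median_b: float
    p: float
    q: float
    cliffs_delta: float
    enriched_in: str  # group label or "none"


def mgs_abundance(
    genes: GeneCountMatrix,
    catalog: MGSCatalog,
    min_marker_frac: float = 0.10,
) -> AbundanceTable:
    """MGS abundance = mean length-normalized abundance of its marker genes.

    Zeros are included in the mean; if fewer than ``min_marker_frac`` of the
    markers have a nonzero raw count in a sample, the MGS abundance in that
    sample is set to null (0).
    """
    norm = genes.normalized()
    raw = genes.counts
    out = {}
    for mgs, markers in catalog.markers.items():
        missing = [g for g in markers if g not in norm.index]
        if missing:
            raise KeyError(f"MGS {mgs!r} markers absent from the gene matrix: {missing[:5]}")
        sub = norm.loc[markers]
        detected_frac = (raw.loc[markers] > 0).mean(axis=0)
        vals = sub.mean(axis=0)
        vals[detected_frac < min_marker_frac] = 0.0
        out[mgs] = vals
    df = pd.DataFrame(out)  # samples x MGS
    df.index.name = "sample_id"
    table = AbundanceTable.__new__(AbundanceTable)  # arbitrary scale, not percent
    table.data = df
    table.kind = "relative"
    return table


def taxon_rollup(mgs: AbundanceTable, catalog: MGSCatalog, rank: str = "genus") -> AbundanceTable:
    """Sum MGS abundances per taxon at the requested rank (sample totals kept)."""
    if catalog.lineage is None:
        raise ValueError("catalog has no lineage table")
    if rank not in catalog.lineage.columns:
        raise KeyError(f"unknown rank {rank!r}; available: {list(catalog.lineage.columns)}")
    taxa = catalog.lineage[rank].reindex(mgs.data.columns)
    if taxa.isna().any():
        missing = list(taxa.index[taxa.isna()])[:5]
        raise ValueError(f"MGS without lineage: {missing}")
    rolled = mgs.data.T.groupby(taxa).sum().T
    out = AbundanceTable.__new__(AbundanceTable)
    out.data = rolled
    out.kind = "relative"
    return out


def ko_abundance(genes: GeneCountMatrix, catalog: MGSCatalog) -> AbundanceTable:
    """KO abundance = sum of length-normalized abundances of its genes."""
    if catalog.gene2ko is None:
        raise ValueError("catalog has no gene -> KO map")
    norm = genes.normalized()
    ko = catalog.gene2ko.reindex(norm.index).dropna()
    rolled = norm.loc[ko.index].groupby(ko).sum().T
    rolled.index.name = "sample_id"
    out = AbundanceTable.__new__(AbundanceTable)
    out.data = rolled
    out.kind = "relative"
    return out


def cliffs_delta(x, y) -> float:
    """Cliff's Delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


def diff_abundance(
    features: AbundanceTable,
    groups: pd.Series,
    group_a: str = "PM",
    group_b: str = "RT",
    q_max: float = 0.1,
    cd_min: float = 0.7,
    relative: bool = True,
) -> pd.DataFrame:
    """Per-feature Wilcoxon-Mann-Whitney tests between two groups.

    ``groups`` maps sample ids to group labels.  With ``relative`` each
    sample's abundance vector is divided by its total first, removing
    sequencing-depth effects (rank tests are invariant to per-sample
    monotone rescaling of a single feature, but depth affects features
    jointly).  p-values are BH-adjusted across all tested features; a
    feature is called enriched when q < ``q_max`` and |Cliff's Delta| >
    ``cd_min``, in the group with the higher values.
    """
    df = features.data
    in_a = df.index[groups.reindex(df.index) == group_a]
    in_b = df.index[groups.reindex(df.index) == group_b]
    if len(in_a) < 2 or len(in_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if relative:
        totals = df.sum(axis=1).replace(0.0, 1.0)
        df = df.div(totals, axis=0)
    rows = []
    pvals = []
    for feat in df.columns:
        x = df.loc[in_a, feat].to_numpy()
        y = df.loc[in_b, feat].to_numpy()
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            p = 1.0
            cd = 0.0
        else:
            use_exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
            method = "exact" if use_exact else "asymptotic"
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
            cd = cliffs_delta(x, y)
        pvals.append(p)
        rows.append({
            "feature": feat,
            "median_" + group_a: float(np.median(x)),
            "median_" + group_b: float(np.median(y)),
            "p": p, "cliffs_delta": cd,
        })
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(rows)
    out["q"] = qvals
    def call(row):
        if row["q"] < q_max and abs(row["cliffs_delta"]) > cd_min:
            return group_a if row["cliffs_delta"] > 0 else group_b
        return "none"
    out["enriched_in"] = out.apply(call, axis=1)
    return out[["feature", f"median_{group_a}", f"median_{group_b}", "p", "q", "cliffs_delta", "enriched_in"]]


def enrich_pathways(
    hits: list[str],
    background: list[str],
    pathways: dict[str, list[str]],
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in a KO hit list.

    For each pathway with at least one hit, p = P(X >= k) with
    X ~ Hypergeom(N=|background|, K=|pathway intersect background|,
    n=|hits|).  Pathways with p < ``p_max`` are returned sorted by p.
    """
    bg = set(background)
    hit_set = set(hits)
    if not hit_set <= bg:
        raise ValueError(f"hits not contained in background: {sorted(hit_set - bg)[:5]}")
    N, n = len(bg), len(hit_set)
    rows = []
    for pathway, kos in pathways.items():
        members = set(kos) & bg
        k = len(members & hit_set)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": pathway, "hits": k, "pathway_size": K, "p": p,
                     "expected": n * K / N})
    out = pd.DataFrame(rows, columns=["pathway", "hits", "pathway_size", "expected", "p"])
    out = out[out["p"] < p_max].sort_values("p", kind="stable").reset_index(drop=True)
    return out


# --- TSV readers for the catalog side-files --------------------------------


def read_marker_catalog(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns mgs_id, marker_rank, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["marker_rank"] = df["marker_rank"].astype(int)
    return {
        mgs: list(sub.sort_values("marker_rank")["gene_id"])
        for mgs, sub in df.groupby("mgs_id")
    }


def read_ko2pathway(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns pathway_id, ko_id -> pathway -> KO list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {p: list(sub["ko_id"]) for p, sub in df.groupby("pathway_id")}
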