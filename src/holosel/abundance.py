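"""Taxon abundance tables: rarefaction, transforms, aggregation, filtering, alpha diversity.

The central container is :class:`AbundanceTable`, a thin wrapper around a
pandas DataFrame (samples as rows, taxa as columns) that tracks whether the
values are raw counts or relative abundances on the percent scale.  All
downstream analyses (enterotyping, genetic analyses) start from a genus-level
table rarefied to a common sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genus labels summed into the composite Prevotella trait used for selection.
PREVOTELLA_MEMBERS = ("Prevotella_9", "Prevotella_7", "Prevotella")
#: Genus labels summed into the composite Ruminococcus trait used for selection.
RUMINOCOCCUS_MEMBERS = (
    "Ruminococcus",
    "Ruminococcus_gnavus_group",
    "Ruminococcus_torques_group",
    "Ruminococcus_gauvreauii_group",
)

ROW_SUM_TOL = 1e-6


class EmptyTableError(ValueError):
    """Raised when an operation would return a table with no samples."""


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with taxon labels as columns.
    kind
        ``"counts"`` for integer read counts, ``"relative"`` for percent
        relative abundances (rows sum to 100).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValueError("abundance values must be non-negative")
        if self.kind == "relative" and len(self.data):
            sums = values.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-4):
                bad = self.data.index[np.abs(sums - 100.0) > 1e-4][:5].tolist()
                raise ValueError(f"relative-abundance rows must sum to 100; offenders: {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_relative(self) -> "AbundanceTable":
        """Convert counts to percent relative abundance (rows sum to 100)."""
        if self.kind == "relative":
            return self
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = list(self.data.index[sums <= 0])[:5]
            raise ValueError(f"cannot normalize all-zero samples: {bad}")
        return AbundanceTable(self.data.div(sums, axis=0) * 100.0, kind="relative")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "counts") -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, kind=kind)


@dataclass
class DiversityRecord:
    """Alpha diversity of one sample: observed richness and Shannon index (nats)."""

    sample_id: object
    richness: int
    shannon: float


@dataclass
class RarefactionResult:
    table: AbundanceTable
    dropped_samples: list = field(default_factory=list)


def rarefy(
    table: AbundanceTable,
    depth: int = 7000,
    seed: int = 0,
    return_dropped: bool = False,
) -> AbundanceTable | RarefactionResult:
    """Subsample every sample without replacement to a common depth.

    Samples whose total count is below ``depth`` are dropped (and logged);
    samples exactly at ``depth`` are returned unchanged.  The default depth of
    7000 reads per sample is the usual working depth for genus-level 16S
    profiles of this kind.
    """
    if table.kind != "counts":
        raise ValueError("rarefy requires a table of counts")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefy requires integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.data.index[~keep])
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped[:10])
    if not keep.any():
        raise EmptyTableError(f"all {len(totals)} samples are below rarefaction depth {depth}")
    out = np.empty((keep.sum(), counts.shape[1]), dtype=np.int64)
    for row_out, row in enumerate(np.nonzero(keep)[0]):
        c = counts[row]
        if totals[row] == depth:
            out[row_out] = c
            continue
        # multivariate hypergeometric == subsampling reads without replacement
        out[row_out] = rng.multivariate_hypergeometric(c, depth)
    df = pd.DataFrame(out, index=table.data.index[keep], columns=table.data.columns)
    result = AbundanceTable(df, kind="counts")
    if return_dropped:
        return RarefactionResult(result, dropped)
    return result


def alpha_diversity(table: AbundanceTable) -> list[DiversityRecord]:
    """Per-sample richness (taxa with abundance > 0) and Shannon index in nats."""
    values = table.values
    records = []
    for sid, row in zip(table.data.index, values):
        total = row.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total abundance")
        p = row[row > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        records.append(DiversityRecord(sid, int((row > 0).sum()), max(shannon, 0.0)))
    return records


def diversity_frame(table: AbundanceTable) -> pd.DataFrame:
    """Alpha diversity as a DataFrame indexed by sample id."""
    recs = alpha_diversity(table)
    return pd.DataFrame(
        {"richness": [r.richness for r in recs], "shannon": [r.shannon for r in recs]},
        index=pd.Index([r.sample_id for r in recs], name="sample_id"),
    )


def aggregate_selection_taxa(
    table: AbundanceTable,
    prevotella_members: Sequence[str] = PREVOTELLA_MEMBERS,
    ruminococcus_members: Sequence[str] = RUMINOCOCCUS_MEMBERS,
    prevotella_name: str = "Prevotella_sum",
    ruminococcus_name: str = "Ruminococcus_sum",
    replace_members: bool = False,
) -> AbundanceTable:
    """Add the two composite selection-criterion columns.

    ``Prevotella_sum`` is the sum of the Prevotella sub-genus labels and
    ``Ruminococcus_sum`` the sum of the four Ruminococcus group labels.
    Members absent from the table contribute zero (and are logged).  With
    ``replace_members`` the member columns are removed so that row sums are
    unchanged; otherwise the composites are appended alongside them.
    """
    if table.kind != "relative":
        raise ValueError("aggregate_selection_taxa expects relative abundances")
    df = table.data.copy()
    composites = {}
    for name, members in ((prevotella_name, prevotella_members), (ruminococcus_name, ruminococcus_members)):
        present = [m for m in members if m in df.columns]
        missing = [m for m in members if m not in df.columns]
        if missing:
            logger.info("aggregate_selection_taxa: members absent, contributing 0: %s", missing)
        composites[name] = df[present].sum(axis=1) if present else pd.Series(0.0, index=df.index)
    drop = []
    if replace_members:
        drop = [m for m in (*prevotella_members, *ruminococcus_members) if m in df.columns]
        df = df.drop(columns=drop)
    for name, col in composites.items():
        df[name] = col
    if replace_members:
        return AbundanceTable(df, kind="relative")
    # appending composites double-counts mass, so the result is no longer a
    # valid relative table; return the raw frame wrapped without validation
    out = AbundanceTable.__new__(AbundanceTable)
    out.data = df
    out.kind = "relative"
    return out


def log_transform(values, pseudo: float = 0.01) -> np.ndarray:
    """ln(x + pseudo) applied elementwise to percent relative abundances.

    The pseudo-count of 0.01 (percent) removes zeros before taking logs.
    """
    x = np.asarray(values, dtype=float)
    if x.size and x.min() < 0:
        raise ValueError("relative abundances must be non-negative")
    return np.log(x + pseudo)


def filter_genera(
    table: AbundanceTable,
    min_mean_pct: float = 0.1,
    max_zero_frac: float | None = None,
) -> AbundanceTable:
    """Keep taxa by mean relative abundance and (optionally) zero fraction.

    A taxon is retained when its mean relative abundance across samples
    exceeds ``min_mean_pct`` percent, and, if ``max_zero_frac`` is given, when
    its fraction of zero values is strictly below that threshold.
    """
    if table.kind != "relative":
        raise ValueError("filter_genera expects relative abundances")
    if not 0 <= min_mean_pct <= 100:
        raise ValueError("min_mean_pct must be in [0, 100]")
    if max_zero_frac is not None and not 0 <= max_zero_frac <= 1:
        raise ValueError("max_zero_frac must be in [0, 1]")
    means = table.data.mean(axis=0)
    keep = means > min_mean_pct if min_mean_pct > 0 else pd.Series(True, index=table.data.columns)
    if max_zero_frac is not None:
        zero_frac = (table.data == 0).mean(axis=0)
        keep &= zero_frac < max_zero_frac
    kept = table.data.loc[:, keep]
    logger.info("filter_genera: retained %d of %d taxa", kept.shape[1], table.data.shape[1])
    out = AbundanceTable.__new__(AbundanceTable)  # rows no longer sum to 100
    out.data = kept
    out.kind = "relative"
    return out
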