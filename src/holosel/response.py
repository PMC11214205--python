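"""Between-line response to selection: per-generation standardized contrasts.

For each feature (taxon abundance, diversity index or growth trait) an
ordinary-least-squares model

    value ~ sex + batch(generation) + generation x line

is fitted on the standardized variable, and the HPM - HRT least-squares-mean
difference within each generation is extracted as a linear contrast with its
t-test p-value and a Tukey (studentized-range) adjusted p-value.  Features
ranked by their G3 difference reproduce the response-to-selection ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _build_design(meta: pd.DataFrame):
    """Design: intercept, sex, batch nested in generation, generation, gen x line."""
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]

    def add_dummies(series: pd.Series, prefix: str) -> None:
        levels = sorted(series.unique())
        for lev in levels[1:]:
            cols.append((series == lev).to_numpy(dtype=float))
            names.append(f"{prefix}[{lev}]")

    add_dummies(meta["sex"].astype(str), "sex")
    gens = sorted(meta["generation"].astype(str).unique())
    # generation main effects
    for g in gens[1:]:
        cols.append((meta["generation"].astype(str) == g).to_numpy(dtype=float))
        names.append(f"gen[{g}]")
    # batch nested intra-generation: within each generation, batch dummies
    for g in gens:
        sub = meta["generation"].astype(str) == g
        batches = sorted(meta.loc[sub, "batch"].astype(str).unique())
        for b in batches[1:]:
            cols.append((sub & (meta["batch"].astype(str) == b)).to_numpy(dtype=float))
            names.append(f"gen[{g}]:batch[{b}]")
    # generation x line: indicator of HRT within each generation that has both lines
    contrast_cols = {}
    for g in gens:
        sub = meta["generation"].astype(str) == g
        lines = sorted(meta.loc[sub, "line"].astype(str).unique())
        if len(lines) < 2:
            continue
        col = (sub & (meta["line"].astype(str) == "HRT")).to_numpy(dtype=float)
        cols.append(col)
        names.append(f"gen[{g}]:lineHRT")
        contrast_cols[g] = len(cols) - 1
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via rank-revealing QR pivots
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(R[min(j, R.shape[0] - 1), j]) < 1e-8]
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); aliased terms: {aliased or 'unknown'}"
        )
    return X, names, contrast_cols


def line_contrasts(
    data: pd.DataFrame,
    features: list[str],
    standardize: bool = True,
    variant: str = "standardized",
) -> pd.DataFrame:
    """Per-feature, per-generation standardized HPM - HRT differences.

    ``data`` needs columns line, generation, sex, batch plus the feature
    columns.  ``variant`` selects the transformation applied before fitting:
    ``standardized`` (divide by SD), ``centered`` (center then scale) or
    ``ranked`` (rank-transform).  Returns a long table with columns feature,
    generation, difference, p_value, p_tukey.
    """
    meta = data[["line", "generation", "sex", "batch"]].copy()
    both = meta.groupby("generation")["line"].nunique() >= 2
    tested_gens = sorted(g for g, ok in both.items() if ok)
    if not tested_gens:
        raise ValueError("no generation has both lines present")
    X, names, contrast_cols = _build_design(meta)
    n, p = X.shape
    df_resid = n - p
    XtX_inv = np.linalg.inv(X.T @ X)
    # Tukey family size: number of generation x line cells compared
    k_cells = 2 * len(contrast_cols)

    rows = []
    for feat in features:
        y = data[feat].to_numpy(dtype=float)
        if variant == "ranked":
            y = stats.rankdata(y)
        if variant in ("standardized", "ranked"):
            y = y / (y.std(ddof=1) or 1.0)
        elif variant == "centered":
            y = (y - y.mean()) / (y.std(ddof=1) or 1.0)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        s2 = float(resid @ resid) / df_resid
        for g in tested_gens:
            j = contrast_cols[str(g)] if str(g) in contrast_cols else contrast_cols[g]
            diff = -beta[j]  # column codes HRT, so HPM - HRT = -coef
            se = np.sqrt(s2 * XtX_inv[j, j])
            t = diff / se if se > 0 else 0.0
            pval = 2 * stats.t.sf(abs(t), df_resid)
            p_tukey = stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k_cells, df_resid)
            rows.append({
                "feature": feat, "generation": g, "difference": float(diff),
                "se": float(se), "p_value": float(pval),
                "p_tukey": float(min(max(p_tukey, pval), 1.0)),
            })
    return pd.DataFrame(rows)


def rank_differences(table: pd.DataFrame, generation: str = "G3") -> list[str]:
    """Features ordered from the largest positive to the largest negative
    line difference in the given generation (ties: stable by feature name)."""
    sub = table[table["generation"].astype(str) == str(generation)]
    if sub.empty:
        raise ValueError(f"generation {generation!r} not present in the response table")
    sub = sub.sort_values(["difference", "feature"], ascending=[False, True], kind="stable")
    return list(sub["feature"])
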