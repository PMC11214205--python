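"""Enterotype stratification: JSD distances, PAM clustering, stability filtering, PCoA.

Samples are clustered on the square root of the Jensen-Shannon divergence
between their genus composition profiles, using partitioning around medoids
(PAM).  The optimal cluster number is chosen with a distance-based
Calinski-Harabasz (pseudo-F) index.  Cluster labels are anchored to the two
pig enterotypes: PM (Prevotella/Mitsuokella-driven) and RT
(Ruminococcus/Treponema-driven).  Repeating the clustering from random PAM
starts and keeping only samples whose label never changes yields the
"stable" subsets used for enterotype contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)

PM = "PM"
RT = "RT"
UNSTABLE = "unstable"

_JSD_PSEUDO = 1e-12


def jsd_distance(P, Q) -> float:
    """Square root of the Jensen-Shannon divergence (natural log) between two
    probability vectors.  Zeros are replaced by a 1e-12 pseudo-count and the
    vectors renormalized.  The result is a metric bounded by sqrt(ln 2)."""
    p = np.asarray(P, dtype=float)
    q = np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    if p.min() < 0 or q.min() < 0:
        raise ValueError("probability vectors must be non-negative")
    for v in (p, q):
        s = v.sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError("probability vectors must sum to 1")
    p = np.maximum(p, _JSD_PSEUDO)
    q = np.maximum(q, _JSD_PSEUDO)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    kl_pm = float((p * np.log(p / m)).sum())
    kl_qm = float((q * np.log(q / m)).sum())
    return float(np.sqrt(max(0.5 * kl_pm + 0.5 * kl_qm, 0.0)))


def jsd_distance_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise sqrt-JSD distances between samples of an abundance table."""
    rel = table.to_relative()
    probs = rel.values / 100.0
    probs = np.maximum(probs, _JSD_PSEUDO)
    probs /= probs.sum(axis=1, keepdims=True)
    logp = np.log(probs)
    n = probs.shape[0]
    D = np.zeros((n, n))
    # entropy identity: JSD(P,Q) = H(M) - (H(P)+H(Q))/2
    H = -(probs * logp).sum(axis=1)
    for i in range(n):
        m = 0.5 * (probs[i] + probs[i + 1 :])
        hm = -(m * np.log(m)).sum(axis=1)
        jsd = hm - 0.5 * (H[i] + H[i + 1 :])
        D[i, i + 1 :] = D[i + 1 :, i] = np.sqrt(np.maximum(jsd, 0.0))
    return pd.DataFrame(D, index=rel.data.index, columns=rel.data.index)


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if D.min() < -1e-12 or not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distances must be non-negative with zero diagonal")
    return D


@dataclass
class PamResult:
    labels: np.ndarray          # cluster index per sample
    medoids: np.ndarray         # sample indices of the medoids
    cost: float                 # total distance of samples to their medoid


def pam_cluster(D, k: int, seed: int = 0, init: str = "build") -> PamResult:
    """Partitioning around medoids on a precomputed distance matrix.

    ``init="build"`` uses the deterministic greedy BUILD phase; ``"random"``
    draws the initial medoids from ``seed`` (used to randomize the repeated
    clustering runs of the stability filter).  The SWAP phase then moves to a
    local optimum of the total within-cluster distance.
    """
    if isinstance(D, pd.DataFrame):
        D = D.to_numpy()
    D = _check_distance(D)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    if init == "random":
        medoids = list(rng.choice(n, size=k, replace=False))
    elif init == "build":
        medoids = [int(np.argmin(D.sum(axis=0)))]
        for _ in range(k - 1):
            dist_to_near = D[:, medoids].min(axis=1)
            # gain of adding candidate c = total reduction in nearest-medoid distance
            gains = np.maximum(dist_to_near[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
    else:
        raise ValueError("init must be 'build' or 'random'")

    medoids = np.array(sorted(medoids))
    non_medoids = np.setdiff1d(np.arange(n), medoids)

    def total_cost(meds: np.ndarray) -> float:
        return float(D[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in non_medoids:
                trial = medoids.copy()
                trial[mi] = h
                c = total_cost(trial)
                if c < cost - 1e-12 and cost - c > best[0]:
                    best = (cost - c, mi, h)
        if best[1] is not None:
            mi, h = best[1], best[2]
            old = medoids[mi]
            medoids[mi] = h
            non_medoids[non_medoids == h] = old
            medoids = np.sort(medoids)
            non_medoids = np.sort(non_medoids)
            cost = total_cost(medoids)
            improved = True
    labels = np.argmin(D[:, medoids], axis=1)
    return PamResult(labels=labels, medoids=medoids, cost=cost)


def calinski_harabasz(D, labels) -> float:
    """Distance-based Calinski-Harabasz (pseudo-F) index.

    Uses the sum-of-squares identity SS = sum_{i<j} d_ij^2 / n, so only the
    distance matrix is needed (no coordinates).
    """
    if isinstance(D, pd.DataFrame):
        D = D.to_numpy()
    D = _check_distance(D)
    labels = np.asarray(labels)
    n = D.shape[0]
    k = len(np.unique(labels))
    D2 = D**2
    total_ss = D2[np.triu_indices(n, 1)].sum() / n
    within = 0.0
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    between = total_ss - within
    if k == 1 or within <= 0:
        return np.inf if between > 0 else 0.0
    return float((between / (k - 1)) / (within / (n - k)))


def optimal_k(D, k_range=range(2, 11), seed: int = 0) -> tuple[int, pd.Series]:
    """Cluster number maximizing the Calinski-Harabasz index over ``k_range``.

    Returns the chosen k and the full index profile.
    """
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("k_range is empty")
    if isinstance(D, pd.DataFrame):
        D = D.to_numpy()
    scores = {}
    for k in ks:
        res = pam_cluster(D, k, seed=seed, init="build")
        scores[k] = calinski_harabasz(D, res.labels)
    profile = pd.Series(scores, name="calinski_harabasz")
    return int(profile.idxmax()), profile


@dataclass
class EnterotypeAssignment:
    sample_id: object
    label: str        # PM, RT or unstable
    stability: float  # fraction of iterations agreeing with the modal label


def _anchor_score(table: AbundanceTable) -> pd.Series:
    """Per-sample PM-ness: Prevotella(+sub-genera) plus Mitsuokella abundance."""
    from .abundance import PREVOTELLA_MEMBERS

    cols = [c for c in (*PREVOTELLA_MEMBERS, "Prevotella_sum", "Mitsuokella") if c in table.data.columns]
    if not cols:
        raise ValueError(
            "no Prevotella/Mitsuokella anchor taxa found; cannot orient PM/RT labels"
        )
    return table.data[cols].sum(axis=1)


def assign_enterotypes(
    table: AbundanceTable,
    iterations: int = 100,
    seed: int = 0,
    stability_filter: bool = True,
) -> list[EnterotypeAssignment]:
    """Cluster samples into the two enterotypes with a repeated-PAM stability filter.

    PAM with k=2 is run ``iterations`` times from random medoid starts; in each
    run the cluster with the higher mean Prevotella+Mitsuokella abundance is
    labelled PM, the other RT.  A sample's label is its modal label across
    runs, with ``stability`` the fraction of runs agreeing; when the stability
    filter is on, any sample that ever changed group is labelled ``unstable``.
    """
    rel = table.to_relative()
    if len(rel.data) < 4:
        raise ValueError("need at least 4 samples to cluster")
    anchor = _anchor_score(rel)
    D = jsd_distance_matrix(rel).to_numpy()
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    pm_votes = np.zeros(n, dtype=int)
    for _ in range(iterations):
        res = pam_cluster(D, 2, seed=int(rng.integers(2**31)), init="random")
        mean0 = anchor.to_numpy()[res.labels == 0].mean()
        mean1 = anchor.to_numpy()[res.labels == 1].mean()
        pm_cluster_idx = 0 if mean0 >= mean1 else 1
        pm_votes += (res.labels == pm_cluster_idx).astype(int)
    out = []
    for i, sid in enumerate(rel.data.index):
        frac_pm = pm_votes[i] / iterations
        modal = PM if frac_pm >= 0.5 else RT
        stability = frac_pm if modal == PM else 1.0 - frac_pm
        label = modal
        if stability_filter and stability < 1.0:
            label = UNSTABLE
        out.append(EnterotypeAssignment(sid, label, float(stability)))
    return out


def assignments_frame(assignments: list[EnterotypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {"label": [a.label for a in assignments], "stability": [a.stability for a in assignments]},
        index=pd.Index([a.sample_id for a in assignments], name="sample_id"),
    )


def pcoa(D, n_axes: int = 2):
    """Classical metric multidimensional scaling (principal coordinates).

    Returns ``(coordinates, eigenvalues)``: coordinates is a DataFrame with
    ``n_axes`` columns ordered by decreasing eigenvalue; the full eigenvalue
    vector (negative values included) is returned alongside.
    """
    ids = None
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        D = D.to_numpy()
    D = _check_distance(D)
    if ids is None:
        ids = list(range(D.shape[0]))
    dm = skbio.DistanceMatrix(D, ids=[str(i) for i in ids])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    pos = int((eigvals > 1e-10).sum())
    if n_axes > pos:
        logger.warning("pcoa: requested %d axes but only %d positive eigenvalues", n_axes, pos)
        n_axes = max(pos, 1)
    frame = pd.DataFrame(
        coords[:, :n_axes],
        index=pd.Index(ids, name="sample_id"),
        columns=[f"PCo{i+1}" for i in range(n_axes)],
    )
    return frame, eigvals
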