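"""Animal-model REML: heritability, litter effects and genetic correlations.

The mixed model is y = Xb + Z_a u + Z_c l + e with u ~ N(0, sigma2_a * A)
(A the pedigree additive relationship matrix), l ~ N(0, sigma2_c * I) a
common-litter effect, and e ~ N(0, sigma2_e * I).  Variance components are
estimated by restricted maximum likelihood with average-information updates
and a monotone (step-halved / EM) fallback, so the restricted log-likelihood
never decreases.  Heritability is h2 = sigma2_a / (sigma2_a + sigma2_c +
sigma2_e) and the common-litter fraction c2 = sigma2_c / (same denominator).

Bivariate fits without a litter effect use an eigendecomposition of the
relationship matrix, which diagonalizes the model into independent 2x2
blocks and makes the restricted likelihood cheap enough for direct
quasi-Newton maximization; with litter effects the generic dense
average-information path is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import Pedigree, a_matrix

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """REML failed to converge within the iteration budget."""


@dataclass
class VarianceComponents:
    """Estimated variance components and derived genetic parameters."""

    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    h2: float
    c2: float
    se: dict = field(default_factory=dict)
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    boundary: bool = False
    # bivariate extras
    genetic_covariance: float | None = None
    rG: float | None = None
    rG_se: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generic dense AI-REML over V(theta) = sum_i theta_i * G_i
# ---------------------------------------------------------------------------


def _reml_loglik(y, X, V):
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    cx = linalg.cho_factor(XtViX)
    logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = linalg.cho_solve(cx, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    ll = -0.5 * (logdet_v + logdet_x + yPy)
    return ll, beta


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    is_variance: list[bool] | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    floor_frac: float = 1e-10,
    ll_trace: list | None = None,
):
    """Maximize the restricted likelihood of V = sum_i theta_i * structures[i].

    Returns ``(theta, se, loglik, n_iter, boundary)``.  ``is_variance`` marks
    parameters constrained to be non-negative (covariance parameters of a
    multi-trait fit are unconstrained).  Updates are average-information
    steps; when a step leaves the parameter space or would decrease the
    restricted log-likelihood it is halved, falling back to an
    expectation-maximization step, so the log-likelihood is non-decreasing.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    m = len(structures)
    if is_variance is None:
        is_variance = [True] * m
    vp = float(np.var(y)) or 1.0
    floor = floor_frac * vp
    if start is None:
        start = np.full(m, vp / m)
    theta = np.array(start, dtype=float)
    theta[np.array(is_variance) & (theta < floor)] = max(floor, vp * 1e-3)

    def build_v(th):
        V = np.zeros((n, n))
        for t, G in zip(th, structures):
            V += t * G
        return V

    def loglik(th):
        try:
            ll, _ = _reml_loglik(y, X, build_v(th))
            return ll
        except linalg.LinAlgError:
            return -np.inf

    ll = loglik(theta)
    if not np.isfinite(ll):
        raise ConvergenceError("restricted likelihood not finite at starting values")
    ai = None
    n_iter = 0
    trace = ll_trace if ll_trace is not None else []
    trace.append(ll)
    for n_iter in range(1, max_iter + 1):
        V = build_v(theta)
        c, low = linalg.cho_factor(V, lower=True)
        Vi = linalg.cho_solve((c, low), np.eye(n))
        ViX = Vi @ X
        XtViX_inv = linalg.inv(X.T @ ViX)
        P = Vi - ViX @ XtViX_inv @ ViX.T
        Py = P @ y
        W = np.column_stack([G @ Py for G in structures])  # n x m
        traces = np.array([np.sum(P * G) for G in structures])
        quad = W.T @ Py  # y' P G_i P y
        score = -0.5 * (traces - quad)
        PW = P @ W
        ai = 0.5 * (W.T @ PW)

        # average-information proposal with monotone safeguard; parameters at
        # the boundary with a negative gradient are frozen (active-set step)
        active = [
            i for i in range(m)
            if not is_variance[i] or theta[i] > 10 * floor or score[i] > 0
        ]
        delta = np.zeros(m)
        try:
            sub = np.ix_(active, active)
            delta[active] = linalg.solve(ai[sub], score[active], assume_a="sym")
        except linalg.LinAlgError:
            delta[active] = score[active] / max(np.trace(ai) / m, 1.0)
        accepted = False
        for _ in range(12):
            cand = theta + delta
            for i in range(m):
                if is_variance[i] and cand[i] < floor:
                    cand[i] = floor
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            delta *= 0.5
        if not accepted:
            # EM fallback: guaranteed ascent direction for variance parameters
            cand = theta + (theta**2 / n) * (quad - traces)
            for i in range(m):
                if is_variance[i] and cand[i] < floor:
                    cand[i] = floor
            ll_new = loglik(cand)
            if ll_new < ll - 1e-8:
                break  # converged to numerical precision
        d_par = np.max(np.abs(cand - theta)) / vp
        d_ll = ll_new - ll
        theta, ll = cand, ll_new
        trace.append(ll)
        if n_iter >= 3 and (abs(d_ll) < tol_ll or d_par < tol_par):
            break
    else:
        raise ConvergenceError(f"AI-REML did not converge in {max_iter} iterations; trace={trace[-5:]}")

    boundary = any(is_variance[i] and theta[i] <= floor * 1.01 for i in range(m))
    try:
        ai_inv = linalg.inv(ai)
        se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except linalg.LinAlgError:
        ai_inv = np.full((m, m), np.nan)
        se = np.full(m, np.nan)
    return theta, se, ai_inv, ll, n_iter, boundary


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _design_matrix(data: pd.DataFrame, fixed: tuple[str, ...]) -> np.ndarray:
    """Intercept + treatment-coded dummies (reference = lexicographically first)."""
    cols = [np.ones(len(data))]
    for f in fixed:
        levels = sorted(map(str, data[f].astype(str).unique()))
        if len(levels) < 2:
            continue
        for lev in levels[1:]:
            cols.append((data[f].astype(str) == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient fixed-effects design for factors {fixed}")
    return X


def _prepare(data: pd.DataFrame, ped: Pedigree, trait: str, fixed, litter):
    df = data.dropna(subset=[trait]).copy()
    df["animal"] = df["animal"].astype(str)
    y = df[trait].to_numpy(dtype=float)
    X = _design_matrix(df, tuple(f for f in fixed if f in df.columns))
    A = a_matrix(ped).loc[df["animal"], df["animal"]].to_numpy()
    structures = [A]
    names = ["sigma2_a"]
    if litter is not None and litter in df.columns:
        lit = df[litter].astype(str).to_numpy()
        if len(np.unique(lit)) >= 2:
            Zc = (lit[:, None] == np.unique(lit)[None, :]).astype(float)
            structures.append(Zc @ Zc.T)
            names.append("sigma2_c")
    structures.append(np.eye(len(df)))
    names.append("sigma2_e")
    return df, y, X, structures, names


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------


def reml_fit(
    data: pd.DataFrame,
    ped: Pedigree,
    trait: str,
    fixed: tuple[str, ...] = ("sex", "batch"),
    litter: str | None = "litter",
    max_iter: int = 200,
) -> VarianceComponents:
    """Univariate animal-model REML fit for one trait.

    ``data`` has one row per phenotyped animal with columns ``animal``, the
    trait, the fixed factors and the litter column.  Returns heritability,
    the common-litter fraction and their standard errors (delta method from
    the inverse average-information matrix).
    """
    df, y, X, structures, names = _prepare(data, ped, trait, fixed, litter)
    if litter is not None and litter in df.columns and df[litter].nunique() < 2:
        raise ValueError("need at least 2 litters for a litter effect")
    sd = float(np.std(y)) or 1.0
    theta, se, ai_inv, ll, n_iter, boundary = ai_reml(y / sd, X, structures, max_iter=max_iter)
    theta, se, ai_inv = theta * sd**2, se * sd**2, ai_inv * sd**4
    comp = dict(zip(names, theta))
    s2a = comp["sigma2_a"]
    s2c = comp.get("sigma2_c", 0.0)
    s2e = comp["sigma2_e"]
    total = s2a + s2c + s2e
    h2, c2 = s2a / total, s2c / total

    se_map = dict(zip(names, se))
    # delta method for ratios of the variance components
    grads = {}
    idx = {nm: i for i, nm in enumerate(names)}
    g_h2 = np.zeros(len(names))
    for nm in names:
        g_h2[idx[nm]] = (total - s2a) / total**2 if nm == "sigma2_a" else -s2a / total**2
    grads["h2"] = g_h2
    if "sigma2_c" in names:
        g_c2 = np.zeros(len(names))
        for nm in names:
            g_c2[idx[nm]] = (total - s2c) / total**2 if nm == "sigma2_c" else -s2c / total**2
        grads["c2"] = g_c2
    for key, g in grads.items():
        var = float(g @ ai_inv @ g)
        se_map[key] = np.sqrt(var) if var > 0 else np.nan

    if boundary:
        logger.warning("reml_fit(%s): a variance component is at its lower boundary", trait)
    return VarianceComponents(
        sigma2_a=s2a, sigma2_c=s2c, sigma2_e=s2e, h2=h2, c2=c2,
        se=se_map, loglik=ll, n_iter=n_iter, boundary=boundary,
    )


def heritability_binary(
    data: pd.DataFrame,
    ped: Pedigree,
    trait: str = "enterotype01",
    fixed: tuple[str, ...] = ("sex", "batch"),
    litter: str | None = "litter",
) -> VarianceComponents:
    """Heritability of a 0/1 enterotype label fitted on the observed scale.

    The binary label is analyzed with the same linear animal model as a
    continuous trait.  The liability-scale conversion
    h2_liab = h2_obs * p(1-p) / z^2 (z the normal density at the threshold)
    is reported in ``extra`` as supplementary output.
    """
    labels = data[trait].dropna().unique()
    if len(labels) < 2:
        raise ValueError("binary trait has a single class")
    vc = reml_fit(data, ped, trait, fixed=fixed, litter=litter)
    p = float(data[trait].mean())
    z = stats.norm.pdf(stats.norm.ppf(1 - p))
    vc.extra["h2_liability"] = vc.h2 * p * (1 - p) / z**2 if z > 0 else np.nan
    vc.extra["prevalence"] = p
    return vc


def bivariate_reml(
    data: pd.DataFrame,
    ped: Pedigree,
    trait_a: str,
    trait_b: str,
    fixed: tuple[str, ...] = ("sex", "batch"),
    litter: str | None = None,
    compute_se: bool = True,
) -> VarianceComponents:
    """Two-trait animal-model REML; returns the genetic correlation rG.

    Without a litter effect (the default) the relationship matrix is
    eigendecomposed once, which reduces the restricted likelihood to a sum of
    independent 2x2 blocks; with ``litter`` set, the generic dense
    average-information algorithm is used on the stacked system.
    """
    df = data.dropna(subset=[trait_a, trait_b]).copy()
    df["animal"] = df["animal"].astype(str)
    if not len(df):
        raise ValueError("no animals with both traits observed")
    ya = df[trait_a].to_numpy(dtype=float)
    yb = df[trait_b].to_numpy(dtype=float)
    sda = float(np.std(ya)) or 1.0
    sdb = float(np.std(yb)) or 1.0
    X = _design_matrix(df, tuple(f for f in fixed if f in df.columns))
    A = a_matrix(ped).loc[df["animal"], df["animal"]].to_numpy()

    if litter is None:
        out = _bivariate_eigen(ya / sda, yb / sdb, X, A, compute_se=compute_se)
    else:
        out = _bivariate_dense(df, ya / sda, yb / sdb, X, A, litter)

    # back to the original trait scales
    scale = np.array([sda**2, sda * sdb, sdb**2])
    out.extra["Sigma_a"] = out.extra["Sigma_a"] * scale
    out.extra["Sigma_e"] = out.extra["Sigma_e"] * scale
    out.sigma2_a = float(out.extra["Sigma_a"][0])
    out.genetic_covariance = float(out.extra["Sigma_a"][1])
    return out


def _bivariate_eigen(ya, yb, X, A, compute_se=True):
    n, p = X.shape
    d, U = linalg.eigh(A)
    d = np.maximum(d, 1e-9)
    ys = np.column_stack([U.T @ ya, U.T @ yb])  # n x 2
    Xs = U.T @ X

    def unpack(par):
        la = np.array([[np.exp(par[0]), 0.0], [par[1], np.exp(par[2])]])
        le = np.array([[np.exp(par[3]), 0.0], [par[4], np.exp(par[5])]])
        return la @ la.T, le @ le.T

    def sigmas_to_par(Sa, Se):
        out = []
        for S in (Sa, Se):
            L = linalg.cholesky(S, lower=True)
            out += [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]
        return np.array(out)

    def neg_ll_from_sigmas(Sa, Se):
        # V_j = d_j * Sa + Se per eigen-coordinate
        v11 = d * Sa[0, 0] + Se[0, 0]
        v12 = d * Sa[0, 1] + Se[0, 1]
        v22 = d * Sa[1, 1] + Se[1, 1]
        det = v11 * v22 - v12**2
        if np.any(det <= 0) or np.any(v11 <= 0):
            return np.inf
        i11, i12, i22 = v22 / det, -v12 / det, v11 / det
        logdet_v = float(np.log(det).sum())
        # 2p x 2p GLS normal equations assembled blockwise
        g11 = Xs.T @ (Xs * i11[:, None])
        g12 = Xs.T @ (Xs * i12[:, None])
        g22 = Xs.T @ (Xs * i22[:, None])
        M = np.block([[g11, g12], [g12, g22]])
        r1 = Xs.T @ (i11 * ys[:, 0] + i12 * ys[:, 1])
        r2 = Xs.T @ (i12 * ys[:, 0] + i22 * ys[:, 1])
        r = np.concatenate([r1, r2])
        sign, logdet_x = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(M, r)
        yViy = float(i11 @ ys[:, 0] ** 2 + 2 * (i12 @ (ys[:, 0] * ys[:, 1])) + i22 @ ys[:, 1] ** 2)
        yPy = yViy - float(r @ beta)
        return 0.5 * (logdet_v + logdet_x + yPy)

    def neg_ll(par):
        Sa, Se = unpack(par)
        return neg_ll_from_sigmas(Sa, Se)

    # moment-based start: half the phenotypic (co)variance in each component
    Sp = np.cov(np.column_stack([ya, yb]).T)
    start = sigmas_to_par(0.5 * Sp + 1e-4 * np.eye(2), 0.5 * Sp + 1e-4 * np.eye(2))
    res = optimize.minimize(neg_ll, start, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"bivariate REML failed: {res.message}")
    Sa, Se = unpack(res.x)
    rg = float(Sa[0, 1] / np.sqrt(Sa[0, 0] * Sa[1, 1]))
    boundary = abs(rg) > 1
    rg = float(np.clip(rg, -1.0, 1.0))
    h2a = Sa[0, 0] / (Sa[0, 0] + Se[0, 0])
    h2b = Sa[1, 1] / (Sa[1, 1] + Se[1, 1])

    rg_se = None
    se = {}
    if compute_se:
        # numerical Hessian on the (co)variance scale, delta method for rG
        v0 = np.array([Sa[0, 0], Sa[0, 1], Sa[1, 1], Se[0, 0], Se[0, 1], Se[1, 1]])

        def nll_v(v):
            Sa_ = np.array([[v[0], v[1]], [v[1], v[2]]])
            Se_ = np.array([[v[3], v[4]], [v[4], v[5]]])
            return neg_ll_from_sigmas(Sa_, Se_)

        try:
            H = _numerical_hessian(nll_v, v0)
            cov = linalg.inv(H)
            dvar = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = {"sigma2_aA": dvar[0], "cov_a": dvar[1], "sigma2_aB": dvar[2]}
            g = np.zeros(6)
            sa, sc, sb = v0[0], v0[1], v0[2]
            denom = np.sqrt(sa * sb)
            g[0] = -0.5 * sc / (denom * sa)
            g[1] = 1.0 / denom
            g[2] = -0.5 * sc / (denom * sb)
            var_rg = float(g @ cov @ g)
            rg_se = float(np.sqrt(var_rg)) if var_rg > 0 else None
        except linalg.LinAlgError:
            pass

    return VarianceComponents(
        sigma2_a=float(Sa[0, 0]), sigma2_c=0.0, sigma2_e=float(Se[0, 0]),
        h2=float(h2a), c2=0.0, se=se, loglik=-float(res.fun),
        n_iter=int(res.nit), converged=bool(res.success), boundary=boundary,
        genetic_covariance=float(Sa[0, 1]), rG=rg, rG_se=rg_se,
        extra={
            "Sigma_a": np.array([Sa[0, 0], Sa[0, 1], Sa[1, 1]]),
            "Sigma_e": np.array([Se[0, 0], Se[0, 1], Se[1, 1]]),
            "h2_a": float(h2a), "h2_b": float(h2b),
        },
    )


def _bivariate_dense(df, ya, yb, X, A, litter=None):
    n = len(ya)
    y = np.concatenate([ya, yb])
    Xf = linalg.block_diag(X, X)
    I = np.eye(n)
    L = None
    if litter is not None:
        lit = df[litter].astype(str).to_numpy()
        Zc = (lit[:, None] == np.unique(lit)[None, :]).astype(float)
        L = Zc @ Zc.T

    def two_trait(G, which):
        out = np.zeros((2 * n, 2 * n))
        if which == "aa":
            out[:n, :n] = G
        elif which == "bb":
            out[n:, n:] = G
        else:
            out[:n, n:] = G
            out[n:, :n] = G
        return out

    structures = [two_trait(A, "aa"), two_trait(A, "ab"), two_trait(A, "bb")]
    is_var = [True, False, True]
    start = [0.3, 0.0, 0.3]
    if L is not None:
        structures += [two_trait(L, "aa"), two_trait(L, "bb")]
        is_var += [True, True]
        start += [0.1, 0.1]
    structures += [two_trait(I, "aa"), two_trait(I, "ab"), two_trait(I, "bb")]
    is_var += [True, False, True]
    start += [0.6, 0.0, 0.6]
    theta, se, ai_inv, ll, n_iter, boundary = ai_reml(
        y, Xf, structures, is_variance=is_var, start=np.array(start))
    sa, sab, sb = theta[0], theta[1], theta[2]
    lit_var = theta[3:5] if L is not None else np.zeros(2)
    res_idx = 5 if L is not None else 3
    rg = sab / np.sqrt(max(sa, 1e-12) * max(sb, 1e-12))
    clipped = abs(rg) > 1
    rg = float(np.clip(rg, -1, 1))
    total_a = sa + lit_var[0] + theta[res_idx]
    return VarianceComponents(
        sigma2_a=float(sa), sigma2_c=float(lit_var[0]), sigma2_e=float(theta[res_idx]),
        h2=float(sa / total_a), c2=float(lit_var[0] / total_a),
        se={}, loglik=ll, n_iter=n_iter, boundary=boundary or clipped,
        genetic_covariance=float(sab), rG=rg, rG_se=None,
        extra={
            "Sigma_a": np.array([sa, sab, sb]),
            "Sigma_e": np.array(theta[res_idx:res_idx + 3]),
            "litter": np.array(lit_var),
        },
    )


def _numerical_hessian(f, x0, rel_step=1e-4):
    m = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1e-3)
    H = np.zeros((m, m))
    f0 = f(x0)
    for i in range(m):
        for j in range(i, m):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def precorrect_batch(data: pd.DataFrame, trait: str, batch: str = "batch") -> pd.Series:
    """Residuals of a fixed-effects-only OLS fit of the trait on batch.

    Used as the selection criterion (selection acts on batch-precorrected
    abundances).
    """
    df = data[[trait, batch]].copy()
    y = df[trait].to_numpy(dtype=float)
    X = _design_matrix(df, (batch,))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=data.index, name=trait)
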