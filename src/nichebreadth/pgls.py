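"""Phylogenetic generalized least squares with Pagel's lambda/kappa/delta.

The error covariance of a comparative regression follows the Brownian
expectation on the parasite tree: V_ij is the shared root-to-MRCA path
length of taxa i and j.  Three branch-length transforms, applied in the
order kappa -> delta -> lambda, modulate that expectation:

* kappa: every branch length b -> b**kappa (punctuational vs gradual change);
* delta: element-wise V -> V**delta, rescaled so the maximal diagonal entry
  is preserved (accelerating vs decelerating evolution through time);
* lambda: off-diagonal entries multiplied by lambda (strength of
  phylogenetic signal; lambda = 0 collapses to ordinary least squares).

Transform parameters are optimised by bounded multi-start maximum
likelihood; coefficients are estimated by GLS through a Cholesky whitening
(no explicit matrix inverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import trees

__all__ = [
    "ComparativeData",
    "PglsFit",
    "brownian_cov",
    "transform_cov",
    "gls_fit",
    "pgls_ml",
    "maybe_drop_intercept",
    "DEFAULT_BOUNDS",
]

DEFAULT_BOUNDS = {"lambda": (0.0, 1.0), "kappa": (1e-6, 3.0), "delta": (1e-6, 3.0)}
_JITTER = 1e-10


@dataclass
class ComparativeData:
    """Response, design matrix, and matched tree for one PGLS model.

    ``X`` must carry named columns; include ``"intercept"`` (a column of
    ones) for models with an intercept.  Row order of ``taxa`` fixes the
    covariance row order.
    """

    taxa: list
    y: np.ndarray
    X: pd.DataFrame
    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.taxa) != n or len(self.y) != n:
            raise ValueError("taxa, y, and X must agree in length")
        if np.isnan(self.y).any() or self.X.isna().any().any():
            raise ValueError("missing values are not allowed in a comparative dataset")
        if n < p + 2:
            raise ValueError(f"need n >= p + 2 observations (n={n}, p={p})")
        tips = set(trees.tip_labels(self.tree))
        missing = set(self.taxa) - tips
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        tree: dendropy.Tree,
        intercept: bool = True,
    ) -> "ComparativeData":
        """Build from a taxa-indexed DataFrame, pruning the tree to match."""
        cols = [response, *predictors]
        sub = df[cols].dropna()
        taxa = [t for t in sub.index if t in set(trees.tip_labels(tree))]
        sub = sub.loc[taxa]
        X = pd.DataFrame(index=sub.index)
        if intercept:
            X["intercept"] = 1.0
        for p in predictors:
            X[p] = sub[p].astype(float)
        pruned = trees.prune(tree, taxa)
        return cls(taxa=taxa, y=sub[response].to_numpy(), X=X, tree=pruned)


@dataclass
class PglsFit:
    """Summary of a fitted (P)GLS model."""

    coef: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    loglik: float
    r2: float
    fstat: float
    df_model: int
    df_resid: int
    model_p: float
    lam: float = 1.0
    kappa: float = 1.0
    delta: float = 1.0
    n: int = 0
    method: str = "ml"
    boundary: dict = field(default_factory=dict)
    optimized: tuple = ()
    alternative: Optional["PglsFit"] = None  # companion with/without intercept

    @property
    def has_intercept(self) -> bool:
        return "intercept" in self.coef.index

    def equation(self) -> str:
        """Human-readable fitted equation, through the origin when fitted so."""
        terms = []
        for name, b in self.coef.items():
            if name == "intercept":
                terms.insert(0, f"{b:.3g}")
            else:
                terms.append(f"{b:+.3g} x {name}")
        return " ".join(terms).lstrip("+").strip()


# ---------------------------------------------------------------------------
# Covariance construction


def brownian_cov(t: dendropy.Tree, taxa: Optional[Sequence[str]] = None) -> np.ndarray:
    """Brownian-motion covariance: V_ij = depth of MRCA(i, j), V_ii = tip depth."""
    labels = trees.tip_labels(t)
    if taxa is None:
        taxa = labels
    missing = set(taxa) - set(labels)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    idx = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))
    depths = trees.node_depths(t)
    tips_below: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            tips_below[node] = [lab] if lab in idx else []
            if lab in idx:
                V[idx[lab], idx[lab]] = depths[node]
        else:
            kids = node.child_nodes()
            tips_below[node] = [lab for k in kids for lab in tips_below[k]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for la in tips_below[kids[a]]:
                        for lb in tips_below[kids[b]]:
                            V[idx[la], idx[lb]] = V[idx[lb], idx[la]] = depths[node]
    return V


def transform_cov(
    t: dendropy.Tree,
    lam: float = 1.0,
    kappa: float = 1.0,
    delta: float = 1.0,
    taxa: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Apply Pagel transforms (kappa on branches, then delta, then lambda).

    ``kappa`` rescales every branch length b -> b**kappa (0**0 := 0) before
    the covariance is rebuilt; ``delta`` raises V element-wise to delta and
    rescales so the maximal diagonal entry is preserved (requires an
    ultrametric tree when delta != 1); ``lambda`` multiplies off-diagonal
    entries.  Raises if the result is not positive definite.
    """
    Vk = _cov_at_kappa(t, kappa, taxa)
    return _apply_delta_lambda(Vk, lam, delta, ultrametric=trees.is_ultrametric(t, rtol=1e-6))


def _cov_at_kappa(t: dendropy.Tree, kappa: float, taxa) -> np.ndarray:
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 1.0:
        return brownian_cov(t, taxa=taxa)
    tk = t.clone(depth=1)
    for node in tk.preorder_node_iter():
        if node.parent_node is not None:
            b = node.edge.length or 0.0
            node.edge.length = 0.0 if b == 0.0 else b**kappa
    return brownian_cov(tk, taxa=taxa)


def _apply_delta_lambda(
    Vk: np.ndarray, lam: float, delta: float, ultrametric: bool
) -> np.ndarray:
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    V = Vk
    if delta != 1.0:
        if not ultrametric:
            raise ValueError("delta transform requires an ultrametric tree")
        top = V.diagonal().max()
        Vd = np.power(V, delta)
        scale = top / Vd.diagonal().max() if Vd.diagonal().max() > 0 else 1.0
        V = Vd * scale
    if lam != 1.0:
        d = V.diagonal().copy()
        V = V * lam
        np.fill_diagonal(V, d)
    # positive-definiteness check with jitter tolerance
    try:
        linalg.cholesky(V + _JITTER * np.eye(V.shape[0]), lower=True)
    except linalg.LinAlgError as e:
        raise ValueError(
            "transformed covariance is not positive definite; tighten the "
            "transform bounds"
        ) from e
    return V


# ---------------------------------------------------------------------------
# GLS at a fixed covariance


def _whiten(V: np.ndarray):
    L = linalg.cholesky(V + _JITTER * np.eye(V.shape[0]), lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return L, logdet


def gls_fit(
    cd: ComparativeData,
    V: np.ndarray,
    method: str = "ml",
    lam: float = 1.0,
    kappa: float = 1.0,
    delta: float = 1.0,
) -> PglsFit:
    """GLS estimates at a fixed covariance, via Cholesky whitening.

    beta = (X' V^-1 X)^-1 X' V^-1 y computed by solving triangular systems;
    sigma2 = r' V^-1 r / (n - p); the log-likelihood is ML or REML per
    ``method``.  R^2 and F are computed in the whitened space against the
    GLS intercept-only null (grand-mean null when the design has no
    intercept column, for comparability across the two variants).
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    X = cd.X.to_numpy(dtype=float)
    names = list(cd.X.columns)
    y = cd.y
    n, p = X.shape
    L, logdet = _whiten(V)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("singular design matrix")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)

    # intercept-only GLS null for R^2 / F
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    null_resid = yw - mu * ones_w
    tss = float(null_resid @ null_resid)
    q = p - (1 if "intercept" in names else 0)
    if q > 0 and tss > 0:
        r2 = 1.0 - rss / tss
        fstat = ((tss - rss) / q) / (rss / (n - p))
        model_p = float(stats.f.sf(fstat, q, n - p))
    else:
        r2, fstat, model_p = 0.0, np.nan, np.nan

    if method == "ml":
        s2_ml = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    else:
        s2_reml = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2_reml) + logdet + logdet_xtx + (n - p)
        )

    return PglsFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=float(sigma2),
        loglik=float(ll),
        r2=float(r2),
        fstat=float(fstat),
        df_model=int(q),
        df_resid=int(n - p),
        model_p=model_p,
        lam=lam,
        kappa=kappa,
        delta=delta,
        n=n,
        method=method,
    )


# ---------------------------------------------------------------------------
# ML optimisation of the transforms


def pgls_ml(
    cd: ComparativeData,
    optimize_params: Sequence[str] = ("lambda",),
    bounds: Optional[dict] = None,
    seed: int = 0,
    method: str = "ml",
) -> PglsFit:
    """PGLS with the selected Pagel transforms optimised by profile ML.

    Non-selected parameters stay at 1.  Five starts per run — both bounds,
    the midpoint, and two seeded random points — feed a bounded L-BFGS-B
    search; the best optimum is returned and near-boundary solutions are
    flagged in ``fit.boundary``.
    """
    optimize_params = tuple(optimize_params)
    for p in optimize_params:
        if p not in DEFAULT_BOUNDS:
            raise ValueError(f"unknown transform parameter {p!r}")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    fixed = {"lambda": 1.0, "kappa": 1.0, "delta": 1.0}
    ultrametric = trees.is_ultrametric(cd.tree, rtol=1e-6)
    kappa_cache: dict = {}

    def fit_at(theta: np.ndarray) -> PglsFit:
        params = dict(fixed)
        params.update(dict(zip(optimize_params, theta)))
        kap = params["kappa"]
        key = round(kap, 12)
        if key not in kappa_cache:
            kappa_cache[key] = _cov_at_kappa(cd.tree, kap, cd.taxa)
        V = _apply_delta_lambda(
            kappa_cache[key], params["lambda"], params["delta"], ultrametric
        )
        return gls_fit(
            cd, V, method=method,
            lam=params["lambda"], kappa=params["kappa"], delta=params["delta"],
        )

    if not optimize_params:
        return fit_at(np.array([]))

    lo = np.array([b[p][0] for p in optimize_params])
    hi = np.array([b[p][1] for p in optimize_params])

    Xnp = cd.X.to_numpy(dtype=float)
    ynp = cd.y
    n, p_dim = Xnp.shape

    def nll(theta: np.ndarray) -> float:
        # lean profile (negative) log-likelihood for the optimizer
        params = dict(fixed)
        params.update(dict(zip(optimize_params, theta)))
        try:
            kap = params["kappa"]
            key = round(kap, 12)
            if key not in kappa_cache:
                kappa_cache[key] = _cov_at_kappa(cd.tree, kap, cd.taxa)
            V = _apply_delta_lambda(
                kappa_cache[key], params["lambda"], params["delta"], ultrametric
            )
            L, logdet = _whiten(V)
            Xw = linalg.solve_triangular(L, Xnp, lower=True)
            yw = linalg.solve_triangular(L, ynp, lower=True)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            resid = yw - Xw @ beta
            rss = float(resid @ resid)
            if method == "ml":
                return 0.5 * (n * np.log(2 * np.pi * rss / n) + logdet + n)
            s2 = rss / (n - p_dim)
            _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
            return 0.5 * (
                (n - p_dim) * np.log(2 * np.pi * s2) + logdet + logdet_xtx + (n - p_dim)
            )
        except (ValueError, linalg.LinAlgError):
            return np.inf

    rng = np.random.default_rng(seed)
    starts = [lo, hi, (lo + hi) / 2.0]
    starts += [lo + (hi - lo) * rng.random(len(lo)) for _ in range(2)]

    best = None
    diagnostics = []
    for s in starts:
        res = optimize.minimize(
            nll, s, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": 200},
        )
        diagnostics.append((s, res))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"transform optimisation failed from all starts: {diagnostics}"
        )
    theta = np.clip(best.x, lo, hi)
    fit = fit_at(theta)
    fit.optimized = optimize_params
    tol = 1e-6 * (hi - lo)
    fit.boundary = {
        p: bool(theta[i] - lo[i] <= tol[i] or hi[i] - theta[i] <= tol[i])
        for i, p in enumerate(optimize_params)
    }
    return fit


def maybe_drop_intercept(fit: PglsFit, cd: ComparativeData, alpha: float = 0.05) -> PglsFit:
    """Report a through-the-origin model when the intercept is not significant.

    If the fitted intercept's p-value is >= ``alpha``, the model is refitted
    without the intercept column at the same covariance transform and that
    variant is returned; the discarded variant is kept on ``alternative``.
    """
    if not fit.has_intercept:
        return fit
    if fit.pvalues["intercept"] < alpha:
        return fit
    X0 = cd.X.drop(columns="intercept")
    if X0.shape[1] == 0:
        return fit  # intercept-only model has nothing left to fit
    cd0 = ComparativeData(taxa=cd.taxa, y=cd.y, X=X0, tree=cd.tree)
    V = transform_cov(cd.tree, lam=fit.lam, kappa=fit.kappa, delta=fit.delta, taxa=cd.taxa)
    origin = gls_fit(cd0, V, method=fit.method, lam=fit.lam, kappa=fit.kappa, delta=fit.delta)
    origin.optimized = fit.optimized
    origin.boundary = dict(fit.boundary)
    origin.alternative = fit
    return origin
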