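"""Within- vs between-species repeatability (ICC) of niche-breadth metrics.

Model: one-way Gaussian random-intercept model

    y_ij = mu + a_i + e_ij,   a_i ~ N(0, s2_between),  e_ij ~ N(0, s2_within)

for species i observed in j = 1..n_i regions.  The ICC (repeatability) is
R = s2_between / (s2_between + s2_within).  Variance components are REML
estimates obtained by maximising the likelihood profiled analytically in the
variance ratio theta = s2_between/s2_within; the design may be arbitrarily
unbalanced.  Uncertainty comes from a parametric bootstrap (simulate from
the fitted model, re-estimate R) and the test of s2_between = 0 from a
likelihood-ratio test against the 50:50 mixture of chi2_0 and chi2_1
(boundary-corrected null distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["GroupedValues", "IccResult", "fit_variance_components", "icc"]


@dataclass
class GroupedValues:
    """Observations of one metric, grouped by species."""

    groups: np.ndarray  # group label per observation
    values: np.ndarray

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.values = np.asarray(self.values, dtype=float)
        if self.groups.shape != self.values.shape or self.values.ndim != 1:
            raise ValueError("groups and values must be equal-length 1-d arrays")
        _, counts = np.unique(self.groups, return_counts=True)
        if len(counts) < 2:
            raise ValueError("need at least two groups")
        if not np.any(counts >= 2):
            raise ValueError("need at least one group with two or more observations")

    def summaries(self):
        """(group sizes n_i, group means, within-group SS, grand stats)."""
        labels, inv = np.unique(self.groups, return_inverse=True)
        n_i = np.bincount(inv).astype(float)
        sums = np.bincount(inv, weights=self.values)
        means = sums / n_i
        ssw = np.bincount(inv, weights=(self.values - means[inv]) ** 2)
        return n_i, means, ssw


@dataclass
class IccResult:
    r: float
    se: float
    ci: tuple
    p: float
    sigma2_between: float
    sigma2_within: float
    loglik: float
    n_groups: int
    n_obs: int


def _neg_profile(theta: float, n_i, means, ssw, reml: bool) -> float:
    """Negative profile log-likelihood in theta = s2_b/s2_w (s2_w profiled out)."""
    w = n_i / (1.0 + n_i * theta)
    wsum = w.sum()
    mu = (w * means).sum() / wsum
    q = ssw.sum() + (w * (means - mu) ** 2).sum()
    n = n_i.sum()
    logdet_w = np.log1p(n_i * theta).sum()
    if reml:
        dof = n - 1.0
        crit = dof * np.log(q / dof) + logdet_w + np.log(wsum) + dof
        const = dof * np.log(2 * np.pi)
    else:
        dof = n
        crit = dof * np.log(q / dof) + logdet_w + dof
        const = dof * np.log(2 * np.pi)
    return 0.5 * (crit + const)


def _fit(n_i, means, ssw, reml: bool):
    """Maximise the profile likelihood over theta >= 0; return (s2b, s2w, ll)."""
    obj = lambda th: _neg_profile(th, n_i, means, ssw, reml)
    # coarse grid (incl. the boundary), then bounded refinement around the best
    grid = np.concatenate(([0.0], np.logspace(-8, 6, 57)))
    vals = [obj(t) for t in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        theta = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        theta = float(grid[k])
    if obj(0.0) <= obj(theta):
        theta = 0.0
    n = n_i.sum()
    w = n_i / (1.0 + n_i * theta)
    mu = (w * means).sum() / w.sum()
    q = ssw.sum() + (w * (means - mu) ** 2).sum()
    dof = (n - 1.0) if reml else n
    s2w = q / dof
    s2b = theta * s2w
    return s2b, s2w, -obj(theta), mu


def fit_variance_components(g: GroupedValues):
    """REML variance components of the one-way random-intercept model.

    Returns (sigma2_between, sigma2_within, reml_loglik).  Degenerate input
    with no variation at all yields (0, 0) with a warning.
    """
    n_i, means, ssw = g.summaries()
    if np.ptp(g.values) == 0.0:
        warnings.warn("all values identical; variance components are zero", stacklevel=2)
        return 0.0, 0.0, np.inf
    s2b, s2w, ll, _ = _fit(n_i, means, ssw, reml=True)
    return s2b, s2w, ll


def _ratio(s2b: float, s2w: float) -> float:
    tot = s2b + s2w
    return s2b / tot if tot > 0 else 0.0


def _lrt_p(g: GroupedValues) -> float:
    """Boundary-corrected LRT of s2_between = 0 (ML fits of both models)."""
    n_i, means, ssw = g.summaries()
    _, _, ll1, _ = _fit(n_i, means, ssw, reml=False)
    ll0 = -_neg_profile(0.0, n_i, means, ssw, reml=False)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    if lrt == 0.0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(lrt, df=1))


def icc(g: GroupedValues, n_boot: int = 1000, seed: int = 0) -> IccResult:
    """Repeatability R with bootstrap SE/CI and boundary-corrected LRT p.

    The point estimate is R = s2_b/(s2_b + s2_w) from REML.  SE and the
    (2.5%, 97.5%) percentile CI come from ``n_boot`` parametric-bootstrap
    refits: datasets are simulated from the fitted model on the observed
    group structure and R re-estimated on each.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    n_i, means, ssw = g.summaries()
    degenerate = np.ptp(g.values) == 0.0
    if degenerate:
        warnings.warn("all values identical; repeatability set to 0", stacklevel=2)
        s2b = s2w = 0.0
        ll = np.inf
        mu = float(g.values[0])
    else:
        s2b, s2w, ll, mu = _fit(n_i, means, ssw, reml=True)
    r = _ratio(s2b, s2w)

    rng = np.random.default_rng(seed)
    sizes = n_i.astype(int)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        a = rng.normal(0.0, np.sqrt(s2b), size=len(sizes))
        y = np.concatenate(
            [mu + a[i] + rng.normal(0.0, np.sqrt(s2w), size=sz) for i, sz in enumerate(sizes)]
        )
        if np.ptp(y) == 0.0:
            boots[b] = 0.0
            continue
        gb = np.repeat(np.arange(len(sizes)), sizes)
        nb_i, mb, sb = GroupedValues(gb, y).summaries()
        bs2b, bs2w, _, _ = _fit(nb_i, mb, sb, reml=True)
        boots[b] = _ratio(bs2b, bs2w)
    se = float(np.std(boots, ddof=1))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    p = 1.0 if degenerate else _lrt_p(g)
    return IccResult(
        r=float(r),
        se=se,
        ci=ci,
        p=p,
        sigma2_between=float(s2b),
        sigma2_within=float(s2w),
        loglik=float(ll),
        n_groups=len(n_i),
        n_obs=int(n_i.sum()),
    )
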