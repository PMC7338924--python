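"""Flavor-health co-mention association analysis.

Posts mentioning exactly one distinct flavor keyword and at least one
health keyword are decomposed into (user, post, flavor category, health
category) entries — one entry per distinct health keyword. For each
health category a marginal logistic model is fitted by generalized
estimating equations (GEE): the outcome is the indicator that an
entry's health category equals the modeled one, the design is a
cell-means indicator over flavor categories (no intercept, so the
inverse-logit of each coefficient *is* that flavor's co-mention
probability), and repeated entries from the same user are handled with
an exchangeable (compound-symmetry) working correlation and a robust
sandwich covariance. Pairwise flavor contrasts within each health
category are adjusted with the single-step Tukey method on the
studentized range at infinite degrees of freedom.

The estimating equations sum over user clusters i:

    U(beta) = sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,
    V_i = phi A_i^{1/2} R(alpha) A_i^{1/2},

with A_i the diagonal of binomial variances, R exchangeable, and alpha
and phi re-estimated from Pearson residuals (moment estimators) at each
Fisher-scoring step. The reported covariance is the sandwich
B^{-1} M B^{-1} with bread B = sum_i D_i'V_i^{-1}D_i and meat
M = sum_i g_i g_i', g_i = D_i'V_i^{-1}(y_i - mu_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import ClassifiedPost, KeywordTaxonomy, Post, classify_post

__all__ = [
    "AssociationEntry",
    "GEEFit",
    "PairwiseContrast",
    "extract_entries",
    "fit_gee",
    "estimate_probabilities",
    "pairwise_tukey",
    "heatmap_table",
]


@dataclass(frozen=True)
class AssociationEntry:
    """One (user, post, flavor, health) co-mention record."""

    user_id: str
    post_id: str
    flavor_category: str
    health_category: str


def extract_entries(
    posts: Iterable[Post],
    health: KeywordTaxonomy,
    flavor: KeywordTaxonomy,
    classified: Mapping[str, ClassifiedPost] | None = None,
) -> list[AssociationEntry]:
    """Entries from posts with exactly one distinct flavor keyword and
    at least one health keyword: one entry per distinct health keyword,
    carrying that keyword's category. Pre-computed classifications can
    be passed to avoid re-matching."""
    entries: list[AssociationEntry] = []
    for post in posts:
        cls = (
            classified.get(post.post_id)
            if classified is not None
            else classify_post(post, health, flavor)
        )
        if cls is None:
            cls = classify_post(post, health, flavor)
        if len(cls.flavor_keywords) != 1 or not cls.health_keywords:
            continue
        flavor_cat = next(iter(cls.flavor_categories))
        for hk in sorted(cls.health_keywords):
            entries.append(
                AssociationEntry(
                    user_id=post.user_id,
                    post_id=post.post_id,
                    flavor_category=flavor_cat,
                    health_category=health.category_of(hk),
                )
            )
    return entries


@dataclass
class GEEFit:
    """Fitted marginal logistic model for one health category."""

    health_category: str
    flavor_levels: list[str]  # levels in the design, in order
    beta: np.ndarray  # log-odds per flavor level
    robust_cov: np.ndarray
    alpha_hat: float
    phi_hat: float
    n_entries: int
    n_users: int
    converged: bool
    n_iter: int
    corstr: str = "exchangeable"
    boundary: dict[str, int] = field(default_factory=dict)  # flavor -> 0/1
    dropped_levels: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))


def _design(
    entries: Sequence[AssociationEntry], health_category: str, min_entries: int
):
    """Outcome vector, cell-means design, cluster ids; boundary and
    undersized flavor levels are split off."""
    df = pd.DataFrame(
        {
            "user": [e.user_id for e in entries],
            "flavor": [e.flavor_category for e in entries],
            "y": [1.0 if e.health_category == health_category else 0.0 for e in entries],
        }
    )
    boundary: dict[str, int] = {}
    dropped: list[str] = []
    levels: list[str] = []
    for level, grp in df.groupby("flavor", sort=True):
        if len(grp) < min_entries:
            dropped.append(level)
        elif grp["y"].nunique() == 1:
            boundary[level] = int(grp["y"].iloc[0])
        else:
            levels.append(level)
    keep = df["flavor"].isin(levels)
    df = df.loc[keep].reset_index(drop=True)
    X = np.zeros((len(df), len(levels)))
    for j, level in enumerate(levels):
        X[df["flavor"].to_numpy() == level, j] = 1.0
    return df, X, levels, boundary, dropped


def _exchangeable_rinv_apply(v: np.ndarray, alpha: float) -> np.ndarray:
    """R(alpha)^{-1} v for exchangeable R of the vector's length."""
    m = v.shape[0]
    if m == 1 or alpha == 0.0:
        return v.copy()
    c1 = 1.0 / (1.0 - alpha)
    c2 = -alpha / ((1.0 - alpha) * (1.0 + (m - 1) * alpha))
    return c1 * v + c2 * v.sum()


def fit_gee(
    entries: Sequence[AssociationEntry],
    health_category: str,
    corstr: str = "exchangeable",
    tol: float = 1e-6,
    max_iter: int = 100,
    min_entries: int = 1,
) -> GEEFit:
    """Binomial-logit GEE with cell-means flavor coding.

    Initialized at the independence solution; ``corstr`` is
    ``exchangeable`` or ``independence``. Flavor levels with fewer than
    ``min_entries`` entries are dropped with a warning; levels whose
    outcome is constant sit on the boundary of the parameter space and
    are reported via ``boundary`` instead of a diverging coefficient.
    """
    if corstr not in ("exchangeable", "independence"):
        raise ValueError(f"unknown working correlation {corstr!r}")
    df, X, levels, boundary, dropped = _design(entries, health_category, min_entries)
    if dropped:
        warnings.warn(
            f"{health_category}: flavor levels {dropped} below "
            f"min_entries={min_entries} dropped"
        )
    n_users_total = len({e.user_id for e in entries})
    if len(levels) < 1:
        return GEEFit(
            health_category, [], np.empty(0), np.empty((0, 0)),
            0.0, 1.0, len(entries), n_users_total, True, 0, corstr,
            boundary, dropped,
        )
    y = df["y"].to_numpy()
    clusters = [idx.to_numpy() for _, idx in df.groupby("user").groups.items()]
    n, p = X.shape

    # Independence initialization = per-cell empirical log-odds
    beta = np.zeros(p)
    for j in range(p):
        pj = y[X[:, j] == 1].mean()
        beta[j] = np.log(pj / (1 - pj))

    alpha_hat, phi_hat = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        var = mu * (1.0 - mu)
        sd = np.sqrt(var)
        resid = (y - mu) / sd  # Pearson

        phi_hat = float(resid @ resid) / (n - p)
        if corstr == "exchangeable":
            num, n_pairs = 0.0, 0
            max_m = 1
            for idx in clusters:
                r = resid[idx]
                m = r.shape[0]
                max_m = max(max_m, m)
                if m > 1:
                    num += (r.sum() ** 2 - (r**2).sum()) / 2.0
                    n_pairs += m * (m - 1) // 2
            denom = (n_pairs - p) * phi_hat
            alpha_hat = num / denom if denom > 0 else 0.0
            lower = -1.0 / (max_m - 1) + 1e-6 if max_m > 1 else 0.0
            alpha_hat = float(np.clip(alpha_hat, lower, 0.999))
        else:
            alpha_hat = 0.0

        B = np.zeros((p, p))
        U = np.zeros(p)
        for idx in clusters:
            Xi = X[idx]
            sdi = sd[idx]
            # D_i' V_i^{-1} = (1/phi) X_i' A^{1/2} R^{-1} A^{-1/2}
            left = Xi.T * sdi  # p x m
            ri = _exchangeable_rinv_apply((y[idx] - mu[idx]) / sdi, alpha_hat)
            U += left @ ri / phi_hat
            rm = np.column_stack(
                [_exchangeable_rinv_apply(sdi * Xi[:, j], alpha_hat) for j in range(p)]
            )
            B += left @ rm / phi_hat
        delta = np.linalg.solve(B, U)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # Sandwich covariance at the final beta
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    sd = np.sqrt(mu * (1.0 - mu))
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for idx in clusters:
        Xi = X[idx]
        sdi = sd[idx]
        left = Xi.T * sdi
        g = left @ _exchangeable_rinv_apply((y[idx] - mu[idx]) / sdi, alpha_hat) / phi_hat
        M += np.outer(g, g)
        rm = np.column_stack(
            [_exchangeable_rinv_apply(sdi * Xi[:, j], alpha_hat) for j in range(p)]
        )
        B += left @ rm / phi_hat
    Binv = np.linalg.inv(B)
    robust_cov = Binv @ M @ Binv
    robust_cov = (robust_cov + robust_cov.T) / 2.0

    return GEEFit(
        health_category=health_category,
        flavor_levels=levels,
        beta=beta,
        robust_cov=robust_cov,
        alpha_hat=alpha_hat,
        phi_hat=phi_hat,
        n_entries=len(entries),
        n_users=n_users_total,
        converged=converged,
        n_iter=it,
        corstr=corstr,
        boundary=boundary,
        dropped_levels=dropped,
    )


@dataclass(frozen=True)
class ProbabilityEstimate:
    probability: float
    se: float | None
    boundary: bool = False


def estimate_probabilities(fit: GEEFit) -> dict[str, ProbabilityEstimate]:
    """Co-mention probability per flavor: inverse-logit of the cell-mean
    coefficient, with the delta-method robust standard error
    p(1-p) * se(beta). Boundary cells report probability 0/1, no se."""
    out: dict[str, ProbabilityEstimate] = {}
    ses = fit.se() if fit.beta.size else np.empty(0)
    for j, level in enumerate(fit.flavor_levels):
        prob = 1.0 / (1.0 + np.exp(-fit.beta[j]))
        out[level] = ProbabilityEstimate(float(prob), float(prob * (1 - prob) * ses[j]))
    for level, value in fit.boundary.items():
        out[level] = ProbabilityEstimate(float(value), None, boundary=True)
    return dict(sorted(out.items()))


@dataclass(frozen=True)
class PairwiseContrast:
    health_category: str
    flavor_a: str
    flavor_b: str
    estimate: float  # difference in log-odds
    se: float
    z: float
    p_adj: float
    significant: bool
    degenerate: bool = False


def pairwise_tukey(fit: GEEFit, sig_level: float = 0.05) -> list[PairwiseContrast]:
    """All k(k-1)/2 flavor contrasts with single-step Tukey adjustment:
    p_adj = P(Q_{k, inf} >= |z| * sqrt(2)) on the studentized range.
    At k = 2 this reduces exactly to the unadjusted two-sided normal p.
    """
    k = len(fit.flavor_levels)
    if k < 2:
        return []
    out: list[PairwiseContrast] = []
    for a in range(k):
        for b in range(a + 1, k):
            est = float(fit.beta[a] - fit.beta[b])
            var = (
                fit.robust_cov[a, a]
                + fit.robust_cov[b, b]
                - 2.0 * fit.robust_cov[a, b]
            )
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0.0:
                out.append(
                    PairwiseContrast(
                        fit.health_category, fit.flavor_levels[a],
                        fit.flavor_levels[b], est, 0.0, float("nan"),
                        1.0, False, degenerate=True,
                    )
                )
                continue
            z = est / se
            p_adj = float(
                stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf)
            )
            out.append(
                PairwiseContrast(
                    fit.health_category, fit.flavor_levels[a],
                    fit.flavor_levels[b], est, se, z, p_adj,
                    p_adj < sig_level,
                )
            )
    return out


def heatmap_table(
    fits: Sequence[GEEFit],
    flavor_order: Sequence[str] | None = None,
    health_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flavor x health matrix of estimated co-mention probabilities.

    Cells excluded from a fit (undersized or absent levels) are missing
    (NaN); boundary cells carry their degenerate 0/1 probability.
    """
    probs: dict[str, dict[str, float]] = {}
    for fit in fits:
        for level, est in estimate_probabilities(fit).items():
            probs.setdefault(level, {})[fit.health_category] = est.probability
    flavors = list(flavor_order) if flavor_order else sorted(probs)
    healths = (
        list(health_order) if health_order else [f.health_category for f in fits]
    )
    table = pd.DataFrame(index=flavors, columns=healths, dtype=float)
    for fl in flavors:
        for h in healths:
            table.loc[fl, h] = probs.get(fl, {}).get(h, np.nan)
    table.index.name = "flavor"
    table.columns.name = "health"
    return table
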