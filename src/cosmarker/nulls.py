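"""Empirical null approximation and marker calling.

With only a handful of samples per subtype, a classical two-sample null is
unavailable for the cosine score, so the null distribution is learned from
the scores themselves under the assumption that the vast majority of
features are non-markers.  A finite normal mixture (FNM) is fitted to the
score histogram by EM; to keep true markers from contaminating the fit, an
outer FDR-guided loop alternates between fitting, computing upper one-sided
p-values from the current mixture, and excluding the scores that look
significant, until the excluded set stabilizes.

P-values are upper-tail probabilities of the fitted mixture (large cosine =
marker-like), q-values are Benjamini-Hochberg by default (Storey's pi0
variant available), and markers are accepted at a one-sided p (and
optionally q) threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .preprocess import SubtypeProfile
from .stats import cot_scores, sdg_scores, subtype_scores

__all__ = [
    "FnmNull",
    "MgCall",
    "call_markers",
    "concordance_table",
    "fit_fnm",
    "fit_null_fdr_guided",
    "mixture_quantile",
    "p_value",
    "q_values",
    "select_components_bic",
]

_MIN_VARIANCE = 1e-10


@dataclass
class FnmNull:
    """Finite normal mixture approximating the null of the cosine scores."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    n_iterations_outer: int = 0
    converged: bool = True
    support: tuple[float, float] = (0.0, 1.0)
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.variances) == self.n_components):
            raise ValueError("component arrays must all have length n_components")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("weights must be a probability vector")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.means) / np.sqrt(self.variances)
        return norm.cdf(z) @ self.weights

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.means) / np.sqrt(self.variances)
        return (norm.pdf(z) / np.sqrt(self.variances)) @ self.weights


@dataclass(frozen=True)
class MgCall:
    feature: str
    k_hat: str
    t: float
    p: float
    q: float
    accepted: bool


def _log_mixture_pdf(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    # log sum_c w_c N(x; mu_c, var_c), numerically stable
    log_comp = (
        np.log(w)
        - 0.5 * np.log(2 * np.pi * var)
        - 0.5 * (x[:, None] - mu) ** 2 / var
    )
    m = log_comp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True))).ravel()


def fit_fnm(
    scores,
    n_components: int = 5,
    inner_tol: float = 1e-7,
    max_inner_iter: int = 500,
) -> FnmNull:
    """Maximum-likelihood normal mixture fit of a 1-D score sample by EM.

    Initialization is deterministic: component means at evenly spaced
    quantiles, equal weights, pooled sample variance for every component.
    Convergence is declared when the mean per-observation log-likelihood
    improves by less than ``inner_tol``; the log-likelihood is
    non-decreasing across iterations, and components that collapse
    (variance below 1e-10) are pruned with a warning.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} scores for {n_components} components"
        )

    qs = (np.arange(n_components) + 0.5) / n_components
    mu = np.quantile(x, qs)
    var = np.full(n_components, max(x.var(), _MIN_VARIANCE))
    w = np.full(n_components, 1.0 / n_components)

    prev_ll = -np.inf
    converged = False
    for _ in range(max_inner_iter):
        # E-step: responsibilities
        log_comp = (
            np.log(w) - 0.5 * np.log(2 * np.pi * var) - 0.5 * (x[:, None] - mu) ** 2 / var
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True))
        resp = np.exp(log_comp - log_norm)
        ll = float(log_norm.sum())

        # M-step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk

        degenerate = var < _MIN_VARIANCE
        if np.any(degenerate) and n_components > 1:
            warnings.warn(
                f"pruning {int(degenerate.sum())} degenerate mixture component(s)",
                stacklevel=2,
            )
            keep = ~degenerate
            w, mu, var = w[keep] / w[keep].sum(), mu[keep], var[keep]
            n_components = int(keep.sum())
            prev_ll = -np.inf
            continue
        var = np.maximum(var, _MIN_VARIANCE)

        if ll - prev_ll < inner_tol * x.size:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    order = np.argsort(mu)
    return FnmNull(
        n_components=n_components,
        weights=w[order],
        means=mu[order],
        variances=var[order],
        converged=converged,
        support=(float(x.min()), float(x.max())),
        log_likelihood=prev_ll,
    )


def select_components_bic(scores, candidates=range(1, 8), **kwargs) -> int:
    """Pick the mixture size minimizing BIC over a candidate range."""
    x = np.asarray(scores, dtype=float).ravel()
    best_c, best_bic = None, np.inf
    for c in candidates:
        if x.size < 10 * c:
            continue
        fit = fit_fnm(x, n_components=c, **kwargs)
        n_params = 3 * fit.n_components - 1
        bic = n_params * np.log(x.size) - 2 * fit.log_likelihood
        if bic < best_bic:
            best_c, best_bic = fit.n_components, bic
    if best_c is None:
        raise ValueError("too few scores for any candidate mixture size")
    return best_c


def p_value(t, null: FnmNull) -> np.ndarray | float:
    """Upper one-sided p-value(s): P(T >= t) under the fitted mixture."""
    p = 1.0 - null.cdf(t)
    return float(p) if np.isscalar(t) else p


def mixture_quantile(null: FnmNull, prob: float) -> float:
    """Inverse CDF of the fitted mixture by bracketing + Brent's method."""
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    sd = np.sqrt(null.variances)
    lo = float((null.means - 10 * sd).min())
    hi = float((null.means + 10 * sd).max())
    return float(brentq(lambda t: null.cdf(np.array(t)) - prob, lo, hi, xtol=1e-12))


def _contamination_components(fit: FnmNull, tail_eps: float, max_weight: float) -> np.ndarray:
    """Flag mixture components that look like absorbed true-marker mass.

    A flexible mixture absorbs right-tail contamination into dedicated
    components, so contamination cannot be recognized from score counts; it
    is recognized structurally instead: a component is flagged when it is
    the rightmost unflagged one, its mean lies beyond the upper tail of the
    remaining (null) sub-mixture (tail probability < ``tail_eps``), and the
    total flagged weight stays below ``max_weight`` (the
    most-features-are-null assumption).  Components are means-sorted.
    """
    flagged = np.zeros(fit.n_components, dtype=bool)
    for c in range(fit.n_components - 1, 0, -1):
        rest = ~flagged
        rest[c] = False
        if flagged[:c].any() or not rest.any():
            break
        w = fit.weights[rest] / fit.weights[rest].sum()
        z = (fit.means[c] - fit.means[rest]) / np.sqrt(fit.variances[rest])
        tail = float(norm.sf(z) @ w)
        if tail < tail_eps and fit.weights[flagged].sum() + fit.weights[c] <= max_weight:
            flagged[c] = True
        else:
            break
    return flagged


def fit_null_fdr_guided(
    scores,
    n_components: int = 5,
    p_cut: float = 0.01,
    max_outer_iter: int = 20,
    tail_eps: float = 1e-3,
    max_contamination_weight: float = 0.25,
    **fit_kwargs,
) -> FnmNull:
    """FDR-guided iterative null fit.

    Alternates (1) FNM fit on the currently retained scores, (2) detection
    of contamination-like components (small, rightmost, separated from the
    rest of the mixture; see :func:`_contamination_components`),
    (3) one-sided p-values for *all* scores from the null-only sub-mixture
    and (4) exclusion of scores significant at false-discovery-rate
    ``p_cut`` (BH-adjusted p < ``p_cut``) — until the excluded set is
    identical between consecutive iterations or ``max_outer_iter`` is
    reached.  The returned fit is the full mixture refitted on the retained
    scores.  On marker-free data nothing is flagged and nothing is
    BH-significant, so the loop stops after one pass and the result matches
    :func:`fit_fnm`.  Errors out if more than half the scores would be
    excluded, which signals that the most-features-are-null assumption does
    not hold.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not 0 < p_cut < 0.5:
        raise ValueError("p_cut must be in (0, 0.5)")

    removed: set[int] = set()
    fit = fit_fnm(x, n_components=n_components, **fit_kwargs)
    n_outer = 0
    for n_outer in range(1, max_outer_iter + 1):
        flagged = _contamination_components(fit, tail_eps, max_contamination_weight)
        if flagged.any():
            keep_c = ~flagged
            null_part = FnmNull(
                n_components=int(keep_c.sum()),
                weights=fit.weights[keep_c] / fit.weights[keep_c].sum(),
                means=fit.means[keep_c],
                variances=fit.variances[keep_c],
                support=fit.support,
            )
        else:
            null_part = fit
        p = p_value(x, null_part)
        new_removed = set(np.flatnonzero(q_values(p) < p_cut).tolist())
        if len(new_removed) > 0.5 * x.size:
            raise ValueError(
                "null assumption violated: more than half the scores look significant"
            )
        if new_removed == removed:
            break
        removed = new_removed
        keep = np.ones(x.size, dtype=bool)
        keep[list(removed)] = False
        fit = fit_fnm(x[keep], n_components=n_components, **fit_kwargs)
    fit.n_iterations_outer = n_outer
    return fit


def q_values(ps, method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values.

    ``bh``: Benjamini-Hochberg step-up (default).  ``storey``: BH scaled by
    Storey's pi0 estimate at lambda = 0.5.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(ps, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, np.mean(ps > lam) / (1 - lam))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return q


def concordance_table(
    ts: np.ndarray,
    ps: np.ndarray,
    qs: np.ndarray,
    null: FnmNull,
    p_grid=(0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1),
) -> pd.DataFrame:
    """Survey of thresholds: for each p cutoff, the implied q, the minimal
    accepted cosine (the mixture's upper quantile) and the accepted count."""
    rows = []
    for p_cut in p_grid:
        sel = ps <= p_cut
        rows.append(
            {
                "p_threshold": p_cut,
                "q_at_threshold": float(qs[sel].max()) if sel.any() else np.nan,
                "cos_at_threshold": mixture_quantile(null, 1.0 - p_cut),
                "n_accepted": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def call_markers(
    profile: SubtypeProfile,
    null_mode: str = "pooled",
    n_components: int = 5,
    p_threshold: float = 0.05,
    q_threshold: float | None = None,
    statistic: str = "mg",
    fdr_guided: bool = True,
    p_cut: float = 0.01,
    q_method: str = "bh",
):
    """Score a cleaned profile, fit the empirical null and call markers.

    Parameters
    ----------
    null_mode : ``pooled`` fits one null over every feature's maximal cosine;
        ``per_subtype`` fits one null per subtype over that subtype's cosine
        (robust when marker counts are strongly imbalanced across subtypes).
    statistic : ``mg`` (marker genes, default) or ``sdg``
        (subtype-downregulated genes); ``sdg`` implies pooled mode.
    q_threshold : when given, acceptance additionally requires q <= it.

    Returns
    -------
    (calls, null(s), concordance) : list of :class:`MgCall`; the fitted
    :class:`FnmNull` (or dict subtype -> FnmNull in per-subtype mode); and
    the threshold-concordance table.
    """
    means = profile.means
    fitter = fit_null_fdr_guided if fdr_guided else fit_fnm
    fit_args = {"n_components": n_components}
    if fdr_guided:
        fit_args["p_cut"] = p_cut

    def fit_scores(t: np.ndarray) -> FnmNull:
        # boundary atoms (exact 0: no expression in this subtype; exact 1:
        # exactly ideal marker) are measure-zero under any continuous null
        # and degenerate the EM into zero-variance components; the null is
        # fitted on interior scores while p-values cover every feature
        interior = t[(t > 0.0) & (t < 1.0)]
        if interior.size < 10 * n_components:
            interior = t
        return fitter(interior, **fit_args)

    if statistic == "sdg":
        k_idx, ts = sdg_scores(means)
    elif statistic == "mg":
        k_idx, ts = cot_scores(means)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if null_mode == "pooled" or statistic == "sdg":
        null = fit_scores(ts)
        ps = p_value(ts, null)
        qs = q_values(ps, method=q_method)
        nulls = null
    elif null_mode == "per_subtype":
        nulls = {}
        ps = np.empty_like(ts)
        for j, k in enumerate(profile.subtypes):
            t_k = subtype_scores(means, j)
            nulls[k] = fit_scores(t_k)
            sel = k_idx == j
            ps[sel] = p_value(t_k[sel], nulls[k])
        null = None
        qs = q_values(ps, method=q_method)
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")

    accepted = ps <= p_threshold
    if q_threshold is not None:
        accepted &= qs <= q_threshold

    calls = [
        MgCall(
            feature=profile.features[i],
            k_hat=profile.subtypes[k_idx[i]],
            t=float(ts[i]),
            p=float(ps[i]),
            q=float(qs[i]),
            accepted=bool(accepted[i]),
        )
        for i in range(len(ts))
    ]
    table_null = null if null_mode == "pooled" or statistic == "sdg" else next(iter(nulls.values()))
    table = concordance_table(ts, ps, qs, table_null)
    return calls, nulls, table
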