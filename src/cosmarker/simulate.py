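"""Simulation harness: Dirichlet null data with spiked-in markers, peer
scoring statistics, and pROC/pAUC evaluation.

Null features draw their cross-subtype pattern from a Dirichlet
distribution (or a mixture of Dirichlets, optionally rotated about the
simplex center to produce correlated off-axis patterns), mimicking generic
non-negative expression data.  Marker features are unit vectors perturbed
by a random rotation of bounded angle, clipped to the non-negative orthant.
Every pattern is scaled by a log-normal per-feature magnitude and expanded
into replicate samples with multiplicative log-normal noise.

Evaluation emphasizes the stringent low-FPR regime: partial ROC curves over
FPR in (0.01, 0.05) and the area under them, plus detection power at
FPR = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .io import ExpressionMatrix
from .preprocess import subtype_means
from .stats import cot_scores

__all__ = [
    "PEER_METHODS",
    "RocResult",
    "SimConfig",
    "SimTruth",
    "benchmark",
    "peer_scores",
    "roc_eval",
    "simulate_dataset",
    "standard_settings",
]

PEER_METHODS = ("anova_f", "ovr_t", "ovr_fc", "ove_fc", "ove_sfc")


def null_mixture(
    k: int, base: float = 2.0, off: float = 0.3, shared_weight: float = 0.3
) -> tuple[tuple[tuple[float, ...], ...], tuple[float, ...], tuple[float, ...]]:
    """Default null law: broad symmetric patterns plus pair-shared genes.

    Non-marker genes fall into two classes in real subtype profiles:
    broadly expressed (housekeeping-like) genes, modeled by a symmetric
    Dirichlet(``base``) concentrated away from the simplex vertices, and
    lineage-shared genes expressed in a strict subset of subtypes, modeled
    by Dirichlet components with concentration ``base`` on a pair of
    subtypes and ``off`` elsewhere (mass near the simplex edges, sparse at
    vertices so the null stays distinguishable from true markers).

    Returns ``(alphas, weights, rotations)`` ready for :class:`SimConfig`.
    """
    pairs = list(itertools.combinations(range(k), 2))
    alphas: list[tuple[float, ...]] = [tuple(base for _ in range(k))]
    weights = [1.0 - shared_weight]
    for pair in pairs:
        a = [off] * k
        for j in pair:
            a[j] = base
        alphas.append(tuple(a))
        weights.append(shared_weight / len(pairs))
    return tuple(alphas), tuple(weights), tuple(0.0 for _ in alphas)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one simulated subtype-expression dataset.

    ``dirichlet_alphas`` is one concentration vector per null-mixture
    component, with ``mixture_weights`` summing to 1 and a rotation angle
    (degrees, about the simplex center) per component.  ``mg_deviation`` is
    the maximal angular deviation of a spiked marker from its ideal unit
    vector; ``noise_cv`` the coefficient of variation of the multiplicative
    replicate noise; ``magnitude_sdlog``/``magnitude_scale`` parametrize the
    log-normal per-feature expression magnitude.
    """

    n_features: int = 10_000
    k: int = 3
    samples_per_subtype: int = 3
    dirichlet_alphas: tuple[tuple[float, ...], ...] | None = None
    mixture_weights: tuple[float, ...] | None = None
    rotation_degrees: tuple[float, ...] | None = None
    mg_fraction: float = 0.05
    mg_subtype_weights: tuple[float, ...] | None = None  # default: uniform over subtypes
    mg_deviation: float = 15.0
    magnitude_sdlog: float = 1.0
    magnitude_scale: float = 100.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dirichlet_alphas is None:
            alphas, weights, rotations = null_mixture(self.k)
            object.__setattr__(self, "dirichlet_alphas", alphas)
            if self.mixture_weights is None:
                object.__setattr__(self, "mixture_weights", weights)
            if self.rotation_degrees is None:
                object.__setattr__(self, "rotation_degrees", rotations)
        if self.mixture_weights is None:
            n = len(self.dirichlet_alphas)
            object.__setattr__(self, "mixture_weights", (1.0 / n,) * n)
        if self.rotation_degrees is None:
            object.__setattr__(self, "rotation_degrees", (0.0,) * len(self.dirichlet_alphas))
        if not 0 <= self.mg_fraction <= 0.5:
            raise ValueError("mg_fraction must lie in [0, 0.5]")
        if not 0 <= self.mg_deviation < 90:
            raise ValueError("mg_deviation must lie in [0, 90) degrees")
        if self.k < 2 or self.samples_per_subtype < 1:
            raise ValueError("need K >= 2 and >= 1 sample per subtype")
        if len(self.dirichlet_alphas) != len(self.mixture_weights):
            raise ValueError("one mixing weight per Dirichlet component")
        if len(self.rotation_degrees) != len(self.dirichlet_alphas):
            raise ValueError("one rotation angle per Dirichlet component")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for a in self.dirichlet_alphas:
            if len(a) != self.k or any(x <= 0 for x in a):
                raise ValueError("each alpha vector must be K positive values")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.mg_subtype_weights is not None and (
            len(self.mg_subtype_weights) != self.k
            or abs(sum(self.mg_subtype_weights) - 1.0) > 1e-9
        ):
            raise ValueError("mg_subtype_weights must be K probabilities summing to 1")


@dataclass
class SimTruth:
    """A simulated dataset together with its ground truth."""

    data: ExpressionMatrix
    is_mg: np.ndarray
    mg_subtype: np.ndarray  # subtype index for MG rows, -1 for null rows
    patterns: np.ndarray  # noise-free feature x K patterns (unit magnitude)
    config: SimConfig


@dataclass(frozen=True)
class RocResult:
    fpr_grid: np.ndarray
    tpr: np.ndarray
    pauc: float
    fpr_range: tuple[float, float]
    power_at_fpr05: float


def _simplex_rotation(patterns: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate simplex points about the center, within the sum=1 hyperplane.

    The rotation acts in the plane spanned by the first two vectors of an
    orthonormal basis of the hyperplane; the result is clipped to the
    non-negative orthant and renormalized to the simplex.
    """
    if degrees == 0:
        return patterns
    k = patterns.shape[1]
    # orthonormal basis of {x : sum x = 0} via QR of the centering projector
    basis = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    theta = np.radians(degrees)
    rot = np.eye(k - 1)
    rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    center = np.full(k, 1.0 / k)
    coords = (patterns - center) @ basis
    rotated = center + coords @ rot.T @ basis.T
    rotated = np.clip(rotated, 0.0, None)
    return rotated / rotated.sum(axis=1, keepdims=True)


def _mg_patterns(n: int, k: int, subtype: np.ndarray, deviation: float, rng) -> np.ndarray:
    """Ideal unit vectors tilted by a random angle within ``deviation`` degrees."""
    e = np.zeros((n, k))
    e[np.arange(n), subtype] = 1.0
    if deviation == 0:
        return e
    # random tilt direction orthogonal to e_k, angle uniform in [0, deviation]
    g = rng.standard_normal((n, k))
    g[np.arange(n), subtype] = 0.0
    g_norm = np.linalg.norm(g, axis=1, keepdims=True)
    g_norm[g_norm == 0] = 1.0
    u = g / g_norm
    theta = np.radians(rng.uniform(0.0, deviation, size=n))[:, None]
    tilted = np.cos(theta) * e + np.sin(theta) * u
    tilted = np.clip(tilted, 0.0, None)
    return tilted / np.linalg.norm(tilted, axis=1, keepdims=True)


def simulate_dataset(config: SimConfig) -> SimTruth:
    """Generate one dataset with planted markers, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    g, k = config.n_features, config.k
    n_mg = int(round(config.mg_fraction * g))

    is_mg = np.zeros(g, dtype=bool)
    is_mg[rng.permutation(g)[:n_mg]] = True
    mg_subtype = np.full(g, -1, dtype=int)
    weights = config.mg_subtype_weights
    mg_subtype[is_mg] = rng.choice(k, size=n_mg, p=weights)

    patterns = np.empty((g, k))
    null_idx = np.flatnonzero(~is_mg)
    comp = rng.choice(len(config.mixture_weights), size=null_idx.size, p=config.mixture_weights)
    for c, (alpha, deg) in enumerate(zip(config.dirichlet_alphas, config.rotation_degrees)):
        sel = null_idx[comp == c]
        if sel.size:
            draws = rng.dirichlet(alpha, size=sel.size)
            patterns[sel] = _simplex_rotation(draws, deg)
    patterns[is_mg] = _mg_patterns(n_mg, k, mg_subtype[is_mg], config.mg_deviation, rng)

    magnitude = config.magnitude_scale * rng.lognormal(0.0, config.magnitude_sdlog, size=g)
    scaled = patterns * magnitude[:, None]

    n_samples = k * config.samples_per_subtype
    values = np.repeat(scaled, config.samples_per_subtype, axis=1)
    if config.noise_cv > 0:
        sigma2 = np.log1p(config.noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=(g, n_samples))
        values = values * noise

    subtype_labels = [f"sub{j + 1}" for j in range(k)]
    samples = [
        f"{subtype_labels[j]}.{r + 1}"
        for j in range(k)
        for r in range(config.samples_per_subtype)
    ]
    data = ExpressionMatrix(
        features=[f"g{i:06d}" for i in range(g)],
        samples=samples,
        values=values,
        subtype_of={s: s.rsplit(".", 1)[0] for s in samples},
    )
    return SimTruth(data=data, is_mg=is_mg, mg_subtype=mg_subtype, patterns=patterns, config=config)


def _group_values(data: ExpressionMatrix) -> list[np.ndarray]:
    """Per-subtype sample submatrices, in sorted subtype order."""
    return [
        data.values[:, [j for j, s in enumerate(data.samples) if data.subtype_of[s] == k]]
        for k in data.subtypes
    ]


_EPS = np.finfo(float).eps


def _ove_fc(group_means: np.ndarray) -> np.ndarray:
    """Highest / second-highest subtype mean, per feature (columns = subtypes).

    Zero denominators are floored at a machine-epsilon-scaled pseudocount so
    ideal markers score finitely large instead of overflowing.
    """
    part = np.partition(group_means, -2, axis=1)
    top, second = part[:, -1], part[:, -2]
    return top / np.maximum(second, _EPS * np.maximum(top, 1.0))


def peer_scores(
    data: ExpressionMatrix,
    method: str,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature score under one of the peer statistics (higher = more MG-like).

    ``anova_f``: one-way F across the K subtypes.
    ``ovr_t``: max over subtypes of the Welch t (subtype vs pooled rest).
    ``ovr_fc``: max over subtypes of mean_subtype / mean_rest.
    ``ove_fc``: highest subtype mean / second-highest subtype mean.
    ``ove_sfc``: ove_fc calibrated against a subtype-label permutation null
        (score = fraction of permuted datasets with a smaller statistic;
        ties broken by the raw statistic).
    """
    groups = _group_values(data)
    if method in {"anova_f", "ovr_t"} and any(grp.shape[1] < 2 for grp in groups):
        raise ValueError(f"{method} needs >= 2 samples per subtype")

    if method == "anova_f":
        f = sps.f_oneway(*groups, axis=1).statistic
        return np.nan_to_num(f, nan=0.0)  # zero-variance features carry no signal

    if method == "ovr_t":
        t_max = np.full(data.values.shape[0], -np.inf)
        for j, grp in enumerate(groups):
            rest = np.concatenate([h for i, h in enumerate(groups) if i != j], axis=1)
            t = sps.ttest_ind(grp, rest, axis=1, equal_var=False).statistic
            t_max = np.maximum(t_max, np.nan_to_num(t, nan=0.0))
        return t_max

    group_means = np.column_stack([grp.mean(axis=1) for grp in groups])

    if method == "ovr_fc":
        n_per = np.array([grp.shape[1] for grp in groups], dtype=float)
        totals = group_means @ n_per
        rest_mean = (totals[:, None] - group_means * n_per) / (n_per.sum() - n_per)
        floor = _EPS * np.maximum(group_means, 1.0)
        return (group_means / np.maximum(rest_mean, floor)).max(axis=1)

    if method == "ove_fc":
        return _ove_fc(group_means)

    if method == "ove_sfc":
        observed = _ove_fc(group_means)
        rng = np.random.default_rng(seed)
        sizes = [grp.shape[1] for grp in groups]
        exceed = np.zeros_like(observed)
        for _ in range(n_permutations):
            perm = rng.permutation(data.values.shape[1])
            values = data.values[:, perm]
            start, perm_means = 0, []
            for n_j in sizes:
                perm_means.append(values[:, start : start + n_j].mean(axis=1))
                start += n_j
            # <= so capped statistics (ideal markers hit the FC ceiling) are
            # not outranked by continuous null scores that never tie
            exceed += _ove_fc(np.column_stack(perm_means)) <= observed
        # permutation percentile as primary score, raw-FC rank breaks ties
        ranks = sps.rankdata(observed) / observed.size
        return exceed / n_permutations + ranks / (n_permutations * 10)

    raise ValueError(f"unknown peer method {method!r}; choose from {PEER_METHODS}")


def cot_feature_scores(data: ExpressionMatrix) -> np.ndarray:
    """Cosine score of each feature computed on its subtype means."""
    return cot_scores(subtype_means(data).means)[1]


def roc_eval(scores, truth: SimTruth, fpr_range: tuple[float, float] = (0.01, 0.05)) -> RocResult:
    """Partial ROC of a score vector against the planted ground truth.

    The ROC curve is the standard threshold sweep (piecewise linear between
    operating points); ``pauc`` is its trapezoidal area restricted to
    ``fpr_range``, and power is the interpolated TPR at FPR = 0.05.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truth.is_mg, dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both positive and negative features for ROC")
    if scores.shape[0] != y.size:
        raise ValueError("scores not aligned with truth")
    lo, hi = fpr_range
    if not 0 <= lo < hi <= 1:
        raise ValueError("invalid fpr_range")

    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    grid = np.union1d(fpr[(fpr >= lo) & (fpr <= hi)], [lo, hi])
    tpr_grid = np.interp(grid, fpr, tpr)
    pauc = float(np.trapezoid(tpr_grid, grid))
    return RocResult(
        fpr_grid=grid,
        tpr=tpr_grid,
        pauc=pauc,
        fpr_range=fpr_range,
        power_at_fpr05=float(np.interp(0.05, fpr, tpr)),
    )


def standard_settings(
    n_features: int = 10_000, seed: int = 0, **overrides
) -> dict[str, SimConfig]:
    """The four evaluation settings: standard (K=3, n=3x3), more-subtype
    (K=5, n=3x5), more-sample (K=3, n=4x3) and complex-null (mixture of a
    rotated uniform Dirichlet and a non-uniform Dirichlet)."""
    base = dict(n_features=n_features, seed=seed, **overrides)
    edge_alphas, edge_weights, _ = null_mixture(3)
    complex_alphas = ((2.0, 2.0, 2.0), (3.0, 2.0, 1.5)) + edge_alphas[1:]
    complex_weights = (0.35, 0.35) + tuple(w * (0.3 / sum(edge_weights[1:])) for w in edge_weights[1:])
    complex_rotations = (15.0, 0.0) + (0.0,) * len(edge_alphas[1:])
    return {
        "standard": SimConfig(k=3, samples_per_subtype=3, **base),
        "more_subtype": SimConfig(k=5, samples_per_subtype=3, **base),
        "more_sample": SimConfig(k=3, samples_per_subtype=4, **base),
        "complex_null": SimConfig(
            k=3,
            samples_per_subtype=3,
            dirichlet_alphas=complex_alphas,
            mixture_weights=complex_weights,
            rotation_degrees=complex_rotations,
            **base,
        ),
    }


def benchmark(
    configs: dict[str, SimConfig],
    methods: tuple[str, ...] = ("cot",) + PEER_METHODS,
    n_replicates: int = 10,
    fpr_range: tuple[float, float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Mean pAUC and power at FPR=0.05 per (setting, method) over seeded replicates."""
    rows = []
    for setting, config in configs.items():
        per_method: dict[str, list[RocResult]] = {m: [] for m in methods}
        for r in range(n_replicates):
            truth = simulate_dataset(replace(config, seed=config.seed + r))
            for m in methods:
                if m == "cot":
                    scores = cot_feature_scores(truth.data)
                else:
                    scores = peer_scores(truth.data, m, seed=config.seed + r)
                per_method[m].append(roc_eval(scores, truth, fpr_range))
        for m in methods:
            rows.append(
                {
                    "setting": setting,
                    "method": m,
                    "pauc": float(np.mean([x.pauc for x in per_method[m]])),
                    "power_at_fpr05": float(
                        np.mean([x.power_at_fpr05 for x in per_method[m]])
                    ),
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
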