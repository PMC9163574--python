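"""Data cleaning and per-subtype averaging.

The workflow's first step collapses replicate samples into one mean
expression value per (feature, subtype) and removes uninformative rows:
features whose expression is below a lower bound in every subtype (noise)
and, optionally, features whose profile norm exceeds an upper bound
(outliers).  All downstream scoring operates on the cleaned subtype-mean
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["CleaningReport", "SubtypeProfile", "clean", "default_low_cut", "subtype_means"]


@dataclass
class SubtypeProfile:
    """Feature x K matrix of sample-averaged expression per subtype.

    ``means[i, k]`` is the arithmetic mean (linear scale) of feature ``i``
    over the samples of subtype ``subtypes[k]``; subtype columns are in
    sorted label order.
    """

    features: list[str]
    subtypes: list[str]
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.features), len(self.subtypes)):
            raise ValueError("means shape does not match features x subtypes")
        if len(self.subtypes) < 2:
            raise ValueError("need K >= 2 subtypes")
        if np.any(self.means < 0):
            raise ValueError("negative subtype means")


@dataclass(frozen=True)
class CleaningReport:
    n_input: int
    n_low_removed: int
    n_outlier_removed: int
    n_retained: int
    low_cut: float
    norm_cut: float


def subtype_means(data: ExpressionMatrix) -> SubtypeProfile:
    """Average replicate samples within each subtype.

    Column order is the sorted subtype labels, so results are invariant to
    the order samples appear in the input file.
    """
    subtypes = data.subtypes
    cols = []
    for k in subtypes:
        idx = [j for j, s in enumerate(data.samples) if data.subtype_of[s] == k]
        if not idx:
            raise ValueError(f"subtype {k!r} has no samples")
        cols.append(data.values[:, idx].mean(axis=1))
    return SubtypeProfile(
        features=list(data.features), subtypes=subtypes, means=np.column_stack(cols)
    )


def default_low_cut(profile: SubtypeProfile) -> float:
    """Data-adaptive noise bound: 5th percentile of per-feature max subtype mean."""
    return float(np.percentile(profile.means.max(axis=1), 5))


def clean(
    profile: SubtypeProfile,
    low_cut: float | None = None,
    norm_cut: float = np.inf,
) -> tuple[SubtypeProfile, CleaningReport]:
    """Remove noise and outlier features from a subtype profile.

    A feature is noise when its mean expression is below ``low_cut`` in
    every subtype (``max_k s_k < low_cut``); it is an outlier when the L2
    norm of its subtype-mean vector exceeds ``norm_cut``.  All-zero rows
    are always removed.  Retained features keep their original order.

    ``low_cut`` defaults to :func:`default_low_cut`; ``norm_cut`` defaults
    to infinity (outlier filter off).
    """
    if low_cut is None:
        low_cut = default_low_cut(profile)
    if low_cut < 0:
        raise ValueError("low_cut must be >= 0")
    if not norm_cut > low_cut:
        raise ValueError("norm_cut must exceed low_cut")

    row_max = profile.means.max(axis=1)
    row_norm = np.linalg.norm(profile.means, axis=1)
    low_mask = (row_max < low_cut) | (row_max == 0)  # all-zero rows even when low_cut=0
    outlier_mask = ~low_mask & (row_norm > norm_cut)
    keep = ~low_mask & ~outlier_mask
    if not np.any(keep):
        raise ValueError(
            "cleaning removed every feature; lower low_cut or raise norm_cut"
        )

    cleaned = SubtypeProfile(
        features=[f for f, k in zip(profile.features, keep) if k],
        subtypes=list(profile.subtypes),
        means=profile.means[keep],
    )
    report = CleaningReport(
        n_input=len(profile.features),
        n_low_removed=int(low_mask.sum()),
        n_outlier_removed=int(outlier_mask.sum()),
        n_retained=int(keep.sum()),
        low_cut=float(low_cut),
        norm_cut=float(norm_cut),
    )
    return cleaned, report
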