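"""Reading expression matrices with subtype labels and writing result tables.

Input matrices are delimited text (comma or tab, auto-detected): first
column holds feature identifiers, the header row holds sample identifiers.
Subtype labels come either from a separate two-column file
(sample, subtype) or from sample headers following the
``subtype.replicate`` convention; an explicit labels file wins when both
are available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CotResult", "ExpressionMatrix", "read_expression", "write_results", "read_results"]


@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample expression matrix with subtype labels.

    Attributes
    ----------
    features, samples : lists of unique identifiers.
    values : array of shape (n_features, n_samples), linear scale, >= 0.
    subtype_of : mapping from sample id to subtype label; every sample is
        labelled and there are K >= 2 distinct subtypes.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    subtype_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        _check_unique(self.features, "feature")
        _check_unique(self.samples, "sample")
        missing = [s for s in self.samples if s not in self.subtype_of]
        if missing:
            raise ValueError(f"samples without a subtype label: {missing}")
        if np.any(~np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at feature {self.features[i]!r}, "
                f"sample {self.samples[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at feature "
                f"{self.features[i]!r}, sample {self.samples[j]!r}"
            )
        if len(self.subtypes) < 2:
            raise ValueError("need at least K=2 distinct subtype labels")

    @property
    def subtypes(self) -> list[str]:
        """Distinct subtype labels in sorted order (the column order used downstream)."""
        return sorted(set(self.subtype_of[s] for s in self.samples))

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s in self.samples if self.subtype_of[s] == subtype]


@dataclass(frozen=True)
class CotResult:
    """Per-feature marker call: assigned subtype, cosine score, p, q, decision."""

    feature: str
    k_hat: str
    t: float
    p: float
    q: float
    accepted: bool


def _check_unique(ids: list[str], kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
    dups = [x for x, n in seen.items() if n > 1]
    if dups:
        raise ValueError(f"duplicate {kind} IDs: {dups[:20]}")


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def _labels_from_file(path: Path) -> dict[str, str]:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} must have two columns (sample, subtype)")
    # tolerate an optional header row
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    if first[0] in {"sample", "sample_id", "id"} or first[1] in {"subtype", "label", "group"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _labels_from_headers(samples: list[str]) -> dict[str, str]:
    labels = {}
    for s in samples:
        if "." not in s:
            raise ValueError(
                f"sample {s!r} does not follow the 'subtype.replicate' header "
                "convention and no labels file was given"
            )
        labels[s] = s.rsplit(".", 1)[0]
    return labels


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    impute_zero: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix plus subtype labels.

    Parameters
    ----------
    matrix_path : delimited text; first column feature IDs, header sample IDs.
    labels_path : optional two-column (sample, subtype) file.  When omitted,
        labels are parsed from ``subtype.replicate`` sample headers.
    impute_zero : replace missing entries by 0 instead of refusing.
    """
    matrix_path = Path(matrix_path)
    sep = _sniff_sep(matrix_path)
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    features = [str(f) for f in df.index]
    samples = [str(s) for s in df.columns]
    values = df.to_numpy(dtype=float)
    if impute_zero:
        values = np.nan_to_num(values, nan=0.0)

    if labels_path is not None:
        labels = _labels_from_file(Path(labels_path))
        unlabeled = [s for s in samples if s not in labels]
        if unlabeled:
            raise ValueError(f"samples present in matrix but absent from labels: {unlabeled}")
        labels = {s: labels[s] for s in samples}
    else:
        labels = _labels_from_headers(samples)

    return ExpressionMatrix(features=features, samples=samples, values=values, subtype_of=labels)


def write_results(results: list[CotResult], path: str | Path, precision: int = 12) -> None:
    """Write marker calls as a delimited table.

    Columns: feature, subtype, cos, p, q, accepted.  Rows are ordered by
    subtype then descending cosine.  With the default precision of 12
    significant digits, :func:`read_results` reproduces the floats exactly
    to that precision.
    """
    if not results:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    ordered = sorted(results, key=lambda r: (r.k_hat, -r.t, r.feature))
    fmt = f"%.{precision}g"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["feature", "subtype", "cos", "p", "q", "accepted"])
        for r in ordered:
            writer.writerow(
                [r.feature, r.k_hat, fmt % r.t, fmt % r.p, fmt % r.q, str(r.accepted)]
            )


def read_results(path: str | Path) -> list[CotResult]:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return [
        CotResult(
            feature=str(row.feature),
            k_hat=str(row.subtype),
            t=float(row.cos),
            p=float(row.p),
            q=float(row.q),
            accepted=str(row.accepted).strip().lower() == "true",
        )
        for row in df.itertuples(index=False)
    ]
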