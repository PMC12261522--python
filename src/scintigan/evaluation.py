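"""Distribution-similarity methodology.

Two phase-space samples are compared feature by feature on their 1-D
marginals: each pair of samples is histogrammed over the combined
min-max range with a common number of bins (default 100), the
histograms are normalized to probability vectors, and the
Jensen-Shannon *distance* (square root of the base-2 Jensen-Shannon
divergence, hence bounded by 1) is computed.  Similarity is 1 - JSD,
conventionally quoted as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .phasespace import FEATURE_COLUMNS

__all__ = [
    "SimilarityReport",
    "jensen_shannon_distance",
    "histogram_jsd",
    "similarity_report",
    "summarize_over_grid",
    "binning_sensitivity",
]


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance between two probability vectors (base 2).

    Inputs are normalized to sum to one; zero-count bins contribute
    nothing through the 0 * log 0 = 0 convention.  The result lies in
    [0, 1] and is symmetric.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors must have equal length")
    d = float(jensenshannon(p, q, base=2))
    # identical vectors can yield a tiny negative radicand -> nan in scipy
    if np.isnan(d) and np.allclose(p / p.sum(), q / q.sum()):
        return 0.0
    return min(d, 1.0)


def histogram_jsd(sample_a, sample_b, n_bins: int = 100) -> float:
    """Jensen-Shannon distance between the histograms of two 1-D samples.

    Bins span the combined min-max of both samples.  Raises on empty
    samples or fewer than two bins.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all mass in one point: identical degenerate distributions
        return 0.0
    pa, _ = np.histogram(a, bins=n_bins, range=(lo, hi))
    pb, _ = np.histogram(b, bins=n_bins, range=(lo, hi))
    return jensen_shannon_distance(pa, pb)


@dataclass
class SimilarityReport:
    """Per-feature JS distances and 1 - JSD similarities for one comparison."""

    features: tuple
    distance: dict
    n_a: int
    n_b: int
    n_bins: int
    bin_policy: str = "combined min-max per feature"

    @property
    def similarity(self) -> dict:
        return {f: 1.0 - d for f, d in self.distance.items()}

    @property
    def mean_similarity(self) -> float:
        return float(np.mean([1.0 - d for d in self.distance.values()]))

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "distance": dict(self.distance),
            "similarity": self.similarity,
            "mean_similarity": self.mean_similarity,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_bins": self.n_bins,
            "bin_policy": self.bin_policy,
        }

    def __str__(self) -> str:  # one-decimal percentages, report style
        lines = [f"{f}: {100 * s:.1f}%" for f, s in self.similarity.items()]
        lines.append(f"mean: {100 * self.mean_similarity:.1f}%")
        return "\n".join(lines)


def similarity_report(table_a, table_b, n_bins: int = 100, features=FEATURE_COLUMNS) -> SimilarityReport:
    """Per-feature histogram JSD similarity between two phase-space tables."""
    for f in features:
        if f not in table_a.columns or f not in table_b.columns:
            raise ValueError(f"both tables must carry feature column {f!r}")
    distance = {
        f: histogram_jsd(table_a[f].to_numpy(), table_b[f].to_numpy(), n_bins) for f in features
    }
    return SimilarityReport(
        features=tuple(features),
        distance=distance,
        n_a=len(table_a),
        n_b=len(table_b),
        n_bins=n_bins,
    )


def summarize_over_grid(reports) -> pd.DataFrame:
    """Mean and std of per-feature similarity across emission points.

    Returns a DataFrame indexed by feature with columns
    ``mean_similarity`` and ``std_similarity``; the last row,
    ``overall``, averages over all features and points.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report to summarize")
    features = reports[0].features
    rows = []
    all_vals = []
    for f in features:
        vals = np.array([r.similarity[f] for r in reports])
        rows.append((f, vals.mean(), vals.std()))
        all_vals.append(vals)
    stacked = np.concatenate(all_vals)
    rows.append(("overall", stacked.mean(), stacked.std()))
    return pd.DataFrame(rows, columns=["feature", "mean_similarity", "std_similarity"]).set_index(
        "feature"
    )


def binning_sensitivity(sample_a, sample_b, bin_counts) -> pd.DataFrame:
    """JSD similarity of the same sample pair under several bin counts.

    Reports one row per bin count plus the spread (max - min) of the
    similarity column, which the caller can compare against a
    sensitivity budget.
    """
    rows = []
    for n_bins in bin_counts:
        d = histogram_jsd(sample_a, sample_b, n_bins)
        rows.append((int(n_bins), d, 1.0 - d))
    out = pd.DataFrame(rows, columns=["bins", "distance", "similarity"])
    out.attrs["similarity_spread"] = float(out["similarity"].max() - out["similarity"].min())
    return out
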