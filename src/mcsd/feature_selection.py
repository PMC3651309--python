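"""Informative-feature scoring and selection.

Every probe is summarized by five class-aware characteristics:

* ``MeanStd`` / ``StdStd`` — mean and standard deviation, over classes, of the
  within-class standard deviation (small for features that are tight within
  each subtype);
* ``StdMean`` — standard deviation over classes of the within-class means
  (large when subtype means differ);
* ``MeanCorr`` / ``StdCorr`` — mean and standard deviation, over classes, of
  the absolute Pearson correlation between the probe's values and a
  one-vs-rest 0/1 class indicator (high and stable correlation marks a
  discriminative probe).

A discriminative probe has low MeanStd, StdStd, StdCorr and high StdMean,
MeanCorr. Each characteristic is normalized by its maximum across probes so
all live in [0, 1]; selection then uses a rank-sum composite so that it is
invariant to any monotone rescaling of the individual characteristics.

All standard deviations are sample (``ddof=1``) standard deviations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import LabeledDataset
from .errors import InsufficientSamplesError

FEATURE_NAMES = ("MeanStd", "StdStd", "StdMean", "MeanCorr", "StdCorr")

#: characteristics where *smaller* is better for classification
ASCENDING = ("MeanStd", "StdStd", "StdCorr")
#: characteristics where *larger* is better
DESCENDING = ("StdMean", "MeanCorr")

__all__ = [
    "FEATURE_NAMES",
    "feature_profile",
    "normalize_profile",
    "rank_sum_score",
    "select_features",
    "profile_table",
]


def feature_profile(data: LabeledDataset) -> pd.DataFrame:
    """Raw (pre-normalization) five-component profile for every probe.

    Returns a DataFrame indexed by probe id with the columns of
    :data:`FEATURE_NAMES`. Correlations with a vanishing denominator
    (constant probe) are defined as 0, so a constant probe profiles to
    all-zeros.
    """
    y = data.y
    X = data.matrix.values
    n_classes = data.n_classes
    counts = data.class_counts()
    if np.any(counts < 2):
        bad = [data.class_names[k] for k in np.flatnonzero(counts < 2)]
        raise InsufficientSamplesError(
            f"classes with fewer than 2 samples: {bad}"
        )

    class_means = np.empty((X.shape[0], n_classes))
    class_stds = np.empty((X.shape[0], n_classes))
    abs_corr = np.empty((X.shape[0], n_classes))

    Xc = X - X.mean(axis=1, keepdims=True)
    row_norm = np.linalg.norm(Xc, axis=1)
    for k in range(n_classes):
        mask = y == k
        Xk = X[:, mask]
        class_means[:, k] = Xk.mean(axis=1)
        class_stds[:, k] = Xk.std(axis=1, ddof=1)
        z = mask.astype(np.float64)
        zc = z - z.mean()
        z_norm = np.linalg.norm(zc)
        denom = row_norm * z_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (Xc @ zc) / np.where(denom > 0, denom, 1.0), 0.0)
        abs_corr[:, k] = np.abs(r)

    return pd.DataFrame(
        {
            "MeanStd": class_stds.mean(axis=1),
            "StdStd": class_stds.std(axis=1, ddof=1),
            "StdMean": class_means.std(axis=1, ddof=1),
            "MeanCorr": abs_corr.mean(axis=1),
            "StdCorr": abs_corr.std(axis=1, ddof=1),
        },
        index=pd.Index(data.matrix.probe_ids, name="probe_id"),
    )


def normalize_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each characteristic by its maximum over probes into [0, 1].

    A characteristic whose maximum is 0 is left all-zero.
    """
    if profiles.empty:
        raise ValueError("no profiles to normalize")
    out = profiles.copy()
    for col in FEATURE_NAMES:
        m = out[col].max()
        if m > 0:
            out[col] = out[col] / m
    return out


def rank_sum_score(profiles: pd.DataFrame) -> np.ndarray:
    """Composite informativeness score: the lower, the better.

    Sum of per-characteristic ranks, ascending for the dispersion-type
    characteristics and descending for the separation-type ones. Ties get
    average ranks, so the score is invariant to sample order and to any
    common positive rescaling of a characteristic.
    """
    score = np.zeros(len(profiles))
    for col in ASCENDING:
        score += rankdata(profiles[col].to_numpy(), method="average")
    for col in DESCENDING:
        score += rankdata(-profiles[col].to_numpy(), method="average")
    return score


def select_features(profiles: pd.DataFrame, m: int) -> np.ndarray:
    """Indices (into the profile table order) of the ``m`` best probes.

    Deterministic: sorted by rank-sum score, ties broken by probe position.
    Selections are nested — the top ``m`` is a prefix of the top ``m+1``.
    """
    n = len(profiles)
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, {n}], got {m}")
    score = rank_sum_score(profiles)
    order = np.lexsort((np.arange(n), score))
    return order[:m]


def profile_table(
    profiles: pd.DataFrame, selected: np.ndarray | None = None
) -> pd.DataFrame:
    """Exportable table: the five characteristics plus score and selection flag."""
    out = profiles.copy()
    out["score"] = rank_sum_score(profiles)
    flag = np.zeros(len(profiles), dtype=bool)
    if selected is not None:
        flag[np.asarray(selected, dtype=int)] = True
    out["selected"] = flag
    return out
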