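"""Descriptor panel for dimensionally reduced features.

Per class and reduction method: mean, sample variance, Fisher skewness,
excess kurtosis, mean within-class Pearson correlation between segments,
sample entropy, and the first canonical correlation across the two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dimred import FeatureMatrix
from .synth import CVD, NORMAL

__all__ = [
    "Moments",
    "moments",
    "pairwise_pcc",
    "sample_entropy",
    "cca_first",
    "stats_table",
    "normal_probability_plot",
]


@dataclass(frozen=True)
class Moments:
    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess kurtosis: 0 for a normal distribution
    degenerate: bool = False


def moments(values) -> Moments:
    """First four moments: sample variance (n-1), Fisher skewness, excess
    kurtosis.  A zero-variance collection has undefined shape moments and is
    returned flagged with NaNs."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var == 0.0 or np.ptp(x) == 0.0:
        warnings.warn("zero variance: skewness and kurtosis undefined")
        return Moments(mean, 0.0, float("nan"), float("nan"), degenerate=True)
    if x.size < 4:
        return Moments(mean, var, float(sps.skew(x)), float("nan"), degenerate=True)
    return Moments(mean, var, float(sps.skew(x)), float(sps.kurtosis(x)))


def pairwise_pcc(
    features: FeatureMatrix | np.ndarray,
    max_pairs: int = 10_000,
    seed: int = 0,
) -> float:
    """Mean Pearson correlation over distinct within-class segment pairs.

    Zero-variance segments carry no correlation information and are excluded
    with a warning.  When the number of distinct pairs exceeds ``max_pairs``
    a seeded random subsample of pairs is used.
    """
    X = np.asarray(getattr(features, "features", features), dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 segments")
    sd = X.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"excluded {int((~keep).sum())} zero-variance segment(s)")
        X = X[keep]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 segments with nonzero variance")
    n = X.shape[0]
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        corr = np.corrcoef(X)
        iu = np.triu_indices(n, k=1)
        return float(np.mean(corr[iu]))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    r = np.einsum("ij,ij->i", Z[i], Z[j]) / X.shape[1]
    return float(np.mean(r))


def sample_entropy(values, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r*sd): ``-ln(A/B)`` with A the count of template matches at
    length m+1 and B at length m (Chebyshev distance, self-matches excluded).

    ``r`` is expressed in standard deviations of the input.  Zero matches at
    either length give ``+inf`` with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if r <= 0:
        raise ValueError("r must be positive")
    if x.size < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples")
    tol = r * np.std(x)
    n_templ = x.size - m  # both lengths use the same template count

    def _matches(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templ]
        # pairwise Chebyshev distances between templates
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        within = d <= tol
        np.fill_diagonal(within, False)
        return int(within.sum()) // 2

    b = _matches(m)
    a = _matches(m + 1)
    if a == 0 or b == 0:
        warnings.warn("no template matches: sample entropy is infinite")
        return float("inf")
    return float(-np.log(a / b))


def cca_first(features_a, features_b, ridge: float = 1e-6) -> float:
    """First canonical correlation between two feature matrices.

    Columns are the variables; rows are paired in order, truncating to the
    shorter matrix when the classes have unequal segment counts.  Covariances
    are ridge-regularized for stability, and rank-deficient inputs are still
    estimated (with a warning).  The result is clipped to [0, 1].
    """
    A = np.asarray(getattr(features_a, "features", features_a), dtype=float)
    B = np.asarray(getattr(features_b, "features", features_b), dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature matrices must share a column count")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 rows per class")
    n = min(A.shape[0], B.shape[0])
    A, B = A[:n] - A[:n].mean(axis=0), B[:n] - B[:n].mean(axis=0)
    caa = A.T @ A / (n - 1)
    cbb = B.T @ B / (n - 1)
    cab = A.T @ B / (n - 1)
    p = A.shape[1]
    if min(n - 1, p) < p:
        warnings.warn("rank-deficient feature matrix: ridge-regularized CCA estimate")
    caa += ridge * np.trace(caa) / p * np.eye(p) + 1e-12 * np.eye(p)
    cbb += ridge * np.trace(cbb) / p * np.eye(p) + 1e-12 * np.eye(p)
    la = np.linalg.cholesky(caa)
    lb = np.linalg.cholesky(cbb)
    m = np.linalg.solve(la, cab) @ np.linalg.inv(lb).T
    sv = np.linalg.svd(m, compute_uv=False)
    return float(np.clip(sv[0], 0.0, 1.0))


def stats_table(features: list[FeatureMatrix], seed: int = 0) -> pd.DataFrame:
    """Descriptor table shaped like the study's summary: rows = statistics,
    columns = (method, class).  Per-class values pool the subjects of that
    class; sample entropy is computed per subject on the pooled feature
    values and averaged."""
    methods = sorted({f.method for f in features})
    cols = {}
    for method in methods:
        fm = [f for f in features if f.method == method]
        by_class = {c: [f for f in fm if f.label == c] for c in (NORMAL, CVD)}
        stacked = {
            c: np.vstack([f.features for f in lst]) if lst else None
            for c, lst in by_class.items()
        }
        cca = (
            cca_first(stacked[CVD], stacked[NORMAL])
            if stacked[CVD] is not None and stacked[NORMAL] is not None
            else float("nan")
        )
        for cls in (NORMAL, CVD):
            X = stacked[cls]
            if X is None:
                continue
            mom = moments(X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ent = float(
                    np.mean(
                        [
                            sample_entropy(f.features.ravel()[:400])
                            for f in by_class[cls]
                        ]
                    )
                )
            cols[(method, cls)] = {
                "mean": mom.mean,
                "variance": mom.variance,
                "skewness": mom.skewness,
                "kurtosis": mom.kurtosis,
                "pcc": pairwise_pcc(X, seed=seed),
                "sample_entropy": ent,
                "cca": cca,
            }
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["method", "class"])
    return df.loc[
        ["mean", "variance", "skewness", "kurtosis", "pcc", "sample_entropy", "cca"]
    ]


def normal_probability_plot(values, ax=None):
    """Basic normal-probability plot of a feature sample (styling minimal)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sps.probplot(np.asarray(values, dtype=float).ravel(), dist="norm", plot=ax)
    ax.set_title("Normal probability plot")
    return ax
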