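"""Twelve segment classifiers under one contract.

Every kind is fit on a feature matrix with target-coded labels (CVD -> 0.85,
NORMAL -> 0.1 by default), emits a real score per test segment, and labels by
thresholding that score at the kind's threshold — so the emitted labels are
always exactly the thresholded scores.

Kinds
-----
PCA          first-principal-axis projection, min-max normalized, threshold 0.72
EM           2-component Gaussian latent-class EM on pooled features
LOGREG       logistic regression, threshold 0.5
GMM          one Gaussian mixture per class, log-likelihood-ratio score
BLDC         Bayesian (pooled-covariance) linear discriminant, equal priors
FIREFLY      firefly search over class-prototype pairs, coded-target MSE objective
HARMONY      harmony search over class-prototype pairs, coded-target MSE objective
DFA          detrended-fluctuation profile of each feature vector, nearest class
PAC_BAYES    PAC-Bayes posterior over single-feature threshold stumps (Gibbs vote)
KNN_PAC      k-NN in the feature space augmented with the PAC-Bayes score
SDC          softmax discriminant: log sum exp(-lambda ||x - x_i||^2) per class
DETREND_SDC  piecewise-linear detrending of each feature vector, then SDC

Iterative kinds honor the stopping rule (MSE 1e-5 or 1000 iterations,
whichever first); randomized kinds are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.decomposition import PCA as _SkPCA
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .synth import CVD, NORMAL

KINDS = (
    "PCA", "EM", "LOGREG", "GMM", "BLDC", "FIREFLY", "HARMONY", "DFA",
    "PAC_BAYES", "KNN_PAC", "SDC", "DETREND_SDC",
)

__all__ = [
    "KINDS", "TargetCoding", "StopRule", "FitResult",
    "code_targets", "training_mse", "dfa_exponent", "fit_predict",
]


@dataclass(frozen=True)
class TargetCoding:
    """Regression targets for the two classes; the gap must be >= 0.5."""

    t_cvd: float = 0.85
    t_normal: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.t_cvd <= 1.0) or not (0.0 <= self.t_normal < 1.0):
            raise ValueError("targets must lie in (0,1] / [0,1)")
        if abs(self.t_cvd - self.t_normal) < 0.5:
            raise ValueError(
                f"|t_cvd - t_normal| = {abs(self.t_cvd - self.t_normal):.3g} "
                "violates the required gap of 0.5"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_cvd + self.t_normal)


@dataclass(frozen=True)
class StopRule:
    """Training stops at MSE <= mse_tol or max_iter, whichever first."""

    mse_tol: float = 1e-5
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.mse_tol <= 0 or self.max_iter <= 0:
            raise ValueError("mse_tol and max_iter must be positive")


@dataclass
class FitResult:
    """Scores, thresholded labels and the training trace of one fit."""

    scores: np.ndarray
    labels: np.ndarray
    mse_trace: np.ndarray
    threshold: float
    objective_trace: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __iter__(self):  # allow (scores, labels, trace) unpacking
        return iter((self.scores, self.labels, self.mse_trace))


def code_targets(labels, coding: TargetCoding = TargetCoding()) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {CVD, NORMAL}
    if bad:
        raise ValueError(f"non-binary labels: {sorted(bad)}")
    return np.where(labels == CVD, coding.t_cvd, coding.t_normal).astype(float)


def training_mse(scores, coded_targets) -> float:
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(coded_targets, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != targets.shape:
        raise ValueError("scores and targets must have equal length")
    return float(np.mean((scores - targets) ** 2))


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis

_DFA_WINDOWS = (4, 8, 16, 32)


def _dfa_fluctuations(X: np.ndarray, window_sizes) -> np.ndarray:
    """F(n) for each row of X and each window size (rows are series)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    profile = np.cumsum(X - X.mean(axis=1, keepdims=True), axis=1)
    out = np.empty((X.shape[0], len(window_sizes)))
    for k, n in enumerate(window_sizes):
        nw = d // n
        Y = profile[:, : nw * n].reshape(X.shape[0], nw, n)
        t = np.arange(n, dtype=float)
        t_mean = t.mean()
        t_var = np.sum((t - t_mean) ** 2)
        y_mean = Y.mean(axis=2, keepdims=True)
        slope = np.sum((t - t_mean) * (Y - y_mean), axis=2, keepdims=True) / t_var
        resid = Y - y_mean - slope * (t - t_mean)
        out[:, k] = np.sqrt(np.mean(resid**2, axis=(1, 2)))
    return out


def dfa_exponent(series, window_sizes=_DFA_WINDOWS) -> float:
    """Scaling exponent alpha: slope of log F(n) vs log n.

    The cumulative mean-removed profile is fit with per-window least-squares
    lines; F(n) is the root-mean-square residual.  White noise gives alpha
    around 0.5, an integrated (Brownian) path around 1.5.  A perfectly linear
    profile has F(n) = 0 everywhere and an undefined exponent (NaN, flagged).
    """
    x = np.asarray(series, dtype=float).ravel()
    window_sizes = sorted(int(n) for n in window_sizes)
    if len(window_sizes) < 3:
        raise ValueError("need at least 3 window sizes")
    if x.size < 2 * max(window_sizes):
        raise ValueError("series must be at least twice the largest window")
    F = _dfa_fluctuations(x[None, :], window_sizes)[0]
    if np.any(F <= 1e-14):
        warnings.warn("F(n) = 0: perfectly linear profile, exponent undefined")
        return float("nan")
    slope, _ = np.polyfit(np.log(window_sizes), np.log(F), 1)
    return float(slope)


def _dfa_log_profile(X: np.ndarray, window_sizes) -> np.ndarray:
    """log F(n) at each window size, per row (the full fluctuation profile;
    the scaling exponent is its log-log slope)."""
    return np.log(np.maximum(_dfa_fluctuations(X, window_sizes), 1e-14))


def _detrend_rows(X: np.ndarray) -> np.ndarray:
    """Subtract per-window least-squares lines from each row (the DFA
    detrending operator applied to the vectors themselves)."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    n = max(3, d // 4)
    out = X.copy()
    for start in range(0, d - n + 1, n):
        seg = X[:, start : start + n]
        t = np.arange(n, dtype=float)
        t_mean, t_var = t.mean(), np.sum((t - t.mean()) ** 2)
        y_mean = seg.mean(axis=1, keepdims=True)
        slope = np.sum((t - t_mean) * (seg - y_mean), axis=1, keepdims=True) / t_var
        out[:, start : start + n] = seg - y_mean - slope * (t - t_mean)
    tail = d % n
    if tail >= 2:
        seg = X[:, d - tail :]
        t = np.arange(tail, dtype=float)
        t_mean, t_var = t.mean(), np.sum((t - t.mean()) ** 2)
        y_mean = seg.mean(axis=1, keepdims=True)
        slope = np.sum((t - t_mean) * (seg - y_mean), axis=1, keepdims=True) / t_var
        out[:, d - tail :] = seg - y_mean - slope * (t - t_mean)
    return out


# ---------------------------------------------------------------------------
# Shared helpers


class _Scaler:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 1e-12, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _ratio_score(d_cvd, d_norm, coding: TargetCoding) -> np.ndarray:
    """Map distances-to-class-references onto the coded-target interval.

    The score crosses the coding midpoint exactly where the two distances are
    equal, so thresholding at the midpoint reproduces nearest-reference
    classification."""
    total = d_cvd + d_norm
    ratio = np.where(total > 0, d_norm / np.where(total > 0, total, 1.0), 0.5)
    return coding.t_normal + (coding.t_cvd - coding.t_normal) * ratio


def _margin_score(margin: np.ndarray) -> np.ndarray:
    """Squash a CVD-vs-NORMAL margin into (0, 1); positive margin -> > 0.5."""
    return expit(margin)


# ---------------------------------------------------------------------------
# Gaussian mixture core (diagonal or full covariance) with a monotone
# log-likelihood guarantee asserted on every fit.


def _gauss_logpdf(X, mean, cov, cov_type):
    d = X.shape[1]
    if cov_type == "diag":
        diff = X - mean
        return -0.5 * (
            np.sum(diff**2 / cov, axis=1) + np.sum(np.log(cov)) + d * np.log(2 * np.pi)
        )
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (np.sum(sol**2, axis=0) + logdet + d * np.log(2 * np.pi))


class _GMM:
    def __init__(self, n_components=2, cov_type="diag", reg=1e-6):
        self.k = n_components
        self.cov_type = cov_type
        self.reg = reg

    def fit(self, X, rng, stop: StopRule):
        n, d = X.shape
        k = min(self.k, n)
        idx = rng.choice(n, size=k, replace=False)
        self.means = X[idx].copy()
        base_var = X.var(axis=0) + self.reg
        if self.cov_type == "diag":
            self.covs = np.tile(base_var, (k, 1))
        else:
            self.covs = np.tile(np.diag(base_var), (k, 1, 1))
        self.weights = np.full(k, 1.0 / k)
        trace = []
        prev = -np.inf
        resp = None
        for _ in range(stop.max_iter):
            log_comp = np.column_stack(
                [
                    np.log(self.weights[q])
                    + _gauss_logpdf(X, self.means[q], self.covs[q], self.cov_type)
                    for q in range(k)
                ]
            )
            ll_rows = logsumexp(log_comp, axis=1)
            ll = float(np.mean(ll_rows))
            if ll < prev - 1e-7 * (1.0 + abs(prev)):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {prev} -> {ll}"
                )
            trace.append(ll)
            resp = np.exp(log_comp - ll_rows[:, None])
            if ll - prev < stop.mse_tol:
                break
            prev = ll
            nk = resp.sum(axis=0) + 1e-12
            self.weights = nk / n
            self.means = (resp.T @ X) / nk[:, None]
            if self.cov_type == "diag":
                for q in range(k):
                    diff = X - self.means[q]
                    self.covs[q] = (resp[:, q] @ diff**2) / nk[q] + self.reg
            else:
                for q in range(k):
                    diff = X - self.means[q]
                    cov = (resp[:, q][:, None] * diff).T @ diff / nk[q]
                    self.covs[q] = cov + self.reg * np.trace(cov) / d * np.eye(d) + 1e-9 * np.eye(d)
        self.trace = np.array(trace)
        self.resp = resp
        return self

    def log_likelihood(self, X) -> np.ndarray:
        log_comp = np.column_stack(
            [
                np.log(self.weights[q])
                + _gauss_logpdf(X, self.means[q], self.covs[q], self.cov_type)
                for q in range(len(self.weights))
            ]
        )
        return logsumexp(log_comp, axis=1)

    def posterior(self, X) -> np.ndarray:
        log_comp = np.column_stack(
            [
                np.log(self.weights[q])
                + _gauss_logpdf(X, self.means[q], self.covs[q], self.cov_type)
                for q in range(len(self.weights))
            ]
        )
        return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])


# ---------------------------------------------------------------------------
# Prototype-pair metaheuristic classifiers (firefly, harmony)


def _prototype_scores(pos, X, coding):
    d = X.shape[1]
    pc, pn = pos[:d], pos[d:]
    dc = np.einsum("ij,ij->i", X - pc, X - pc)
    dn = np.einsum("ij,ij->i", X - pn, X - pn)
    return np.where(dc <= dn, coding.t_cvd, coding.t_normal)


def _prototype_mse(pos, X, coded, coding):
    return float(np.mean((_prototype_scores(pos, X, coding) - coded) ** 2))


def _class_mean_pair(X, y):
    return np.concatenate([X[y == CVD].mean(axis=0), X[y == NORMAL].mean(axis=0)])


def _fit_firefly(X, y, coded, coding, stop, rng, pop_size=12, gamma_rand=0.1,
                 alpha_s0=0.65, beta_absorb=None):
    d2 = 2 * X.shape[1]
    beta_absorb = 1.0 / d2 if beta_absorb is None else beta_absorb
    base = _class_mean_pair(X, y)
    scale = X.std() + 1e-12
    pos = base + rng.normal(0.0, 0.25 * scale, size=(pop_size, d2))
    pos[0] = base
    mse = np.array([_prototype_mse(p, X, coded, coding) for p in pos])
    best_i = int(np.argmin(mse))
    best_pos, best_mse = pos[best_i].copy(), float(mse[best_i])
    trace = [best_mse]
    for _ in range(stop.max_iter):
        if best_mse <= stop.mse_tol:
            break
        order = np.argsort(mse, kind="stable")
        for t in range(pop_size):
            for s in order:
                if mse[s] < mse[t]:  # firefly s is brighter
                    r2 = float(np.sum((pos[s] - pos[t]) ** 2))
                    attract = alpha_s0 * np.exp(-beta_absorb * r2)
                    pos[t] = (
                        pos[t]
                        + attract * (pos[s] - pos[t])
                        + gamma_rand * rng.uniform(-1.0, 1.0, size=d2) * scale
                    )
                    break
            else:
                pos[t] = pos[t] + gamma_rand * rng.uniform(-1.0, 1.0, size=d2) * scale
        mse = np.array([_prototype_mse(p, X, coded, coding) for p in pos])
        i = int(np.argmin(mse))
        if mse[i] < best_mse:
            best_pos, best_mse = pos[i].copy(), float(mse[i])
        trace.append(best_mse)
    return best_pos, np.array(trace)


def _fit_harmony(X, y, coded, coding, stop, rng, memory_size=12, hmcr=0.9,
                 par=0.3, bandwidth=0.004):
    d2 = 2 * X.shape[1]
    lo = np.tile(X.min(axis=0), 2)
    hi = np.tile(X.max(axis=0), 2)
    span = np.where(hi > lo, hi - lo, 1.0)
    hm = rng.uniform(lo, hi, size=(memory_size, d2))
    hm[0] = _class_mean_pair(X, y)
    mse = np.array([_prototype_mse(p, X, coded, coding) for p in hm])
    trace = [float(mse.min())]
    for _ in range(stop.max_iter):
        if trace[-1] <= stop.mse_tol:
            break
        new = np.empty(d2)
        use_mem = rng.random(d2) < hmcr
        donors = rng.integers(memory_size, size=d2)
        new[use_mem] = hm[donors[use_mem], np.flatnonzero(use_mem)]
        adjust = use_mem & (rng.random(d2) < par)
        new[adjust] += rng.uniform(-1.0, 1.0, size=int(adjust.sum())) * bandwidth * span[adjust]
        rand_dims = ~use_mem
        new[rand_dims] = rng.uniform(lo[rand_dims], hi[rand_dims])
        f_new = _prototype_mse(new, X, coded, coding)
        worst = int(np.argmax(mse))
        if f_new < mse[worst]:
            hm[worst], mse[worst] = new, f_new
        trace.append(float(mse.min()))
    best = hm[int(np.argmin(mse))]
    return best, np.array(trace)


# ---------------------------------------------------------------------------
# PAC-Bayes stumps


def _pac_bayes_fit(Xtr, y, coding, c_temp=2.0, quantiles=np.arange(0.1, 0.91, 0.1)):
    """Gibbs posterior over single-feature threshold stumps.

    The posterior weight of stump s is ``exp(-c * sqrt(n) * err(s))`` under a
    uniform prior — the sqrt(n) rate keeps the posterior an ensemble over all
    competitive stumps rather than collapsing onto the single best one, which
    is what makes the Gibbs vote stronger than any individual stump.
    """
    thr = np.quantile(Xtr, quantiles, axis=0)  # [q x d]
    n, d = Xtr.shape
    y_cvd = (np.asarray(y) == CVD)
    # stump predictions: polarity +1 -> predict CVD when feature > threshold
    pred = Xtr[:, None, :] > thr[None, :, :]  # [n x q x d]
    err_pos = np.mean(pred != y_cvd[:, None, None], axis=0)
    err_neg = 1.0 - err_pos
    errs = np.concatenate([err_pos.ravel(), err_neg.ravel()])
    log_w = -c_temp * np.sqrt(n) * errs
    log_w -= logsumexp(log_w)
    return thr, np.exp(log_w)


def _pac_bayes_score(X, thr, w, coding):
    pred = X[:, None, :] > thr[None, :, :]
    votes = np.concatenate([pred.reshape(X.shape[0], -1),
                            (~pred).reshape(X.shape[0], -1)], axis=1)
    coded = np.where(votes, coding.t_cvd, coding.t_normal)
    return coded @ w


# ---------------------------------------------------------------------------
# Softmax discriminant


def _sdc_margin(Xtr, y, Xte, lam=0.5, chunk=1024):
    m_cvd = np.empty(Xte.shape[0])
    m_norm = np.empty(Xte.shape[0])
    A_c, A_n = Xtr[y == CVD], Xtr[y == NORMAL]
    for start in range(0, Xte.shape[0], chunk):
        B = Xte[start : start + chunk]
        for A, out in ((A_c, m_cvd), (A_n, m_norm)):
            d2 = (
                np.sum(B**2, axis=1)[:, None]
                + np.sum(A**2, axis=1)[None, :]
                - 2.0 * B @ A.T
            )
            out[start : start + B.shape[0]] = logsumexp(-lam * np.maximum(d2, 0.0), axis=1)
    return m_cvd, m_norm


# ---------------------------------------------------------------------------
# fit_predict dispatch


def _validate(X_train, y_train, X_test):
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if X_test.size == 0:
        raise ValueError("empty test set")
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    classes = set(np.unique(y_train))
    if classes != {CVD, NORMAL}:
        raise ValueError(f"training data must contain both classes, got {sorted(classes)}")
    return X_train, y_train, X_test


def fit_predict(
    kind: str,
    train_features,
    train_labels,
    test_features,
    params: dict | None = None,
    coding: TargetCoding = TargetCoding(),
    stop: StopRule = StopRule(),
    seed: int = 0,
) -> FitResult:
    """Fit one classifier kind and score/label the test segments.

    Returns a :class:`FitResult`; ``labels`` always equal
    ``scores >= result.threshold``.  ``params`` carries kind-specific
    overrides (see the per-kind helpers for names and defaults).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    X, y, Xt = _validate(train_features, train_labels, test_features)
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    coded = code_targets(y, coding)
    mid = coding.midpoint
    objective = None
    extras = {}

    if kind == "PCA":
        pca = _SkPCA(n_components=1, svd_solver="full").fit(X)
        proj = pca.transform(X)[:, 0]
        flip = 1.0
        if proj[y == CVD].mean() < proj[y == NORMAL].mean():
            proj, flip = -proj, -1.0
        # normalize the projection onto [0, 1] by mapping the training class
        # means onto the coded targets (CVD high), then clip
        m_c, m_n = proj[y == CVD].mean(), proj[y == NORMAL].mean()
        span = m_c - m_n
        if span <= 1e-12:
            tr_scores = np.full(proj.shape, mid)
            scores = np.full(Xt.shape[0], mid)
        else:
            scale = (coding.t_cvd - coding.t_normal) / span
            tr_scores = np.clip(coding.t_normal + (proj - m_n) * scale, 0.0, 1.0)
            proj_t = flip * pca.transform(Xt)[:, 0]
            scores = np.clip(coding.t_normal + (proj_t - m_n) * scale, 0.0, 1.0)
        threshold = p.get("threshold", 0.72)

    elif kind == "EM":
        scaler = _Scaler(X)
        Z, Zt = scaler(X), scaler(Xt)
        gmm = _GMM(2, p.get("covariance_type", "diag")).fit(Z, rng, stop)
        objective = gmm.trace
        resp = gmm.resp
        cvd_mass = resp[y == CVD].sum(axis=0) / (resp.sum(axis=0) + 1e-12)
        cvd_comp = int(np.argmax(cvd_mass))
        tr_scores = gmm.posterior(Z)[:, cvd_comp]
        scores = gmm.posterior(Zt)[:, cvd_comp]
        threshold = p.get("threshold", 0.5)

    elif kind == "LOGREG":
        scaler = _Scaler(X)
        clf = LogisticRegression(max_iter=stop.max_iter, random_state=0)
        clf.fit(scaler(X), (y == CVD).astype(int))
        tr_scores = clf.predict_proba(scaler(X))[:, 1]
        scores = clf.predict_proba(scaler(Xt))[:, 1]
        threshold = p.get("threshold", 0.5)

    elif kind == "GMM":
        scaler = _Scaler(X)
        Z, Zt = scaler(X), scaler(Xt)
        z_comp = p.get("z_components", 2)
        cov_type = p.get("covariance_type", "diag")
        g_cvd = _GMM(z_comp, cov_type).fit(Z[y == CVD], rng, stop)
        g_norm = _GMM(z_comp, cov_type).fit(Z[y == NORMAL], rng, stop)
        objective = np.concatenate([g_cvd.trace, g_norm.trace])
        extras["trace_cvd"], extras["trace_normal"] = g_cvd.trace, g_norm.trace
        d = Z.shape[1]
        tr_scores = _margin_score((g_cvd.log_likelihood(Z) - g_norm.log_likelihood(Z)) / d)
        scores = _margin_score((g_cvd.log_likelihood(Zt) - g_norm.log_likelihood(Zt)) / d)
        threshold = p.get("threshold", 0.5)

    elif kind == "BLDC":
        scaler = _Scaler(X)
        Z, Zt = scaler(X), scaler(Xt)
        mu_x = Z[y == CVD].mean(axis=0)
        mu_y = Z[y == NORMAL].mean(axis=0)
        nc, nn = (y == CVD).sum(), (y == NORMAL).sum()
        cov = (
            (Z[y == CVD] - mu_x).T @ (Z[y == CVD] - mu_x)
            + (Z[y == NORMAL] - mu_y).T @ (Z[y == NORMAL] - mu_y)
        ) / (nc + nn - 2)
        d = Z.shape[1]
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance: ridge-regularized")
            extras["regularized"] = True
        cov = cov + 1e-6 * (np.trace(cov) / d + 1.0) * np.eye(d)
        prec = np.linalg.inv(cov)

        def margin(Q):
            dx = Q - mu_x
            dy = Q - mu_y
            return 0.5 * (
                np.einsum("ij,jk,ik->i", dy, prec, dy)
                - np.einsum("ij,jk,ik->i", dx, prec, dx)
            )

        tr_scores = _margin_score(margin(Z))
        scores = _margin_score(margin(Zt))
        threshold = p.get("threshold", 0.5)  # margin >= D = 0

    elif kind in ("FIREFLY", "HARMONY"):
        scaler = _Scaler(X)
        Z, Zt = scaler(X), scaler(Xt)
        if kind == "FIREFLY":
            proto, trace = _fit_firefly(
                Z, y, coded, coding, stop, rng,
                pop_size=p.get("pop_size", 12),
                gamma_rand=p.get("gamma", 0.1),
                alpha_s0=p.get("alpha_s0", 0.65),
                beta_absorb=p.get("beta"),
            )
        else:
            proto, trace = _fit_harmony(
                Z, y, coded, coding, stop, rng,
                memory_size=p.get("memory_size", 12),
                hmcr=p.get("hmcr", 0.9),
                par=p.get("par", 0.3),
                bandwidth=p.get("bandwidth", 0.004),
            )
        d = Z.shape[1]
        pc, pn = proto[:d], proto[d:]
        dc = np.sqrt(np.einsum("ij,ij->i", Z - pc, Z - pc))
        dn = np.sqrt(np.einsum("ij,ij->i", Z - pn, Z - pn))
        tr_scores = _ratio_score(dc, dn, coding)
        dc = np.sqrt(np.einsum("ij,ij->i", Zt - pc, Zt - pc))
        dn = np.sqrt(np.einsum("ij,ij->i", Zt - pn, Zt - pn))
        scores = _ratio_score(dc, dn, coding)
        threshold = p.get("threshold", mid)
        objective = trace

    elif kind == "DFA":
        windows = p.get("window_sizes", _DFA_WINDOWS)
        windows = [n for n in windows if 2 * n <= X.shape[1]]
        if len(windows) < 3:
            raise ValueError("feature dimension too small for the DFA window grid")
        feat_tr = _dfa_log_profile(X, windows)
        feat_te = _dfa_log_profile(Xt, windows)
        sd = feat_tr.std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        m_cvd = feat_tr[y == CVD].mean(axis=0)
        m_norm = feat_tr[y == NORMAL].mean(axis=0)
        dc = np.linalg.norm((feat_te - m_cvd) / sd, axis=1)
        dn = np.linalg.norm((feat_te - m_norm) / sd, axis=1)
        scores = _ratio_score(dc, dn, coding)
        dc_tr = np.linalg.norm((feat_tr - m_cvd) / sd, axis=1)
        dn_tr = np.linalg.norm((feat_tr - m_norm) / sd, axis=1)
        tr_scores = _ratio_score(dc_tr, dn_tr, coding)
        threshold = p.get("threshold", mid)
        logn = np.log(np.asarray(windows, dtype=float))
        A = np.vstack([logn, np.ones_like(logn)]).T
        exps = np.linalg.lstsq(A, np.vstack([m_cvd, m_norm]).T, rcond=None)[0][0]
        extras["class_mean_exponents"] = {CVD: float(exps[0]), NORMAL: float(exps[1])}

    elif kind == "PAC_BAYES":
        thr, w = _pac_bayes_fit(X, y, coding, c_temp=p.get("c_temp", 2.0))
        tr_scores = _pac_bayes_score(X, thr, w, coding)
        scores = _pac_bayes_score(Xt, thr, w, coding)
        threshold = p.get("threshold", mid)

    elif kind == "KNN_PAC":
        thr, w = _pac_bayes_fit(X, y, coding, c_temp=p.get("c_temp", 2.0))
        scaler = _Scaler(X)
        aug_tr = np.column_stack([scaler(X), _pac_bayes_score(X, thr, w, coding)])
        aug_te = np.column_stack([scaler(Xt), _pac_bayes_score(Xt, thr, w, coding)])
        k_grid = p.get("k_grid", (3, 5, 7))
        perm = rng.permutation(len(y))
        cut = max(2, int(0.8 * len(y)))
        tr_i, ho_i = perm[:cut], perm[cut:]
        best_k, best_acc = k_grid[0], -1.0
        if ho_i.size >= 2 and len(set(y[tr_i])) == 2:
            for k in k_grid:
                if k >= tr_i.size:
                    continue
                knn = KNeighborsClassifier(n_neighbors=k).fit(aug_tr[tr_i], y[tr_i])
                acc = float(np.mean(knn.predict(aug_tr[ho_i]) == y[ho_i]))
                if acc > best_acc:
                    best_k, best_acc = k, acc
        knn = KNeighborsClassifier(n_neighbors=best_k).fit(aug_tr, y)
        cvd_col = int(np.flatnonzero(knn.classes_ == CVD)[0])
        tr_scores = knn.predict_proba(aug_tr)[:, cvd_col]
        scores = knn.predict_proba(aug_te)[:, cvd_col]
        threshold = p.get("threshold", 0.5)
        extras["k"] = best_k

    elif kind in ("SDC", "DETREND_SDC"):
        lam = p.get("lambda", 0.5)
        if kind == "DETREND_SDC":
            X, Xt = _detrend_rows(X), _detrend_rows(Xt)
        scaler = _Scaler(X)
        Z, Zt = scaler(X), scaler(Xt)
        m_cvd, m_norm = _sdc_margin(Z, y, Zt, lam=lam)
        scores = _margin_score(m_cvd - m_norm)
        m_cvd_tr, m_norm_tr = _sdc_margin(Z, y, Z, lam=lam)
        tr_scores = _margin_score(m_cvd_tr - m_norm_tr)
        threshold = p.get("threshold", 0.5)
        extras["lambda"] = lam

    else:  # pragma: no cover
        raise AssertionError(kind)

    labels = np.where(scores >= threshold, CVD, NORMAL)
    if kind in ("FIREFLY", "HARMONY"):
        # the per-iteration best coded-target MSE is the training trace
        mse_trace = np.asarray(objective)
    else:
        mse_trace = np.array([training_mse(tr_scores, coded)])
    return FitResult(scores, labels, mse_trace, threshold, objective, extras)
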