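"""Dimensionality reduction: 200-sample segments -> 100 features.

Five reducers are provided, in two families:

* transform-based — the analytic-signal (Hilbert) envelope decimated by two,
  and a nonlinear-regression fit (sum of Gaussian lobes, Levenberg–Marquardt
  least squares) evaluated at 100 points;
* metaheuristic selection — ABC-PSO, cuckoo search (Lévy flights) and the
  dragonfly algorithm search over binary masks retaining exactly half of the
  200 sample positions, scored by a wrapper fitness
  ``F = a * phi(K) + b * (T - K) / T`` where ``phi(K)`` is the hold-out
  accuracy of a nearest-centroid probe on the masked columns.

All three swarm selectors share the same continuous-position encoding: a
candidate is a real vector of length 200, converted to a mask by
``sigmoid(position) > 0.5`` and repaired to exactly 100 selected columns by
flipping the lowest-impact bits under a class-separation ranking.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import hilbert as _scipy_hilbert
from scipy.special import expit

from .signal_io import SegmentMatrix

METHODS = ("HT", "NLR", "ABC_PSO", "CUCKOO", "DRAGONFLY")

__all__ = [
    "METHODS",
    "FeatureMatrix",
    "BinaryMask",
    "SwarmParams",
    "hilbert_transform",
    "ht_reduce",
    "nlr_fit",
    "nlr_reduce",
    "mask_fitness",
    "abc_pso_select",
    "cuckoo_select",
    "dragonfly_select",
    "select_mask",
    "apply_mask",
    "reduce_cohort",
    "levy_steps",
    "write_features_csv",
    "read_features_csv",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Dimensionally reduced segments plus provenance of the method."""

    subject_id: str
    features: np.ndarray  # [n_segments x n_features]
    label: str
    method: str
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"subject {self.subject_id}: non-finite features")


@dataclass(frozen=True)
class BinaryMask:
    """A candidate column-selection mask and its wrapper fitness."""

    mask: np.ndarray  # boolean, length = segment_len
    fitness: float

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.mask))

    def indices(self) -> list[int]:
        return np.flatnonzero(self.mask).tolist()


@dataclass(frozen=True)
class SwarmParams:
    """Shared knobs of the three metaheuristic selectors.

    ``a_weight``/``b_weight`` are the convex wrapper-fitness weights;
    ``accel_a``/``accel_b`` the PSO acceleration coefficients;
    ``beta_step``/``levy_gamma`` the Lévy-flight scale and tail exponent
    (1 < gamma <= 3); ``pa_abandon`` the per-generation nest-abandonment
    fraction; ``s, a, c, f, e, omega`` the dragonfly separation, alignment,
    cohesion, food, enemy and inertia weights.
    """

    pop_size: int = 20
    max_iter: int = 30
    a_weight: float = 0.8
    b_weight: float = 0.2
    phi_range: float = 1.0
    accel_a: float = 1.5
    accel_b: float = 1.5
    beta_step: float = 0.5
    levy_gamma: float = 2.5
    pa_abandon: float = 0.25
    s: float = 0.1
    a: float = 0.1
    c: float = 0.7
    f: float = 1.0
    e: float = 1.0
    omega: float = 0.9
    #: use the conventional enemy-repulsion term (Q- minus Q) instead of the
    #: printed additive form (Q- plus Q)
    enemy_conventional: bool = False
    #: cap on rows used by the wrapper fitness, for tractability
    fitness_subsample: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (1.0 < self.levy_gamma <= 3.0):
            raise ValueError("levy_gamma must satisfy 1 < gamma <= 3")
        if not (0.0 <= self.pa_abandon <= 1.0):
            raise ValueError("pa_abandon must lie in [0, 1]")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


# ---------------------------------------------------------------------------
# Transform-based reducers


def hilbert_transform(x: np.ndarray) -> np.ndarray:
    """Analytic signal ``x + i H(x)`` via the frequency-domain construction.

    The imaginary part is the Hilbert transform: a -90 degree phase shift on
    positive frequencies, +90 on negative ones, leaving the magnitude
    spectrum untouched.  The real part equals the input exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("hilbert_transform expects a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return _scipy_hilbert(x)


def ht_reduce(segments: SegmentMatrix) -> FeatureMatrix:
    """Envelope of the analytic signal, decimated by two.

    Per segment the 200-point envelope ``|x + iH(x)|`` is computed and the
    even-indexed samples kept, giving exactly ``segment_len / 2`` features.
    """
    if segments.segment_len % 2:
        raise ValueError("segment length must be even for the 2:1 envelope decimation")
    analytic = _scipy_hilbert(segments.segments, axis=1)
    env = np.abs(analytic)[:, ::2]
    return FeatureMatrix(segments.subject_id, env, segments.label, "HT", {})


def _gauss_sum(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    amps = phi[0::3][:, None]
    centers = phi[1::3][:, None]
    widths = np.abs(phi[2::3][:, None]) + 1e-9
    return np.sum(amps * np.exp(-0.5 * ((t[None, :] - centers) / widths) ** 2), axis=0)


def _gauss_sum_jac(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    n_k = phi.size // 3
    J = np.empty((t.size, phi.size))
    for g in range(n_k):
        a, c, wp = phi[3 * g : 3 * g + 3]
        w = abs(wp) + 1e-9
        u = (t - c) / w
        G = np.exp(-0.5 * u**2)
        J[:, 3 * g] = G
        J[:, 3 * g + 1] = a * G * u / w
        J[:, 3 * g + 2] = np.sign(wp) * a * G * u**2 / w if wp != 0 else a * G * u**2 / w
    return J


def nlr_fit(
    segment: np.ndarray, n_kernels: int = 4, n_starts: int = 3, seed: int = 0
) -> tuple[np.ndarray, float, bool]:
    """Least-squares fit of a sum of Gaussian lobes to one segment.

    Model: ``f(t, phi) = sum_g A_g exp(-(t - c_g)^2 / (2 w_g^2))`` on the unit
    time interval, fitted by Levenberg–Marquardt minimization of the residual
    sum of squares, with ``n_starts`` jittered initializations (best kept).

    Returns ``(phi, rss, converged)`` where ``phi`` is the flat
    ``(A_1, c_1, w_1, ...)`` vector.
    """
    x = np.asarray(segment, dtype=float)
    if n_kernels < 1:
        raise ValueError("n_kernels must be >= 1")
    if x.size < 3 * n_kernels:
        raise ValueError("segment must have at least 3 parameters' worth of samples")
    t = np.linspace(0.0, 1.0, x.size)
    rng = np.random.default_rng(seed)
    span = float(x.max() - x.min())
    amp0 = span if span > 0 else 1.0
    base_centers = (np.arange(n_kernels) + 0.5) / n_kernels
    best = None
    for start in range(n_starts):
        phi0 = np.empty(3 * n_kernels)
        jitter = 0.0 if start == 0 else rng.uniform(-0.1, 0.1, size=n_kernels)
        phi0[0::3] = amp0 * (0.5 if start == 0 else rng.uniform(0.2, 1.0, n_kernels))
        phi0[1::3] = np.clip(base_centers + jitter, 0.0, 1.0)
        phi0[2::3] = 0.5 / n_kernels
        try:
            res = least_squares(
                lambda p: _gauss_sum(t, p) - x, phi0, method="lm",
                jac=lambda p: _gauss_sum_jac(t, p), max_nfev=400,
            )
        except Exception:  # pragma: no cover - LM failures are data-dependent
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss, bool(res.status > 0))
    if best is None:
        raise RuntimeError("all nonlinear least-squares starts failed")
    return best


def nlr_reduce(
    segments: SegmentMatrix, n_kernels: int = 4, n_out: int | None = None, seed: int = 0
) -> FeatureMatrix:
    """Fitted-curve features: evaluate each segment's Gaussian-sum fit at
    ``n_out`` (default ``segment_len / 2``) equispaced time points."""
    n_out = segments.segment_len // 2 if n_out is None else n_out
    t_out = np.linspace(0.0, 1.0, n_out)
    feats = np.empty((segments.n_segments, n_out))
    any_fail = False
    for i in range(segments.n_segments):
        phi, _, converged = nlr_fit(segments.segments[i], n_kernels, seed=seed)
        any_fail |= not converged
        feats[i] = _gauss_sum(t_out, phi)
    params = {"n_kernels": n_kernels, "all_converged": not any_fail}
    return FeatureMatrix(segments.subject_id, feats, segments.label, "NLR", params)


# ---------------------------------------------------------------------------
# Wrapper fitness and mask machinery


def _column_ranking(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column usefulness score: standardized class-mean separation, or
    plain variance when only one class is present."""
    classes = np.unique(y)
    if classes.size == 2:
        a = X[y == classes[0]]
        b = X[y == classes[1]]
        pooled = np.sqrt(0.5 * (a.var(axis=0) + b.var(axis=0))) + 1e-12
        return np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled
    return X.var(axis=0)


class _MaskEvaluator:
    """Precomputed train/hold-out split and ranking for fast mask scoring."""

    def __init__(self, X, y, a_weight, b_weight, rng, subsample, n_keep):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if subsample and X.shape[0] > subsample:
            idx = rng.choice(X.shape[0], size=subsample, replace=False)
            idx.sort()
            X, y = X[idx], y[idx]
        self.a_weight = a_weight
        self.b_weight = b_weight
        self.T = X.shape[1]
        self.n_keep = n_keep
        self.ranking = _column_ranking(X, y)
        self.classes = np.unique(y)
        self.degenerate = self.classes.size < 2
        if self.degenerate:
            warnings.warn(
                "single-class data: wrapper accuracy phi(K) is 0; fitness "
                "reduces to the parsimony term"
            )
            self._split = None
            return
        order = rng.permutation(X.shape[0])
        X, y = X[order], y[order]
        # stratified 70/30 split
        tr_idx, ho_idx = [], []
        for cls in self.classes:
            cls_idx = np.flatnonzero(y == cls)
            cut = max(1, int(round(0.7 * cls_idx.size)))
            cut = min(cut, cls_idx.size - 1)
            tr_idx.append(cls_idx[:cut])
            ho_idx.append(cls_idx[cut:])
        tr = np.concatenate(tr_idx)
        ho = np.concatenate(ho_idx)
        self._split = (X[tr], y[tr], X[ho], y[ho])

    def repair(self, mask: np.ndarray) -> np.ndarray:
        """Flip lowest-impact bits until exactly ``n_keep`` are selected."""
        mask = mask.copy()
        k = int(np.count_nonzero(mask))
        if k > self.n_keep:
            sel = np.flatnonzero(mask)
            drop = sel[np.argsort(self.ranking[sel], kind="stable")[: k - self.n_keep]]
            mask[drop] = False
        elif k < self.n_keep:
            unsel = np.flatnonzero(~mask)
            add = unsel[
                np.argsort(-self.ranking[unsel], kind="stable")[: self.n_keep - k]
            ]
            mask[add] = True
        return mask

    def accuracy(self, mask: np.ndarray) -> float:
        if self.degenerate:
            return 0.0
        Xtr, ytr, Xho, yho = self._split
        cols = np.flatnonzero(mask)
        c0 = Xtr[np.ix_(ytr == self.classes[0], cols)].mean(axis=0)
        c1 = Xtr[np.ix_(ytr == self.classes[1], cols)].mean(axis=0)
        H = Xho[:, cols]
        d0 = np.einsum("ij,ij->i", H - c0, H - c0)
        d1 = np.einsum("ij,ij->i", H - c1, H - c1)
        pred = np.where(d0 <= d1, self.classes[0], self.classes[1])
        return float(np.mean(pred == yho))

    def fitness(self, mask: np.ndarray) -> float:
        k = int(np.count_nonzero(mask))
        return self.a_weight * self.accuracy(mask) + self.b_weight * (self.T - k) / self.T

    def to_mask(self, position: np.ndarray) -> np.ndarray:
        return self.repair(expit(position) > 0.5)


def mask_fitness(
    mask,
    train_features,
    train_labels,
    a_weight: float = 0.8,
    b_weight: float = 0.2,
    seed: int = 0,
) -> float:
    """Wrapper fitness ``F = a * phi(K) + b * (T - K) / T``.

    ``phi(K)`` is the hold-out accuracy of a nearest-centroid probe
    restricted to the masked columns; the second term rewards parsimony.
    """
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one column")
    ev = _MaskEvaluator(
        train_features, train_labels, a_weight, b_weight,
        np.random.default_rng(seed), subsample=0, n_keep=int(mask.sum()),
    )
    return ev.fitness(mask)


# ---------------------------------------------------------------------------
# Swarm selectors

_POS_CLIP = 6.0
_VEL_CLIP = 4.0


def _prepare(X, y, params, n_keep):
    rng = np.random.default_rng(params.seed)
    X = np.asarray(X, dtype=float)
    T = X.shape[1]
    n_keep = T // 2 if n_keep is None else n_keep
    ev = _MaskEvaluator(
        X, y, params.a_weight, params.b_weight, rng,
        params.fitness_subsample, n_keep,
    )
    # diverse selection densities: per-individual bias spreads the initial
    # masks from near-empty to near-full, so the count repair (ranked by
    # class separation) seeds the population with both random and
    # ranking-guided candidates
    bias = rng.permutation(np.linspace(-2.0, 2.0, params.pop_size))
    pos = rng.uniform(-1.0, 1.0, size=(params.pop_size, T)) + bias[:, None]
    fit = np.array([ev.fitness(ev.to_mask(p)) for p in pos])
    return rng, ev, pos, fit


def _best_mask(ev, pos, fit) -> BinaryMask:
    i = int(np.argmax(fit))
    return BinaryMask(ev.to_mask(pos[i]), float(fit[i]))


def abc_pso_select(X, y, params: SwarmParams, n_keep: int | None = None) -> BinaryMask:
    """Hybrid artificial-bee-colony / particle-swarm mask search.

    Employed and onlooker bees mutate single dimensions of personal bests
    (greedy acceptance); the scout phase is replaced by PSO velocity and
    position updates toward the personal and global bests, per the hybrid
    algorithm.  Returns the global-best mask (elitist, fitness never
    decreases across generations).
    """
    rng, ev, pos, fit = _prepare(X, y, params, n_keep)
    pop, T = pos.shape
    pbest, pbest_fit = pos.copy(), fit.copy()
    vel = np.zeros_like(pos)
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    def bee_update(m: int) -> None:
        nonlocal gbest, gbest_fit
        k = rng.integers(T)
        l = rng.integers(pop - 1)
        l = l if l < m else l + 1
        cand = pbest[m].copy()
        phi = rng.uniform(-params.phi_range, params.phi_range)
        cand[k] = pbest[m, k] + phi * (pbest[m, k] - pbest[l, k])
        f_cand = ev.fitness(ev.to_mask(cand))
        if f_cand > pbest_fit[m]:
            pbest[m], pbest_fit[m] = cand, f_cand
            if f_cand > gbest_fit:
                gbest, gbest_fit = cand.copy(), float(f_cand)

    for _ in range(params.max_iter):
        for m in range(pop):  # employed bees
            bee_update(m)
        w = pbest_fit - pbest_fit.min() + 1e-12  # onlookers, fitness-proportional
        w = w / w.sum()
        for m in rng.choice(pop, size=pop, p=w):
            bee_update(m)
        # PSO step in place of scouts
        vel = np.clip(
            vel + params.accel_a * (pbest - pos) + params.accel_b * (gbest - pos),
            -_VEL_CLIP, _VEL_CLIP,
        )
        pos = np.clip(pos + vel, -_POS_CLIP, _POS_CLIP)
        for m in range(pop):
            f_new = ev.fitness(ev.to_mask(pos[m]))
            if f_new > pbest_fit[m]:
                pbest[m], pbest_fit[m] = pos[m].copy(), f_new
                if f_new > gbest_fit:
                    gbest, gbest_fit = pos[m].copy(), float(f_new)
    return BinaryMask(ev.to_mask(gbest), gbest_fit)


def levy_steps(size, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Mantegna-sampled Lévy steps with power-law tail exponent ``gamma``.

    The step density falls off as ``|step|**-gamma`` (1 < gamma <= 3), i.e.
    the Mantegna stability parameter is ``beta = gamma - 1``.
    """
    if not (1.0 < gamma <= 3.0):
        raise ValueError("gamma must satisfy 1 < gamma <= 3")
    beta = gamma - 1.0
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def cuckoo_select(X, y, params: SwarmParams, n_keep: int | None = None) -> BinaryMask:
    """Cuckoo-search mask selection with Lévy-flight position updates.

    New candidates follow ``z' = z + beta (*) Levy(gamma)`` (entry-wise) and
    replace a random nest when fitter; each generation the worst
    ``pa_abandon`` fraction of nests (never the best) is rebuilt at random.
    """
    rng, ev, pos, fit = _prepare(X, y, params, n_keep)
    pop, T = pos.shape
    best = int(np.argmax(fit))
    best_pos, best_fit = pos[best].copy(), float(fit[best])
    n_abandon = min(pop - 1, int(round(params.pa_abandon * pop)))
    for _ in range(params.max_iter):
        for i in range(pop):
            cand = np.clip(
                pos[i] + params.beta_step * levy_steps(T, params.levy_gamma, rng),
                -_POS_CLIP, _POS_CLIP,
            )
            f_cand = ev.fitness(ev.to_mask(cand))
            j = rng.integers(pop)
            if f_cand > fit[j]:
                pos[j], fit[j] = cand, f_cand
                if f_cand > best_fit:
                    best_pos, best_fit = cand.copy(), float(f_cand)
        if n_abandon:
            order = np.argsort(fit, kind="stable")
            doomed = [i for i in order if not np.array_equal(pos[i], best_pos)]
            for i in doomed[:n_abandon]:
                pos[i] = rng.uniform(-1.0, 1.0, size=T)
                fit[i] = ev.fitness(ev.to_mask(pos[i]))
                if fit[i] > best_fit:
                    best_pos, best_fit = pos[i].copy(), float(fit[i])
    return BinaryMask(ev.to_mask(best_pos), best_fit)


def dragonfly_select(X, y, params: SwarmParams, n_keep: int | None = None) -> BinaryMask:
    """Dragonfly-algorithm mask selection.

    Step vectors combine separation, alignment, cohesion, attraction to the
    best (food) position and the enemy term with inertia:
    ``dQ' = s*S + a*A + c*C + f*F + e*E + omega*dQ``.  The enemy term is the
    printed additive form ``Q- + Q`` by default; set
    ``enemy_conventional=True`` for the usual repulsion ``Q- - Q``.
    """
    rng, ev, pos, fit = _prepare(X, y, params, n_keep)
    pop, T = pos.shape
    dq = np.zeros_like(pos)
    best = int(np.argmax(fit))
    best_pos, best_fit = pos[best].copy(), float(fit[best])
    for _ in range(params.max_iter):
        food = pos[int(np.argmax(fit))]
        enemy = pos[int(np.argmin(fit))]
        total = pos.sum(axis=0)
        sep = -(pop * pos - total)  # -sum_j (Q - Qj) over all neighbours
        align = (dq.sum(axis=0) - dq) / (pop - 1)
        coh = (total - pos) / (pop - 1) - pos
        attr = food - pos
        if params.enemy_conventional:
            env = enemy - pos
        else:
            env = enemy + pos
        dq = np.clip(
            params.s * sep + params.a * align + params.c * coh
            + params.f * attr + params.e * env + params.omega * dq,
            -_VEL_CLIP, _VEL_CLIP,
        )
        pos = np.clip(pos + dq, -_POS_CLIP, _POS_CLIP)
        fit = np.array([ev.fitness(ev.to_mask(p)) for p in pos])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_pos, best_fit = pos[gen_best].copy(), float(fit[gen_best])
    return BinaryMask(ev.to_mask(best_pos), best_fit)


_SELECTORS = {
    "ABC_PSO": abc_pso_select,
    "CUCKOO": cuckoo_select,
    "DRAGONFLY": dragonfly_select,
}


def select_mask(method: str, X, y, params: SwarmParams, n_keep=None) -> BinaryMask:
    try:
        return _SELECTORS[method](X, y, params, n_keep)
    except KeyError:
        raise ValueError(f"unknown swarm method {method!r}") from None


def apply_mask(segments: SegmentMatrix, mask: BinaryMask, method: str) -> FeatureMatrix:
    cols = np.flatnonzero(mask.mask)
    return FeatureMatrix(
        segments.subject_id,
        segments.segments[:, cols].copy(),
        segments.label,
        method,
        {"indices": cols.tolist(), "fitness": mask.fitness},
    )


def reduce_cohort(
    seg_matrices: list[SegmentMatrix],
    method: str,
    params: SwarmParams | None = None,
    n_kernels: int = 4,
    seed: int = 0,
) -> list[FeatureMatrix]:
    """Apply one reduction method to every subject.

    Swarm methods fit a single mask on the pooled, segment-labeled cohort and
    apply it to all subjects (reduction precedes cross-validation, mirroring
    the study's pipeline order); transform methods act per segment.
    """
    if method == "HT":
        return [ht_reduce(s) for s in seg_matrices]
    if method == "NLR":
        return [nlr_reduce(s, n_kernels=n_kernels, seed=seed) for s in seg_matrices]
    if method in _SELECTORS:
        if params is None:
            params = SwarmParams(seed=seed)
        X = np.vstack([s.segments for s in seg_matrices])
        y = np.concatenate([[s.label] * s.n_segments for s in seg_matrices])
        mask = select_mask(method, X, y, params)
        return [apply_mask(s, mask, method) for s in seg_matrices]
    raise ValueError(f"unknown reduction method {method!r}")


# ---------------------------------------------------------------------------
# CSV/JSON interfaces


def write_features_csv(fm: FeatureMatrix, csv_path, params_path=None) -> None:
    pd.DataFrame(fm.features).to_csv(csv_path, index=False, float_format="%.10g")
    if params_path is not None:
        meta = {"subject_id": fm.subject_id, "label": fm.label,
                "method": fm.method, "method_params": fm.method_params}
        Path(params_path).write_text(json.dumps(meta, indent=1))


def read_features_csv(csv_path, params_path) -> FeatureMatrix:
    meta = json.loads(Path(params_path).read_text())
    feats = pd.read_csv(csv_path).to_numpy(dtype=float)
    return FeatureMatrix(
        meta["subject_id"], feats, meta["label"], meta["method"],
        meta.get("method_params", {}),
    )
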