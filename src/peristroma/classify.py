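"""Ki-67 status classification from the 168-feature table.

The classification stack mirrors a two-stage radiomics design:

1. a genetic algorithm searches chromosome space (one bit per feature) for
   the "optimal feature pool", scoring each chromosome by the stratified
   k-fold cross-validated AUC of a ridge-stabilised multivariate logistic
   model restricted to the chromosome's features;
2. leave-one-out cross-validation (LOOCV): in every fold a wrapper subset
   evaluator — greedy forward selection over the pool, scored by internal
   stratified k-fold AUC on the training cases only — picks the features, a
   logistic model is fitted and the held-out case scored.  Pooled held-out
   scores give the ROC, AUC with a bootstrap CI, and the Youden-optimal
   operating point.

All imputation (training medians), standardisation (training mean/SD) and
selection statistics are computed on training cases only, so the pooled
LOOCV scores are leakage-free.  The logistic fits carry a small L2 ridge
(default 1e-4 on standardised features) purely for identifiability under
(near-)separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

DEFAULT_RIDGE = 1e-4
WRAPPER_MIN_IMPROVEMENT = 1e-4


# ---------------------------------------------------------------------------
# scoring primitives


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) formula, ties counted half.

    Equals the exhaustive pairwise-concordance estimate and the area under
    the trapezoidal ROC curve.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Score cut maximising Youden's J = sensitivity + specificity - 1.

    All midpoints between consecutive distinct scores are scanned (predict
    positive at score >= threshold); ties in J resolve to the lowest
    threshold.  Returns ``(threshold, sensitivity, specificity)``.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (y.any() and (~y).any()):
        raise ValueError("Youden threshold needs both classes present")
    distinct = np.unique(s)
    if distinct.size == 1:
        return float(distinct[0]), 1.0, 0.0
    candidates = (distinct[:-1] + distinct[1:]) / 2
    best = (-np.inf, np.nan, np.nan, np.nan)
    for t in candidates:
        pred = s >= t
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        j = sens + spec - 1
        if j > best[0] + 1e-15:
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]


def bootstrap_auc_ci(
    labels: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (case resampling).

    Resamples that lose a class are redrawn from the remaining draws, i.e.
    simply skipped; with both classes well represented this is rare.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n = y.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        aucs.append(auc_score(yb, s[idx]))
    lo = (1 - level) / 2
    return tuple(float(q) for q in np.quantile(aucs, [lo, 1 - lo]))


# ---------------------------------------------------------------------------
# ridge logistic regression (IRLS)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """Penalised-ML logistic fit by Newton/IRLS; returns [intercept, coefs].

    The L2 penalty (``ridge``) applies to the slope coefficients only.  The
    inputs are assumed standardised, so a single ridge scale is meaningful.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(k + 1)
    penalty = ridge * np.eye(k + 1)
    penalty[0, 0] = 0.0
    for _ in range(max_iter):
        p = expit(Xa @ beta)
        w = np.maximum(p * (1 - p), 1e-10)
        grad = Xa.T @ (y - p) - penalty @ beta
        hess = (Xa * w[:, None]).T @ Xa + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def predict_logistic(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return expit(beta[0] + X @ beta[1:])


def _fit_logistic_batch(
    Xa: np.ndarray,
    y: np.ndarray,
    ridge: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """Newton/IRLS on a stack of design matrices (m, n, k+1), intercept first.

    Identical update to :func:`fit_logistic`, run simultaneously for m
    candidate models via batched linear solves; converged members keep
    taking (vanishing) steps until the whole batch is done.
    """
    m, n, k1 = Xa.shape
    beta = np.zeros((m, k1))
    penalty = ridge * np.eye(k1)
    penalty[0, 0] = 0.0
    for _ in range(max_iter):
        p = expit(np.einsum("mnk,mk->mn", Xa, beta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = np.einsum("mnk,mn->mk", Xa, y[None, :] - p) - beta @ penalty
        hess = np.einsum("mnk,mn,mnl->mkl", Xa, w, Xa) + penalty
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(hess, grad)]
            )
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


@dataclass(frozen=True)
class _Preprocessor:
    """Training-fold median imputation + mean/SD standardisation."""

    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Preprocessor":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
        filled = np.where(np.isnan(X), medians, X)
        means = filled.mean(axis=0)
        sds = filled.std(axis=0)
        sds = np.where(sds > 0, sds, 1.0)
        return cls(medians=medians, means=means, sds=sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        filled = np.where(np.isnan(X), self.medians, X)
        return (filled - self.means) / self.sds


def _stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = np.bincount(np.asarray(y, dtype=int), minlength=2)
    n_folds = max(2, min(n_folds, int(counts[counts > 0].min())))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    ridge: float,
    prepped: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean AUC of the logistic model over pre-split stratified folds.

    ``prepped`` optionally carries per-fold (train, test) matrices already
    imputed and standardised on the training part, to avoid recomputation in
    tight selection loops.
    """
    scores = np.empty(y.size)
    for f, (tr, te) in enumerate(folds):
        if prepped is not None:
            Xtr, Xte = prepped[f]
        else:
            prep = _Preprocessor.fit(X[tr])
            Xtr, Xte = prep.transform(X[tr]), prep.transform(X[te])
        beta = fit_logistic(Xtr[:, feature_idx], y[tr], ridge)
        scores[te] = predict_logistic(beta, Xte[:, feature_idx])
    return auc_score(y, scores)


# ---------------------------------------------------------------------------
# univariate screening


def univariate_screen(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    ridge: float = DEFAULT_RIDGE,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-feature logistic performance of every feature.

    Per feature: a one-covariate logistic fit on the standardised,
    median-imputed values; AUC of the fitted probabilities with a bootstrap
    percentile CI; the Youden-optimal sensitivity/specificity.  A feature
    that separates the classes perfectly is flagged (the ridge keeps the fit
    finite).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    prep = _Preprocessor.fit(X)
    Xs = prep.transform(X)
    rows = []
    for j, name in enumerate(feature_names):
        beta = fit_logistic(Xs[:, [j]], y, ridge)
        prob = predict_logistic(beta, Xs[:, [j]])
        auc = auc_score(y, prob)
        ci_lo, ci_hi = bootstrap_auc_ci(y, prob, n_boot=n_boot, seed=seed + j)
        thr, sens, spec = youden_threshold(prob, y)
        rows.append(
            {
                "feature": name,
                "auc": auc,
                "ci_low": ci_lo,
                "ci_high": ci_hi,
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
                "separable": bool(auc == 1.0),
            }
        )
    return pd.DataFrame(rows).sort_values("auc", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# evolutionary feature-pool search


@dataclass(frozen=True)
class EAConfig:
    """Simple-GA parameters; the full-scale defaults are population 500 and
    200 generations with per-bit mutation 0.01 and crossover 0.6."""

    population_size: int = 500
    max_generations: int = 200
    mutation_prob: float = 0.01
    crossover_prob: float = 0.6
    fitness_folds: int = 5
    elitism_count: int = 1
    stagnation_generations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_prob <= 1 and 0 <= self.crossover_prob <= 1):
            raise ValueError("mutation/crossover probabilities must lie in [0, 1]")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count out of range")


#: a reduced budget for desk-scale runs and tests; same operators
REDUCED_EA = dict(population_size=40, max_generations=30)


@dataclass(frozen=True)
class EAResult:
    mask: np.ndarray
    best_fitness: float
    history: list[float] = field(repr=False)  # best-so-far fitness per generation


def ea_feature_pool(
    X: np.ndarray,
    y: np.ndarray,
    config: EAConfig,
    ridge: float = DEFAULT_RIDGE,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> EAResult:
    """Generational binary GA returning the best-ever feature mask.

    Operators: tournament selection (size 2), single-point crossover,
    per-bit flip mutation, elitism.  Fitness is the mean stratified
    ``fitness_folds``-fold CV AUC of the logistic model on the chromosome's
    features (the all-zero chromosome scores chance, 0.5); ``fitness_fn``
    substitutes an arbitrary fitness for benchmarking the GA machinery.
    Deterministic given ``config.seed``; stops early after
    ``stagnation_generations`` without improvement of the best fitness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]
    rng = np.random.default_rng(config.seed)

    if fitness_fn is None:
        folds = _stratified_folds(y, config.fitness_folds, seed=config.seed)
        prepped = []
        for tr, te in folds:
            prep = _Preprocessor.fit(X[tr])
            prepped.append((prep.transform(X[tr]), prep.transform(X[te])))

        def fitness_fn(chrom: np.ndarray) -> float:
            idx = np.flatnonzero(chrom)
            if idx.size == 0:
                return 0.5
            return _cv_auc(X, y, idx, folds, ridge, prepped)

    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = fitness_fn(chrom)
        return cache[key]

    pop = rng.random((config.population_size, n_features)) < 0.5
    pop = pop.astype(np.uint8)
    fitness = np.array([evaluate(c) for c in pop])
    best_idx = int(np.argmax(fitness))
    best_chrom, best_fit = pop[best_idx].copy(), float(fitness[best_idx])
    history = [best_fit]
    stagnant = 0

    for _ in range(1, config.max_generations):
        order = np.argsort(fitness)[::-1]
        elites = pop[order[: config.elitism_count]].copy()
        children = []
        while len(children) < config.population_size - config.elitism_count:
            pa = _tournament(pop, fitness, rng)
            pb = _tournament(pop, fitness, rng)
            ca, cb = pa.copy(), pb.copy()
            if rng.random() < config.crossover_prob and n_features > 1:
                point = int(rng.integers(1, n_features))
                ca[point:], cb[point:] = pb[point:], pa[point:].copy()
            for child in (ca, cb):
                flip = rng.random(n_features) < config.mutation_prob
                child ^= flip.astype(np.uint8)
                children.append(child)
        pop = np.vstack([elites, np.array(children[: config.population_size - config.elitism_count])])
        fitness = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit + 1e-12:
            best_fit = float(fitness[gen_best])
            best_chrom = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        if stagnant >= config.stagnation_generations:
            break
    return EAResult(mask=best_chrom.astype(bool), best_fitness=best_fit, history=history)


def _tournament(
    pop: np.ndarray, fitness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    i, j = rng.integers(0, pop.shape[0], size=2)
    return pop[i] if fitness[i] >= fitness[j] else pop[j]


# ---------------------------------------------------------------------------
# LOOCV with per-fold wrapper subset selection


@dataclass(frozen=True)
class ClassifierReport:
    """Pooled LOOCV evaluation of the final classifier."""

    scores: np.ndarray = field(repr=False)  # pooled held-out probabilities
    labels: np.ndarray = field(repr=False)
    auc: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0
    threshold: float = 0.5
    sensitivity: float = 0.0
    specificity: float = 0.0
    accuracy: float = 0.0
    selection_frequency: pd.Series = field(repr=False, default=None)
    selected_per_fold: list[list[str]] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_95": [self.ci_low, self.ci_high],
            "youden_threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_cases": int(self.labels.size),
            "mean_subset_size": float(
                np.mean([len(s) for s in self.selected_per_fold])
            ),
        }


def wrapper_forward_select(
    X: np.ndarray,
    y: np.ndarray,
    pool_idx: np.ndarray,
    inner_folds: int = 5,
    ridge: float = DEFAULT_RIDGE,
    min_improvement: float = WRAPPER_MIN_IMPROVEMENT,
    seed: int = 0,
) -> list[int]:
    """Greedy forward wrapper selection over a candidate pool.

    Starts empty (baseline AUC 0.5) and adds the candidate giving the
    largest internal stratified CV AUC, stopping when no addition improves
    it by more than ``min_improvement``.
    """
    folds = _stratified_folds(y, inner_folds, seed=seed)
    prepped = []
    for tr, te in folds:
        prep = _Preprocessor.fit(X[tr])
        prepped.append((prep.transform(X[tr]), prep.transform(X[te])))
    selected: list[int] = []
    current = 0.5
    remaining = list(pool_idx)
    while remaining:
        m = len(remaining)
        scores = np.empty((m, y.size))
        for f, (tr, te) in enumerate(folds):
            Xtr, Xte = prepped[f]
            # stacked designs [1 | selected | candidate], one per candidate
            base_tr = np.hstack([np.ones((tr.size, 1)), Xtr[:, selected]])
            Xa = np.concatenate(
                [
                    np.broadcast_to(base_tr, (m,) + base_tr.shape),
                    Xtr[:, remaining].T[:, :, None],
                ],
                axis=2,
            )
            beta = _fit_logistic_batch(Xa, y[tr].astype(float), ridge)
            base_te = np.hstack([np.ones((te.size, 1)), Xte[:, selected]])
            Xa_te = np.concatenate(
                [
                    np.broadcast_to(base_te, (m,) + base_te.shape),
                    Xte[:, remaining].T[:, :, None],
                ],
                axis=2,
            )
            scores[:, te] = expit(np.einsum("mnk,mk->mn", Xa_te, beta))
        ranks = rankdata(scores, axis=1)
        n1 = int(y.sum())
        n0 = y.size - n1
        trial = (ranks[:, y.astype(bool)].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
        best = int(np.argmax(trial))
        if trial[best] <= current + min_improvement:
            break
        current = float(trial[best])
        selected.append(remaining.pop(best))
    return selected


def loocv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    pool_mask: np.ndarray,
    inner_folds: int = 5,
    ridge: float = DEFAULT_RIDGE,
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassifierReport:
    """LOOCV with per-fold wrapper selection; pooled ROC/AUC/Youden report.

    Per fold, imputation and standardisation statistics, the wrapper's
    internal CV and the final fit all use the training cases only; a fold
    where the wrapper selects nothing scores the held-out case at the
    training prevalence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 10 or min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("LOOCV needs n >= 10 with >= 3 cases per class")
    pool_idx = np.flatnonzero(np.asarray(pool_mask, dtype=bool))

    scores = np.empty(n)
    counts = np.zeros(X.shape[1])
    selected_per_fold: list[list[str]] = []
    for i in range(n):
        tr = np.r_[0:i, i + 1 : n]
        prep = _Preprocessor.fit(X[tr])
        Xtr = prep.transform(X[tr])
        Xte = prep.transform(X[[i]])
        selected = wrapper_forward_select(
            X[tr], y[tr], pool_idx, inner_folds, ridge,
            seed=(seed * 100003 + i) % (2**31 - 1),
        )
        selected_per_fold.append([feature_names[j] for j in selected])
        if not selected:
            scores[i] = y[tr].mean()
        else:
            beta = fit_logistic(Xtr[:, selected], y[tr], ridge)
            scores[i] = predict_logistic(beta, Xte[:, selected])[0]
        counts[selected] += 1

    auc = auc_score(y, scores)
    ci_lo, ci_hi = bootstrap_auc_ci(y, scores, n_boot=n_boot, seed=seed)
    thr, sens, spec = youden_threshold(scores, y)
    pred = scores >= thr
    accuracy = float((pred == y.astype(bool)).mean())
    return ClassifierReport(
        scores=scores,
        labels=y,
        auc=auc,
        ci_low=ci_lo,
        ci_high=ci_hi,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        selection_frequency=pd.Series(counts / n, index=list(feature_names)),
        selected_per_fold=selected_per_fold,
    )


def roc_points(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) over all distinct score cuts."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    thresholds = np.r_[np.inf, np.unique(s)[::-1]]
    rows = []
    for t in thresholds:
        pred = s >= t
        rows.append(
            {
                "threshold": t,
                "tpr": float((pred & y).sum() / y.sum()),
                "fpr": float((pred & ~y).sum() / (~y).sum()),
            }
        )
    return pd.DataFrame(rows)
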