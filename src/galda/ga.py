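"""Genetic-algorithm variable selection with an LDA fitness (GA-LDA).

A chromosome is a binary mask over the spectral variables with a bounded
number of active genes.  Its fitness is the cross-validated (leave-one-out
by default) misclassification rate of LDA restricted to the active
variables, plus a small parsimony penalty that breaks plateaus in favor of
smaller subsets.  Selection is by size-2 tournament, recombination by
single-point crossover, mutation by per-gene bit flips followed by a
cardinality repair, with one elite carried over per generation.  The whole
search is restarted from independent seeds and the best chromosome overall
is kept; the final model is LDA refit on the winning variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .classifiers import LDAModel, auto_shrinkage, fit_lda, predict_lda


@dataclass
class GAConfig:
    n_generations: int = 200
    population_size: int = 400
    p_crossover: float = 0.60
    p_mutation: float = 0.01          # per gene
    n_restarts: int = 3
    min_vars: int = 5
    max_vars: int = 30
    fitness_cv: str = "leave_one_out"  # or "k_fold"
    cv_folds: int = 5
    parsimony: float = 0.01
    #: weight of the cross-validated posterior-risk (margin) term; together
    #: with ``parsimony`` it must stay below one misclassification (1/n) so
    #: the error count always dominates the fitness ordering
    margin_weight: float = 0.02
    #: gene space for spectra: contiguous ppm bins of this width (column
    #: means), matching the 0.01-ppm granularity at which selected variables
    #: are conventionally reported; None selects raw columns
    bin_width: float | None = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_crossover", "p_mutation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1 <= self.min_vars <= self.max_vars:
            raise ValueError("need 1 <= min_vars <= max_vars")
        if self.fitness_cv not in ("leave_one_out", "k_fold"):
            raise ValueError("fitness_cv must be 'leave_one_out' or 'k_fold'")

    @classmethod
    def smoke(cls, **overrides) -> "GAConfig":
        """Reduced search profile (20 generations, 60 chromosomes) for quick
        runs; full-scale defaults are 200 x 400."""
        base = dict(n_generations=20, population_size=60)
        base.update(overrides)
        return cls(**base)


def loo_lda_error(X: np.ndarray, labels: np.ndarray,
                  shrinkage: float | str = "auto",
                  return_risk: bool = False):
    """Exact leave-one-out misclassification rate of LDA on (X, labels).

    Uses rank-1 downdates of the class means and pooled scatter per fold.
    Returns ``inf`` when a fold's covariance cannot be factorized.  With
    ``return_risk`` also returns the mean held-out posterior risk
    (1 - posterior probability of the true class), a continuous margin
    measure that separates strongly discriminating variable subsets from
    ones that merely happen to achieve the same error count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=object)
    n, m = X.shape
    classes = sorted(set(y.tolist()), key=str)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    cls_idx = {c: np.flatnonzero(y == c) for c in classes}
    for c in classes:
        if cls_idx[c].size < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples for LOO fitness")
    if n - 1 - k < 1:
        raise ValueError("too few samples for pooled covariance")
    counts = np.array([cls_idx[c].size for c in classes], dtype=float)
    means = np.vstack([X[cls_idx[c]].mean(axis=0) for c in classes])
    S = np.zeros((m, m))
    for ci, c in enumerate(classes):
        d = X[cls_idx[c]] - means[ci]
        S += d.T @ d
    if shrinkage == "auto":
        gamma = auto_shrinkage(m, n - 1)
    else:
        gamma = float(shrinkage or 0.0)
    errors = 0
    risk = 0.0
    cls_of = {c: i for i, c in enumerate(classes)}
    for i in range(n):
        ci = cls_of[y[i]]
        nc = counts[ci]
        d = X[i] - means[ci]
        S_i = S - (nc / (nc - 1.0)) * np.outer(d, d)
        cov = S_i / (n - 1 - k)
        if gamma > 0:
            cov = (1.0 - gamma) * cov + gamma * np.diag(np.diag(cov))
        try:
            cho = cho_factor(cov)
        except LinAlgError:
            return (np.inf, np.inf) if return_risk else np.inf
        mu_i = means.copy()
        mu_i[ci] = (nc * means[ci] - X[i]) / (nc - 1.0)
        counts_i = counts.copy()
        counts_i[ci] -= 1.0
        priors = counts_i / (n - 1.0)
        diffs = X[i][None, :] - mu_i            # (k x m)
        sol = cho_solve(cho, diffs.T)           # (m x k)
        scores = -np.einsum("ij,ji->i", diffs, sol) + 2.0 * np.log(priors)
        if classes[int(np.argmax(scores))] != y[i]:
            errors += 1
        if return_risk:
            # posterior of the true class under the Gaussian model
            shifted = 0.5 * (scores - scores.max())
            post = np.exp(shifted)
            risk += 1.0 - post[ci] / post.sum()
    if return_risk:
        return errors / n, risk / n
    return errors / n


def kfold_lda_error(X: np.ndarray, labels: np.ndarray, n_folds: int = 5,
                    shrinkage: float | str = "auto") -> float:
    """Deterministic stratified k-fold misclassification rate of LDA."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=object)
    n = X.shape[0]
    folds = [[] for _ in range(n_folds)]
    for c in sorted(set(y.tolist()), key=str):
        for j, i in enumerate(np.flatnonzero(y == c)):
            folds[j % n_folds].append(int(i))
    errors = 0
    for fold in folds:
        if not fold:
            continue
        test = np.asarray(fold, dtype=int)
        train = np.setdiff1d(np.arange(n), test)
        if len(set(y[train].tolist())) < 2:
            return np.inf
        try:
            model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        except (LinAlgError, ValueError):
            return np.inf
        pred, _ = predict_lda(model, X[test])
        errors += int((pred != y[test]).sum())
    return errors / n


def make_bins(ppm: np.ndarray, width: float):
    """Contiguous ~``width``-ppm bins over an ascending axis.

    Returns ``(starts, centers)``: start indices of each bin (for
    ``np.add.reduceat``) and the mean ppm per bin.
    """
    ppm = np.asarray(ppm, dtype=float)
    bounds = np.arange(ppm[0], ppm[-1], width)[1:]
    starts = np.unique(np.concatenate([[0], np.searchsorted(ppm, bounds)]))
    starts = starts[starts < ppm.size]
    counts = np.diff(np.concatenate([starts, [ppm.size]]))
    centers = np.add.reduceat(ppm, starts) / counts
    return starts.astype(int), centers


def bin_matrix(X: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Column-mean binning of a (samples x points) matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    counts = np.diff(np.concatenate([starts, [X.shape[1]]]))
    return np.add.reduceat(X, starts, axis=1) / counts


def _repair(mask: np.ndarray, min_vars: int, max_vars: int,
            rng: np.random.Generator) -> None:
    """Randomly add/remove genes in place until cardinality is in bounds."""
    active = np.flatnonzero(mask)
    if active.size > max_vars:
        drop = rng.choice(active, size=active.size - max_vars, replace=False)
        mask[drop] = False
    elif active.size < min_vars:
        inactive = np.flatnonzero(~mask)
        add = rng.choice(inactive, size=min_vars - active.size, replace=False)
        mask[add] = True


def _random_mask(n_vars: int, min_vars: int, max_vars: int,
                 rng: np.random.Generator) -> np.ndarray:
    card = int(rng.integers(min_vars, max_vars + 1))
    mask = np.zeros(n_vars, dtype=bool)
    mask[rng.choice(n_vars, size=card, replace=False)] = True
    return mask


def ga_select(X: np.ndarray, labels: np.ndarray, config: GAConfig | None = None):
    """Run the GA and return ``(selected_indices, fitness_traces)``.

    ``selected_indices`` is the sorted variable set of the best chromosome
    over all restarts; ``fitness_traces`` holds the best fitness per
    generation for each restart (non-increasing thanks to elitism).  Ties
    between chromosomes prefer fewer variables, then the lexicographically
    lowest index set.
    """
    cfg = config if config is not None else GAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=object)
    n, n_vars = X.shape
    if len(set(y.tolist())) < 2:
        raise ValueError("GA selection needs at least 2 classes")
    min_vars = min(cfg.min_vars, n_vars)
    max_vars = min(cfg.max_vars, n_vars)
    if n < min_vars + 2:
        raise ValueError(
            f"need at least min_vars + 2 = {min_vars + 2} training samples"
        )

    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        key = idx.tobytes()
        if key not in cache:
            if cfg.fitness_cv == "leave_one_out":
                err, risk = loo_lda_error(X[:, idx], y, return_risk=True)
            else:
                err = kfold_lda_error(X[:, idx], y, cfg.cv_folds)
                risk = 0.0
            cache[key] = (err + cfg.margin_weight * risk
                          + cfg.parsimony * idx.size / max_vars)
        return cache[key]

    def sort_key(mask: np.ndarray):
        idx = np.flatnonzero(mask)
        return (fitness(mask), idx.size, tuple(idx.tolist()))

    best_overall = None
    traces = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
    for restart in range(cfg.n_restarts):
        rng = np.random.default_rng(seeds[restart])
        pop = [_random_mask(n_vars, min_vars, max_vars, rng)
               for _ in range(cfg.population_size)]
        fits = np.array([fitness(m) for m in pop])
        elite = pop[int(np.argmin(fits))].copy()
        trace = []
        for _ in range(cfg.n_generations):
            children = [elite.copy()]
            while len(children) < cfg.population_size:
                # size-2 tournaments
                pa, pb = rng.integers(0, cfg.population_size, size=2)
                p1 = pop[pa] if fits[pa] <= fits[pb] else pop[pb]
                pa, pb = rng.integers(0, cfg.population_size, size=2)
                p2 = pop[pa] if fits[pa] <= fits[pb] else pop[pb]
                c1, c2 = p1.copy(), p2.copy()
                if rng.random() < cfg.p_crossover:
                    point = int(rng.integers(1, n_vars))
                    c1[point:], c2[point:] = p2[point:].copy(), p1[point:].copy()
                for child in (c1, c2):
                    flips = rng.random(n_vars) < cfg.p_mutation
                    child ^= flips
                    _repair(child, min_vars, max_vars, rng)
                    if len(children) < cfg.population_size:
                        children.append(child)
            pop = children
            fits = np.array([fitness(m) for m in pop])
            gen_best = int(np.argmin(fits))
            if fits[gen_best] < fitness(elite) or (
                fits[gen_best] == fitness(elite)
                and sort_key(pop[gen_best]) < sort_key(elite)
            ):
                elite = pop[gen_best].copy()
            trace.append(float(fitness(elite)))
        traces.append(trace)
        if best_overall is None or sort_key(elite) < sort_key(best_overall):
            best_overall = elite.copy()
    return np.sort(np.flatnonzero(best_overall)), traces


@dataclass
class GALDAModel:
    selected_indices: np.ndarray    # into the gene space (bins or raw columns)
    selected_ppm: np.ndarray | None
    lda: LDAModel
    fitness_trace: list
    config: GAConfig = field(default_factory=GAConfig)
    ppm: np.ndarray | None = None       # full training axis, for axis checks
    bin_starts: np.ndarray | None = None  # bin start indices, None = raw


def design_matrix(X: np.ndarray, bin_starts: np.ndarray | None) -> np.ndarray:
    """Map full-resolution spectra into the model's gene space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X if bin_starts is None else bin_matrix(X, bin_starts)


def fit_galda(
    X: np.ndarray,
    labels: np.ndarray,
    config: GAConfig | None = None,
    ppm: np.ndarray | None = None,
) -> GALDAModel:
    """GA variable selection followed by LDA on the selected variables.

    With a ppm axis and ``config.bin_width`` set, selection runs over
    contiguous ppm-bin means; otherwise over the raw columns.
    """
    cfg = config if config is not None else GAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    starts = None
    centers = None if ppm is None else np.asarray(ppm, dtype=float)
    Xg = X
    if ppm is not None and cfg.bin_width:
        starts, centers = make_bins(ppm, cfg.bin_width)
        Xg = bin_matrix(X, starts)
    selected, traces = ga_select(Xg, labels, cfg)
    lda = fit_lda(Xg[:, selected], labels, shrinkage="auto")
    return GALDAModel(
        selected_indices=selected,
        selected_ppm=None if centers is None else centers[selected],
        lda=lda, fitness_trace=traces, config=cfg,
        ppm=None if ppm is None else np.asarray(ppm, dtype=float),
        bin_starts=starts,
    )


def predict_galda(model: GALDAModel, X: np.ndarray):
    Xg = design_matrix(X, model.bin_starts)
    return predict_lda(model.lda, Xg[:, model.selected_indices])


# --------------------------------------------------------------------------
# plain-text persistence

def galda_to_dict(model: GALDAModel) -> dict:
    return {
        "selected_indices": model.selected_indices.tolist(),
        "selected_ppm": None if model.selected_ppm is None
        else model.selected_ppm.tolist(),
        "lda": {
            "class_means": model.lda.class_means.tolist(),
            "pooled_covariance": model.lda.pooled_covariance.tolist(),
            "priors": model.lda.priors.tolist(),
            "class_order": list(model.lda.class_order),
            "shrinkage": model.lda.shrinkage,
        },
        "fitness_trace": model.fitness_trace,
        "config": asdict(model.config),
        "ppm": None if model.ppm is None else model.ppm.tolist(),
        "bin_starts": None if model.bin_starts is None
        else model.bin_starts.tolist(),
    }


def galda_from_dict(payload: dict) -> GALDAModel:
    lda = LDAModel(
        class_means=np.asarray(payload["lda"]["class_means"], dtype=float),
        pooled_covariance=np.asarray(payload["lda"]["pooled_covariance"],
                                     dtype=float),
        priors=np.asarray(payload["lda"]["priors"], dtype=float),
        class_order=tuple(payload["lda"]["class_order"]),
        shrinkage=float(payload["lda"]["shrinkage"]),
    )
    return GALDAModel(
        selected_indices=np.asarray(payload["selected_indices"], dtype=int),
        selected_ppm=None if payload["selected_ppm"] is None
        else np.asarray(payload["selected_ppm"], dtype=float),
        lda=lda,
        fitness_trace=payload["fitness_trace"],
        config=GAConfig(**payload["config"]),
        ppm=None if payload["ppm"] is None
        else np.asarray(payload["ppm"], dtype=float),
        bin_starts=None if payload.get("bin_starts") is None
        else np.asarray(payload["bin_starts"], dtype=int),
    )
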