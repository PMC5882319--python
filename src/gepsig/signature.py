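"""Model-selection engine for the expression signature.

The response is the null-model deviance residual, standardized to unit
mean square ("Euclidean-length" scaling).  Candidate probe subsets are
scored by fitting an epsilon-insensitive RBF support-vector regression
of the standardized residual on the subset, squashing predictions to a
(0,1) risk score, and computing Harrell's C between scores and the
censored outcomes.  A genetic algorithm searches subsets; model
comparison is lexicographic (max C, then min AIC, min BIC, min RMSE).
The fitted score is rank-inverse-normal transformed and a single
regression-tree split of the residuals locates the risk cutoff that
separates the Favorable / Non-favorable classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .containers import ExpressionMatrix
from .survstats import harrell_c

__all__ = [
    "GAConfig",
    "ModelScore",
    "SVRParams",
    "FittedSVR",
    "SignatureModel",
    "CVReport",
    "standardize_response",
    "fit_svr",
    "score_samples",
    "inverse_transform_scores",
    "partition_cutoff",
    "cross_validate",
    "ga_select",
    "classify",
    "FAVORABLE",
    "NON_FAVORABLE",
]

FAVORABLE = "Favorable"
NON_FAVORABLE = "Non-favorable"


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for probe-subset search."""

    population: int = 100
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # default 1/n_probes at run time
    subset_min: int = 15
    subset_max: int = 21
    elitism: int = 1
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1):
            raise ValueError("crossover_prob must be in [0,1]")
        if self.mutation_prob is not None and not (0 <= self.mutation_prob <= 1):
            raise ValueError("mutation_prob must be in [0,1]")
        if self.subset_min > self.subset_max:
            raise ValueError("subset_min must be <= subset_max")
        if self.subset_min < 1:
            raise ValueError("subset_min must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass(frozen=True)
class ModelScore:
    """Multi-criterion fitness; compared lexicographically."""

    harrell_c: float
    aic: float
    bic: float
    rmse: float  # out-of-fold RMSE; the 50x10% holdout RMSE lives in CVReport

    def key(self) -> tuple:
        return (-self.harrell_c, self.aic, self.bic, self.rmse)

    def better_than(self, other: "ModelScore") -> bool:
        return self.key() < other.key()


@dataclass
class SVRParams:
    """RBF support-vector-regression hyperparameters.

    ``gamma`` accepts a positive float, ``"scale"`` (the conventional
    1 / (n_features * feature variance)), or the default ``"smooth"``
    (1 / (30 * n_features)): a deliberately wide bandwidth under which
    the kernel regression behaves near-linearly, so that predictions
    extrapolate to samples outside the training cloud instead of
    collapsing to the intercept.
    """

    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "smooth"

    def validate(self) -> None:
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("SVR hyperparameters must be positive")
        if isinstance(self.gamma, (int, float)):
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")
        elif self.gamma not in {"scale", "smooth"}:
            raise ValueError("gamma must be a float, 'scale' or 'smooth'")

    def resolve_gamma(self, n_features: int) -> float | str:
        if self.gamma == "smooth":
            return 1.0 / (30.0 * n_features)
        return self.gamma


@dataclass
class FittedSVR:
    """An RBF support-vector regression with frozen feature scaling."""

    probe_ids: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    params: SVRParams
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma_value: float

    def predict(self, matrix: ExpressionMatrix) -> np.ndarray:
        Xs = self._design(matrix)
        sq = (
            (Xs**2).sum(axis=1)[:, None]
            - 2 * Xs @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.gamma_value * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def _design(self, matrix: ExpressionMatrix) -> np.ndarray:
        missing = [p for p in self.probe_ids if p not in matrix.values.index]
        if missing:
            raise KeyError(f"model probes missing from matrix: {missing}")
        X = matrix.values.loc[self.probe_ids].to_numpy(dtype=float).T
        return (X - self.feature_mean) / self.feature_sd


def standardize_response(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a residual vector to unit mean square (||y||_2 = sqrt(n)).

    Returns the scaled vector and the multiplicative constant applied,
    so the transform can be inverted.
    """
    d = np.asarray(d, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm == 0:
        raise ValueError("zero residual vector cannot be standardized")
    scale = float(np.sqrt(d.size) / norm)
    return d * scale, scale


def fit_svr(
    matrix: ExpressionMatrix,
    probe_ids,
    y: np.ndarray,
    params: SVRParams | None = None,
) -> FittedSVR:
    """Fit an RBF-kernel epsilon-SVR of ``y`` on the given probe subset.

    Features (probes) are z-scored with training statistics that are
    frozen into the returned model for prospective application.
    """
    probe_ids = list(probe_ids)
    if not probe_ids:
        raise ValueError("probe subset is empty")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    params = params or SVRParams()
    params.validate()
    X = matrix.values.loc[probe_ids].to_numpy(dtype=float).T
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    reg = SVR(
        kernel="rbf",
        C=params.C,
        epsilon=params.epsilon,
        gamma=params.resolve_gamma(len(probe_ids)),
    )
    reg.fit(Xs, np.asarray(y, dtype=float))
    return FittedSVR(
        probe_ids=probe_ids,
        feature_mean=mean,
        feature_sd=sd,
        params=params,
        support_vectors=reg.support_vectors_.copy(),
        dual_coef=reg.dual_coef_.ravel().copy(),
        intercept=float(reg.intercept_[0]),
        gamma_value=float(reg._gamma),
    )


def score_samples(
    regressor: FittedSVR,
    matrix: ExpressionMatrix,
    pred_mean: float,
    pred_sd: float,
) -> np.ndarray:
    """Map raw SVR predictions to (0,1) risk scores.

    Predictions are standardized by the training-prediction mean/SD and
    passed through a logistic squash; the map is strictly monotone, so
    ranks (and hence Harrell's C and downstream classes) are preserved.
    """
    raw = regressor.predict(matrix)
    z = (raw - pred_mean) / pred_sd
    return 1.0 / (1.0 + np.exp(-z))


def inverse_transform_scores(scores: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets), rescaled to [0,1].

    Compresses outliers and homogenizes the score distribution; strictly
    monotone, with ties sharing a value.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if np.unique(scores).size < 2:
        raise ValueError("all scores equal: transform undefined")
    ranks = stats.rankdata(scores, method="average")
    n = scores.size
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    lo, hi = z.min(), z.max()
    return (z - lo) / (hi - lo)


def partition_cutoff(scores: np.ndarray, d: np.ndarray, min_leaf: int = 1) -> float:
    """Single CART-style regression split of ``d`` along ``scores``.

    Returns the midpoint of the adjacent distinct score pair whose split
    maximizes the between-group sum-of-squares reduction; ties break
    toward the smaller cutoff.  ``min_leaf`` imposes the usual CART
    minimum group size on both sides of the split, guarding against
    degenerate cutoffs isolating a handful of extreme residuals.
    """
    scores = np.asarray(scores, dtype=float)
    d = np.asarray(d, dtype=float)
    if scores.size != d.size or scores.size < 2:
        raise ValueError("need >= 2 aligned scores and residuals")
    if np.unique(scores).size < 2:
        raise ValueError("need >= 2 distinct scores")
    if np.unique(d).size < 2:
        raise ValueError("constant residuals: no informative split")
    if min_leaf < 1 or 2 * min_leaf > scores.size:
        raise ValueError("min_leaf must be >= 1 and <= n/2")
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], d[order]
    distinct = np.unique(s)
    best_c, best_red = None, -np.inf
    total_sse = float(((y - y.mean()) ** 2).sum())
    for a, b in zip(distinct[:-1], distinct[1:]):
        c = (a + b) / 2.0
        left = y[s <= c]
        right = y[s > c]
        if len(left) < min_leaf or len(right) < min_leaf:
            continue
        sse = (
            float(((left - left.mean()) ** 2).sum())
            + float(((right - right.mean()) ** 2).sum())
        )
        red = total_sse - sse
        if red > best_red + 1e-12:
            best_red, best_c = red, c
    if best_c is None:
        raise ValueError("no admissible split under the min_leaf constraint")
    return float(best_c)


@dataclass
class CVReport:
    """Repeated random-holdout cross-validation RMSEs."""

    rmse: list[float]
    folds: int
    holdout: float
    seed: int

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))


def cross_validate(
    matrix: ExpressionMatrix,
    probe_ids,
    y: np.ndarray,
    folds: int = 50,
    holdout: float = 0.10,
    seed: int = 0,
    params: SVRParams | None = None,
) -> CVReport:
    """``folds`` independent random holdout splits (not a partition).

    Each repetition refits the SVR on the retained fraction and records
    the root-mean-square prediction error on the held-out samples.
    """
    if not (0 < holdout < 1):
        raise ValueError("holdout must be in (0,1)")
    if folds < 1:
        raise ValueError("folds must be >= 1")
    n = matrix.n_samples
    n_hold = int(round(n * holdout))
    if n_hold < 1:
        raise ValueError("holdout fraction leaves no held-out sample")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rmses = []
    sample_ids = np.array(matrix.sample_ids)
    for _ in range(folds):
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        sub = matrix.subset_samples(sample_ids[train])
        reg = fit_svr(sub, probe_ids, y[train], params)
        pred = reg.predict(matrix.subset_samples(sample_ids[hold]))
        rmses.append(float(np.sqrt(np.mean((pred - y[hold]) ** 2))))
    return CVReport(rmse=rmses, folds=folds, holdout=holdout, seed=seed)


def _fitness(
    matrix: ExpressionMatrix,
    probe_ids,
    y: np.ndarray,
    time,
    event,
    params: SVRParams | None,
    fold_sets: list[np.ndarray] | None = None,
) -> ModelScore:
    """Out-of-fold ModelScore for one candidate probe subset.

    Predictions are assembled from internal deterministic K-fold splits
    (default: fold = sample index mod 3), so that the concordance and
    RMSE reflect generalization rather than kernel memorization; with
    several ``fold_sets`` the criteria are averaged across splits to
    damp fold noise.  AIC/BIC are Gaussian-likelihood surrogates on the
    out-of-fold residuals with parameter count |subset| + 1.
    """
    n = y.size
    if fold_sets is None:
        fold_sets = [np.arange(n) % 3]
    sample_ids = np.array(matrix.sample_ids)
    cs, rsss = [], []
    for folds in fold_sets:
        pred = np.empty(n)
        for f in np.unique(folds):
            hold = folds == f
            sub = matrix.subset_samples(sample_ids[~hold])
            reg = fit_svr(sub, probe_ids, y[~hold], params)
            pred[hold] = reg.predict(matrix.subset_samples(sample_ids[hold]))
        mu, sd = float(pred.mean()), float(pred.std())
        scores = 1.0 / (1.0 + np.exp(-(pred - mu) / (sd if sd > 0 else 1.0)))
        try:
            cs.append(harrell_c(scores, time, event))
        except ValueError:
            cs.append(0.5)
        rsss.append(float(((y - pred) ** 2).sum()))
    c = float(np.mean(cs))
    k = len(probe_ids) + 1
    sigma2 = max(float(np.mean(rsss)) / n, 1e-12)
    aic = n * np.log(sigma2) + 2 * k
    bic = n * np.log(sigma2) + k * np.log(n)
    rmse = float(np.sqrt(sigma2))
    return ModelScore(harrell_c=c, aic=float(aic), bic=float(bic), rmse=rmse)


def ga_fold_sets(seed: int, n: int) -> list[np.ndarray]:
    """The two deterministic 3-fold assignments used by the GA fitness."""
    fold_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5039]))
    return [fold_rng.permutation(n) % 3 for _ in range(2)]


def candidate_score(
    matrix: ExpressionMatrix, probe_ids, y, time, event,
    seed: int = 0, params: SVRParams | None = None,
) -> ModelScore:
    """ModelScore of one probe subset under the GA's fitness definition."""
    y = np.asarray(y, dtype=float)
    return _fitness(matrix, probe_ids, y, time, event, params,
                    ga_fold_sets(seed, y.size))


def _repair(mask: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """Clamp a bit mask's popcount into [lo, hi] in place."""
    on = np.nonzero(mask)[0]
    off = np.nonzero(~mask)[0]
    if on.size < lo:
        add = rng.choice(off, size=lo - on.size, replace=False)
        mask[add] = True
    elif on.size > hi:
        drop = rng.choice(on, size=on.size - hi, replace=False)
        mask[drop] = False


def ga_select(
    matrix: ExpressionMatrix,
    y: np.ndarray,
    time,
    event,
    config: GAConfig | None = None,
    params: SVRParams | None = None,
) -> tuple[list[str], ModelScore]:
    """Genetic-algorithm search over probe subsets.

    Bit-mask encoding with subset-size repair, tournament selection,
    uniform crossover, per-bit mutation and elitism; returns the best
    subset ever evaluated with its lexicographic ModelScore.  Fully
    reproducible from ``config.seed``.

    The initial population is biased toward probes with high univariate
    rank correlation to the response (half of each starting subset drawn
    from the top of that ranking), a standard screening warm-start that
    lets the limited evaluation budget concentrate on refining rather
    than locating the signal; the search itself remains free to discard
    screened probes.  Candidate fitness is computed out-of-fold on two
    deterministic 3-fold splits (see ``_fitness``).
    """
    config = config or GAConfig()
    probes = np.array(matrix.probe_ids)
    n_probes = probes.size
    if n_probes < config.subset_min:
        raise ValueError(
            f"candidate pool ({n_probes}) smaller than subset_min ({config.subset_min})"
        )
    hi = min(config.subset_max, n_probes)
    lo = config.subset_min
    pmut = config.mutation_prob if config.mutation_prob is not None else 1.0 / n_probes
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=float)

    n = y.size
    fold_sets = ga_fold_sets(config.seed, n)

    cache: dict[tuple, ModelScore] = {}

    def evaluate(mask: np.ndarray) -> ModelScore:
        key = tuple(np.nonzero(mask)[0])
        if key not in cache:
            cache[key] = _fitness(
                matrix, probes[list(key)], y, time, event, params, fold_sets
            )
        return cache[key]

    # univariate screening ranks for the warm start
    rows = matrix.values.to_numpy(dtype=float)
    r_y = stats.rankdata(y)
    r_rows = np.apply_along_axis(stats.rankdata, 1, rows)
    corr = np.abs(np.corrcoef(np.vstack([r_y, r_rows]))[0, 1:])
    ranking = np.argsort(-corr)

    pop = []
    # deterministic screened individuals: the top-k ranked probes for a
    # few subset sizes, competing from generation 0
    for size in sorted({lo, (lo + hi) // 2, hi}):
        mask = np.zeros(n_probes, dtype=bool)
        mask[ranking[:size]] = True
        pop.append(mask)
    while len(pop) < config.population:
        size = int(rng.integers(lo, hi + 1))
        n_top = size // 2
        top_window = ranking[: min(max(2 * size, 20), n_probes)]
        mask = np.zeros(n_probes, dtype=bool)
        mask[rng.choice(top_window, size=n_top, replace=False)] = True
        rest = np.nonzero(~mask)[0]
        mask[rng.choice(rest, size=size - n_top, replace=False)] = True
        pop.append(mask)
    pop = pop[: config.population]
    scores = [evaluate(m) for m in pop]
    best_idx = min(range(len(pop)), key=lambda i: scores[i].key())
    best_mask, best_score = pop[best_idx].copy(), scores[best_idx]

    for _ in range(config.generations):
        new_pop = []
        elite = sorted(range(len(pop)), key=lambda i: scores[i].key())[: config.elitism]
        for i in elite:
            new_pop.append(pop[i].copy())
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=config.tournament)
                winner = min(contenders, key=lambda i: scores[i].key())
                parents.append(pop[winner])
            if rng.random() < config.crossover_prob:
                swap = rng.random(n_probes) < 0.5
                child = np.where(swap, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(n_probes) < pmut
            child = child ^ flip
            _repair(child, lo, hi, rng)
            new_pop.append(child)
        pop = new_pop
        scores = [evaluate(m) for m in pop]
        gen_best = min(range(len(pop)), key=lambda i: scores[i].key())
        if scores[gen_best].better_than(best_score):
            best_mask, best_score = pop[gen_best].copy(), scores[gen_best]
    return list(probes[best_mask]), best_score


@dataclass
class SignatureModel:
    """A complete, frozen signature classifier.

    Bundles the selected probes, the fitted SVR, the score squash and
    the frozen monotone score transform, and the partition cutoff that
    separates the Favorable / Non-favorable classes.  The transform is
    stored as the training (raw score -> transformed score) pairs and
    applied to new cohorts by monotone interpolation, so validation
    classification never re-estimates anything.
    """

    regressor: FittedSVR
    response_scale: float
    pred_mean: float
    pred_sd: float
    transform_x: np.ndarray  # sorted training raw scores
    transform_y: np.ndarray  # matching transformed scores
    cutoff: float
    class_names: tuple[str, str] = (FAVORABLE, NON_FAVORABLE)
    metadata: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return self.regressor.probe_ids

    def raw_scores(self, matrix: ExpressionMatrix) -> np.ndarray:
        return score_samples(self.regressor, matrix, self.pred_mean, self.pred_sd)

    def transformed_scores(self, matrix: ExpressionMatrix) -> np.ndarray:
        raw = self.raw_scores(matrix)
        return np.interp(raw, self.transform_x, self.transform_y)

    def to_json(self) -> str:
        payload = {
            "format": "gepsig-signature-model",
            "version": 1,
            "probe_ids": self.regressor.probe_ids,
            "svr": {
                "C": self.regressor.params.C,
                "epsilon": self.regressor.params.epsilon,
                "gamma": self.regressor.params.gamma,
                "gamma_value": self.regressor.gamma_value,
                "feature_mean": self.regressor.feature_mean.tolist(),
                "feature_sd": self.regressor.feature_sd.tolist(),
                "support_vectors": self.regressor.support_vectors.tolist(),
                "dual_coef": self.regressor.dual_coef.tolist(),
                "intercept": self.regressor.intercept,
            },
            "response_scale": self.response_scale,
            "pred_mean": self.pred_mean,
            "pred_sd": self.pred_sd,
            "transform_x": self.transform_x.tolist(),
            "transform_y": self.transform_y.tolist(),
            "cutoff": self.cutoff,
            "class_names": list(self.class_names),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        if payload.get("format") != "gepsig-signature-model":
            raise ValueError("not a signature-model artifact")
        svr = payload["svr"]
        reg = FittedSVR(
            probe_ids=list(payload["probe_ids"]),
            feature_mean=np.array(svr["feature_mean"], dtype=float),
            feature_sd=np.array(svr["feature_sd"], dtype=float),
            params=SVRParams(C=svr["C"], epsilon=svr["epsilon"], gamma=svr["gamma"]),
            support_vectors=np.array(svr["support_vectors"], dtype=float),
            dual_coef=np.array(svr["dual_coef"], dtype=float),
            intercept=float(svr["intercept"]),
            gamma_value=float(svr["gamma_value"]),
        )
        return cls(
            regressor=reg,
            response_scale=float(payload["response_scale"]),
            pred_mean=float(payload["pred_mean"]),
            pred_sd=float(payload["pred_sd"]),
            transform_x=np.array(payload["transform_x"], dtype=float),
            transform_y=np.array(payload["transform_y"], dtype=float),
            cutoff=float(payload["cutoff"]),
            class_names=tuple(payload["class_names"]),
            metadata=dict(payload.get("metadata", {})),
        )

    @classmethod
    def load(cls, path) -> "SignatureModel":
        return cls.from_json(Path(path).read_text())


def classify(model: SignatureModel, matrix: ExpressionMatrix) -> pd.Series:
    """Assign each sample to Favorable (score <= cutoff) or Non-favorable."""
    t = model.transformed_scores(matrix)
    fav, nonfav = model.class_names
    labels = np.where(t > model.cutoff, nonfav, fav)
    return pd.Series(labels, index=matrix.values.columns, name="risk_class")
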