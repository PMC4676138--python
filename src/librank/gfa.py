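"""Genetic Function Approximation (GFA) QSAR model building.

GFA evolves regression models whose terms are drawn from a descriptor pool:
plain linear terms x and truncated-power spline terms <a - x> or <x - a>
(<y> = max(0, y)), with knots drawn from observed descriptor quantiles.
Individuals are term lists; coefficients come from least squares on the
training data; fitness is Friedman's lack-of-fit (LOF) score,

    LOF = (SSE / m) / (1 - (c + d * p) / m)^2

with m samples, c basis functions (terms), p total parameters and a
smoothness factor d (default 1.0) — SSE alone divided by m when c = p = 0.
The complexity penalty drives term-set selection; the best individual by
LOF is returned.

Supporting steps: a k-nearest-neighbour outlier filter (mean distance to
the k nearest neighbours in standardized descriptor space, z-score
thresholded), random or diversity (MaxMin) train/test splitting, and
Y-scrambling validation (refit on permuted responses; training/test R²
collapsing toward zero indicates no chance correlation).

Everything is deterministic under a fixed seed.  A fitted model exports to
the same plain-text format the ADME/T module loads, so a GFA product is
directly usable as a logBB model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .admet import LogBBModel
from .chemio import LibrankError

LINEAR = "linear"
SPLINE_BELOW = "spline_below"  # coef * max(0, knot - x)
SPLINE_ABOVE = "spline_above"  # coef * max(0, x - knot)


@dataclass
class RegressionDataset:
    """Named descriptor matrix plus response vector."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise LibrankError("X and y must have the same length")
        if self.X.isna().any().any() or self.y.isna().any():
            raise LibrankError("dataset contains missing values")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "RegressionDataset":
        return RegressionDataset(self.X.iloc[idx].reset_index(drop=True),
                                 self.y.iloc[idx].reset_index(drop=True))


@dataclass(frozen=True)
class Term:
    descriptor: str
    kind: str  # linear | spline_below | spline_above
    knot: float = 0.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.kind == LINEAR:
            return x
        if self.kind == SPLINE_BELOW:
            return np.maximum(0.0, self.knot - x)
        if self.kind == SPLINE_ABOVE:
            return np.maximum(0.0, x - self.knot)
        raise LibrankError(f"unknown term kind {self.kind!r}")


@dataclass
class GFAModel:
    terms: list[Term]
    intercept: float
    coefficients: list[float]
    lof: float
    r2_train: float
    r2_test: float | None = None

    def design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [t.evaluate(X[t.descriptor].to_numpy(float)) for t in self.terms]
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + self.design(X) @ np.asarray(self.coefficients)

    def r_squared(self, data: RegressionDataset) -> float:
        y = data.y.to_numpy(float)
        resid = y - self.predict(data.X)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    def coefficient_of(self, descriptor: str, kind: str = LINEAR) -> float | None:
        for t, c in zip(self.terms, self.coefficients):
            if t.descriptor == descriptor and t.kind == kind:
                return c
        return None

    def to_logbb_model(self) -> LogBBModel:
        linear = [(t.descriptor, c) for t, c in zip(self.terms, self.coefficients) if t.kind == LINEAR]
        splines = [
            (t.descriptor, t.knot, c, t.kind.split("_")[1])
            for t, c in zip(self.terms, self.coefficients)
            if t.kind != LINEAR
        ]
        return LogBBModel(intercept=self.intercept, linear_terms=linear, spline_terms=splines)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def knn_outlier_filter(data: RegressionDataset, k: int, z_threshold: float) -> np.ndarray:
    """Indices of compounds kept after kNN mean-distance outlier removal.

    Descriptors are standardized; each compound's score is its mean
    Euclidean distance to its k nearest neighbours; compounds scoring above
    mean + z_threshold * sd of all scores are removed.
    """
    if k <= 0:
        raise LibrankError("k must be positive")
    n = len(data)
    if k >= n:
        raise LibrankError(f"k must be < n ({n})")
    X = data.X.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    dist, _ = nn.kneighbors(Z)
    scores = dist[:, 1:].mean(axis=1)  # drop self-distance column
    cutoff = scores.mean() + z_threshold * scores.std(ddof=0)
    return np.flatnonzero(scores <= cutoff)


def split_train_test(
    data: RegressionDataset, fraction: float, mode: str = "random", seed: int = 0
) -> tuple[RegressionDataset, RegressionDataset]:
    """Disjoint, exhaustive train/test split; deterministic given seed.

    ``mode='diversity'`` builds the training side by MaxMin selection in
    standardized descriptor space (Euclidean distance) starting from the
    point farthest from the centroid; ``mode='random'`` shuffles.
    """
    if not 0.0 < fraction < 1.0:
        raise LibrankError("fraction must be in (0, 1)")
    n = len(data)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if mode == "random":
        order = np.random.default_rng(seed).permutation(n)
        train_idx = np.sort(order[:n_train])
    elif mode == "diversity":
        X = data.X.to_numpy(float)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        start = int(np.argmax(np.linalg.norm(Z - Z.mean(axis=0), axis=1)))
        chosen = [start]
        min_d = np.linalg.norm(Z - Z[start], axis=1)
        min_d[start] = -1.0
        while len(chosen) < n_train:
            pick = int(np.argmax(min_d))
            chosen.append(pick)
            d = np.linalg.norm(Z - Z[pick], axis=1)
            np.minimum(min_d, d, out=min_d, where=min_d >= 0)
            min_d[pick] = -1.0
        train_idx = np.sort(np.array(chosen))
    else:
        raise LibrankError(f"unknown split mode {mode!r}")
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return data.subset(train_idx), data.subset(test_idx)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def lof_score(sse: float, n_samples: int, n_basis: int, n_params: int, d: float = 1.0) -> float:
    """Friedman's lack-of-fit score (see module docstring)."""
    m = n_samples
    denom = 1.0 - (n_basis + d * n_params) / m
    if denom <= 0:
        raise LibrankError("model too complex for sample size (LOF denominator <= 0)")
    return (sse / m) / denom**2


_PENALTY = float("inf")


def _fit_terms(terms: list[Term], data: RegressionDataset, d: float) -> tuple[float, float, list[float], float]:
    """Least-squares fit; returns (lof, intercept, coefs, sse).

    Rank-deficient systems are penalized with infinite LOF rather than
    failing the evolution.
    """
    y = data.y.to_numpy(float)
    cols = [t.evaluate(data.X[t.descriptor].to_numpy(float)) for t in terms]
    A = np.column_stack([np.ones(len(y))] + cols)
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        return _PENALTY, 0.0, [0.0] * len(terms), float("inf")
    resid = y - A @ sol
    sse = float(resid @ resid)
    c = len(terms)
    p = c + 1  # coefficients + intercept
    try:
        lof = lof_score(sse, len(y), c, p, d=d)
    except LibrankError:
        return _PENALTY, 0.0, [0.0] * len(terms), sse
    return lof, float(sol[0]), [float(v) for v in sol[1:]], sse


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

@dataclass
class GFAParams:
    population: int = 80
    generations: int = 40
    min_terms: int = 1
    max_terms: int = 5
    splines: bool = True
    p_crossover: float = 0.7
    p_mutation: float = 0.35
    tournament: int = 3
    elitism: int = 2
    d: float = 1.0  # LOF smoothness factor
    knot_quantiles: tuple[float, float] = (0.05, 0.95)


def _random_term(rng: np.random.Generator, names: list[str], knots: dict[str, np.ndarray], splines: bool) -> Term:
    name = names[rng.integers(len(names))]
    if splines and rng.random() < 0.4:
        kind = SPLINE_BELOW if rng.random() < 0.5 else SPLINE_ABOVE
        pool = knots[name]
        return Term(name, kind, float(pool[rng.integers(len(pool))]))
    return Term(name, LINEAR)


def _dedupe(terms: list[Term]) -> list[Term]:
    seen, out = set(), []
    for t in terms:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def gfa_evolve(
    data: RegressionDataset,
    params: GFAParams | None = None,
    seed: int = 0,
    test_data: RegressionDataset | None = None,
) -> GFAModel:
    """Evolve term subsets by a genetic algorithm scored with LOF.

    Crossover exchanges term sublists between parents; mutation adds,
    removes or replaces a term or re-draws a spline knot from the observed
    descriptor quantile range.  Fully reproducible given the seed.
    """
    params = params or GFAParams()
    if len(data) < params.max_terms + 2:
        raise LibrankError("dataset too small for the configured term bounds")
    rng = np.random.default_rng(seed)
    names = list(data.X.columns)
    lo, hi = params.knot_quantiles
    knots = {
        name: np.unique(np.quantile(data.X[name].to_numpy(float), np.linspace(lo, hi, 19)))
        for name in names
    }

    def random_individual() -> list[Term]:
        size = int(rng.integers(params.min_terms, params.max_terms + 1))
        terms = [_random_term(rng, names, knots, params.splines) for _ in range(size)]
        return _dedupe(terms) or [_random_term(rng, names, knots, False)]

    def clip(terms: list[Term]) -> list[Term]:
        terms = _dedupe(terms)
        if len(terms) > params.max_terms:
            terms = terms[: params.max_terms]
        while len(terms) < params.min_terms:
            terms = _dedupe(terms + [_random_term(rng, names, knots, params.splines)])
        return terms

    population = [random_individual() for _ in range(params.population)]
    fits = [_fit_terms(ind, data, params.d)[0] for ind in population]

    def tournament() -> list[Term]:
        idx = rng.integers(len(population), size=params.tournament)
        best = min(idx, key=lambda i: fits[i])
        return list(population[best])

    for _ in range(params.generations):
        order = np.argsort(fits)
        next_pop = [list(population[i]) for i in order[: params.elitism]]
        while len(next_pop) < params.population:
            a, b = tournament(), tournament()
            if rng.random() < params.p_crossover and a and b:
                ca, cb = int(rng.integers(len(a) + 1)), int(rng.integers(len(b) + 1))
                child = a[:ca] + b[cb:]
            else:
                child = a
            if rng.random() < params.p_mutation or not child:
                op = rng.random()
                if op < 0.3 and len(child) < params.max_terms:
                    child = child + [_random_term(rng, names, knots, params.splines)]
                elif op < 0.6 and len(child) > params.min_terms:
                    child = [t for i, t in enumerate(child) if i != rng.integers(len(child))]
                elif child:
                    i = int(rng.integers(len(child)))
                    old = child[i]
                    if old.kind != LINEAR and rng.random() < 0.5:
                        pool = knots[old.descriptor]
                        child[i] = Term(old.descriptor, old.kind, float(pool[rng.integers(len(pool))]))
                    else:
                        child[i] = _random_term(rng, names, knots, params.splines)
            next_pop.append(clip(child))
        population = next_pop
        fits = [_fit_terms(ind, data, params.d)[0] for ind in population]

    best_i = int(np.argmin(fits))
    terms = population[best_i]
    lof, intercept, coefs, _ = _fit_terms(terms, data, params.d)
    model = GFAModel(terms=terms, intercept=intercept, coefficients=coefs, lof=lof, r2_train=0.0)
    model.r2_train = model.r_squared(data)
    if test_data is not None:
        model.r2_test = model.r_squared(test_data)
    return model


@dataclass
class YScrambleResult:
    r2_train: list[float]
    r2_test: list[float]

    def summary(self) -> dict[str, float]:
        tr, te = np.asarray(self.r2_train), np.asarray(self.r2_test)
        sd_flagged = len(tr) < 2
        return {
            "r2_train_mean": float(tr.mean()),
            "r2_train_sd": 0.0 if sd_flagged else float(tr.std(ddof=1)),
            "r2_test_mean": float(te.mean()) if te.size else float("nan"),
            "r2_test_sd": 0.0 if sd_flagged or not te.size else float(te.std(ddof=1)),
            "sd_undefined": float(sd_flagged),
        }


def y_scramble(
    train: RegressionDataset,
    test: RegressionDataset | None = None,
    params: GFAParams | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> YScrambleResult:
    """Refit after shuffling the training responses, ``n_repeats`` times.

    Models built on scrambled activities should show near-zero R²; retained
    performance would indicate chance correlation.
    """
    if n_repeats < 1:
        raise LibrankError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    r2_train, r2_test = [], []
    for _ in range(n_repeats):
        perm = rng.permutation(len(train))
        scrambled = RegressionDataset(train.X.copy(), train.y.iloc[perm].reset_index(drop=True))
        sub_seed = int(rng.integers(2**31))
        model = gfa_evolve(scrambled, params=params, seed=sub_seed, test_data=test)
        r2_train.append(model.r2_train)
        if test is not None:
            r2_test.append(model.r2_test)
    return YScrambleResult(r2_train=r2_train, r2_test=r2_test)


def make_planted_dataset(
    n: int, p: int, coefs: dict[str, float], noise_sd: float, seed: int,
    spline: tuple[str, float, float] | None = None, x_sd: float = 1.0,
) -> RegressionDataset:
    """Synthetic regression data with a known planted model.

    Descriptors are iid normal columns x0..x{p-1} with sd ``x_sd``; the
    response is the given linear combination (plus, optionally, one
    <knot - x> spline contribution ``spline=(name, knot, coef)``) with
    Gaussian noise.  For spline planting choose ``x_sd`` so the knot lies
    well inside the descriptor's 5th-95th quantile range, otherwise the
    kink is outside data support and the knot is unidentifiable.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(scale=x_sd, size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = np.zeros(n)
    for name, c in coefs.items():
        y += c * X[name].to_numpy()
    if spline is not None:
        name, knot, c = spline
        y += c * np.maximum(0.0, knot - X[name].to_numpy())
    y += rng.normal(scale=noise_sd, size=n)
    return RegressionDataset(X, pd.Series(y, name="y"))
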