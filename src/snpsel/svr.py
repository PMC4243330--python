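"""epsilon-SVR with linear, RBF and Pearson VII universal (PUK) kernels.

The regression solves the standard epsilon-insensitive dual

    max_{a, a*}  -1/2 (a-a*)' K (a-a*) - eps * sum(a+a*) + y'(a-a*)
    s.t.         sum(a-a*) = 0,   0 <= a_i, a*_i <= C,

so predictions are the dual expansion f(x) = sum_i (a_i - a*_i) K(x_i, x)
+ b.  The quadratic program is delegated to libsvm via scikit-learn with a
precomputed Gram matrix; the kernels themselves are evaluated here.

Kernels (d = ||x - z||):

* linear:  K = <x, z>
* rbf:     K = exp(-gamma * d^2)
* puk:     K = 1 / [1 + (2 d sqrt(2^(1/omega) - 1) / sigma)^2]^omega

The PUK interpolates between Lorentzian (omega = 1) and Gaussian
(omega -> infinity) shapes, which lets a single kernel family mimic the
usual stock kernels once (omega, sigma) are tuned.

Model comparison uses repeated k-fold cross-validation: within each repeat
the out-of-fold predictions for all samples are pooled and a single
Pearson correlation with the observed phenotype is computed, giving r
correlation estimates for r repeats.  Features are standardized using
statistics of the training folds only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _SkSVR

# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters.

    gamma is required for 'rbf'; omega and sigma for 'puk'; 'linear' has
    no parameters.
    """

    family: str
    gamma: float | None = None
    omega: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family == "linear":
            pass
        elif self.family == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("rbf kernel needs gamma > 0")
        elif self.family == "puk":
            if self.omega is None or self.omega <= 0:
                raise ValueError("puk kernel needs omega > 0")
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("puk kernel needs sigma > 0")
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")

    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        if self.family == "rbf":
            return f"rbf(gamma={self.gamma:g})"
        return f"puk(omega={self.omega:g}, sigma={self.sigma:g})"


def kernel_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j]) for the given kernel."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[1] != Z.shape[1]:
        raise ValueError("dimension mismatch between X and Z")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
        raise ValueError("kernel inputs must be finite")
    if spec.family == "linear":
        return X @ Z.T
    d2 = cdist(X, Z, metric="sqeuclidean")
    np.maximum(d2, 0.0, out=d2)
    if spec.family == "rbf":
        return np.exp(-spec.gamma * d2)
    # PUK
    c = 4.0 * (2.0 ** (1.0 / spec.omega) - 1.0) / spec.sigma**2
    return (1.0 + c * d2) ** (-spec.omega)


# ---------------------------------------------------------------------------
# epsilon-SVR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVRHyper:
    """Regularization C, tube half-width epsilon and the kernel."""

    C: float
    epsilon: float
    kernel: KernelSpec

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


@dataclass
class SVRModel:
    """Fitted epsilon-SVR in dual form.

    ``dual_coef`` holds a_i - a*_i for every training point (zero for
    points strictly inside the tube); ``predict`` evaluates the dual
    expansion against the stored training inputs.
    """

    X_train: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    hyper: SVRHyper

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = kernel_matrix(np.asarray(X, dtype=float), self.X_train, self.hyper.kernel)
        return K @ self.dual_coef + self.intercept


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    hyper: SVRHyper,
    tol: float = 1e-3,
    max_iter: int = 1_000_000,
) -> SVRModel:
    """Fit epsilon-SVR by solving the dual QP (libsvm backend).

    ``tol`` is the solver's KKT tolerance; the default suits model
    comparison, pass a tighter value when dual coefficients themselves
    are of interest.  ``max_iter`` bounds the solver (ill-conditioned
    corners of a hyperparameter grid can otherwise spin indefinitely);
    hitting the cap returns the truncated solution, which scores poorly
    in cross-validation and is discarded by tuning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    K = kernel_matrix(X, X, hyper.kernel)
    est = _SkSVR(
        kernel="precomputed", C=hyper.C, epsilon=hyper.epsilon, tol=tol, max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(K, y)
    if est.fit_status_ not in (0, 1):  # 1 = iteration cap reached
        raise RuntimeError(f"libsvm failed to converge (status {est.fit_status_})")
    dual = np.zeros(X.shape[0])
    dual[est.support_] = est.dual_coef_.ravel()
    return SVRModel(X.copy(), dual, float(est.intercept_[0]), hyper)


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    correlations: list[float]
    mean: float
    sd: float
    folds: int
    repeats: int
    seed: int
    degenerate_repeats: list[int] = field(default_factory=list)
    mode: str = "pooled"

    @classmethod
    def from_correlations(cls, corrs, folds, repeats, seed, degenerate=(), mode="pooled"):
        corrs = [float(c) for c in corrs]
        mean = float(np.mean(corrs))
        sd = float(np.std(corrs, ddof=1)) if len(corrs) > 1 else 0.0
        return cls(corrs, mean, sd, folds, repeats, seed, list(degenerate), mode)


def _standardize_train_apply(X_train: np.ndarray, X_test: np.ndarray):
    """Zero-mean/unit-variance scaling fit on the training fold only."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_test - mu) / sd


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def repeated_cv_correlation(
    X: np.ndarray,
    y: np.ndarray,
    hyper: SVRHyper,
    k: int = 10,
    r: int = 10,
    seed: int = 0,
    standardize: bool = True,
    mode: str = "pooled",
) -> CVResult:
    """Repeated k-fold CV Pearson correlation of an epsilon-SVR.

    ``mode='pooled'`` (default) pools the out-of-fold predictions of all
    samples within a repeat and computes one correlation per repeat;
    ``mode='per_fold'`` computes one correlation per fold and averages the
    k values within each repeat.  Constant out-of-fold predictions yield a
    correlation of 0 and flag the repeat as degenerate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2 * k:
        raise ValueError("need at least 2k samples for k-fold CV")
    if mode not in ("pooled", "per_fold"):
        raise ValueError("mode must be 'pooled' or 'per_fold'")

    corrs: list[float] = []
    degenerate: list[int] = []
    for rep in range(r):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        folds = _fold_indices(n, k, rng)
        pred = np.empty(n)
        fold_corrs: list[float] = []
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            X_tr, X_te = X[train_mask], X[test_idx]
            if standardize:
                X_tr, X_te = _standardize_train_apply(X_tr, X_te)
            model = fit_svr(X_tr, y[train_mask], hyper)
            pred[test_idx] = model.predict(X_te)
            if mode == "per_fold":
                c, _ = _safe_pearson(pred[test_idx], y[test_idx])
                fold_corrs.append(c)
        if mode == "pooled":
            c, degen = _safe_pearson(pred, y)
            if degen:
                degenerate.append(rep)
            corrs.append(c)
        else:
            corrs.append(float(np.mean(fold_corrs)))
    return CVResult.from_correlations(corrs, k, r, seed, degenerate, mode)


# ---------------------------------------------------------------------------
# hyperparameter grids and search
# ---------------------------------------------------------------------------

_FULL_GRIDS = {
    "C": (0.1, 1.0, 10.0, 100.0, 1000.0),
    "epsilon_rel": (0.001, 0.01, 0.1, 1.0),  # multiples of sd(y)
    "gamma": tuple(float(g) for g in np.logspace(-4, 1, 6)),
    "omega": (0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    "sigma": (0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
}

_COARSE_GRIDS = {
    "C": (1.0, 10.0, 100.0, 1000.0),
    "epsilon_rel": (0.01, 0.1),
    "gamma": (0.01, 0.1, 1.0),
    "omega": (0.5, 1.0, 4.0, 16.0),
    "sigma": (0.5, 1.0, 4.0),
}


def default_grids(
    family: str, y_sd: float, preset: str = "full", n_features: int = 1
) -> list[SVRHyper]:
    """Hyperparameter grid for one kernel family.

    Epsilon values are specified relative to the phenotype SD so the tube
    width follows the scale of the trait, and the distance-kernel scale
    parameters follow the dimensionality of the standardized feature
    space (pairwise distances grow like sqrt(d)): gamma values are
    divided by ``n_features`` and PUK sigma values multiplied by
    ``sqrt(n_features)``.  ``preset='coarse'`` is a smaller grid for
    quick tuning runs.
    """
    g = {"full": _FULL_GRIDS, "coarse": _COARSE_GRIDS}[preset]
    eps_values = [e * y_sd for e in g["epsilon_rel"]]
    scale = float(np.sqrt(max(n_features, 1)))
    combos: list[SVRHyper] = []
    if family == "linear":
        kernels = [KernelSpec("linear")]
    elif family == "rbf":
        kernels = [KernelSpec("rbf", gamma=ga / scale**2) for ga in g["gamma"]]
    elif family == "puk":
        kernels = [
            KernelSpec("puk", omega=w, sigma=s * scale)
            for w, s in itertools.product(g["omega"], g["sigma"])
        ]
    else:
        raise ValueError(f"unknown kernel family {family!r}")
    for C, eps, kern in itertools.product(g["C"], eps_values, kernels):
        combos.append(SVRHyper(C=C, epsilon=eps, kernel=kern))
    return combos


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[SVRHyper],
    k: int = 10,
    r: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[SVRHyper, CVResult, pd.DataFrame]:
    """Evaluate every grid point under repeated CV; return the best.

    The best point has the highest mean correlation; ties break by lower
    SD, then smaller C, then grid order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    results: list[CVResult] = []
    for idx, hyper in enumerate(grid):
        res = repeated_cv_correlation(X, y, hyper, k=k, r=r, seed=seed, standardize=standardize)
        results.append(res)
        rows.append(
            {
                "index": idx,
                "kernel": hyper.kernel.label(),
                "C": hyper.C,
                "epsilon": hyper.epsilon,
                "mean_r": res.mean,
                "sd_r": res.sd,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (-results[i].mean, results[i].sd, grid[i].C, i),
    )
    best = order[0]
    return grid[best], results[best], table


def tune_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    k: int = 10,
    r: int = 10,
    seed: int = 0,
    tuning_repeats: int = 1,
    grid_preset: str = "coarse",
    grid: list[SVRHyper] | None = None,
) -> tuple[SVRHyper, CVResult]:
    """Tune a kernel family with a light CV budget, then evaluate fully.

    Tuning uses ``tuning_repeats`` repeats of k-fold CV over the grid; the
    winning hyperparameters are then re-scored with the full r repeats.
    """
    if grid is None:
        n_features = 1 if np.ndim(X) == 1 else np.asarray(X).shape[1]
        grid = default_grids(family, float(np.std(y)), preset=grid_preset, n_features=n_features)
    best, _, _ = grid_search(X, y, grid, k=k, r=tuning_repeats, seed=seed)
    final = repeated_cv_correlation(X, y, best, k=k, r=r, seed=seed)
    return best, final


# ---------------------------------------------------------------------------
# group selection rule
# ---------------------------------------------------------------------------


def select_best_group(
    groups,
    evaluations: list[CVResult],
    tie_tolerance: float = 0.005,
) -> int:
    """Pick the group index with maximal mean CV correlation.

    Among groups whose mean is within ``tie_tolerance`` of the maximum the
    smallest group wins; remaining ties break by lower SD, then lower
    threshold (i.e. earlier rung).
    """
    sizes = groups.sizes()
    if len(evaluations) != len(sizes):
        raise ValueError("every group needs an evaluation")
    candidates = [i for i, s in enumerate(sizes) if s > 0]
    if not candidates:
        raise ValueError("all groups are empty")
    best_mean = max(evaluations[i].mean for i in candidates)
    near = [i for i in candidates if evaluations[i].mean >= best_mean - tie_tolerance]
    near.sort(key=lambda i: (sizes[i], evaluations[i].sd, groups.thresholds[i]))
    return near[0]
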