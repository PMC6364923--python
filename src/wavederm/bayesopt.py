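"""Bayesian optimization of SVM kernel hyperparameters.

The cross-validated loss (1 - mean CV AUC) is minimized over the kernel's
box-constraint C and its own parameter (gamma or polynomial degree), scanned
on the log10 scale between 1e-3 and 1e6 with a budget of 60 evaluations.  A
Gaussian-process surrogate with a squared-exponential kernel models the
posterior Q over the objective; candidates are proposed by maximizing the
expected improvement

    EI(x) = E_Q[max(0, mu_Q(x_best) - f(x))]

where mu_Q(x_best) is the lowest posterior mean among evaluated points.  If
the posterior standard deviation sigma_Q collapses everywhere on the
candidate set the region is deemed overexploited and the surrogate's scale is
inflated for one proposal, pushing the search to unexplored territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .svm import DEFAULT_SEED, CVResult, KernelSpec, cv_auc

LOG_RANGE = (-3.0, 6.0)  # log10 of the scanned 1e-3 .. 1e6 box
DEFAULT_BUDGET = 60
N_INITIAL = 5
OVEREXPLOIT_SD = 1e-4
SCALE_INFLATION = 10.0
EARLY_STOP_OBJECTIVE = 0.02


def expected_improvement(
    mu: np.ndarray | float, sigma: np.ndarray | float, best_mean: float
) -> np.ndarray | float:
    """Closed-form EI under a Gaussian posterior (minimization).

    With z = (best_mean - mu) / sigma,
    EI = (best_mean - mu) * Phi(z) + sigma * phi(z); at sigma = 0 it
    degenerates to max(0, best_mean - mu).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    improve = best_mean - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, improve / np.where(sigma > 0, sigma, 1.0), 0.0)
    ei = np.where(
        sigma > 0,
        improve * norm.cdf(z) + sigma * norm.pdf(z),
        np.maximum(improve, 0.0),
    )
    if ei.ndim == 0:
        return float(ei)
    return ei


@dataclass
class BOState:
    """Trace of one optimization run: evaluated points and incumbents."""

    bounds: tuple[tuple[float, float], ...]
    X: list[tuple[float, ...]] = field(default_factory=list)
    f: list[float] = field(default_factory=list)
    incumbents: list[float] = field(default_factory=list)
    escapes: list[int] = field(default_factory=list)
    budget: int = DEFAULT_BUDGET

    @property
    def iteration(self) -> int:
        return len(self.f)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.f))

    @property
    def x_best(self) -> tuple[float, ...]:
        return self.X[self.best_index]

    @property
    def f_best(self) -> float:
        return self.f[self.best_index]

    def write_trace(self, path) -> None:
        """CSV audit trail: iteration, coordinates, objective, incumbent."""
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            dims = [f"x{i}" for i in range(len(self.bounds))]
            writer.writerow(["iteration", *dims, "objective", "incumbent"])
            for i, (x, fx, inc) in enumerate(zip(self.X, self.f, self.incumbents)):
                writer.writerow([i, *[repr(v) for v in x], repr(fx), repr(inc)])


def _fit_surrogate(X: np.ndarray, f: np.ndarray, seed: int) -> GaussianProcessRegressor:
    span = max(hi - lo for lo, hi in zip(X.min(axis=0), X.max(axis=0))) or 1.0
    kernel = ConstantKernel(1.0, (1e-4, 1e4)) * RBF(
        length_scale=span / 4 + 1e-6, length_scale_bounds=(1e-3, 1e3)
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-12, 1e-1))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # hyperparameters pinned at a bound are fine for an acquisition
        # surrogate; the posterior is still valid
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, f)
    return gp


def minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    budget: int = DEFAULT_BUDGET,
    seed: int = DEFAULT_SEED,
    n_initial: int = N_INITIAL,
    n_candidates: int = 2000,
    early_stop: float | None = None,
) -> BOState:
    """EI-driven sequential minimization of a black-box objective in a box.

    The initial design is ``n_initial`` seeded scrambled-Sobol points; each
    following proposal maximizes EI over a fresh seeded uniform candidate set.
    Proposals that collide with an already-evaluated point are replaced by
    the most uncertain candidate (duplicate rejection).  The run stops after
    ``budget`` evaluations or once the incumbent drops below ``early_stop``.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    ndim = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    state = BOState(bounds=bounds, budget=budget)

    def evaluate(x: np.ndarray) -> None:
        fx = float(objective(x))
        state.X.append(tuple(float(v) for v in x))
        state.f.append(fx)
        state.incumbents.append(min(state.f))

    n_init = min(n_initial, budget)
    sobol = qmc.Sobol(d=ndim, scramble=True, seed=seed)
    # draw a power-of-two block (Sobol balance) and keep the first n_init
    unit = sobol.random(1 << max(1, (n_init - 1).bit_length()))[:n_init]
    init = lo + (hi - lo) * unit
    for x in init:
        evaluate(x)
        if early_stop is not None and state.incumbents[-1] <= early_stop:
            return state

    while state.iteration < budget:
        X = np.array(state.X)
        f = np.array(state.f)
        gp = _fit_surrogate(X, f, seed)
        cand = lo + (hi - lo) * rng.random((n_candidates, ndim))
        mu, sigma = gp.predict(cand, return_std=True)
        if sigma.max() < OVEREXPLOIT_SD:
            # overexploited: inflate the surrogate scale for this proposal to
            # force exploration of untouched regions
            sigma = sigma * SCALE_INFLATION + OVEREXPLOIT_SD
            state.escapes.append(state.iteration)
        mu_obs = gp.predict(X)
        best_mean = float(mu_obs.min())
        ei = expected_improvement(mu, sigma, best_mean)
        x_next = cand[int(np.argmax(ei))]
        if np.min(np.linalg.norm(X - x_next, axis=1)) < 1e-9:
            x_next = cand[int(np.argmax(sigma))]
        evaluate(x_next)
        if early_stop is not None and state.incumbents[-1] <= early_stop:
            break
    return state


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter box for one kernel, log10-scaled where continuous."""

    kernel: str
    log10_C_range: tuple[float, float] = LOG_RANGE
    log10_gamma_range: tuple[float, float] = LOG_RANGE
    degree_range: tuple[int, int] = (1, 10)

    def bounds(self) -> list[tuple[float, float]]:
        dims = [self.log10_C_range]
        if self.kernel == "gaussian":
            dims.append(self.log10_gamma_range)
        elif self.kernel == "polynomial":
            dims.append((float(self.degree_range[0]), float(self.degree_range[1])))
        return dims

    def to_kernel_spec(self, x: np.ndarray) -> KernelSpec:
        C = float(10.0 ** x[0])
        if self.kernel == "gaussian":
            return KernelSpec(kernel="gaussian", C=C, gamma=float(10.0 ** x[1]))
        if self.kernel == "polynomial":
            return KernelSpec(kernel="polynomial", C=C, degree=int(round(x[1])))
        return KernelSpec(kernel="linear", C=C)


def optimize_kernel(
    features: np.ndarray,
    labels: np.ndarray,
    space: SearchSpace,
    budget: int = DEFAULT_BUDGET,
    seed: int = DEFAULT_SEED,
    n_folds: int = 10,
    leakage_mode: str = "fold_safe",
    early_stop: float = EARLY_STOP_OBJECTIVE,
) -> tuple[KernelSpec, CVResult, BOState]:
    """Tune (C, gamma | degree) by minimizing the cross-validated loss.

    The objective of a point x is 1 - mean 10-fold CV AUC of the kernel it
    encodes; integer degrees are a rounded continuous relaxation, and repeat
    evaluations of an identical rounded spec are served from a cache.
    Returns the incumbent kernel, its CVResult and the full trace.
    """
    cache: dict[KernelSpec, CVResult] = {}

    def objective(x: np.ndarray) -> float:
        spec = space.to_kernel_spec(x)
        if spec not in cache:
            cache[spec] = cv_auc(
                features, labels, spec, n_folds=n_folds, seed=seed, leakage_mode=leakage_mode
            )
        return 1.0 - cache[spec].mean_auc

    state = minimize(
        objective,
        space.bounds(),
        budget=budget,
        seed=seed,
        early_stop=early_stop,
    )
    best_spec = space.to_kernel_spec(np.array(state.x_best))
    return best_spec, cache[best_spec], state
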