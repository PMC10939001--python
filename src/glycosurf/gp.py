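"""Gaussian-process surrogate over a reduced search space.

The kernel is a product over dimensions: a squared-exponential component for
bounded variables and a standard periodic component
``exp(-2 sin^2(pi d / P) / l^2)`` for periodic ones (torsions, in-cell
translations), scaled by a signal variance, plus observation noise.  The
prior mean is the mean of the (transformed) training energies.
Hyperparameters are fitted by maximising the log marginal likelihood with
multistart bounded L-BFGS (analytic gradient); a jitter escalation from 1e-8
to 1e-4 of the signal variance guards against singular kernel matrices.

Acquisition is the exploratory lower confidence bound ``mean - kappa * sd``
(kappa default 2.0).  Candidate generation for both acquisition minimisation
and posterior-mean minimisation uses seeded low-discrepancy (Halton) points
screened in a vectorised pass, with gradient polishing of the best
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import qmc

from .coordinates import SearchSpace


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def _pairwise_terms(space: SearchSpace, X1: np.ndarray, X2: np.ndarray):
    """Per-dimension squared 'distance' entering the exponential.

    For non-periodic dims this is 0.5 * delta^2; for periodic dims it is
    2 * sin^2(pi * delta / P).  Both are divided by l^2 in the kernel, and
    their derivative w.r.t. log l is -2x the term itself.
    """
    d = X1[:, None, :] - X2[None, :, :]
    per = space.periodic
    span = space.span
    out = np.empty_like(d)
    out[..., ~per] = 0.5 * d[..., ~per] ** 2
    if per.any():
        out[..., per] = 2.0 * np.sin(np.pi * d[..., per] / span[per]) ** 2
    return out


def kernel_matrix(space: SearchSpace, X1: np.ndarray, X2: np.ndarray,
                  signal_var: float, lengthscales: np.ndarray) -> np.ndarray:
    terms = _pairwise_terms(space, X1, X2)
    return signal_var * np.exp(-(terms / lengthscales ** 2).sum(axis=-1))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class GPModel:
    """A fitted GP posterior over a search space."""

    space: SearchSpace
    X: np.ndarray
    y: np.ndarray
    signal_var: float
    lengthscales: np.ndarray
    noise_var: float
    prior_mean: float = 0.0
    jitter: float = 0.0
    _chol: tuple | None = field(default=None, repr=False)

    def _factorise(self) -> None:
        n = len(self.X)
        K = kernel_matrix(self.space, self.X, self.X, self.signal_var, self.lengthscales)
        jitter = self.jitter
        while True:
            try:
                c, low = cho_factor(K + (self.noise_var + jitter) * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                # jitter escalation: 1e-8 -> 1e-4 of the signal variance
                jitter = max(jitter * 10.0, 1e-8 * self.signal_var)
                if jitter > 1.05e-4 * self.signal_var:
                    raise
        self.jitter = jitter
        alpha = cho_solve((c, low), self.y - self.prior_mean)
        self._chol = (c, alpha)

    def posterior(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at query points (m, D)."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if self._chol is None:
            self._factorise()
        c, alpha = self._chol
        Ks = kernel_matrix(self.space, self.X, Xq, self.signal_var, self.lengthscales)
        mean = Ks.T @ alpha + self.prior_mean
        v = solve_triangular(c, Ks, lower=True)
        var = self.signal_var - (v ** 2).sum(axis=0)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def acquisition(self, Xq: np.ndarray, kappa: float = 2.0) -> np.ndarray:
        """Lower confidence bound ``mean - kappa * sd`` (to be minimised)."""
        mean, sd = self.posterior(Xq)
        return mean - kappa * sd

    def with_data(self, X: np.ndarray, y: np.ndarray) -> "GPModel":
        """Same hyperparameters, new data (prior mean re-centred)."""
        return GPModel(self.space, np.asarray(X, float), np.asarray(y, float),
                       self.signal_var, self.lengthscales.copy(), self.noise_var,
                       float(np.mean(y)))

    def to_dict(self) -> dict:
        return {
            "signal_var": float(self.signal_var),
            "lengthscales": [float(v) for v in self.lengthscales],
            "noise_var": float(self.noise_var),
            "prior_mean": float(self.prior_mean),
            "n_train": int(len(self.X)),
        }


# ---------------------------------------------------------------------------
# Hyperparameter fitting
# ---------------------------------------------------------------------------

def _neg_lml_and_grad(theta, space, X, y, terms):
    """Negative log marginal likelihood and gradient in log-parameters.

    theta = [log signal_var, log l_1..D, log noise_var].
    """
    n, D = X.shape
    sv = np.exp(theta[0])
    ls = np.exp(theta[1:1 + D])
    nv = np.exp(theta[-1])
    scaled = terms / ls ** 2
    K = sv * np.exp(-scaled.sum(axis=-1))
    Ky = K + (nv + 1e-10 * sv) * np.eye(n)
    try:
        c, low = cho_factor(Ky, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    alpha = cho_solve((c, low), y)
    lml = -0.5 * y @ alpha - np.log(np.diag(c)).sum() - 0.5 * n * np.log(2 * np.pi)
    Kinv = cho_solve((c, low), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.zeros_like(theta)
    grad[0] = 0.5 * (W * K).sum()
    for d in range(D):
        dK = K * (2.0 * scaled[..., d])
        grad[1 + d] = 0.5 * (W * dK).sum()
    grad[-1] = 0.5 * np.trace(W) * nv
    return -lml, -grad


def fit_hyperparameters(space: SearchSpace, X: np.ndarray, y: np.ndarray, *,
                        seed: int = 0, n_restarts: int = 3,
                        noise_bounds: tuple[float, float] = (1e-8, 1e-2),
                        fixed_noise: float | None = None) -> GPModel:
    """Maximise the log marginal likelihood by multistart bounded L-BFGS.

    Deterministic for a given seed.  ``fixed_noise`` pins the noise variance
    (useful for noiseless toy objectives).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least two observations")
    D = space.dimension
    prior_mean = float(np.mean(y))
    yc = y - prior_mean
    var = max(float(np.var(yc)), 1e-12)
    terms = _pairwise_terms(space, X, X)
    rng = np.random.default_rng(seed)

    scale = np.where(space.periodic, 1.0, space.span)
    lo = np.concatenate([[np.log(var * 1e-4)], np.log(0.03 * scale), [np.log(noise_bounds[0])]])
    hi = np.concatenate([[np.log(var * 1e3 + 1e-12)], np.log(10.0 * scale), [np.log(noise_bounds[1])]])
    if fixed_noise is not None:
        lo[-1] = hi[-1] = np.log(fixed_noise)

    starts = [np.concatenate([[np.log(var)], np.log(0.3 * scale),
                              [np.log(fixed_noise) if fixed_noise else np.log(1e-4 * var + 1e-10)]])]
    for _ in range(n_restarts - 1):
        starts.append(lo + rng.random(D + 2) * (hi - lo))

    best = None
    for s0 in starts:
        s0 = np.clip(s0, lo, hi)
        res = minimize(_neg_lml_and_grad, s0, args=(space, X, yc, terms),
                       jac=True, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)), options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    model = GPModel(space, X, y, float(np.exp(theta[0])),
                    np.exp(theta[1:1 + D]), float(np.exp(theta[-1])), prior_mean)
    model._factorise()
    return model


def log_marginal_likelihood(model: GPModel) -> float:
    terms = _pairwise_terms(model.space, model.X, model.X)
    theta = np.concatenate([[np.log(model.signal_var)], np.log(model.lengthscales),
                            [np.log(model.noise_var)]])
    nll, _ = _neg_lml_and_grad(theta, model.space, model.X,
                               model.y - model.prior_mean, terms)
    return -nll


# ---------------------------------------------------------------------------
# Surface minimisation (acquisition / posterior mean)
# ---------------------------------------------------------------------------

def minimize_surface(fn, space: SearchSpace, *, seed: int, n_starts: int,
                     n_polish: int = 8, return_all: bool = False):
    """Minimise a vectorisable function over the space.

    Seeded Halton candidates are screened in one vectorised call; the best
    ``n_polish`` candidates are refined with bounded L-BFGS (numeric
    gradient).  Returns ``(x_best, f_best)`` or, with ``return_all``, the
    polished points and values (for local-minima harvesting).
    """
    D = space.dimension
    sampler = qmc.Halton(d=D, scramble=True, seed=seed)
    cand = space.lower + sampler.random(max(n_starts, n_polish)) * space.span
    vals = np.asarray(fn(cand), dtype=float)
    order = np.argsort(vals)[:n_polish]
    bounds = list(zip(space.lower, space.upper))

    def scalar(x):
        return float(fn(x[None, :])[0])

    xs, fs = [], []
    for idx in order:
        res = minimize(scalar, cand[idx], method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 120})
        xs.append(space.wrap(res.x))
        fs.append(res.fun)
    xs = np.array(xs)
    fs = np.array(fs)
    if return_all:
        return xs, fs
    best = int(np.argmin(fs))
    return xs[best], float(fs[best])


def propose_next(model: GPModel, space: SearchSpace, kappa: float = 2.0, *,
                 seed: int = 0, n_starts: int | None = None,
                 n_polish: int = 8) -> np.ndarray:
    """Next point to evaluate: argmin of the lower confidence bound."""
    if n_starts is None:
        n_starts = 20 * space.dimension
    x, _ = minimize_surface(lambda X: model.acquisition(X, kappa), space,
                            seed=seed, n_starts=n_starts, n_polish=n_polish)
    return x
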