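"""Bayesian-optimization structure search over reduced coordinates.

The loop follows the active-learning recipe: evaluate a handful of seeded
low-discrepancy initial points, then iterate {fit GP, minimise the
acquisition, realize the proposed structure, evaluate the backend, transform
the energy, augment by the surface symmetry group}.  The run terminates when
the predicted global-minimum location has not moved for ``stall_limit``
consecutive iterations (100 in the production setting) or at the iteration
budget.  Afterwards the surrogate is traversed for local minima, which are
deduplicated with the Kabsch algorithm and handed to local relaxation.

A force-seeking variant swaps the objective for the negative largest force
component, harvesting high-force configurations that enrich interatomic-
potential training data.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .coordinates import (SearchSpace, realize_adsorption, realize_conformer,
                          RingClosureError)
from .energy import Calculator, TransformSettings, transform_energy
from .gp import GPModel, fit_hyperparameters, minimize_surface, propose_next
from .structures import Structure, min_interatomic_distance

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class Observation:
    """One evaluated (or symmetry-copied) point of the search."""

    x: np.ndarray
    e_raw: float
    e_transformed: float
    provenance: str = "sampled"       # sampled | augmented | capped
    max_force: float | None = None
    min_dist: float | None = None
    structure: Structure | None = None
    forces: np.ndarray | None = None


@dataclass
class LocalMinimum:
    """A harvested surrogate minimum, later filled in by relaxation."""

    x: np.ndarray
    predicted_energy: float
    realized: Structure | None = None
    relaxed: Structure | None = None
    relaxed_energy: float | None = None
    rmsd: float | None = None
    n_steps: int | None = None
    rank: int | None = None


@dataclass
class SearchResult:
    space: SearchSpace
    observations: list[Observation]
    model: GPModel
    minima: list[LocalMinimum]
    history: list[np.ndarray]
    termination: str

    @property
    def dataset(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([o.x for o in self.observations])
        y = np.array([o.e_transformed for o in self.observations])
        return X, y


@dataclass
class BOSettings:
    """Loop controls: 5 initial points and the 100-iteration stall rule by default."""

    n_init: int = 5
    max_iter: int = 100
    stall_limit: int = 100
    kappa: float = 2.0
    seed: int = 0
    refit_interval: int = 5
    n_restarts: int = 2
    fixed_noise: float | None = 1e-6
    stall_tol: float = 1e-2   # fraction of each dimension's range
    n_polish: int = 8
    augment: bool = True
    # every explore_interval-th iteration proposes the maximum-uncertainty
    # point instead of the LCB minimiser, so the surrogate maps the whole
    # landscape (all local minima) rather than only the incumbent basin
    explore_interval: int = 3


# ---------------------------------------------------------------------------
# Problems: how a reduced vector becomes a structure and an energy
# ---------------------------------------------------------------------------

class Problem:
    """Realization + evaluation of reduced vectors for one search mode."""

    space: SearchSpace
    transform: TransformSettings = TransformSettings()

    def realize(self, x: np.ndarray) -> Structure | None:
        raise NotImplementedError

    def evaluate(self, x: np.ndarray) -> Observation:
        raise NotImplementedError

    def augment(self, obs: Observation) -> list[Observation]:
        return []


class FunctionProblem(Problem):
    """A plain vector objective (used by toy landscapes and tests)."""

    def __init__(self, space: SearchSpace, fn,
                 transform: TransformSettings = TransformSettings(),
                 apply_transform: bool = True):
        self.space = space
        self.fn = fn
        self.transform = transform
        self.apply_transform = apply_transform

    def realize(self, x):
        return None

    def evaluate(self, x):
        x = self.space.wrap(np.asarray(x, float))
        e = float(self.fn(x[None, :])[0])
        et = transform_energy(e, np.inf, self.transform) if self.apply_transform else e
        return Observation(x, e, et)


class _CalculatorProblem(Problem):
    """Shared evaluate(): contact check, backend call, energy transform."""

    calculator: Calculator

    def evaluate(self, x):
        x = self.space.wrap(np.asarray(x, float))
        try:
            s = self.realize(x)
        except RingClosureError:
            return Observation(x, self.transform.cap_energy,
                               self.transform.cap_energy, "capped")
        dmin = min_interatomic_distance(s)
        if dmin < self.transform.contact_cutoff:
            return Observation(x, self.transform.cap_energy,
                               self.transform.cap_energy, "capped",
                               min_dist=dmin, structure=s)
        try:
            e, f = self.calculator.evaluate(s)
        except Exception:
            return Observation(x, self.transform.cap_energy,
                               self.transform.cap_energy, "capped",
                               min_dist=dmin, structure=s)
        e_rel = e - self.calculator.reference_energy
        et = transform_energy(e_rel, dmin, self.transform)
        free = ~s.frozen
        fmax = float(np.abs(f[free]).max()) if free.any() else 0.0
        return Observation(x, e_rel, et, "sampled", fmax, dmin, s, f)


class ConformerProblem(_CalculatorProblem):
    """Torsional conformer search of an isolated molecule."""

    def __init__(self, space: SearchSpace, template: Structure,
                 calculator: Calculator,
                 transform: TransformSettings = TransformSettings()):
        self.space = space
        self.template = template
        self.calculator = calculator
        self.transform = transform

    def realize(self, x):
        return realize_conformer(self.template, self.space, x)


class AdsorptionProblem(_CalculatorProblem):
    """Rigid-body placement of a conformer over a slab, with symmetry images."""

    def __init__(self, space: SearchSpace, conformer: Structure, slab: Structure,
                 calculator: Calculator, surface_cell: tuple[float, float],
                 transform: TransformSettings = TransformSettings(),
                 augment_enabled: bool = True):
        self.space = space
        self.conformer = conformer
        self.slab = slab
        self.calculator = calculator
        self.surface_cell = surface_cell
        self.transform = transform
        self.augment_enabled = augment_enabled

    def realize(self, x):
        return realize_adsorption(self.conformer, self.slab, x)

    def augment(self, obs):
        if not self.augment_enabled or obs.provenance != "sampled":
            return []
        return augment_symmetry(obs, self.space, *self.surface_cell)


# ---------------------------------------------------------------------------
# Symmetry augmentation
# ---------------------------------------------------------------------------

def augment_symmetry(obs: Observation, space: SearchSpace, a: float, b: float,
                     tol: float = 1e-6) -> list[Observation]:
    """Symmetry images of a 6-D rigid-body observation (free of charge).

    The image group is {identity, translation by (a/2, b/2)} x {C3^0, C3^1,
    C3^2 about the surface normal through the cell origin} — six operations;
    the identity is the source itself, so a general-position point gains five
    augmented copies.  A C3 rotation about the lab z axis maps the lateral
    center by the rotation and composes into the first intrinsic z-y-z Euler
    angle.  Coincident images (within ``tol`` of an earlier one, periodic
    wrapping honoured) are dropped.
    """
    x = np.asarray(obs.x, float)
    if x.shape[0] != 6:
        raise ValueError("symmetry augmentation applies to 6-D rigid-body points")
    images = [x]
    out = []
    for shift in (False, True):
        for j in (0, 1, 2):
            if not shift and j == 0:
                continue  # identity
            xi = x.copy()
            th = j * TWO_PI / 3.0
            ct, st = np.cos(th), np.sin(th)
            tx, ty = xi[0], xi[1]
            xi[0] = ct * tx - st * ty
            xi[1] = st * tx + ct * ty
            xi[3] = xi[3] + th
            if shift:
                xi[0] += a / 2.0
                xi[1] += b / 2.0
            xi = space.wrap(xi)
            if any(np.all(space.distance(xi, prev) < tol) for prev in images):
                continue
            images.append(xi)
            out.append(Observation(xi, obs.e_raw, obs.e_transformed, "augmented",
                                   obs.max_force, obs.min_dist))
    return out


# ---------------------------------------------------------------------------
# Kabsch RMSD and deduplication
# ---------------------------------------------------------------------------

def kabsch_rmsd(A: Structure, B: Structure) -> float:
    """Minimum RMSD over optimal proper rotation + translation."""
    if len(A) != len(B) or A.composition() != B.composition():
        raise ValueError("structures must share atom count and composition")
    P = A.positions - A.positions.mean(axis=0)
    Q = B.positions - B.positions.mean(axis=0)
    _, rssd = Rotation.align_vectors(P, Q)
    return float(rssd / np.sqrt(len(A)))


def deduplicate(minima: list[LocalMinimum], threshold: float = 0.3,
                key=None) -> list[LocalMinimum]:
    """Greedy pass in predicted-energy order; near-duplicates are dropped.

    ``key(minimum) -> Structure`` selects what the Kabsch comparison sees
    (default: the realized structure).  A minimum without a comparable
    structure is always kept.
    """
    if key is None:
        key = lambda m: m.realized
    ordered = sorted(minima, key=lambda m: m.predicted_energy)
    kept: list[LocalMinimum] = []
    for m in ordered:
        sm = key(m)
        dup = False
        for k in kept:
            sk = key(k)
            if sm is not None and sk is not None and kabsch_rmsd(sm, sk) < threshold:
                dup = True
                break
        if not dup:
            kept.append(m)
    for rank, m in enumerate(kept):
        m.rank = rank
    return kept


# ---------------------------------------------------------------------------
# The BO loop
# ---------------------------------------------------------------------------

def _objective_value(obs: Observation, mode: str) -> float:
    if mode == "energy":
        return obs.e_transformed
    # force-seeking: minimise the negative largest force component; capped
    # points carry no forces and sit at the worst value, 0
    return -obs.max_force if obs.max_force is not None else 0.0


def run_search(problem: Problem, settings: BOSettings = BOSettings(), *,
               objective: str = "energy") -> SearchResult:
    """Run the Bayesian-optimization loop; reproducible for a given seed."""
    space = problem.space
    D = space.dimension
    rng = np.random.default_rng(settings.seed)
    iter_seeds = rng.integers(2 ** 31 - 1, size=3 * (settings.max_iter + 2))
    seed_iter = iter(int(v) for v in iter_seeds)

    from scipy.stats import qmc
    sampler = qmc.Halton(d=D, scramble=True, seed=next(seed_iter))
    X0 = space.lower + sampler.random(settings.n_init) * space.span

    observations: list[Observation] = []
    for x0 in X0:
        obs = problem.evaluate(x0)
        observations.append(obs)
        observations.extend(problem.augment(obs) if settings.augment else [])

    history: list[np.ndarray] = []
    model: GPModel | None = None
    stall = 0
    termination = "max_iter"
    tol = settings.stall_tol * space.span

    for it in range(settings.max_iter):
        X = np.array([o.x for o in observations])
        y = np.array([_objective_value(o, objective) for o in observations])
        fit_seed = next(seed_iter)
        if model is None or it % settings.refit_interval == 0:
            model = fit_hyperparameters(space, X, y, seed=fit_seed,
                                        n_restarts=settings.n_restarts,
                                        fixed_noise=settings.fixed_noise)
        else:
            model = model.with_data(X, y)

        xmin, _ = minimize_surface(lambda Q: model.posterior(Q)[0], space,
                                   seed=next(seed_iter), n_starts=20 * D,
                                   n_polish=max(4, settings.n_polish // 2))
        if history and np.all(space.distance(xmin, history[-1]) < tol):
            stall += 1
        else:
            stall = 0
        history.append(xmin)
        if stall >= settings.stall_limit:
            termination = "stalled"
            break

        if settings.explore_interval and (it + 1) % settings.explore_interval == 0:
            x_next, _ = minimize_surface(lambda Q: -model.posterior(Q)[1], space,
                                         seed=next(seed_iter), n_starts=20 * D,
                                         n_polish=settings.n_polish)
        else:
            x_next = propose_next(model, space, settings.kappa, seed=next(seed_iter),
                                  n_polish=settings.n_polish)
        obs = problem.evaluate(x_next)
        observations.append(obs)
        observations.extend(problem.augment(obs) if settings.augment else [])

    X = np.array([o.x for o in observations])
    y = np.array([_objective_value(o, objective) for o in observations])
    model = fit_hyperparameters(space, X, y, seed=next(seed_iter),
                                n_restarts=settings.n_restarts,
                                fixed_noise=settings.fixed_noise)
    return SearchResult(space, observations, model, [], history, termination)


def run_force_seeking(problem: Problem,
                      settings: BOSettings = BOSettings()) -> SearchResult:
    """BO with objective = negative largest force component (data curation)."""
    return run_search(problem, settings, objective="force")


# ---------------------------------------------------------------------------
# Harvesting surrogate minima
# ---------------------------------------------------------------------------

def harvest_minima(model: GPModel, space: SearchSpace, *, seed: int = 0,
                   n_starts: int | None = None, n_polish: int = 40,
                   cluster_tol: float = 0.05, problem: Problem | None = None
                   ) -> list[LocalMinimum]:
    """Traverse the surrogate for local minima of the posterior mean.

    Polished minimisation endpoints are clustered (points within
    ``cluster_tol`` of each other's range per dimension merge); one
    representative per cluster is returned, sorted by predicted energy and
    realized as a structure when a problem is supplied.
    """
    if n_starts is None:
        n_starts = 100 * space.dimension
    xs, fs = minimize_surface(lambda Q: model.posterior(Q)[0], space,
                              seed=seed, n_starts=n_starts,
                              n_polish=n_polish, return_all=True)
    tol = cluster_tol * space.span
    order = np.argsort(fs)
    reps: list[LocalMinimum] = []
    for i in order:
        if any(np.all(space.distance(xs[i], r.x) < tol) for r in reps):
            continue
        reps.append(LocalMinimum(xs[i], float(fs[i])))
    if problem is not None:
        for m in reps:
            try:
                m.realized = problem.realize(m.x)
            except RingClosureError:
                m.realized = None
    for rank, m in enumerate(reps):
        m.rank = rank
    return reps
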