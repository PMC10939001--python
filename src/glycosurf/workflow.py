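"""End-to-end two-pass workflow: search, curate, train, search again.

This driver wires the whole pipeline together for the packaged toy system
(by default a rigid diol over a small Cu(111) slab patch with the pairwise
empirical backend):

1. first-pass Bayesian-optimization adsorption search on the toy backend,
   with surface-symmetry augmentation;
2. harvest + Kabsch deduplication of surrogate minima, local relaxation of
   the best candidates (their trajectories enrich the training set, just as
   production relaxations feed interatomic-potential training);
3. training of the lightweight surrogate potential on all sampled frames;
4. second-pass search with the learned potential as the backend.

``toy_global_minimum`` establishes the toy backend's own rigid global
minimum by brute force (low-discrepancy scan + local descent), independent
of any surrogate machinery, for use as an oracle.

Symmetry-aware structure comparison uses the toy backend's exact in-plane
symmetry group — the 3-fold rotation about the atop axis times the
half-cell translation, the same group the data augmentation applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .coordinates import SearchSpace, adsorption_space, realize_adsorption
from .energy import ToyIntramolecular, ToySurface, SurfaceParams
from .fixtures import make_sugar
from .mlip import SurrogatePotentialModel, SurrogateCalculator, train
from .relaxation import relax
from .search import (AdsorptionProblem, BOSettings, LocalMinimum, SearchResult,
                     deduplicate, harvest_minima, kabsch_rmsd, run_search,
                     run_force_seeking)
from .structures import (SlabSpec, Structure, build_slab,
                         surface_cell_dimensions)

TWO_PI = 2.0 * np.pi


@dataclass
class ToySystem:
    """A packaged desk-scale adsorption system (small molecule on a slab patch)."""

    conformer: Structure
    slab: Structure
    calculator: ToySurface
    space: SearchSpace
    surface_cell: tuple[float, float]
    lattice_constant: float

    def problem(self, calculator=None, augment: bool = True) -> AdsorptionProblem:
        return AdsorptionProblem(self.space, self.conformer, self.slab,
                                 calculator or self.calculator,
                                 self.surface_cell, augment_enabled=augment)

    def symmetry_images(self, x: np.ndarray) -> list[np.ndarray]:
        """All rigid-body vectors equivalent to x under the toy's symmetry.

        C3 rotations about the atop axis times the half-cell translation:
        6 operations including the identity.
        """
        a, b = self.surface_cell
        out = []
        for j in range(3):
            th = j * TWO_PI / 3.0
            ct, st = np.cos(th), np.sin(th)
            for shift in (False, True):
                xi = np.array(x, float)
                xi[0], xi[1] = ct * xi[0] - st * xi[1], st * xi[0] + ct * xi[1]
                xi[3] += th
                if shift:
                    xi[0] += a / 2.0
                    xi[1] += b / 2.0
                out.append(self.space.wrap(xi))
        return out

    def min_symmetry_rmsd(self, x1: np.ndarray, x2: np.ndarray) -> float:
        """Kabsch RMSD between two placements, minimised over symmetry images."""
        ref = realize_adsorption(self.conformer, self.slab, x2)
        return min(kabsch_rmsd(realize_adsorption(self.conformer, self.slab, xi),
                               ref)
                   for xi in self.symmetry_images(x1))


def make_toy_system(*, lattice_constant: float = 3.632, nx: int = 4, ny: int = 4,
                    n_layers: int = 2, z_range: tuple[float, float] = (2.0, 7.0),
                    adsorbate: str = "diol",
                    params: SurfaceParams = SurfaceParams()) -> ToySystem:
    """Assemble the toy adsorption system used by tests and demos.

    The slab is a 4x4x2 patch (the search cell itself is one orthogonal
    surface cell, so a small periodic slab suffices for the pairwise toy
    backend); the z bounds are the production 3-12 A window rescaled to
    2-7 A to match the toy pair potential, whose equilibrium pair distance
    (2.3 A) sits lower than a real molecule-metal contact and whose
    interaction is negligible beyond ~5 A.  The default adsorbate is the
    rigid two-anchor diol, small enough for searches to converge reliably
    at desk budgets; any packaged sugar template can be substituted.
    """
    conformer, _ = make_sugar(adsorbate)
    slab = build_slab(SlabSpec(lattice_constant, nx, ny, n_layers, 60.0, 1))
    a, b = surface_cell_dimensions(lattice_constant)
    intra = ToyIntramolecular(conformer)
    calc = ToySurface(slab, intra, lattice_constant, params)
    calc.set_reference(conformer)
    space = adsorption_space(a, b, *z_range)
    return ToySystem(conformer, slab, calc, space, (a, b), lattice_constant)


def toy_global_minimum(system: ToySystem, *, seed: int = 0, n_scan: int = 3000,
                       n_polish: int = 40) -> tuple[np.ndarray, float]:
    """Rigid global minimum of the toy backend by scan + descent (oracle)."""
    from scipy.stats import qmc
    space = system.space

    def f(x):
        s = realize_adsorption(system.conformer, system.slab, space.wrap(np.asarray(x)))
        return system.calculator.evaluate(s)[0] - system.calculator.reference_energy

    sampler = qmc.Halton(d=space.dimension, scramble=True, seed=seed)
    cand = space.lower + sampler.random(n_scan) * space.span
    vals = np.array([f(x) for x in cand])
    best_x, best_f = None, np.inf
    for i in np.argsort(vals)[:n_polish]:
        r = minimize(f, cand[i], method="Nelder-Mead",
                     options={"maxfev": 1500, "xatol": 1e-5, "fatol": 1e-9})
        if r.fun < best_f:
            best_f, best_x = r.fun, space.wrap(r.x)
    return best_x, float(best_f)


@dataclass
class TwoPassResult:
    first: SearchResult
    first_minima: list[LocalMinimum]
    potential: SurrogatePotentialModel
    second: SearchResult
    second_minima: list[LocalMinimum]
    n_training_frames: int
    # engine-validated results: each pass's top candidates relaxed
    # (rigid-body) on the toy backend, best by validated energy.  The
    # first-pass value is the desk analogue of "the global minimum the
    # expensive-engine search found"; the second-pass value is what the
    # learned-potential search found, validated the same way.
    first_validated_x: np.ndarray | None = None
    first_validated_energy: float | None = None
    validated_x: np.ndarray | None = None
    validated_energy: float | None = None


def _rigid_polish(system: ToySystem, calc, x0: np.ndarray) -> tuple[np.ndarray, float]:
    """Descend the backend energy in the 6 rigid-body coordinates."""
    space = system.space

    def f(x):
        s = realize_adsorption(system.conformer, system.slab,
                               space.wrap(np.asarray(x)))
        return calc.evaluate(s)[0] - calc.reference_energy

    r = minimize(f, np.asarray(x0, float), method="Nelder-Mead",
                 options={"maxfev": 1200, "xatol": 1e-5, "fatol": 1e-9})
    return space.wrap(r.x), float(r.fun)


def _scan_candidates(system: ToySystem, calc, *, seed: int, n_scan: int = 4000,
                     n_polish: int = 30) -> list[LocalMinimum]:
    """Low-discrepancy scan + rigid descent on a cheap backend."""
    from scipy.stats import qmc
    space = system.space

    def f(x):
        s = realize_adsorption(system.conformer, system.slab,
                               space.wrap(np.asarray(x)))
        return calc.evaluate(s)[0] - calc.reference_energy

    sampler = qmc.Halton(d=space.dimension, scramble=True, seed=seed)
    cand = space.lower + sampler.random(n_scan) * space.span
    vals = np.array([f(x) for x in cand])
    out = []
    for i in np.argsort(vals)[:n_polish]:
        xv, ev = _rigid_polish(system, calc, cand[i])
        out.append(LocalMinimum(
            xv, ev, realized=realize_adsorption(system.conformer, system.slab,
                                                xv)))
    return out


def run_two_pass(system: ToySystem, *, seed: int = 0,
                 first_iters: int = 100, second_iters: int = 100,
                 force_seeking_iters: int = 40, n_relax: int = 4,
                 n_refine: int = 8, n_validate: int = 18,
                 dedup_threshold: float = 0.3,
                 settings: BOSettings | None = None) -> TwoPassResult:
    """First-pass toy search -> curated surrogate potential -> second pass.

    Training data combines the first-pass frames, relaxation trajectories of
    the best deduplicated minima, and a force-seeking run that harvests
    high-force configurations (guarding the learned potential against
    spurious extrapolation minima).  Second-pass surrogate minima are
    refined by rigid-body descent on the learned potential, deduplicated,
    and the top ``n_validate`` candidates are then relaxed on the *toy*
    backend and re-ranked by its energies — the analogue of relaxing every
    predicted minimum with the expensive engine before declaring a global
    minimum, which is how the production workflow resolves candidates that
    the learned potential cannot separate.
    """
    st1 = settings or BOSettings(seed=seed, max_iter=first_iters, stall_limit=100)
    prob1 = system.problem()
    res1 = run_search(prob1, st1)
    mins1 = deduplicate(
        harvest_minima(res1.model, system.space, seed=seed + 1, problem=prob1,
                       n_polish=30),
        dedup_threshold)

    frames = [(o.structure, o.e_raw, o.forces) for o in res1.observations
              if o.provenance == "sampled" and o.forces is not None]
    for m in mins1[:n_relax]:
        traj: list = []
        r = relax(m.realized, system.calculator, fmax=0.01, max_steps=400,
                  trajectory=traj)
        m.relaxed, m.relaxed_energy, m.n_steps = r.structure, r.energy, r.n_steps
        m.rmsd = kabsch_rmsd(m.realized, r.structure)
        for s_, e_, f_ in traj[::5]:
            frames.append((s_, e_ - system.calculator.reference_energy, f_))

    if force_seeking_iters:
        fs_settings = BOSettings(seed=seed + 3, max_iter=force_seeking_iters,
                                 stall_limit=100)
        res_fs = run_force_seeking(system.problem(), fs_settings)
        frames += [(o.structure, o.e_raw, o.forces) for o in res_fs.observations
                   if o.provenance == "sampled" and o.forces is not None]

    potential = train(frames, seed=seed)
    mlip = SurrogateCalculator(potential)
    far = realize_adsorption(system.conformer, system.slab,
                             [0.0, 0.0, system.space.upper[2] - 0.1, 0, 0, 0])
    mlip.reference_energy = mlip.evaluate(far)[0]

    st2 = BOSettings(seed=seed + 7, max_iter=second_iters, stall_limit=100)
    prob2 = system.problem(calculator=mlip)
    res2 = run_search(prob2, st2)
    mins2 = harvest_minima(res2.model, system.space, seed=seed + 8,
                           problem=prob2, n_polish=30)
    for m in mins2[:n_refine]:
        m.x, m.predicted_energy = _rigid_polish(system, mlip, m.x)
        m.realized = realize_adsorption(system.conformer, system.slab, m.x)
    # the learned potential is cheap enough to scan exhaustively — the very
    # capability the second pass exists to exploit.  Direct low-discrepancy
    # scan + descent on the potential supplies candidates the GP-smoothed
    # harvest can miss.
    mins2 += _scan_candidates(system, mlip, seed=seed + 9)
    mins2 = deduplicate(mins2, dedup_threshold)

    def validate(minima, result):
        """Relax each candidate on the toy backend; best validated energy wins.

        Candidates are the deduplicated surrogate minima plus the
        lowest-energy sampled observations of the pass (a practitioner
        would send both to the engine).
        """
        best_x, best_e = None, np.inf
        for m in minima[:n_validate]:
            xv, ev = _rigid_polish(system, system.calculator, m.x)
            m.relaxed = realize_adsorption(system.conformer, system.slab, xv)
            m.relaxed_energy = ev
            m.rmsd = kabsch_rmsd(m.realized, m.relaxed)
            if ev < best_e:
                best_x, best_e = xv, ev
        sampled = sorted((o for o in result.observations
                          if o.provenance == "sampled"),
                         key=lambda o: o.e_transformed)
        for o in sampled[:n_validate // 2]:
            xv, ev = _rigid_polish(system, system.calculator, o.x)
            if ev < best_e:
                best_x, best_e = xv, ev
        return best_x, best_e

    x1, e1 = validate(mins1, res1)
    x2, e2 = validate(mins2, res2)
    return TwoPassResult(res1, mins1, potential, res2, mins2, len(frames),
                         x1, e1, x2, e2)
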