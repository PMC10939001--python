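"""Local geometry relaxation with a damped quasi-Newton (BFGS) descent.

Frozen atoms (the bottom slab layers, plus every substrate atom when
``fix_substrate`` is set) are excluded from the optimisation variables and
move exactly 0.  Steps are capped at 0.2 A per atom and backtracked until the
energy does not increase, so the energy trace is monotonically
non-increasing.  Convergence is reached when the largest unfrozen force
component drops below ``fmax`` (0.01 eV/A by default, matching a tight
surface-science force threshold; 0.03 is a common slightly relaxed choice
for surrogate-potential relaxations).  The reported step count is the number
of force evaluations after the first, which is 0 for an already-relaxed
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import Calculator
from .structures import SUBSTRATE, Structure


@dataclass
class RelaxResult:
    structure: Structure
    energy: float
    n_steps: int
    converged: bool
    forces: np.ndarray


def relax(s: Structure, calc: Calculator, *, fmax: float = 0.01,
          max_steps: int = 500, fix_substrate: bool = False,
          max_step_length: float = 0.2,
          trajectory: list | None = None) -> RelaxResult:
    """Relax a structure until the largest unfrozen force component < fmax.

    Returns the relaxed structure, its energy, the number of additional
    force evaluations, and a convergence flag (non-convergence yields the
    best partial result, flagged).  If ``trajectory`` is a list, each
    accepted frame is appended as ``(structure, energy, forces)``.
    """
    s = s.copy()
    free = ~s.frozen
    if fix_substrate:
        free &= np.array([t != SUBSTRATE for t in s.tags])
    idx = np.flatnonzero(free)
    if idx.size == 0:
        e, f = calc.evaluate(s)
        return RelaxResult(s, e, 0, True, f)

    def unfrozen_fmax(forces):
        return float(np.abs(forces[idx]).max())

    energy, forces = calc.evaluate(s)
    n_eval = 1
    if trajectory is not None:
        trajectory.append((s.copy(), energy, forces.copy()))
    m = idx.size * 3
    H = np.eye(m) / 70.0  # initial inverse Hessian (eV/A^2)^-1, stiff guess
    g = -forces[idx].ravel()
    converged = unfrozen_fmax(forces) < fmax
    scaled = False

    while not converged and (n_eval - 1) < max_steps:
        p = -H @ g
        # cap the displacement of every atom at max_step_length
        steps = np.linalg.norm(p.reshape(-1, 3), axis=1)
        longest = steps.max()
        if longest > max_step_length:
            p *= max_step_length / longest
        accepted = False
        for _ in range(10):
            trial = s.copy()
            trial.positions[idx] += p.reshape(-1, 3)
            e_new, f_new = calc.evaluate(trial)
            n_eval += 1
            if e_new <= energy + 1e-12:
                accepted = True
                break
            p *= 0.5
            if (n_eval - 1) >= max_steps:
                break
        if not accepted:
            break
        g_new = -f_new[idx].ravel()
        sv = p
        yv = g_new - g
        sy = sv @ yv
        if sy > 1e-10 and not scaled:
            # standard first-update curvature scaling of the inverse Hessian
            H = np.eye(m) * (sy / (yv @ yv))
            scaled = True
        if sy > 1e-10:
            rho = 1.0 / sy
            I = np.eye(m)
            V = I - rho * np.outer(sv, yv)
            H = V @ H @ V.T + rho * np.outer(sv, sv)
        else:
            # negative curvature along the step: BFGS update is invalid.
            # Reset to a steepest-descent scale bold enough to traverse the
            # concave region (backtracking guards against overshoot).
            gmax = np.abs(g_new.reshape(-1, 3)).max()
            if gmax > 0:
                H = np.eye(m) * (max_step_length / gmax)
                scaled = False
        s, energy, forces, g = trial, e_new, f_new, g_new
        if trajectory is not None:
            trajectory.append((s.copy(), energy, forces.copy()))
        converged = unfrozen_fmax(forces) < fmax

    return RelaxResult(s, energy, n_eval - 1, converged, forces)
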