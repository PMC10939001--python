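"""Energy backends and the low-energy-focused energy transformation.

All backends satisfy a single calculator contract: ``evaluate(structure) ->
(energy_eV, forces_eV_per_A)`` plus a ``reference_energy`` (the energy of the
relaxed isolated building blocks at infinite separation, so that relative
energies have a stable zero across a search).  The production engine behind
this contract would be a DFT code or a trained interatomic potential; the
packaged backends are deliberately simple empirical models (Lennard-Jones +
directional hydrogen bond intramolecular term; corrugated Morse
molecule-surface term) that reproduce the *qualitative* features the search
workflow relies on — multiple minima, a Pauli wall at short contact, exact
surface symmetry — at desk-scale cost.

The energy transformation keeps the Gaussian-process surrogate focused on the
low-energy region: configurations with any interatomic contact below 0.5 A
are not evaluated at all and are assigned a flat 5.0 eV placeholder, and
relative energies above 1.0 eV are compressed to ``1 + ln(E)`` eV.  The
transform is continuous at 1.0 eV and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .structures import (ADSORBATE, Structure, detect_bonds,
                         mic_displacements, surface_cell_dimensions,
                         top_layer_z)


# ---------------------------------------------------------------------------
# Contract and transform
# ---------------------------------------------------------------------------

class Calculator:
    """Calculator contract: deterministic energies and forces for a structure."""

    reference_energy: float = 0.0

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        raise NotImplementedError


@dataclass(frozen=True)
class TransformSettings:
    """Contact cutoff (A), placeholder cap (eV) and log-tail threshold (eV)."""

    contact_cutoff: float = 0.5
    cap_energy: float = 5.0
    tail_threshold: float = 1.0

    def __post_init__(self) -> None:
        if min(self.contact_cutoff, self.cap_energy, self.tail_threshold) <= 0:
            raise ValueError("all transform settings must be positive")
        if self.cap_energy <= self.tail_threshold:
            raise ValueError("cap_energy must exceed tail_threshold")


def transform_energy(e_rel: float, min_dist: float,
                     s: TransformSettings = TransformSettings()) -> float:
    """Transformed objective for GP fitting.

    Below the contact cutoff the backend is skipped and the cap (5.0 eV)
    returned; relative energies above the 1.0 eV threshold are compressed to
    ``1 + ln(E)`` (natural log, which makes the transform continuous at the
    threshold); lower energies pass through unchanged.
    """
    if min_dist < s.contact_cutoff:
        return s.cap_energy
    if e_rel <= s.tail_threshold:
        return float(e_rel)
    return float(s.tail_threshold + np.log(e_rel / s.tail_threshold))


# ---------------------------------------------------------------------------
# Toy intramolecular backend
# ---------------------------------------------------------------------------

# Per-element Lennard-Jones parameters (eV, Angstrom).
LJ_EPS = {"H": 0.0030, "C": 0.0048, "O": 0.0070}
LJ_SIGMA = {"H": 2.40, "C": 3.40, "O": 3.00}


class ToyIntramolecular(Calculator):
    """Empirical conformational energy of an isolated molecule.

    Nonbonded Lennard-Jones terms act between atom pairs four or more bonds
    apart (Lorentz-Berthelot mixing of per-element parameters) and a
    directional well rewards near-linear O-H...O hydrogen bonds.  Forces are
    analytic; the energy is exactly invariant under rigid motion.

    Topology (bond graph, hence the pair list and the donor/acceptor list)
    is fixed at construction from a reference geometry of the same molecule,
    so torsional scans do not change the interaction lists.
    """

    def __init__(self, reference: Structure, *, hb_eps: float = 0.20,
                 hb_r0: float = 1.90, hb_width: float = 0.30,
                 min_separation: int = 4):
        self.n_atoms = len(reference)
        self.symbols = list(reference.symbols)
        self.hb_eps = hb_eps
        self.hb_r0 = hb_r0
        self.hb_width = hb_width
        bonds = detect_bonds(reference)
        n = self.n_atoms
        if bonds:
            rows = [b[0] for b in bonds] + [b[1] for b in bonds]
            cols = [b[1] for b in bonds] + [b[0] for b in bonds]
            graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
            dist = shortest_path(graph, method="D", unweighted=True)
        else:
            dist = np.full((n, n), np.inf)
            np.fill_diagonal(dist, 0.0)
        self._graph_dist = dist

        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] >= min_separation:
                    eps = np.sqrt(LJ_EPS[self.symbols[i]] * LJ_EPS[self.symbols[j]])
                    sig = 0.5 * (LJ_SIGMA[self.symbols[i]] + LJ_SIGMA[self.symbols[j]])
                    pairs.append((i, j, eps, sig))
        self._pairs = pairs

        # hydrogen-bond triples: O-H donors x O acceptors >= min_separation
        # bonds from the H (excludes the donor oxygen's own neighbourhood)
        donors = [(i, j) for (i, j) in bonds
                  if {self.symbols[i], self.symbols[j]} == {"O", "H"}]
        donors = [(i, j) if self.symbols[i] == "O" else (j, i) for (i, j) in donors]
        triples = []
        for d_o, d_h in donors:
            for a in range(n):
                if self.symbols[a] != "O" or a == d_o:
                    continue
                if dist[d_h, a] >= min_separation:
                    triples.append((d_o, d_h, a))
        self._triples = triples

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        pos = s.positions
        if len(s) != self.n_atoms:
            raise ValueError("structure does not match the reference topology")
        energy = 0.0
        forces = np.zeros_like(pos)
        for i, j, eps, sig in self._pairs:
            d = pos[i] - pos[j]
            r2 = float(d @ d)
            r = np.sqrt(r2)
            sr6 = (sig * sig / r2) ** 3
            energy += 4.0 * eps * (sr6 * sr6 - sr6)
            # dE/dr = 4 eps (-12 sr12 + 6 sr6)/r
            dedr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            f = -dedr * d / r
            forces[i] += f
            forces[j] -= f
        for d_o, d_h, a in self._triples:
            e, g_o, g_h, g_a = self._hbond(pos[d_o], pos[d_h], pos[a])
            energy += e
            forces[d_o] -= g_o
            forces[d_h] -= g_h
            forces[a] -= g_a
        return energy, forces

    def _hbond(self, p_o, p_h, p_a):
        """Directional well E = -eps * cos^2(phi) * gauss(r) for phi > 90 deg.

        phi is the O-H...A angle at the hydrogen, r the H...A distance.
        Returns the energy and its gradients w.r.t. the three positions.
        """
        u = p_o - p_h
        v = p_a - p_h
        nu = np.linalg.norm(u)
        nv = np.linalg.norm(v)
        c = float(u @ v) / (nu * nv)
        zeros = np.zeros(3)
        if c >= 0.0:
            return 0.0, zeros, zeros, zeros
        r = nv
        f = np.exp(-((r - self.hb_r0) ** 2) / (2.0 * self.hb_width ** 2))
        g = c * c
        e = -self.hb_eps * g * f
        # gradients
        dc_du = v / (nu * nv) - c * u / (nu * nu)
        dc_dv = u / (nu * nv) - c * v / (nv * nv)
        df_dr = f * (-(r - self.hb_r0) / self.hb_width ** 2)
        dr_dv = v / nv
        de_dc = -self.hb_eps * 2.0 * c * f
        de_dv = de_dc * dc_dv + (-self.hb_eps * g) * df_dr * dr_dv
        de_du = de_dc * dc_du
        g_o = de_du
        g_a = de_dv
        g_h = -(de_du + de_dv)
        return e, g_o, g_h, g_a


# ---------------------------------------------------------------------------
# Toy molecule-surface backend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceParams:
    """Pairwise Morse parameters of the toy molecule-surface interaction.

    ``pair_depth`` is the per-element well depth (eV) of one adsorbate-atom /
    substrate-atom Morse pair; an adsorbate atom interacts with all metal
    atoms within ``cutoff`` (minimum image), so the total binding and the
    lateral corrugation emerge from the lattice geometry.  Oxygen binds the
    metal far more strongly than C or H (lone-pair/metal interaction), so
    orientation and adsorption site matter and the global-minimum basin is
    energetically distinct.
    """

    pair_depth: tuple[tuple[str, float], ...] = (
        ("H", 0.010), ("C", 0.050), ("O", 0.150))
    alpha: float = 1.20   # 1/Angstrom
    r0: float = 2.30      # Angstrom, pair equilibrium distance
    cutoff: float = 4.0   # Angstrom; must be < half the shortest cell vector

    def depth_of(self, symbol: str) -> float:
        return dict(self.pair_depth)[symbol]


class ToySurface(Calculator):
    """Adsorbate-surface energy: pairwise Morse to the metal + intramolecular.

    Each adsorbate atom i contributes ``sum_j D_i M(r_ij) S(r_ij)`` over
    substrate atoms j within the cutoff (minimum image), with
    ``M(r) = (1 - exp(-alpha (r - r0)))^2 - 1`` and the C1 switching
    function ``S = (1 - (r/rc)^2)^2``.  Because the interaction depends only
    on interatomic distances to the periodic metal lattice, the half-cell
    translation and the 3-fold rotation about the atop axis through the cell
    origin (where the slab builder places a top-layer atom) are *exact*
    symmetries of this backend — the group used by the data augmentation.
    The corrugation between atop, bridge and hollow sites emerges from the
    neighbour geometry.  Substrate atoms feel no net force (the slab is
    rigid by construction); their reaction forces are dropped.
    """

    def __init__(self, slab: Structure, intra: ToyIntramolecular,
                 lattice_constant: float,
                 params: SurfaceParams = SurfaceParams()):
        self.params = params
        self.intra = intra
        self.top_z = top_layer_z(slab)
        a, b = surface_cell_dimensions(lattice_constant)
        self.surface_cell = (a, b)
        self.reference_energy = 0.0

    def set_reference(self, conformer: Structure) -> None:
        """Fix the zero of relative energy to the isolated conformer energy."""
        e, _ = self.intra.evaluate(conformer)
        self.reference_energy = e

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        ads = np.array([t == ADSORBATE for t in s.tags])
        sub = ~ads
        pos = s.positions
        forces = np.zeros_like(pos)
        idx = np.flatnonzero(ads)
        jdx = np.flatnonzero(sub)
        p = self.params
        energy = 0.0
        if len(idx) > 0 and len(jdx) > 0:
            delta = pos[idx][:, None, :] - pos[jdx][None, :, :]
            delta = mic_displacements(delta, s.cell, s.pbc)
            r = np.sqrt((delta ** 2).sum(axis=-1))
            depths = np.array([p.depth_of(s.symbols[i]) for i in idx])
            within = r < p.cutoff
            ex = np.exp(-p.alpha * (r - p.r0))
            morse = (1.0 - ex) ** 2 - 1.0
            dmorse = 2.0 * p.alpha * (1.0 - ex) * ex
            t2 = (r / p.cutoff) ** 2
            sw = (1.0 - t2) ** 2
            dsw = -4.0 * (1.0 - t2) * r / p.cutoff ** 2
            pair_e = np.where(within, morse * sw, 0.0) * depths[:, None]
            pair_de = np.where(within, dmorse * sw + morse * dsw, 0.0) * depths[:, None]
            energy += float(pair_e.sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[..., None] > 0, delta / r[..., None], 0.0)
            forces[idx] -= (pair_de[..., None] * unit).sum(axis=1)
        if len(idx) > 0:
            mol = s.subset(ads)
            mol.cell = np.zeros((3, 3))
            mol.pbc = np.zeros(3, dtype=bool)
            e_intra, f_intra = self.intra.evaluate(mol)
            energy += e_intra
            forces[idx] += f_intra
        return energy, forces
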