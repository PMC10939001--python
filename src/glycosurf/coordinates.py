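"""Reduced search coordinates and their realization as full structures.

Two kinds of reduced spaces are supported:

* **conformer spaces** — hydroxyl torsions, glycosidic (phi, psi) torsions and
  a reduced two-torsion ring-flip coordinate per pyranose ring.  Realization
  edits a template molecule in place of full Cartesian freedom, leaving every
  bond length untouched.
* **adsorption spaces** — the 6 rigid-body coordinates (tx, ty, tz, alpha,
  beta, gamma) placing a rigid conformer over a slab; tz is the height of the
  adsorbate geometric center above the top substrate layer and the Euler
  convention is intrinsic z-y-z.

Dimensionality accounting follows the sugar searches: 4 hydroxyls + 2 reduced
ring coordinates = 6D for xylose; 10 hydroxyls + 2x3 glycosidic torsions =
16D for xylotetraose; adding the reduced ring flips of all four rings gives
24; the full one-coordinate-per-ring-atom parametrization of xylose gives
4 + 6 = 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure, top_layer_z, assemble

TWO_PI = 2.0 * np.pi

REALIZER_TAGS = (
    "dihedral", "translation_x", "translation_y", "translation_z",
    "euler_alpha", "euler_beta", "euler_gamma", "ringflip_coord",
)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralSpec:
    """A driven torsion i-j-k-l with the set of atoms rotated about j-k."""

    i: int
    j: int
    k: int
    l: int
    kind: str  # hydroxyl | ring | glycosidic
    moving: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = (self.i, self.j, self.k, self.l)
        if len(set(idx)) != 4:
            raise ValueError("dihedral atom indices must be distinct")
        if {self.i, self.j, self.k} & set(self.moving):
            raise ValueError("moving set must exclude i, j, k")


@dataclass(frozen=True)
class RingSpec:
    """A six-membered pyranose ring O5-C1-C2-C3-C4-C5.

    ``atoms`` lists the ring atom indices in that order.  The reduced flip
    coordinates drive the torsions O5-C1-C2-C3 and C3-C4-C5-O5.
    ``substituents[m]`` lists the atom indices of the subtree hanging off
    ring atom ``atoms[m]`` (they ride rigidly on that atom's local frame
    when the ring is rebuilt).
    """

    atoms: tuple[int, ...]
    substituents: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.atoms) != 6:
            raise ValueError("ring must have 6 atoms")


@dataclass
class Variable:
    label: str
    lower: float
    upper: float
    periodic: bool
    tag: str
    # payload: DihedralSpec for dihedral vars, (RingSpec, which) for ring vars
    payload: object | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"variable {self.label}: lower must be < upper")
        if self.tag not in REALIZER_TAGS:
            raise ValueError(f"unknown realizer tag {self.tag}")


@dataclass
class SearchSpace:
    """Ordered, bounded (possibly periodic) variables of a reduced search."""

    variables: list[Variable]

    @property
    def dimension(self) -> int:
        return len(self.variables)

    @property
    def lower(self) -> np.ndarray:
        return np.array([v.lower for v in self.variables])

    @property
    def upper(self) -> np.ndarray:
        return np.array([v.upper for v in self.variables])

    @property
    def periodic(self) -> np.ndarray:
        return np.array([v.periodic for v in self.variables])

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Wrap periodic components into bounds, clip the rest."""
        x = np.array(x, dtype=float)
        lo, span, per = self.lower, self.span, self.periodic
        x[..., per] = lo[per] + np.mod(x[..., per] - lo[per], span[per])
        x[..., ~per] = np.clip(x[..., ~per], lo[~per], self.upper[~per])
        return x

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-dimension separation honouring periodic wrapping."""
        d = np.abs(np.asarray(x, float) - np.asarray(y, float))
        per = self.periodic
        span = self.span
        d[..., per] = np.minimum(d[..., per], span[per] - d[..., per])
        return d


# ---------------------------------------------------------------------------
# Annotations and dimensionality accounting
# ---------------------------------------------------------------------------

@dataclass
class MoleculeAnnotations:
    """Rotatable-bond and ring annotations of a sugar template."""

    hydroxyls: list[DihedralSpec] = field(default_factory=list)
    glycosidic: list[DihedralSpec] = field(default_factory=list)  # phi/psi pairs, flattened
    rings: list[RingSpec] = field(default_factory=list)

    @property
    def n_linkages(self) -> int:
        if len(self.glycosidic) % 2:
            raise ValueError("glycosidic torsions must come in (phi, psi) pairs")
        return len(self.glycosidic) // 2


def count_dimensions(annotations: MoleculeAnnotations, *, hydroxyls: bool = True,
                     glycosidic: bool = False, ring_mode: str = "none") -> int:
    """Dimensionality of a conformer search over the annotated molecule.

    ``D = #OH + 2 * #linkages + {0 | 2 | 6} * #rings`` for ring_mode in
    none / reduced / full.  The full mode assigns one coordinate per ring
    atom (6 for a pyranose).
    """
    if ring_mode not in ("none", "reduced", "full"):
        raise ValueError("ring_mode must be none, reduced or full")
    if annotations is None:
        raise ValueError("molecule annotations required")
    d = 0
    if hydroxyls:
        d += len(annotations.hydroxyls)
    if glycosidic:
        d += 2 * annotations.n_linkages
    if ring_mode == "reduced":
        d += 2 * len(annotations.rings)
    elif ring_mode == "full":
        d += 6 * len(annotations.rings)
    return d


# ---------------------------------------------------------------------------
# Torsion geometry
# ---------------------------------------------------------------------------

def measure_dihedral(pos: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion angle i-j-k-l in radians, IUPAC convention."""
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def set_dihedral(pos: np.ndarray, spec: DihedralSpec, value: float) -> np.ndarray:
    """Rotate ``spec.moving`` about the j-k axis so torsion i-j-k-l = value."""
    pos = pos.copy()
    current = measure_dihedral(pos, spec.i, spec.j, spec.k, spec.l)
    axis = pos[spec.k] - pos[spec.j]
    axis = axis / np.linalg.norm(axis)
    # right-hand rotation of the l-side about j->k decreases the IUPAC
    # torsion, hence the sign
    rot = Rotation.from_rotvec(axis * (current - value))
    idx = list(spec.moving) + [spec.l] if spec.l not in spec.moving else list(spec.moving)
    idx = sorted(set(idx))
    pivot = pos[spec.k]
    pos[idx] = rot.apply(pos[idx] - pivot) + pivot
    return pos


# ---------------------------------------------------------------------------
# Ring rebuilding (reduced two-torsion flip coordinate)
# ---------------------------------------------------------------------------

class RingClosureError(RuntimeError):
    """Raised when the ring cannot be closed for the requested torsions."""


def _nerf_place(p1, p2, p3, bond, angle, torsion):
    """Place the next chain atom from three predecessors (NeRF construction)."""
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # colinear predecessors: pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    # signs chosen so measure_dihedral(p1, p2, p3, p4) == torsion (IUPAC)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.cos(torsion) * np.sin(angle),
        -bond * np.sin(torsion) * np.sin(angle),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _ring_internal(pos: np.ndarray, atoms: tuple[int, ...]):
    """Bond lengths and angles of the 6-ring (cyclic, template values)."""
    a = list(atoms)
    bonds = np.array([np.linalg.norm(pos[a[(m + 1) % 6]] - pos[a[m]]) for m in range(6)])
    angles = np.zeros(6)
    for m in range(6):
        u = pos[a[(m - 1) % 6]] - pos[a[m]]
        v = pos[a[(m + 1) % 6]] - pos[a[m]]
        angles[m] = np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return bonds, angles


def _build_ring_chain(bonds, angles, torsions):
    """Positions of the 6 ring atoms built as an open chain O5,C1,...,C5.

    ``torsions`` = (t1, t2, t3) are the chain torsions (O5,C1,C2,C3),
    (C1,C2,C3,C4), (C2,C3,C4,C5).  Bond m connects atom m to m+1; angle m is
    at atom m.
    """
    p = np.zeros((6, 3))
    p[0] = [0.0, 0.0, 0.0]
    p[1] = [bonds[0], 0.0, 0.0]
    # place atom 2 using angle at atom 1
    ang = angles[1]
    p[2] = p[1] + bonds[1] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for m in (3, 4, 5):
        p[m] = _nerf_place(p[m - 3], p[m - 2], p[m - 1],
                           bonds[m - 1], angles[m - 1], torsions[m - 3])
    return p


def solve_ring(bonds, angles, t1: float, t4: float, guess=( -0.9, 0.9),
               tol: float = 1e-4, max_iter: int = 80):
    """Close the pyranose ring with the two flip torsions fixed.

    ``t1`` is the target torsion (O5,C1,C2,C3) and ``t4`` the target torsion
    (C3,C4,C5,O5).  Free parameters are the two interior chain torsions plus
    small regularised perturbations of the angles at C2, C3 and C4; the
    closure residual is the mismatch between the actual position of O5 and
    the position implied by building it from (C3, C4, C5) with the template
    C5-O5 bond, the C4-C5-O5 angle and torsion ``t4``.  Solved by damped
    Gauss-Newton.  Returns the 6 ring-atom positions.
    """
    u = np.array([guess[0], guess[1], 0.0, 0.0, 0.0])
    reg = 0.05  # penalty weight on angle perturbations (rad -> Angstrom scale)

    def residual(u):
        t2, t3, d2, d3, d4 = u
        ang = angles.copy()
        ang[2] += d2
        ang[3] += d3
        ang[4] += d4
        p = _build_ring_chain(bonds, ang, (t1, t2, t3))
        o5_img = _nerf_place(p[3], p[4], p[5], bonds[5], ang[5], t4)
        r = o5_img - p[0]
        return np.concatenate([r, reg * u[2:]]), p

    lam = 1e-6
    r, p = residual(u)
    for _ in range(max_iter):
        if np.linalg.norm(r[:3]) < tol:
            return p
        J = np.zeros((len(r), 5))
        h = 1e-6
        for c in range(5):
            up = u.copy()
            up[c] += h
            rp, _ = residual(up)
            J[:, c] = (rp - r) / h
        step = np.linalg.solve(J.T @ J + lam * np.eye(5), -J.T @ r)
        accepted = False
        for _ in range(12):
            un = u + step
            rn, pn = residual(un)
            if np.linalg.norm(rn) < np.linalg.norm(r):
                u, r, p = un, rn, pn
                lam = max(lam / 3.0, 1e-9)
                accepted = True
                break
            step *= 0.5
            lam *= 3.0
        if not accepted:
            break
    if np.linalg.norm(r[:3]) >= tol:
        raise RingClosureError(
            f"ring closure residual {np.linalg.norm(r[:3]):.2e} above {tol:.0e}")
    return p


def _kabsch_transform(P: np.ndarray, Q: np.ndarray):
    """Rotation + translation mapping point set P onto Q (least squares)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    return rot, qc - rot.apply(pc[None])[0]


def rebuild_ring(pos: np.ndarray, ring: RingSpec, t1: float, t4: float,
                 tol: float = 1e-4) -> np.ndarray:
    """Set the two reduced ring-flip torsions and restore ring closure.

    The ring is rebuilt with template bond lengths; substituent subtrees ride
    on the local frame (prev, atom, next) of their ring atom.  The new ring
    is Kabsch-aligned onto the old one to minimise overall molecular motion.
    """
    bonds, angles = _ring_internal(pos, ring.atoms)
    a = ring.atoms
    # current free chain torsions as the Gauss-Newton starting point
    t2_0 = measure_dihedral(pos, a[1], a[2], a[3], a[4])
    t3_0 = measure_dihedral(pos, a[2], a[3], a[4], a[5])
    chain = solve_ring(bonds, angles, t1, t4, guess=(t2_0, t3_0), tol=tol)

    old_ring = pos[list(ring.atoms)]
    rot, trans = _kabsch_transform(chain, old_ring)
    new_ring = rot.apply(chain) + trans

    out = pos.copy()
    out[list(ring.atoms)] = new_ring
    # re-place substituent subtrees using per-atom local frames
    for m, subs in enumerate(ring.substituents):
        if not subs:
            continue
        prev_i = ring.atoms[(m - 1) % 6]
        at_i = ring.atoms[m]
        next_i = ring.atoms[(m + 1) % 6]
        old_frame = _local_frame(pos[prev_i], pos[at_i], pos[next_i])
        new_frame = _local_frame(out[prev_i], out[at_i], out[next_i])
        rel = (pos[list(subs)] - pos[at_i]) @ old_frame.T  # coords in old frame
        out[list(subs)] = rel @ new_frame + out[at_i]
    return out


def _local_frame(p_prev: np.ndarray, p_at: np.ndarray, p_next: np.ndarray) -> np.ndarray:
    """Orthonormal frame rows (e1, e2, e3) attached to a ring atom."""
    u = p_prev - p_at
    v = p_next - p_at
    e1 = u + v
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        e1 = u
        n1 = np.linalg.norm(e1)
    e1 = e1 / n1
    e3 = np.cross(u, v)
    n3 = np.linalg.norm(e3)
    if n3 < 1e-9:
        e3 = np.cross(e1, np.array([1.0, 0.0, 0.0]))
        n3 = np.linalg.norm(e3)
    e3 = e3 / n3
    e2 = np.cross(e3, e1)
    return np.vstack([e1, e2, e3])


# ---------------------------------------------------------------------------
# Space builders
# ---------------------------------------------------------------------------

def conformer_space(annotations: MoleculeAnnotations, template: Structure, *,
                    hydroxyls: bool = True, glycosidic: bool = False,
                    ring_mode: str = "none") -> SearchSpace:
    """Build the conformer search space matching ``count_dimensions``.

    Dihedral variables are periodic over [-pi, pi).  The reduced ring-flip
    torsions are bounded (non-periodic) within +-70 deg around zero, which
    spans the two chair values of a pyranose ring.
    """
    variables: list[Variable] = []
    if hydroxyls:
        for n, spec in enumerate(annotations.hydroxyls):
            variables.append(Variable(f"oh{n}", -np.pi, np.pi, True, "dihedral", spec))
    if glycosidic:
        for n, spec in enumerate(annotations.glycosidic):
            name = "phi" if n % 2 == 0 else "psi"
            variables.append(Variable(f"{name}{n // 2}", -np.pi, np.pi, True,
                                      "dihedral", spec))
    if ring_mode == "reduced":
        lim = np.deg2rad(70.0)
        for n, ring in enumerate(annotations.rings):
            variables.append(Variable(f"ring{n}_t1", -lim, lim, False,
                                      "ringflip_coord", (ring, 0)))
            variables.append(Variable(f"ring{n}_t4", -lim, lim, False,
                                      "ringflip_coord", (ring, 1)))
    elif ring_mode == "full":
        for n, ring in enumerate(annotations.rings):
            for m in range(6):
                variables.append(Variable(f"ring{n}_tau{m}", -np.pi, np.pi, True,
                                          "ringflip_coord", (ring, m)))
    elif ring_mode != "none":
        raise ValueError("ring_mode must be none, reduced or full")
    return SearchSpace(variables)


def adsorption_space(a: float, b: float, z_lo: float = 3.0, z_hi: float = 12.0) -> SearchSpace:
    """The 6-D rigid-body space over one orthogonal surface cell.

    tx in [0, a], ty in [0, b] (periodic), tz in [z_lo, z_hi] above the top
    layer plane (non-periodic; bounds 3.0-12.0 A by default), Euler angles
    alpha, gamma in [0, 2 pi) periodic and beta in [0, pi].
    """
    return SearchSpace([
        Variable("tx", 0.0, a, True, "translation_x"),
        Variable("ty", 0.0, b, True, "translation_y"),
        Variable("tz", z_lo, z_hi, False, "translation_z"),
        Variable("alpha", 0.0, TWO_PI, True, "euler_alpha"),
        Variable("beta", 0.0, np.pi, False, "euler_beta"),
        Variable("gamma", 0.0, TWO_PI, True, "euler_gamma"),
    ])


# ---------------------------------------------------------------------------
# Realizers
# ---------------------------------------------------------------------------

def realize_conformer(template: Structure, space: SearchSpace, x: np.ndarray,
                      closure_tol: float = 1e-4) -> Structure:
    """Set each search variable of a conformer space on a template copy.

    Dihedral variables rotate their moving set; the reduced ring-flip pair of
    each ring rebuilds the ring with Gauss-Newton closure.  Raises
    RingClosureError when closure fails (callers treat the point as
    high-energy).
    """
    x = space.wrap(np.asarray(x, dtype=float))
    if x.shape[-1] != space.dimension:
        raise ValueError("reduced vector length does not match space dimension")
    pos = template.positions.copy()
    ring_targets: dict[int, dict[int, float]] = {}
    for value, var in zip(x, space.variables):
        if var.tag == "dihedral":
            pos = set_dihedral(pos, var.payload, value)
        elif var.tag == "ringflip_coord":
            ring, which = var.payload
            if which > 1:
                raise NotImplementedError(
                    "the full per-ring-atom parametrization is supported for "
                    "dimensionality accounting only; realize with "
                    "ring_mode='reduced'")
            ring_targets.setdefault(id(ring), {})["ring"] = ring
            ring_targets[id(ring)][which] = value
        else:
            raise ValueError(f"variable {var.label}: tag {var.tag} not valid "
                             "in a conformer space")
    for entry in ring_targets.values():
        ring = entry["ring"]
        a = ring.atoms
        t1 = entry.get(0, measure_dihedral(pos, a[0], a[1], a[2], a[3]))
        t4 = entry.get(1, measure_dihedral(pos, a[3], a[4], a[5], a[0]))
        pos = rebuild_ring(pos, ring, t1, t4, tol=closure_tol)
    out = template.copy()
    out.positions = pos
    return out


def realize_adsorption(conformer: Structure, slab: Structure, x: np.ndarray) -> Structure:
    """Place a rigid conformer over the slab at rigid-body coordinates x.

    ``x = (tx, ty, tz, alpha, beta, gamma)``: the conformer is rotated by the
    intrinsic z-y-z Euler angles about its geometric center and its center is
    translated to ``(tx, ty, top_plane + tz)``.
    """
    tx, ty, tz, alpha, beta, gamma = np.asarray(x, dtype=float)
    mol = conformer.copy()
    center = mol.center
    rot = Rotation.from_euler("ZYZ", [alpha, beta, gamma])
    pos = rot.apply(mol.positions - center)
    top = top_layer_z(slab)
    pos += np.array([tx, ty, top + tz])
    mol.positions = pos
    combined = assemble(mol, slab, tz)
    return combined
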