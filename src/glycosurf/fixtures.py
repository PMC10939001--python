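"""Test-input generators: idealized sugar templates and planted landscapes.

``make_sugar`` builds chemically sensible idealized geometries of
beta-D-xylopyranose (in either the 4C1 or the 1C4 chair) and of
alpha-terminated 1,4-beta-D-xylotetraose, together with the annotations
(hydroxyl torsions, glycosidic phi/psi pairs, ring atom lists) that the
reduced-coordinate machinery consumes.  Geometries are constructed from
standard bond lengths and angles with exact ring closure (the same
Gauss-Newton solver used by the ring-flip realizer), deterministically and
with no external input, so every test builds its own fixtures in well under
a second.

``make_planted_surface`` returns a periodic 2-D landscape with Gaussian
wells at known, registered locations — the independent oracle for the
search loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .coordinates import (DihedralSpec, MoleculeAnnotations, RingSpec,
                          SearchSpace, Variable, measure_dihedral,
                          solve_ring, _nerf_place, _kabsch_transform)
from .search import FunctionProblem
from .structures import Structure

# standard bond lengths (Angstrom) and angles (rad)
B_CC = 1.53
B_CO = 1.43
B_OH = 0.96
B_CH = 1.10
A_TET = np.deg2rad(109.5)
A_COH = np.deg2rad(108.0)
A_RING_C = np.deg2rad(110.5)
A_RING_O = np.deg2rad(112.0)
CHAIR = np.deg2rad(55.0)
ZETA = np.deg2rad(54.75)  # half the tetrahedral angle, for substituent splay


def molecular_formula(s: Structure) -> str:
    comp = s.composition()
    return "".join(f"{el}{comp[el]}" for el in ("C", "H", "O") if el in comp)


# ---------------------------------------------------------------------------
# Single pyranose unit
# ---------------------------------------------------------------------------

def _ring_positions(chair: str) -> np.ndarray:
    """Six ring atoms O5,C1..C5 of an ideal chair, exact closure."""
    bonds = np.array([B_CO, B_CC, B_CC, B_CC, B_CC, B_CO])  # O5-C1, ..., C5-O5
    angles = np.array([A_RING_O, A_RING_C, A_RING_C, A_RING_C, A_RING_C, A_RING_C])
    sign = +1.0 if chair == "4C1" else -1.0
    t1, t4 = sign * CHAIR, -sign * CHAIR
    return solve_ring(bonds, angles, t1, t4, guess=(-sign * CHAIR, sign * CHAIR),
                      tol=1e-6)


def _substituent_dirs(prev, at, nxt):
    """The two free tetrahedral directions at a ring atom (unit vectors)."""
    d1 = prev - at
    d1 /= np.linalg.norm(d1)
    d2 = nxt - at
    d2 /= np.linalg.norm(d2)
    e1 = -(d1 + d2)
    e1 /= np.linalg.norm(e1)
    e3 = np.cross(d1, d2)
    e3 /= np.linalg.norm(e3)
    return (np.cos(ZETA) * e1 + np.sin(ZETA) * e3,
            np.cos(ZETA) * e1 - np.sin(ZETA) * e3)


def _build_xylose(chair: str = "4C1", anomer: str = "beta"):
    """Positions, symbols and index map of one xylopyranose unit.

    Atom order: O5 C1..C5 (ring), then per carbon C1..C4 the O, its H and the
    ring H, then the two C5 hydrogens.  The hydroxyl oxygens sit equatorial
    in the beta-4C1 chair (axial after the flip to 1C4); the alpha anomer
    swaps the branch at C1 only.
    """
    ring = _ring_positions(chair)
    normal = _ring_normal(ring)

    # equatorial/axial branch choice is made on the 4C1 geometry and the
    # same branch parity reused for 1C4, so the flip preserves stereochemistry
    ring_ref = _ring_positions("4C1") if chair != "4C1" else ring
    nrm_ref = _ring_normal(ring_ref)

    symbols = ["O", "C", "C", "C", "C", "C"]
    pos = [ring[m] for m in range(6)]
    idx = {"O5": 0, "C1": 1, "C2": 2, "C3": 3, "C4": 4, "C5": 5}
    next_i = 6

    def parity(m):
        """+1 if the s_plus branch is equatorial at ring position m (on 4C1)."""
        sp, sm = _substituent_dirs(ring_ref[m - 1], ring_ref[m],
                                   ring_ref[(m + 1) % 6])
        return 1 if abs(sp @ nrm_ref) < abs(sm @ nrm_ref) else -1

    for m, name in ((1, "1"), (2, "2"), (3, "3"), (4, "4")):
        sp, sm = _substituent_dirs(ring[m - 1], ring[m], ring[(m + 1) % 6])
        p = parity(m)
        if m == 1 and anomer == "alpha":
            p = -p
        d_oh = sp if p > 0 else sm
        d_h = sm if p > 0 else sp
        o_pos = ring[m] + B_CO * d_oh
        h_ring = ring[m] + B_CH * d_h
        # hydroxyl H anti to the preceding ring atom
        ho = _nerf_place(ring[m - 1], ring[m], o_pos, B_OH, A_COH, np.pi)
        pos += [o_pos, ho, h_ring]
        symbols += ["O", "H", "H"]
        idx[f"O{name}"] = next_i
        idx[f"HO{name}"] = next_i + 1
        idx[f"H{name}"] = next_i + 2
        next_i += 3

    sp, sm = _substituent_dirs(ring[4], ring[5], ring[0])
    pos += [ring[5] + B_CH * sp, ring[5] + B_CH * sm]
    symbols += ["H", "H"]
    idx["H5a"], idx["H5b"] = next_i, next_i + 1

    return np.array(pos), symbols, idx


def _ring_normal(ring: np.ndarray) -> np.ndarray:
    c = ring - ring.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    return vt[2]


def _xylose_annotations(idx) -> MoleculeAnnotations:
    hydroxyls = []
    for name, ref in (("1", "C2"), ("2", "C1"), ("3", "C2"), ("4", "C3")):
        hydroxyls.append(DihedralSpec(
            idx[ref], idx[f"C{name}"], idx[f"O{name}"], idx[f"HO{name}"],
            "hydroxyl", (idx[f"HO{name}"],)))
    subs = (
        (),  # O5
        (idx["O1"], idx["HO1"], idx["H1"]),
        (idx["O2"], idx["HO2"], idx["H2"]),
        (idx["O3"], idx["HO3"], idx["H3"]),
        (idx["O4"], idx["HO4"], idx["H4"]),
        (idx["H5a"], idx["H5b"]),
    )
    ring = RingSpec((idx["O5"], idx["C1"], idx["C2"], idx["C3"], idx["C4"],
                     idx["C5"]), subs)
    return MoleculeAnnotations(hydroxyls, [], [ring])


# ---------------------------------------------------------------------------
# Xylotetraose (beta-1,4 chain, alpha-terminated reducing end)
# ---------------------------------------------------------------------------

GLYCO_PHI = np.deg2rad(-80.0)
GLYCO_PSI = np.deg2rad(115.0)


def _build_xylotetraose(terminal_anomer: str = "alpha"):
    """Four beta-1,4-linked units; unit 0 is the (default alpha) reducing end.

    Each condensation removes the child's anomeric hydroxyl (O1 + its H) and
    the parent's O4 hydrogen: 4 x 20 - 3 x 3 = 71 atoms, C20H34O17.
    """
    units = []
    for u in range(4):
        anomer = terminal_anomer if u == 0 else "beta"
        units.append(_build_xylose("4C1", anomer))

    # measure the local anomeric torsion used to orient each child unit
    pos0, _, idx0 = units[1]
    tau_c2 = measure_dihedral(pos0, idx0["O1"], idx0["O5"], idx0["C1"], idx0["C2"])
    ang_o5 = _angle(pos0[idx0["O5"]], pos0[idx0["C1"]], pos0[idx0["O1"]])
    ang_c2 = _angle(pos0[idx0["O5"]], pos0[idx0["C1"]], pos0[idx0["C2"]])
    b_c1c2 = np.linalg.norm(pos0[idx0["C2"]] - pos0[idx0["C1"]])

    placed = [units[0][0]]
    for u in range(1, 4):
        prev = placed[u - 1]
        prev_idx = units[u - 1][2]
        c3p, c4p, o4p = prev[prev_idx["C3"]], prev[prev_idx["C4"]], prev[prev_idx["O4"]]
        # target anomeric frame from the glycosidic internal coordinates
        c1t = _nerf_place(c3p, c4p, o4p, B_CO, np.deg2rad(117.0), GLYCO_PSI)
        o5t = _nerf_place(c4p, o4p, c1t, B_CO, ang_o5, GLYCO_PHI)
        c2t = _nerf_place(o4p, o5t, c1t, b_c1c2, ang_c2, tau_c2)
        upos, _, uidx = units[u]
        src = np.array([upos[uidx["C1"]], upos[uidx["O5"]], upos[uidx["C2"]]])
        dst = np.array([c1t, o5t, c2t])
        rot, trans = _kabsch_transform(src, dst)
        placed.append(rot.apply(upos) + trans)

    # assemble with condensation removals and build the global index maps
    removed = []
    for u in range(4):
        rm = set()
        if u > 0:
            rm.update({units[u][2]["O1"], units[u][2]["HO1"]})  # child anomeric OH
        if u < 3:
            rm.add(units[u][2]["HO4"])  # parent O4 hydrogen
        removed.append(rm)

    symbols, positions, gmaps = [], [], []
    offset = 0
    for u in range(4):
        upos, usym, uidx = placed[u], units[u][1], units[u][2]
        gmap = {}
        for local in range(len(usym)):
            if local in removed[u]:
                continue
            gmap[local] = offset
            symbols.append(usym[local])
            positions.append(upos[local])
            offset += 1
        gmaps.append((gmap, uidx))
    positions = np.array(positions)

    def g(u, name):
        gmap, uidx = gmaps[u]
        return gmap[uidx[name]]

    n = len(symbols)
    unit_atoms = []
    for u in range(4):
        gmap, _ = gmaps[u]
        unit_atoms.append(sorted(gmap.values()))

    hydroxyls = []
    for u in range(4):
        names = ["2", "3"]
        if u == 0:
            names = ["1"] + names
        if u == 3:
            names = names + ["4"]
        for name in names:
            ref = {"1": "C2", "2": "C1", "3": "C2", "4": "C3"}[name]
            hydroxyls.append(DihedralSpec(
                g(u, ref), g(u, f"C{name}"), g(u, f"O{name}"), g(u, f"HO{name}"),
                "hydroxyl", (g(u, f"HO{name}"),)))

    glycosidic = []
    for u in range(3):
        child = tuple(sorted(a for v in range(u + 1, 4) for a in unit_atoms[v]))
        c1c = g(u + 1, "C1")
        phi = DihedralSpec(g(u, "C4"), g(u, "O4"), c1c, g(u + 1, "O5"),
                           "glycosidic", tuple(a for a in child if a != c1c))
        psi = DihedralSpec(g(u, "C3"), g(u, "C4"), g(u, "O4"), c1c,
                           "glycosidic", child)
        glycosidic += [phi, psi]

    rings = []
    for u in range(4):
        subs = []
        for m, name in enumerate(("O5", "C1", "C2", "C3", "C4", "C5")):
            sub: list[int] = []
            if name == "C1":
                if u == 0:
                    sub += [g(u, "O1"), g(u, "HO1")]
                sub.append(g(u, "H1"))
            elif name in ("C2", "C3"):
                k = name[1]
                sub += [g(u, f"O{k}"), g(u, f"HO{k}"), g(u, f"H{k}")]
            elif name == "C4":
                sub += [g(u, "O4"), g(u, "H4")]
                if u == 3:
                    sub.append(g(u, "HO4"))
                else:
                    # everything downstream rides on C4's frame
                    sub += [a for v in range(u + 1, 4) for a in unit_atoms[v]]
            elif name == "C5":
                sub += [g(u, "H5a"), g(u, "H5b")]
            subs.append(tuple(sub))
        rings.append(RingSpec(tuple(g(u, nm) for nm in
                                    ("O5", "C1", "C2", "C3", "C4", "C5")),
                              tuple(subs)))

    ann = MoleculeAnnotations(hydroxyls, glycosidic, rings)
    return Structure(symbols, positions), ann


def _angle(p1, p2, p3) -> float:
    u = p1 - p2
    v = p3 - p2
    return float(np.arccos(np.clip(
        u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


# ---------------------------------------------------------------------------
# Small diol test adsorbate
# ---------------------------------------------------------------------------

def _build_diol():
    """Ethylene glycol (gauche conformation), a 10-atom two-anchor adsorbate.

    Small enough that desk-scale searches converge reliably, yet with two
    metal-binding oxygens so that adsorption site and orientation matter.
    The gauche backbone torsion is set to 100 deg, which makes the O...O
    separation (2.57 A) commensurate with the hollow-site spacing of the
    Cu(111) mesh built at the packaged lattice constant — a lock-and-key
    arrangement that gives the adsorption landscape one energetically
    distinct global registry.  The inequivalent hydroxyl torsions leave the
    molecule with no internal symmetry, so no two rigid placements are
    exactly degenerate under an atom permutation (which an
    ordered-correspondence Kabsch comparison cannot see).
    """
    c1 = np.zeros(3)
    c2 = np.array([B_CC, 0.0, 0.0])
    # O1 at the tetrahedral angle from C2, in the xy-plane
    o1 = c1 + B_CO * np.array([np.cos(np.pi - A_TET), np.sin(np.pi - A_TET), 0.0])
    o2 = _nerf_place(o1, c1, c2, B_CO, A_TET, np.deg2rad(100.0))  # commensurate
    h1a = _nerf_place(o2, c2, c1, B_CH, A_TET, np.deg2rad(-175.0))
    h1b = _nerf_place(o2, c2, c1, B_CH, A_TET, np.deg2rad(-55.0))
    h2a = _nerf_place(o1, c1, c2, B_CH, A_TET, np.deg2rad(-60.0))
    h2b = _nerf_place(o1, c1, c2, B_CH, A_TET, np.deg2rad(-178.0))
    ho1 = _nerf_place(c2, c1, o1, B_OH, A_COH, np.pi)
    ho2 = _nerf_place(c1, c2, o2, B_OH, A_COH, np.deg2rad(70.0))
    pos = np.array([c1, c2, o1, o2, h1a, h1b, h2a, h2b, ho1, ho2])
    symbols = ["C", "C", "O", "O", "H", "H", "H", "H", "H", "H"]
    s = Structure(symbols, pos)
    ann = MoleculeAnnotations(
        hydroxyls=[DihedralSpec(1, 0, 2, 8, "hydroxyl", (8,)),
                   DihedralSpec(0, 1, 3, 9, "hydroxyl", (9,))],
        glycosidic=[], rings=[])
    return s, ann


# ---------------------------------------------------------------------------
# Public fixture API
# ---------------------------------------------------------------------------

def make_sugar(kind: str) -> tuple[Structure, MoleculeAnnotations]:
    """Build a packaged sugar template with annotations.

    ``kind`` is one of ``xylose_4C1``, ``xylose_1C4`` or ``xylotetraose``
    (alpha-terminated; pass ``xylotetraose_beta`` for the beta-terminated
    variant of the reducing end).
    """
    if kind in ("xylose_4C1", "xylose_1C4"):
        chair = kind.split("_")[1]
        pos, symbols, idx = _build_xylose(chair)
        s = Structure(symbols, pos)
        return s, _xylose_annotations(idx)
    if kind == "xylotetraose":
        return _build_xylotetraose("alpha")
    if kind == "xylotetraose_beta":
        return _build_xylotetraose("beta")
    if kind == "diol":
        return _build_diol()
    raise ValueError(f"unknown sugar kind {kind!r}")


# ---------------------------------------------------------------------------
# Planted periodic landscape (search oracle)
# ---------------------------------------------------------------------------

@dataclass
class PlantedLandscape:
    """Periodic 2-D landscape of Gaussian wells at registered positions."""

    a: float
    b: float
    centers: np.ndarray
    depths: np.ndarray
    sigma: float
    minima_x: np.ndarray | None = None
    minima_f: np.ndarray | None = None

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        vals = np.zeros(len(X))
        shifts = np.array([(i * self.a, j * self.b)
                           for i in (-2, -1, 0, 1, 2) for j in (-2, -1, 0, 1, 2)])
        for c, d in zip(self.centers, self.depths):
            delta = X[:, None, :] - (c[None, None, :] + shifts[None, :, :])
            r2 = (delta ** 2).sum(axis=-1)
            vals -= d * np.exp(-r2 / (2.0 * self.sigma ** 2)).sum(axis=1)
        return vals

    @property
    def space(self) -> SearchSpace:
        return SearchSpace([
            Variable("tx", 0.0, self.a, True, "translation_x"),
            Variable("ty", 0.0, self.b, True, "translation_y"),
        ])

    def problem(self) -> FunctionProblem:
        return FunctionProblem(self.space, self)


def make_planted_surface(n_minima: int = 3, seed: int = 0, *,
                         a: float = 2.568, b: float = 4.448,
                         sigma: float = 0.45) -> PlantedLandscape:
    """Periodic toy landscape with ``n_minima`` planted wells.

    Well centers are drawn with a seeded RNG subject to a minimum pairwise
    (periodic) separation of 2.5 sigma; depths descend from 1.0 eV in steps
    of 0.15.  The registered minima are the exact local minimisers obtained
    by descent from each center, so they serve as an oracle for the search.
    """
    rng = np.random.default_rng(seed)
    centers = []
    while len(centers) < n_minima:
        cand = rng.random(2) * np.array([a, b])
        ok = True
        for c in centers:
            d = np.abs(cand - c)
            d = np.minimum(d, np.array([a, b]) - d)
            if np.linalg.norm(d) < 2.5 * sigma:
                ok = False
                break
        if ok:
            centers.append(cand)
    depths = np.array([1.0 - 0.15 * m for m in range(n_minima)])
    land = PlantedLandscape(a, b, np.array(centers), depths, sigma)

    minima_x, minima_f = [], []
    for c in centers:
        res = minimize(lambda x: float(land(x[None, :])[0]), c, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        x = land.space.wrap(res.x)
        minima_x.append(x)
        minima_f.append(res.fun)
    land.minima_x = np.array(minima_x)
    land.minima_f = np.array(minima_f)
    return land
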