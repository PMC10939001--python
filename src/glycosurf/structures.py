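"""Atomistic structures: containers, fcc(111) slabs, assembly, distances, XYZ I/O.

The surface building block is the orthogonal cell of the close-packed (111)
face of an fcc metal: a rectangle with in-plane repeat lengths
``a = a_fcc / sqrt(2)`` (the nearest-neighbour distance) and
``b = a_fcc * sqrt(3) / sqrt(2)``, so that ``b / a = sqrt(3)`` always.

Slab size accounting: ``nx`` and ``ny`` count *atoms* per layer row/column
directly, so a slab holds ``nx * ny * n_layers`` atoms in total (a 6x8x4 Cu
slab has 192 atoms; adding a 20-atom xylose molecule gives the 212-atom
system, and 14x16x4 + 71 gives 967).  Note that this differs from the common
convention where an orthogonal (111) cell carries 2 atoms per layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

ADSORBATE = "adsorbate"
SUBSTRATE = "substrate"

# Covalent radii (Angstrom) for bond detection in molecules; values from the
# Cordero 2008 compilation, rounded.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "Cu": 1.32, "Ag": 1.45, "Au": 1.36, "Pt": 1.36, "Pd": 1.39,
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """An atomistic structure with optional periodicity and bookkeeping masks.

    Parameters
    ----------
    symbols : list of str
        Element symbols, length N.
    positions : (N, 3) float array
        Cartesian coordinates in Angstrom.
    cell : (3, 3) float array
        Lattice vectors as rows; zero rows for non-periodic directions.
    pbc : (3,) bool array
        Periodicity flags per cell vector.
    frozen : (N,) bool array
        Atoms that must not move during relaxation.
    tags : list of str
        Per-atom role, ``"adsorbate"`` or ``"substrate"``.
    """

    symbols: list[str]
    positions: np.ndarray
    cell: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    frozen: np.ndarray | None = None
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        n = len(self.symbols)
        if self.positions.shape[0] != n:
            raise ValueError("positions length does not match symbols")
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool).reshape(n)
        if self.tags is None:
            self.tags = [ADSORBATE] * n
        if len(self.tags) != n:
            raise ValueError("tags length does not match symbols")
        for ax in range(3):
            if self.pbc[ax] and not np.any(self.cell[ax]):
                raise ValueError(f"periodic axis {ax} has a zero cell vector")
        if np.any(self.pbc) and np.linalg.det(self.cell) < 0:
            raise ValueError("cell must be right-handed")

    def __len__(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Structure":
        return Structure(
            list(self.symbols),
            self.positions.copy(),
            self.cell.copy(),
            self.pbc.copy(),
            self.frozen.copy(),
            list(self.tags),
        )

    @property
    def center(self) -> np.ndarray:
        """Geometric center (unweighted mean of positions)."""
        return self.positions.mean(axis=0)

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return Structure(
            [self.symbols[i] for i in idx],
            self.positions[idx],
            self.cell.copy(),
            self.pbc.copy(),
            self.frozen[idx],
            [self.tags[i] for i in idx],
        )

    def adsorbate_part(self) -> "Structure":
        return self.subset(np.array([t == ADSORBATE for t in self.tags]))

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.symbols:
            out[s] = out.get(s, 0) + 1
        return out


@dataclass(frozen=True)
class SlabSpec:
    """Specification of an orthogonal fcc(111) slab.

    ``nx`` / ``ny`` count atoms per layer row/column (total atoms
    ``nx * ny * n_layers``); ``vacuum`` is split symmetrically above and below
    the slab; the bottom ``n_frozen_layers`` layers are frozen to mimic bulk.
    """

    lattice_constant: float
    nx: int
    ny: int
    n_layers: int
    vacuum: float = 60.0
    n_frozen_layers: int = 2
    element: str = "Cu"

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError("lattice constant must be positive")
        if min(self.nx, self.ny, self.n_layers) < 1:
            raise ValueError("nx, ny, n_layers must be >= 1")
        if self.n_frozen_layers >= self.n_layers:
            raise ValueError("n_frozen_layers must be < n_layers")
        if self.n_frozen_layers < 0:
            raise ValueError("n_frozen_layers must be >= 0")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def surface_cell_dimensions(a_fcc: float) -> tuple[float, float]:
    """In-plane repeat lengths (a, b) of the orthogonal (111) surface cell.

    ``a = a_fcc / sqrt(2)`` is the nearest-neighbour distance of the fcc
    lattice and ``b = a * sqrt(3)``.  For Cu with ``a_fcc = 3.632`` this gives
    the (2.568, 4.448) Angstrom search cell.
    """
    if a_fcc <= 0:
        raise ValueError("lattice constant must be positive")
    a = a_fcc / np.sqrt(2.0)
    return a, a * np.sqrt(3.0)


def build_slab(spec: SlabSpec) -> Structure:
    """Build an orthogonal fcc(111) slab.

    Each layer is an ``nx x ny`` grid of atoms on the triangular (111) mesh:
    rows run along x with spacing ``a``, the row pitch along y is ``b/2`` and
    odd rows are offset by ``a/2``.  Layers are ABC-stacked with interlayer
    spacing ``a_fcc / sqrt(3)``; stacking offsets are chosen so the *top*
    layer has an atom exactly at the cell origin (the atop high-symmetry
    axis used by the surface symmetry group).  ``ny`` should be even for the
    in-plane y-periodicity to be exact.
    """
    a, b = surface_cell_dimensions(spec.lattice_constant)
    d111 = spec.lattice_constant / np.sqrt(3.0)
    cell_x = spec.nx * a
    cell_y = spec.ny * b / 2.0
    thickness = (spec.n_layers - 1) * d111
    cell_z = thickness + spec.vacuum
    z0 = spec.vacuum / 2.0

    symbols: list[str] = []
    positions: list[list[float]] = []
    frozen: list[bool] = []
    for layer in range(spec.n_layers):
        # shift so the top layer (layer == n_layers-1) sits on the unshifted grid
        k = spec.n_layers - 1 - layer
        sx = k * a / 2.0
        sy = k * b / 6.0
        z = z0 + layer * d111
        for j in range(spec.ny):
            row_off = (j % 2) * a / 2.0
            for i in range(spec.nx):
                x = (i * a + row_off + sx) % cell_x
                y = (j * b / 2.0 + sy) % cell_y
                symbols.append(spec.element)
                positions.append([x, y, z])
                frozen.append(layer < spec.n_frozen_layers)

    cell = np.diag([cell_x, cell_y, cell_z])
    return Structure(
        symbols,
        np.array(positions),
        cell,
        np.array([True, True, False]),
        np.array(frozen),
        [SUBSTRATE] * len(symbols),
    )


def top_layer_z(slab: Structure) -> float:
    """Mean z of the highest substrate layer (the surface reference plane).

    Atoms within 0.1 Angstrom of the maximum substrate z are taken to form
    the top layer.
    """
    sub = np.array([t == SUBSTRATE for t in slab.tags])
    if not sub.any():
        raise ValueError("structure has no substrate atoms")
    z = slab.positions[sub, 2]
    return float(z[z > z.max() - 0.1].mean())


def assemble(adsorbate: Structure, slab: Structure, height: float) -> Structure:
    """Combine an adsorbate and a slab into one periodic system.

    The adsorbate's geometric center is placed ``height`` Angstrom above the
    mean z of the top substrate layer; its lateral position is kept as given.
    Atom counts, element composition, frozen flags and tags are preserved.
    """
    if len(adsorbate) == 0:
        return slab.copy()
    if np.any(adsorbate.pbc):
        raise ValueError("adsorbate must be non-periodic")
    top = top_layer_z(slab)
    pos = adsorbate.positions.copy()
    pos[:, 2] += (top + height) - pos[:, 2].mean()
    return Structure(
        list(adsorbate.symbols) + list(slab.symbols),
        np.vstack([pos, slab.positions]),
        slab.cell.copy(),
        slab.pbc.copy(),
        np.concatenate([adsorbate.frozen, slab.frozen]),
        list(adsorbate.tags) + list(slab.tags),
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def mic_displacements(delta: np.ndarray, cell: np.ndarray, pbc: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Valid for orthogonal (and mildly skewed) cells: displacements are wrapped
    by rounding their fractional components along periodic axes.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.any(pbc):
        return delta
    frac = delta @ np.linalg.inv(_safe_cell(cell))
    for ax in range(3):
        if pbc[ax]:
            frac[..., ax] -= np.round(frac[..., ax])
    return frac @ _safe_cell(cell)


def _safe_cell(cell: np.ndarray) -> np.ndarray:
    """Cell with zero rows replaced by unit vectors so it is invertible."""
    c = np.array(cell, dtype=float)
    for ax in range(3):
        if not np.any(c[ax]):
            c[ax, ax] = 1.0
    return c


def min_interatomic_distance(s: Structure) -> float:
    """Minimum pair distance under the minimum-image convention."""
    n = len(s)
    if n < 2:
        raise ValueError("need at least two atoms")
    pos = s.positions
    d = pos[:, None, :] - pos[None, :, :]
    d = mic_displacements(d, s.cell, s.pbc)
    r = np.sqrt((d ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    return float(r[iu].min())


def detect_bonds(s: Structure, scale: float = 1.2) -> list[tuple[int, int]]:
    """Bonded pairs by covalent-radius criterion (non-periodic molecules)."""
    pos = s.positions
    radii = np.array([COVALENT_RADII[sym] for sym in s.symbols])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    cut = scale * (radii[:, None] + radii[None, :])
    bonds = []
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cut[i, j]:
                bonds.append((i, j))
    return bonds


# ---------------------------------------------------------------------------
# Extended XYZ I/O
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+)=(?:"([^"]*)"|(\S+))')


def _format_comment(s: Structure, energy: float | None, forces: np.ndarray | None,
                    extra_tags: bool) -> str:
    props = "species:S:1:pos:R:3"
    if extra_tags:
        props += ":tags:S:1:frozen:I:1"
    if forces is not None:
        props += ":forces:R:3"
    fields = []
    if np.any(s.cell):
        lat = " ".join(f"{v:.10f}" for v in s.cell.reshape(9))
        fields.append(f'Lattice="{lat}"')
    fields.append(f"Properties={props}")
    pbc = " ".join("T" if f else "F" for f in s.pbc)
    fields.append(f'pbc="{pbc}"')
    if energy is not None:
        fields.append(f"energy={energy:.10f}")
    return " ".join(fields)


def write_extxyz(path, frames, append: bool = False) -> None:
    """Write one or more frames as extended XYZ.

    ``frames`` is a Structure, or an iterable of Structure or of
    ``(Structure, energy, forces)`` tuples (energy/forces may be None).
    Tags and frozen flags are written for bare structures; energy/force
    frames use the ``species:S:1:pos:R:3:forces:R:3`` layout with
    ``energy=`` on the comment line.
    """
    if isinstance(frames, Structure):
        frames = [frames]
    lines: list[str] = []
    for frame in frames:
        if isinstance(frame, Structure):
            s, energy, forces = frame, None, None
            extra = True
        else:
            s, energy, forces = frame
            extra = False
        lines.append(str(len(s)))
        lines.append(_format_comment(s, energy, forces, extra))
        for i in range(len(s)):
            parts = [f"{s.symbols[i]:2s}"] + [f"{v:15.8f}" for v in s.positions[i]]
            if extra:
                parts.append(s.tags[i])
                parts.append(str(int(s.frozen[i])))
            if forces is not None:
                parts += [f"{v:15.8f}" for v in forces[i]]
            lines.append(" ".join(parts))
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_extxyz(path) -> list[tuple[Structure, float | None, np.ndarray | None]]:
    """Read all frames of an (extended) XYZ file.

    Returns a list of ``(Structure, energy, forces)``; energy/forces are None
    when absent.  Plain XYZ comment lines are tolerated.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        kv = {m.group(1): (m.group(2) if m.group(2) is not None else m.group(3))
              for m in _KV_RE.finditer(comment)}
        cell = np.zeros((3, 3))
        if "Lattice" in kv:
            cell = np.array([float(v) for v in kv["Lattice"].split()]).reshape(3, 3)
        pbc = np.zeros(3, dtype=bool)
        if "pbc" in kv:
            pbc = np.array([t == "T" for t in kv["pbc"].split()])
        energy = float(kv["energy"]) if "energy" in kv else None
        cols = kv.get("Properties", "species:S:1:pos:R:3").split(":")
        names, widths = cols[0::3], [int(w) for w in cols[2::3]]
        symbols, rows = [], []
        for k in range(n):
            rows.append(lines[i + 2 + k].split())
        pos = np.zeros((n, 3))
        forces = None
        tags = None
        frozen = None
        for k, row in enumerate(rows):
            c = 0
            for name, w in zip(names, widths):
                vals = row[c:c + w]
                c += w
                if name == "species":
                    symbols.append(vals[0])
                elif name == "pos":
                    pos[k] = [float(v) for v in vals]
                elif name == "forces":
                    if forces is None:
                        forces = np.zeros((n, 3))
                    forces[k] = [float(v) for v in vals]
                elif name == "tags":
                    if tags is None:
                        tags = [ADSORBATE] * n
                    tags[k] = vals[0]
                elif name == "frozen":
                    if frozen is None:
                        frozen = np.zeros(n, dtype=bool)
                    frozen[k] = bool(int(vals[0]))
        s = Structure(symbols, pos, cell, pbc, frozen, tags)
        frames.append((s, energy, forces))
        i += 2 + n
    return frames
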