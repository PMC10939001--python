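"""Desk-scale learned surrogate potential and training-data export.

The descriptor is a per-atom Gaussian-smeared radial distribution: for every
(center element, neighbour element) channel, Gaussians on a radial grid up
to a 3.5 A cutoff, multiplied by the C1 polynomial switch
``(1 - (r/rc)^2)^2`` so predictions vanish smoothly at the cutoff.  Energies
are modelled as a sum of per-atom contributions linear in the descriptor
plus per-element offsets; weights come from a joint ridge least-squares fit
of total energies and force components with 1:1 weighting.  Forces are the
exact negative gradient of the predicted energy (the descriptor gradients
are analytic), so the model can serve as a relaxation and search backend
through the calculator contract.

This deliberately simple regressor stands in for a full equivariant neural
potential: the workflow contract (train on search-generated frames, run a
second cheap search pass) is what matters here, and heavier models plug in
through the same calculator interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .energy import Calculator
from .structures import Structure, mic_displacements, write_extxyz


@dataclass(frozen=True)
class DescriptorSettings:
    """Radial-basis descriptor controls (cutoff in Angstrom)."""

    cutoff: float = 3.5
    n_basis: int = 8
    r_min: float = 0.6

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.r_min, self.cutoff, self.n_basis)

    @property
    def width(self) -> float:
        return (self.cutoff - self.r_min) / max(self.n_basis - 1, 1)


def _switch(r: np.ndarray, rc: float):
    """C1 cutoff switch and its radial derivative."""
    t2 = (r / rc) ** 2
    f = np.where(r < rc, (1.0 - t2) ** 2, 0.0)
    df = np.where(r < rc, -4.0 * (1.0 - t2) * r / rc ** 2, 0.0)
    return f, df


class _Featurizer:
    def __init__(self, elements: list[str], settings: DescriptorSettings):
        self.elements = sorted(elements)
        self.settings = settings
        self.n_el = len(self.elements)
        self.n_feat = self.n_el * self.n_el * settings.n_basis

    def _channel(self, ei: int, ej: int) -> slice:
        nb = self.settings.n_basis
        start = (ei * self.n_el + ej) * nb
        return slice(start, start + nb)

    def _pairs(self, s: Structure):
        pos = s.positions
        n = len(s)
        d = pos[:, None, :] - pos[None, :, :]
        d = mic_displacements(d, s.cell, s.pbc)
        r = np.sqrt((d ** 2).sum(axis=-1))
        iu, ju = np.triu_indices(n, k=1)
        mask = r[iu, ju] < self.settings.cutoff
        return iu[mask], ju[mask], d[iu[mask], ju[mask]], r[iu[mask], ju[mask]]

    def features(self, s: Structure, with_grad: bool = False):
        """Per-atom feature matrix (N, F); optionally d(sum_i phi_i)/dr (N,3,F)."""
        st = self.settings
        n = len(s)
        el_idx = [self.elements.index(sym) for sym in s.symbols]
        phi = np.zeros((n, self.n_feat))
        grad = np.zeros((n, 3, self.n_feat)) if with_grad else None
        ii, jj, dvec, r = self._pairs(s)
        if len(ii) == 0:
            return (phi, grad) if with_grad else phi
        fc, dfc = _switch(r, st.cutoff)
        w2 = 2.0 * st.width ** 2
        for i, j, dv, rij, f, df in zip(ii, jj, dvec, r, fc, dfc):
            g = np.exp(-((rij - st.centers) ** 2) / w2)
            val = g * f
            phi[i, self._channel(el_idx[i], el_idx[j])] += val
            phi[j, self._channel(el_idx[j], el_idx[i])] += val
            if with_grad:
                dval = g * (df - f * 2.0 * (rij - st.centers) / w2)
                u = dv / rij  # dv = r_i - r_j, so dr/dr_i = u, dr/dr_j = -u
                contrib = np.outer(u, dval)  # (3, n_basis)
                for ch in (self._channel(el_idx[i], el_idx[j]),
                           self._channel(el_idx[j], el_idx[i])):
                    grad[i, :, ch] += contrib
                    grad[j, :, ch] -= contrib
        return (phi, grad) if with_grad else phi


@dataclass
class SurrogatePotentialModel:
    """Linear per-atom surrogate: offsets per element + radial-feature weights."""

    elements: list[str]
    settings: DescriptorSettings
    offsets: np.ndarray          # per-element energy offsets, eV
    weights: np.ndarray          # feature weights
    metrics: dict = field(default_factory=dict)

    def predict(self, s: Structure) -> tuple[float, np.ndarray]:
        feat = _Featurizer(self.elements, self.settings)
        phi, grad = feat.features(s, with_grad=True)
        e = float(phi.sum(axis=0) @ self.weights)
        for sym in s.symbols:
            e += self.offsets[self.elements.index(sym)]
        forces = -np.einsum("ncf,f->nc", grad, self.weights)
        return e, forces

    def save(self, path) -> None:
        payload = {
            "elements": self.elements,
            "cutoff": self.settings.cutoff,
            "n_basis": self.settings.n_basis,
            "r_min": self.settings.r_min,
            "offsets": self.offsets.tolist(),
            "weights": self.weights.tolist(),
            "metrics": self.metrics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SurrogatePotentialModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(p["elements"],
                   DescriptorSettings(p["cutoff"], p["n_basis"], p["r_min"]),
                   np.array(p["offsets"]), np.array(p["weights"]), p["metrics"])


class SurrogateCalculator(Calculator):
    """Calculator-contract adapter so the model can back a search pass."""

    def __init__(self, model: SurrogatePotentialModel, reference_energy: float = 0.0):
        self.model = model
        self.reference_energy = reference_energy

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        return self.model.predict(s)


def featurize(s: Structure, settings: DescriptorSettings = DescriptorSettings(),
              elements: list[str] | None = None) -> np.ndarray:
    """Per-atom descriptor matrix of one structure."""
    if elements is None:
        elements = sorted(set(s.symbols))
    return _Featurizer(elements, settings).features(s)


def train(data: list[tuple[Structure, float, np.ndarray | None]], *,
          settings: DescriptorSettings = DescriptorSettings(),
          split: float = 0.9, seed: int = 0, ridge: float = 1e-8,
          force_weight: float = 1.0) -> SurrogatePotentialModel:
    """Fit the surrogate on (structure, energy, forces) frames.

    Energy rows and force-component rows enter one ridge least-squares
    problem.  The loss is the *sum of the two mean-squared blocks* with 1:1
    weighting (``force_weight`` rescales the force block): each block is
    normalised by its own row count so that the thousands of force
    components cannot swamp the one energy row per frame.  Frames are split
    90/10 into train/validation by a seeded shuffle and energy/force MAEs
    for both splits are stored in ``metrics``.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 training frames")
    elements = sorted({sym for s, _, _ in data for sym in s.symbols})
    feat = _Featurizer(elements, settings)
    n_el = len(elements)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_train = max(int(round(split * len(data))), 1)
    train_idx = set(order[:n_train].tolist())

    rows_A, rows_b, row_frame, row_kind = [], [], [], []
    for fi, (s, e, f) in enumerate(data):
        phi, grad = feat.features(s, with_grad=True)
        counts = np.zeros(n_el)
        for sym in s.symbols:
            counts[elements.index(sym)] += 1.0
        rows_A.append(np.concatenate([counts, phi.sum(axis=0)]))
        rows_b.append(e)
        row_frame.append(fi)
        row_kind.append("E")
        if f is not None:
            block = np.hstack([np.zeros((grad.shape[0] * 3, n_el)),
                               -grad.reshape(-1, feat.n_feat)])
            for rr, bb in zip(block, np.asarray(f, float).reshape(-1)):
                rows_A.append(rr)
                rows_b.append(bb)
                row_frame.append(fi)
                row_kind.append("F")
    A = np.array(rows_A)
    b = np.array(rows_b)
    kind = np.array(row_kind)
    # block-normalised 1:1 loss: mean-square over energies + mean-square
    # over force components
    n_e = max(int((kind == "E").sum()), 1)
    n_f = max(int((kind == "F").sum()), 1)
    w = np.where(kind == "E", 1.0 / np.sqrt(n_e),
                 np.sqrt(force_weight) / np.sqrt(n_f))
    A = A * w[:, None]
    b = b * w
    in_train = np.array([fi in train_idx for fi in row_frame])

    At = A[in_train]
    bt = b[in_train]
    # ridge via stacked regularisation rows + least squares (robust to
    # feature columns that never activate); offsets barely regularised
    reg = np.sqrt(ridge) * np.ones(A.shape[1])
    reg[:n_el] *= 1e-2
    A_aug = np.vstack([At, np.diag(reg)])
    b_aug = np.concatenate([bt, np.zeros(A.shape[1])])
    coef = np.linalg.lstsq(A_aug, b_aug, rcond=None)[0]
    offsets = coef[:n_el]
    weights = coef[n_el:]

    model = SurrogatePotentialModel(elements, settings, offsets, weights)
    model.metrics = _metrics(data, model, train_idx)
    return model


def _metrics(data, model, train_idx) -> dict:
    out = {"train": {"e": [], "f": []}, "val": {"e": [], "f": []}}
    for fi, (s, e, f) in enumerate(data):
        ep, fp = model.predict(s)
        split = "train" if fi in train_idx else "val"
        out[split]["e"].append(abs(ep - e) / len(s))
        if f is not None:
            out[split]["f"].append(np.abs(fp - np.asarray(f)).mean())
    metrics = {}
    for split in ("train", "val"):
        metrics[f"{split}_energy_mae_per_atom"] = (
            float(np.mean(out[split]["e"])) if out[split]["e"] else None)
        metrics[f"{split}_force_mae"] = (
            float(np.mean(out[split]["f"])) if out[split]["f"] else None)
    metrics["n_train_frames"] = int(len(train_idx))
    metrics["n_val_frames"] = int(len(data) - len(train_idx))
    return metrics


def export_training_data(observations, path) -> int:
    """Write sampled, non-capped observations as an extended-XYZ archive.

    One frame per evaluated structure, with ``energy=`` (relative to the
    search reference) on the comment line and a forces column.  Returns the
    number of frames written.
    """
    frames = [(o.structure, o.e_raw, o.forces) for o in observations
              if o.provenance == "sampled" and o.structure is not None]
    write_extxyz(path, frames)
    return len(frames)
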