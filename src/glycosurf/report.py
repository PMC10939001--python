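"""Run diagnostics and persistence: correlation reports, summary tables, run dirs.

Predicted-vs-relaxed energy correlation mirrors the standard diagnostic for
reduced-dimensionality searches: both energy sets are shifted to their own
minimum, then the coefficient of determination (R^2 of the least-squares
line; 0 by convention for constant predictions) and the Spearman rank
correlation are reported.  The run directory layout is
``dataset.csv`` (x, E_raw, E_transformed, provenance), ``minima/`` as
extended XYZ, ``model.json``, ``config.yaml`` and ``run.log``; every report
regenerates deterministically from these files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .search import LocalMinimum, SearchResult
from .structures import write_extxyz

log = logging.getLogger("glycosurf")


def configure_logging(level: str = "INFO", logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(levelname)s %(message)s",
                        handlers=handlers, force=True)


def rank_and_correlate(predicted: list[tuple[int, float]],
                       relaxed: list[tuple[int, float]]) -> dict:
    """Correlate surrogate-predicted and relaxed energies of the same minima.

    Energies are made relative to each set's own minimum before comparison.
    Returns the merged table plus R^2 and Spearman rank correlation.
    """
    pred = dict(predicted)
    rel = dict(relaxed)
    common = sorted(set(pred) & set(rel))
    if not common:
        raise ValueError("no common minima between the two sets")
    p = np.array([pred[i] for i in common])
    r = np.array([rel[i] for i in common])
    p_rel = p - p.min()
    r_rel = r - r.min()
    if len(common) < 2 or np.var(p_rel) == 0 or np.var(r_rel) == 0:
        r2 = 0.0
        rho = 0.0
    else:
        r2 = float(np.corrcoef(p_rel, r_rel)[0, 1] ** 2)
        rho = float(spearmanr(p_rel, r_rel).statistic)
    table = pd.DataFrame({"index": common, "predicted_rel": p_rel,
                          "relaxed_rel": r_rel})
    return {"table": table, "r_squared": r2, "spearman": rho}


def summarize_run(result: SearchResult, minima: list[LocalMinimum]) -> dict:
    """Per-minimum table (rank, energies, RMSD, relaxation steps) + averages."""
    rows = []
    for m in minima:
        rows.append({
            "rank": m.rank,
            "predicted_energy": m.predicted_energy,
            "relaxed_energy": m.relaxed_energy,
            "rmsd": m.rmsd,
            "n_steps": m.n_steps,
        })
    table = pd.DataFrame(rows)
    averages = {}
    for col in ("n_steps", "rmsd", "relaxed_energy"):
        vals = table[col].dropna() if len(table) else pd.Series(dtype=float)
        averages[f"mean_{col}"] = float(vals.mean()) if len(vals) else None
    return {"table": table, "averages": averages,
            "n_minima": len(minima),
            "n_observations": len(result.observations),
            "termination": result.termination}


def write_run_directory(outdir, result: SearchResult, config: dict,
                        minima: list[LocalMinimum] | None = None) -> Path:
    """Persist a search run: dataset, minima, model, config snapshot."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X, y = result.dataset
    data = {f"x{d}": X[:, d] for d in range(X.shape[1])}
    data["E_raw"] = [o.e_raw for o in result.observations]
    data["E_transformed"] = y
    data["provenance"] = [o.provenance for o in result.observations]
    data["max_force"] = [o.max_force if o.max_force is not None else np.nan
                         for o in result.observations]
    pd.DataFrame(data).to_csv(out / "dataset.csv", index=False)
    with open(out / "model.json", "w") as fh:
        json.dump(result.model.to_dict(), fh, indent=1)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    if minima:
        mdir = out / "minima"
        mdir.mkdir(exist_ok=True)
        for m in minima:
            if m.realized is not None:
                write_extxyz(mdir / f"min_{m.rank:03d}.xyz", m.realized)
            if m.relaxed is not None:
                write_extxyz(mdir / f"min_{m.rank:03d}_relaxed.xyz",
                             [(m.relaxed, m.relaxed_energy, None)])
    log.info("run directory written to %s", out)
    return out
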