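# glycosurf

Gaussian-process Bayesian-optimization structure search for flexible
carbohydrate adsorbates on fcc(111) metal surfaces.

Finding the global-minimum structure of a sugar on a metal surface is a
needle-in-a-haystack problem: the molecule has many soft torsions, the
surface adds translational/rotational placement, and every energy
evaluation with an electronic-structure engine is expensive. This package
implements an accelerated workflow for that problem, aimed at surface
scientists and method developers:

1. **Conformer search** over reduced internal coordinates — hydroxyl
   torsions, glycosidic (φ, ψ) torsions, and a two-torsion pyranose
   ring-flip coordinate (6-D for β-D-xylose, 16-D for
   1,4-β-D-xylotetraose).
2. **Adsorption search** using the building-block approximation: a rigid
   conformer placed over a rigid slab by 6 rigid-body coordinates
   (tx, ty, tz, and intrinsic z-y-z Euler angles), with tx, ty spanning
   one orthogonal (111) surface cell (a_fcc/√2 × a_fcc·√3/√2).
3. A **GP surrogate** (product of squared-exponential and periodic kernel
   components) refined by a lower-confidence-bound acquisition
   `μ − κσ` with periodic uncertainty sampling; high-energy configurations
   are tamed by an energy transformation (contacts below 0.5 Å are capped
   at 5.0 eV; relative energies above 1.0 eV are compressed to
   `1 + ln E`).
4. **Surface-symmetry data augmentation** — each sampled placement is
   duplicated under the half-cell translation and the 3-fold rotation
   about the atop axis, growing the dataset sixfold for free — and
   **Kabsch deduplication** of the harvested surrogate minima.
5. **Local relaxation** (damped BFGS, frozen bottom layers, 0.01 eV/Å
   force threshold) of predicted minima.
6. A **lightweight learned potential** (radial descriptors + joint
   energy/force ridge regression, 3.5 Å cutoff) trained on the
   search-generated frames — optionally enriched by a **force-seeking**
   BO run that hunts high-force configurations — enabling a cheap second
   search pass that is validated against the original engine.

Any real engine (DFT, a production ML potential) plugs in through a
two-method calculator contract; the packaged empirical backends
(Lennard-Jones + directional hydrogen bonds intramolecular; pairwise
corrugated Morse molecule–surface) make everything runnable on a laptop.

## Worked example

A hydroxyl-torsion conformer search on β-D-xylose with the packaged
intramolecular backend, followed by harvesting, deduplication and local
relaxation of the best minima:

```python
import glycosurf as g
from glycosurf.coordinates import conformer_space
from glycosurf.energy import ToyIntramolecular
from glycosurf.search import (BOSettings, ConformerProblem, run_search,
                              harvest_minima, deduplicate)
from glycosurf.relaxation import relax

mol, ann = g.make_sugar("xylose_4C1")
space = conformer_space(ann, mol, hydroxyls=True, ring_mode="none")
calc = ToyIntramolecular(mol)
calc.reference_energy = calc.evaluate(mol)[0]
problem = ConformerProblem(space, mol, calc)

res = run_search(problem, BOSettings(seed=1, max_iter=40, stall_limit=100))
minima = deduplicate(harvest_minima(res.model, space, seed=2,
                                    problem=problem), 0.3)
print(f"observations: {len(res.observations)}   "
      f"deduplicated minima: {len(minima)}")
for m in minima[:3]:
    r = relax(m.realized, calc, fmax=0.01, max_steps=300)
    print(f"rank {m.rank}: predicted {m.predicted_energy:+.4f} eV, "
          f"relaxed {r.energy - calc.reference_energy:+.4f} eV, "
          f"RMSD {g.kabsch_rmsd(m.realized, r.structure):.3f} A, "
          f"steps {r.n_steps}")
```

Output:

```
observations: 45   deduplicated minima: 6
rank 0: predicted -0.0728 eV, relaxed -0.1377 eV, RMSD 0.464 A, steps 22
rank 1: predicted -0.0568 eV, relaxed -0.1387 eV, RMSD 0.557 A, steps 12
rank 2: predicted -0.0532 eV, relaxed -0.1539 eV, RMSD 0.559 A, steps 20
```

The search spent 45 backend evaluations (5 initial + 40 proposed) on the
4-D hydroxyl-torsion space and found six distinct surrogate minima.
Each is then relaxed with the engine: the relaxed energies (relative to
the starting template) drop below the surrogate predictions because
relaxation releases the degrees of freedom the reduced search holds
fixed, and the 0.4–0.8 Å RMSDs quantify how far each predicted structure
moved — both standard diagnostics for judging how well the reduced space
captures the true landscape.

The end-to-end two-pass workflow (search → train a potential → search
again on the potential → validate with the engine) is available as
`glycosurf.run_two_pass` on the packaged toy adsorption system
(`glycosurf.make_toy_system`).

There is also a small CLI (`glycosurf fixtures | conformer-search |
adsorb-search | relax | export-training | train-mlip | report`) for
running the same stages from a shell; each search writes a reproducible
run directory (dataset.csv, minima/, model.json, config snapshot).

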