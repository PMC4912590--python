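# ureaconf

Cis/trans conformer analysis for substituted ureas: substructure and
torsion mining from 3D structures, matched-molecular-pair /
transformation-cycle non-additivity analysis of bioactivity data, and a
desk-scale umbrella-sampling + periodic-WHAM reconstruction of the
torsional free-energy profile with Monte-Carlo error bars.

## The problem

The urea motif N–C(=O)–N is ubiquitous in medicinal chemistry (kinase
inhibitors such as sorafenib carry it), and each of its two amide-like
C–N bonds can adopt a planar *trans* (substituent syn to the carbonyl
oxygen, torsion ≈ 0°) or *cis* (≈ ±180°) arrangement. Crystal-structure
surveys show an overwhelming preference for *trans* and essentially no
population between the planar states, which implies a rotational barrier
far above thermal energy. For molecular modelling this matters twice:
a free-energy calculation started from the wrong conformer state cannot
relax to the right one on accessible time scales, and structure–activity
data around ureas show non-additive substituent effects that plausibly
trace back to conformer switches.

`ureaconf` packages that analysis chain as tested, reusable code:

- **`ureaconf.chem`** — urea detection (SMARTS `N–C(=O)–N`), substitution
  classification (parent / mono / N,N-di / N,N′-di / tri / tetra from
  heavy-substituent counts), the two flanking torsions measured over
  (substituent, N, C, O), per-torsion classes (trans within ±20°, cis
  within 180° ± 20°, 20–30° shoulder, other) and joint two-torsion states
  (trans/trans, cis/trans, cis/cis, nonplanar at a ±30° state tolerance).
- **`ureaconf.hbond`** — geometric hydrogen-bond counting (donor–acceptor
  heavy-atom distance ≤ 3.0 Å, donor–H–acceptor angle ≥ 135°) with
  per-group means over coordinate frames.
- **`ureaconf.mmp`** — single-cut matched-molecular-pair indexing
  restricted to urea-adjacent replacements, activity deltas within one
  (assay, publication, activity-type) group, double-transformation-cycle
  enumeration and the cycle non-additivity
  ΔΔ = Δ(a→c) − Δ(b→d) = pA(c) − pA(a) − pA(d) + pA(b).
- **`ureaconf.sim`** — overdamped Langevin dynamics of one periodic
  dihedral on a cosine-series potential
  U(φ) = Σⱼ Aⱼ(1 + cos(nⱼφ − δⱼ)), umbrella windows
  (121 windows, 3° shift, harmonic bias reaching 200 kcal/mol at 180°),
  transition counting and a Kramers rate diagnostic.
- **`ureaconf.wham`** — periodic weighted-histogram analysis
  (self-consistent f-iteration with minimum-image bias evaluation),
  profile features (minima, cis–trans offset ΔΔG, barrier, transition
  state) and ten-fold Monte-Carlo bootstrap errors.
- **`ureaconf.synth`** — generators for every input with known ground
  truth: torsion-angle mixtures, substitution-class molecule sets,
  factorial SAR tables with injectable interaction terms, idealized 3D
  dimethylurea conformers, and H-bond frames with scheduled contacts.
- **`ureaconf.pipeline` / `ureaconf.cli`** — stage drivers and the
  `ureaconf mine|mmp|simulate|wham|pmf|generate` command line.

## Worked example

```python
import numpy as np
from ureaconf import sim, wham

pot = sim.get_preset("paper_vacuum")          # 4.1 kcal/mol cis offset, 14.0 barrier
windows = sim.make_umbrella_protocol()        # 121 windows, 3 deg shift
cfg = sim.SimConfig(n_snapshots=1000, seed=1)
sampled = sim.run_umbrella_protocol(pot, windows, cfg)
profile = wham.wham_solve(wham.build_wham_input(sampled, bin_width=3.0))
feats = wham.pmf_features(profile.angles, profile.free_energy)
print(f"ddG(cis-trans) = {feats.delta_g:.2f} kcal/mol, "
      f"barrier = {feats.barrier:.2f} kcal/mol at +-{feats.ts_angle:.1f} deg")
```

prints

```
ddG(cis-trans) = 4.25 kcal/mol, barrier = 14.07 kcal/mol at +-91.5 deg
```

i.e. the estimator chain recovers the preset's built-in cis–trans offset
(4.1 kcal/mol) and barrier (14.0 kcal/mol) to well within the 0.3 kcal/mol
oracle tolerance at one tenth of the standard snapshot budget. A barrier
of ~14 kcal/mol makes spontaneous cis↔trans flips astronomically rare for
unbiased sampling: ten unbiased runs of the same length show zero
transitions.

The numbered scripts under `analysis/` run the full story — conformer
survey statistics (814 torsions from 407 molecules: 88 % trans torsions,
79 % / 21 % trans/trans vs cis/trans states), the substitution partition,
matched-pair non-additivity (a 2.5 log-unit substituent effect in one
context vs 0.85 in the other: non-additivity 1.65 log units), both PMF
presets with bootstrap errors, and the per-state hydrogen-bond counts
(e.g. trans/trans: 1.69 carbonyl + 0.88 amide = 2.57) — and write their
tables under `results/`.

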