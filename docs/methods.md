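# Methods

## Conformer mining and classification

A urea core is any N–C(=O)–N match with trivalent nitrogens. Symmetric
SMARTS hits (swapped nitrogens) are collapsed to one match; nitrogens are
ordered by canonical atom rank (ties by index) so results are independent
of input atom order. A match is *acyclic* iff none of the three core
atoms sits in a ring; this automates the manual curation step that
removes e.g. biotin-like imidazolidinones, whose urea is locked by the
ring and not comparable to open-chain ureas.

The substitution class is a pure function of the heavy-atom substituent
counts on the two nitrogens: (0,0) parent, (1,0) mono, (2,0) N,N-di,
(1,1) N,N′-di, (2,1) tri, (2,2) tetra.

Each torsion is measured over (substituent first atom, N, carbonyl C,
carbonyl O), so 0° means the substituent eclipses the oxygen — the planar
*trans* amide arrangement — and ±180° the planar *cis*. When a nitrogen
carries two heavy substituents the one with the lowest canonical rank is
measured; this case does not occur for the N,N′-disubstituted sets the
mining stage retains, but the rule keeps the function total and
deterministic. All angles are wrapped to [−180°, 180°).

Two tolerance layers are deliberately distinct:

| parameter | default | role |
|---|---|---|
| per-torsion tolerance | 20° | trans iff \|φ\| ≤ 20°, cis iff \|φ\| ≥ 160°; the 20–30° band is the sparsely populated "intermediate" shoulder |
| per-state tolerance | 30° | trans/trans etc. from both torsions; wider because joint deviations accumulate |

Class boundaries are inclusive toward the named class (|φ| = 20° is
trans, 160° is cis), so no angle can straddle two classes. Percentages in
reports are integers, rounded half away from zero — the convention that
maps the survey counts 716/814, 320/407 and 87/407 to the printed 88 %,
79 % and 21 %.

Hydrogen bonds are geometric: a donor-H···acceptor contact counts iff the
donor-heavy to acceptor-heavy distance is ≤ 3.0 Å and the D–H–A angle is
≥ 135°. Frames must carry explicit hydrogens on donors; no hydrogen
inference is performed. Contacts are credited to the labelled group(s) of
the participating sites, which is how the carbonyl-acceptor and
amide-donor means are separated.

## Matched pairs and non-additivity

Fragmentation is single-cut: every acyclic single bond between heavy
atoms is broken once, giving a context (the larger piece) and a fragment,
both as attachment-labelled canonical SMILES. Single cuts express exactly
the "replacement directly connected to the urea" transformations the
analysis targets; double and triple cuts of the general
fragment-and-index algorithm are intentionally out of scope. A cut is
urea-adjacent when the bond touches a core atom or a substituent first
atom of any urea in the molecule.

Two compounds form a matched pair when they share a context within one
(assay, publication, activity type) group and differ in the fragment.
Since the literature does not spell out its fragment-size filters, the
defaults are a fragment of at most 12 heavy atoms and at most 50 % of the
parent's heavy atoms, both configurable. Duplicate measurements for one
(compound, assay) are rejected with an explicit error by default; a
median policy is available. K_i and IC50 records never mix.

A double transformation cycle is four compounds a, b, c, d where one
fragment replacement maps a→c and b→d and a second maps a→b and c→d. Its
non-additivity Δ(a→c) − Δ(b→d) equals the closure sum
pA(c) − pA(a) − pA(d) + pA(b) exactly. Each cycle is reported once, in
the orientation with the lexicographically smallest (a, b, c, d) among
the eight structure-preserving relabelings. Note the algebra: reversing a
transformation's direction flips the sign; exchanging the roles of the
two transformations leaves the value unchanged; only |ΔΔ| is
orientation-free and is what summaries report.

## The torsional simulator

The analyzed observable is a single dihedral, so the simulator is the
one-dimensional overdamped Langevin process

dφ = −(D/k_BT) U′(φ) dt + √(2D dt) η,

integrated by Euler–Maruyama with periodic wrapping. Its stationary law
is Boltzmann in U, which is the only property the umbrella/WHAM estimator
chain downstream consumes; solvation physics is *not* modelled. Claims
validated against this simulator are claims about the estimator chain,
not about water.

Potentials are cosine series U(φ) = Σ Aⱼ(1 + cos(nⱼφ − δⱼ)). The two
named presets are two-term fits A₁(1 − cos φ) + A₂(1 − cos 2φ) solved in
closed form for two constraints each:

| preset | U(180°) − U(0°) | barrier from trans | implied TS |
|---|---|---|---|
| `paper_vacuum` | 4.1 kcal/mol | 14.0 kcal/mol | ±95.0° |
| `paper_solution` | 5.7 kcal/mol | 14.8 kcal/mol | ±97.0° |

The offsets and barriers are the published umbrella-sampling values for
vacuum and explicit solvent; the transition-state angle is whatever the
two-term form implies (the published ±82°/±98° locations come from
all-atom sampling and are not fit targets — the solvent-induced TS shift
is not reproduced from physics here, it is only encoded as two presets).

Integrator defaults and why:

- **D = 100 deg²/ps, dt = 0.02 ps.** The harmonic-window relaxation time
  at the default bias is k_BT/(2kD) ≈ 0.5 ps, far below the production
  length, and the Euler–Maruyama bias on the stationary variance of a
  window (factor ≈ 1 + kD·dt/k_BT) stays near 2 %.
- **stride = 20** (0.4 ps between stored snapshots ≈ one window
  relaxation time), so stored snapshots are roughly decorrelated and a
  1,000-snapshot window carries ~1,000 effective samples rather than ~40.
- **equilibration 2,000 steps (40 ps)** from the window center.
- The integrator aborts if the deterministic drift ever exceeds 60° in a
  single step; the Gaussian kick is exempt because large kicks are
  legitimate for fast free diffusion.
- Angles are stored in degrees; all trigonometry happens in radians
  inside the potential object.

The umbrella protocol follows the published one: 121 windows shifted by
3°, spanning the full circle with both representations of the cis state,
and a harmonic bias V = k·wrap(φ − c)² with k = 200/180² kcal/mol/deg²,
i.e. the "200 kcal/mol over 180°" specification read as a harmonic
reaching 200 kcal/mol at a 180° displacement. That sentence is ambiguous;
the alternative reading (a constant slope of 200/180 kcal/mol/deg matched
by the harmonic gradient at 180°, giving half the k) is selectable via
`bias_constant(mode="slope")`, and neither is asserted to be the original
intent.

Transition counting uses hysteresis: a crossing registers only when the
trajectory fully enters the opposite basin (trans |φ| ≤ 30°, cis
|φ| ≥ 150°); barrier excursions that fall back do not count. The Kramers
diagnostic is the high-friction rate
D√(U″_min·|U″_b|)/(2πk_BT)·exp(−ΔU‡/k_BT), summed over the two exits of
the global minimum — an order-of-magnitude tool (validated to within a
factor of three on a low-barrier well), documented as such.

## Periodic WHAM and errors

Window histograms share one periodic grid (default 3° bins, matching the
window spacing; display histograms use 10°). The self-consistent
iteration

p_b ∝ (Σᵢ n_ib) / (Σᵢ Nᵢ exp((fᵢ − Vᵢ(φ_b))/k_BT)),
fᵢ = −k_BT ln Σ_b p_b exp(−Vᵢ(φ_b)/k_BT)

runs in log space (logsumexp) with all bias evaluations using
minimum-image angular distances, until the window free energies move less
than 10⁻⁷ kcal/mol. The residual trace is logged; it decays monotonically
after a short cold-start transient. The free energy −k_BT ln p_b is
shifted to min 0. A single window with identically zero bias is the
degenerate case whose exact solution is direct Boltzmann inversion of its
histogram, and is returned as such (bitwise). Bins with zero total counts
are treated as uncovered and are a hard error — no pseudocounts anywhere.

Features: the trans (cis) minimum is the grid argmin within ±90° of 0°
(180°); the barrier is the maximum along the lower-energy of the two
periodic paths between the minima, measured from the trans minimum;
symmetric ±φ locations are reported as the positive representative. A
missing cis local minimum is flagged and the offset evaluated at 180°.
Profiles are not symmetrized over ±φ (a flag exists, off by default,
since whether published profiles were symmetrized is unknown).

Error bars follow "ten-fold Monte Carlo random subset sampling", which
underdetermines the scheme; the default here is bootstrap with
replacement at fraction 1.0 with 10 subsets, seeded, warm-started from
the full-data solution (without-replacement subsets at any fraction are
selectable). Errors are standard deviations across subsets, per bin and
per feature; angular features use minimum-image deviations so a minimum
oscillating between +178.5° and −178.5° reads as a 3° spread, not 357°.
At 1,000 snapshots/window the per-bin errors stay below 0.1 kcal/mol and
scale as 1/√snapshots (log-log slope ≈ −0.5) — an internal-consistency
property of the surrogate chain, not a reproduction of all-atom error
bars.

## Synthetic data: what it does and does not emulate

Generators provide every pipeline input with known ground truth.

- **Torsion mixture**: wrapped-normal modes at 0° and 180° (σ = 8°)
  with weights 0.88/0.11 and a 0.01 uniform shoulder on ±(20°, 30°).
  Each mode is truncated to its class window (±20° about the mode): the
  empirical torsion distribution is unpopulated outside the modes and
  the shoulder, and truncation makes the class fractions exactly
  multinomial, so classifier-recovery tests have clean binomial
  statistics. Wrapped normals were chosen over von Mises for exact,
  simple sampling; at σ = 8° the difference is immaterial.
- **Molecule sets** are minimal acyclic alkyl-substituted ureas built
  from per-class templates — they make no attempt to mimic real chemical
  diversity, only to satisfy the classifier contracts exactly (including
  tetra-substituted ureas, which real bioactivity databases lack).
- **SAR tables** are two-site full factorials with
  pActivity = base + effect₁ + effect₂ + γ + noise. Two sites are
  enough because a double transformation cycle varies exactly two
  positions. With dyadic (exactly representable) effects and γ = 0 the
  cycle closure is 0.0 to the last bit, which is how "the pipeline adds
  no error of its own" is tested; non-dyadic decimals leave ~10⁻¹⁶
  representation residue that has nothing to do with the chain.
- **Conformer fixtures** are idealized dimethylurea geometries (C=O
  1.23 Å, C–N 1.36 Å, N–CH₃ 1.45 Å, sp² angles, planar core) built by
  natural-extension placement with the two torsions set exactly; only
  the dihedrals matter to the operations under test.
- **H-bond frames** schedule integer contact totals so per-group means
  hit their targets exactly, and plant decoys that fail either the
  distance or the angle cut-off so counting exactness exercises both
  criteria.

Passing tests on these generators therefore demonstrate correctness of
the classifiers, the pair/cycle enumeration and the estimator chain under
known ground truth; they do not demonstrate robustness to real-data
pathologies (tautomers, disorder, measurement heterogeneity), which the
generators deliberately omit.

## Problem sizes and reproducibility

The standard umbrella budget is 10,000 snapshots/window; analyses and the
acceptance script run at 1,000 snapshots/window (121,000 snapshots per
profile), which already recovers the preset profiles to well under
0.3 kcal/mol sup-norm and localizes features to a fraction of a bin.
Every stochastic component takes an explicit seed and is bitwise
reproducible given it; identical config + seed yields identical outputs.

## Known limitations

- The simulator is a 1-D surrogate: no explicit solvent, no pressure
  coupling, no multi-dimensional reaction coordinates, no protein
  environment; solvent effects enter only through preset parameters.
- Single-cut matched pairs only; ring replacements and multi-point
  changes are invisible to the indexer.
- PDB input carries no bond orders; urea detection on ligand coordinates
  requires a template SMILES to restore them.
- The enantiomorphic ±φ convention of published torsion histograms is
  unknown; signed angles are reported, with absolute-value reporting
  available downstream.
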