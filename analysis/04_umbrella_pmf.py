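#!/usr/bin/env python
"""Umbrella sampling + periodic WHAM reconstruction of the urea torsion PMF.

For both torsional presets (vacuum: cis offset 4.1 / barrier 14.0
kcal/mol; solution: 5.7 / 14.8) this runs the full 121-window, 3-degree
shift protocol with the 200-kcal/mol-over-180-degrees harmonic bias at
1,000 snapshots per window, reconstructs the profile with periodic WHAM,
extracts features, and attaches ten-fold Monte-Carlo bootstrap errors.
Sampling is reduced from 10,000 to 1,000 snapshots per window, which
already localizes features to a fraction of the bin width.

Also demonstrates transition scarcity: ten unbiased runs of umbrella-run
length never cross the barrier, in line with the Kramers estimate.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ureaconf import sim, wham

OUT = Path(__file__).resolve().parent.parent / "results" / "04_pmf"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 1
summary = {}

for preset in ("paper_vacuum", "paper_solution"):
    pot = sim.get_preset(preset)
    windows = sim.make_umbrella_protocol()
    cfg = sim.SimConfig(n_snapshots=1000, seed=SEED)
    sampled = sim.run_umbrella_protocol(pot, windows, cfg)
    profile = wham.wham_solve(wham.build_wham_input(sampled, bin_width=3.0))
    feats = wham.pmf_features(profile.angles, profile.free_energy)
    per_bin, feat_err, _ = wham.bootstrap_errors(sampled, seed=SEED + 1)

    analytic = pot.energy(profile.angles)
    analytic -= analytic.min()
    sup = float(np.abs(profile.free_energy - analytic).max())

    pd.DataFrame(
        {
            "angle_deg": profile.angles,
            "free_energy_kcal_mol": profile.free_energy,
            "error_kcal_mol": per_bin,
            "analytic_kcal_mol": analytic,
        }
    ).to_csv(OUT / f"pmf_{preset}.csv", index=False)

    summary[preset] = {
        "delta_g_cis_trans": feats.delta_g,
        "barrier": feats.barrier,
        "ts_angle": feats.ts_angle,
        "sup_norm_vs_analytic": sup,
        "max_per_bin_error": float(per_bin.max()),
        "feature_errors": feat_err,
    }
    print(f"{preset}: ddG(cis-trans) = {feats.delta_g:.2f} kcal/mol, "
          f"barrier = {feats.barrier:.2f} kcal/mol at +-{feats.ts_angle:.1f} deg; "
          f"|PMF - analytic| <= {sup:.3f}, max bootstrap error {per_bin.max():.3f}")

# transition scarcity on the vacuum preset
pot = sim.get_preset("paper_vacuum")
total = 0
for i in range(10):
    traj = sim.run_langevin(pot, None, sim.SimConfig(n_snapshots=10000, seed=SEED + i))
    total += sim.count_transitions(traj.angles)
rate = sim.kramers_estimate(pot, sim.SimConfig())
summary["unbiased_transitions_10_runs"] = total
summary["kramers_rate_per_ps"] = rate
print(f"unbiased transitions over 10 x 10,000 snapshots: {total} "
      f"(Kramers estimate {rate:.2e}/ps -> expected {rate * 10 * 4000:.1e} events)")

(OUT / "summary.json").write_text(json.dumps(summary, indent=1))
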