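"""Stage orchestration: conformer mining, MMP analysis, umbrella/WHAM.

Each ``cmd_*`` function is a thin driver over the library modules; the CLI
and the numbered analysis scripts call these.  Reports carry counts and
integer percentages computed by round-half-away-from-zero, which matches
the conventional rounding of published percentages (716/814 -> 88 %,
320/407 -> 79 %, 87/407 -> 21 %).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from . import chem, mmp, sim, wham
from .chem import ConformerState, SubstitutionClass, TorsionClass, TorsionRecord

__all__ = [
    "RunConfig",
    "round_pct",
    "cmd_mine",
    "cmd_mmp",
    "cmd_pmf",
]


def round_pct(count: int, total: int) -> int:
    """Integer percentage, round half away from zero."""
    if total == 0:
        return 0
    x = 100.0 * count / total
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class RunConfig:
    """Fully-resolved stage parameters; unknown keys are rejected on load."""

    tol_torsion: float = 20.0
    tol_state: float = 30.0
    histogram_bin_width: float = 10.0
    urea_only: bool = True
    max_fragment_heavy_atoms: int = 12
    max_fragment_fraction: float = 0.5
    duplicate_policy: str = "reject"
    preset: str = "paper_vacuum"
    n_windows: int = 121
    window_shift: float = 3.0
    bias_height: float = 200.0
    bias_mode: str = "harmonic"
    temperature: float = 300.0
    n_snapshots: int = 10000
    wham_bin_width: float = 3.0
    wham_tol: float = 1e-7
    bootstrap_subsets: int = 10
    bootstrap_fraction: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def cmd_mine(mols: Sequence[Chem.Mol], config: Optional[RunConfig] = None) -> dict:
    """Mine urea torsions: detect cores, filter acyclic N,N'-disubstituted
    ureas, measure and classify both torsions, and assemble the report.

    Returns a dict with ``torsions`` and ``states`` DataFrames, the angle
    ``histogram`` and a ``report`` of counts and integer percentages.
    """
    config = config or RunConfig()
    torsion_rows = []
    state_rows = []
    skipped = []
    for i, mol in enumerate(mols):
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i}"
        for match in chem.find_urea(mol, mol_id):
            if not match.acyclic:
                skipped.append((mol_id, "cyclic"))
                continue
            if chem.classify_substitution(mol, match) != SubstitutionClass.VIC_DI:
                skipped.append((mol_id, "not N,N'-disubstituted"))
                continue
            if mol.GetNumConformers() == 0:
                skipped.append((mol_id, "no 3D conformer"))
                continue
            a1, a2 = chem.urea_dihedrals(mol, match)
            angles = []
            for side, a in ((1, a1), (2, a2)):
                if a is None:
                    continue
                torsion_rows.append(
                    {
                        "molecule_id": mol_id,
                        "side": side,
                        "angle_deg": a,
                        "torsion_class": chem.classify_torsion(
                            a, config.tol_torsion, config.tol_torsion
                        ).value,
                    }
                )
                angles.append(a)
            if len(angles) == 2:
                state_rows.append(
                    {
                        "molecule_id": mol_id,
                        "angle1_deg": angles[0],
                        "angle2_deg": angles[1],
                        "state": chem.classify_state(
                            angles[0], angles[1], config.tol_state
                        ).value,
                    }
                )
    torsions = pd.DataFrame(
        torsion_rows, columns=["molecule_id", "side", "angle_deg", "torsion_class"]
    )
    states = pd.DataFrame(
        state_rows, columns=["molecule_id", "angle1_deg", "angle2_deg", "state"]
    )
    hist = chem.torsion_histogram(
        torsions["angle_deg"].to_numpy() if len(torsions) else [],
        config.histogram_bin_width,
    )
    n_t = len(torsions)
    n_s = len(states)
    report = {
        "n_molecules": len(mols),
        "n_torsions": n_t,
        "n_states": n_s,
        "n_skipped": len(skipped),
        "torsion_counts": {
            c.value: int((torsions["torsion_class"] == c.value).sum()) for c in TorsionClass
        },
        "state_counts": {
            s.value: int((states["state"] == s.value).sum()) for s in ConformerState
        },
    }
    report["torsion_percentages"] = {
        k: round_pct(v, n_t) for k, v in report["torsion_counts"].items()
    }
    report["state_percentages"] = {
        k: round_pct(v, n_s) for k, v in report["state_counts"].items()
    }
    return {"torsions": torsions, "states": states, "histogram": hist,
            "report": report, "skipped": skipped}


def cmd_mmp(records: Sequence[mmp.ActivityRecord], config: Optional[RunConfig] = None) -> dict:
    """Matched pairs, double transformation cycles and non-additivity.

    Pair finding and cycle enumeration are performed separately within
    each (assay, publication, activity type) group; K_i and IC50 data are
    never mixed.
    """
    config = config or RunConfig()
    pairs = mmp.find_matched_pairs(
        records,
        urea_only=config.urea_only,
        max_fragment_heavy_atoms=config.max_fragment_heavy_atoms,
        max_fragment_fraction=config.max_fragment_fraction,
        duplicate_policy=config.duplicate_policy,
    )
    groups: dict[tuple, list] = {}
    for p in pairs:
        groups.setdefault((p.assay_id, p.doc_id, p.activity_type), []).append(p)
    cycles = []
    for group_pairs in groups.values():
        cycles.extend(mmp.find_cycles(group_pairs))
    pairs_df = pd.DataFrame(
        [
            {
                "compound_a": p.compound_a, "compound_b": p.compound_b,
                "context": p.context, "fragment_a": p.fragment_a,
                "fragment_b": p.fragment_b, "assay_id": p.assay_id,
                "doc_id": p.doc_id, "activity_type": p.activity_type,
                "delta": p.delta,
            }
            for p in pairs
        ]
    )
    cycles_df = pd.DataFrame(
        [
            {
                "a": c.a, "b": c.b, "c": c.c, "d": c.d,
                "t1_from": c.t1[0], "t1_to": c.t1[1],
                "t2_from": c.t2[0], "t2_to": c.t2[1],
                "delta_ac": c.delta_ac, "delta_bd": c.delta_bd,
                "nonadditivity": c.nonadditivity,
                "assay_id": c.assay_id, "activity_type": c.activity_type,
            }
            for c in cycles
        ]
    )
    summary = {
        "n_pairs": len(pairs),
        "n_cycles": len(cycles),
        "max_abs_delta": float(max((abs(p.delta) for p in pairs), default=0.0)),
        "max_abs_nonadditivity": float(
            max((abs(c.nonadditivity) for c in cycles), default=0.0)
        ),
    }
    if pairs:
        summary["delta_summary"] = mmp.delta_distribution(pairs)
    return {"pairs": pairs, "cycles": cycles, "pairs_table": pairs_df,
            "cycles_table": cycles_df, "summary": summary}


def cmd_pmf(config: Optional[RunConfig] = None, with_errors: bool = True) -> dict:
    """Umbrella sampling + periodic WHAM + feature extraction + errors."""
    config = config or RunConfig()
    pot = sim.get_preset(config.preset)
    windows = sim.make_umbrella_protocol(
        n_windows=config.n_windows,
        shift=config.window_shift,
        bias_height=config.bias_height,
        bias_mode=config.bias_mode,
    )
    cfg = sim.SimConfig(
        temperature=config.temperature,
        n_snapshots=config.n_snapshots,
        seed=config.seed,
    )
    sampled = sim.run_umbrella_protocol(pot, windows, cfg)
    inp = wham.build_wham_input(sampled, config.wham_bin_width)
    profile = wham.wham_solve(inp, tol=config.wham_tol)
    features = wham.pmf_features(profile.angles, profile.free_energy)
    profile.features = features
    out = {
        "windows": sampled,
        "profile": profile,
        "features": features,
        "config": config.resolved(),
    }
    if with_errors:
        per_bin, feat_err, _ = wham.bootstrap_errors(
            sampled,
            n_subsets=config.bootstrap_subsets,
            subset_fraction=config.bootstrap_fraction,
            seed=config.seed + 1,
            bin_width=config.wham_bin_width,
            tol=config.wham_tol,
        )
        profile.errors = per_bin
        out["feature_errors"] = feat_err
    return out
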