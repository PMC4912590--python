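"""Readers and writers for the file dialects the pipeline exchanges.

Structures come in as V2000 SDF with 3D coordinates, SMILES files (one
record per line, id after whitespace) or PDB ligand records; activity data
as CSV.  All tabular outputs are plain CSV; run metadata is JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import MoleculeParseError
from .mmp import ActivityRecord
from .sim import UmbrellaWindow, TrajectorySample

logger = logging.getLogger("ureaconf")

__all__ = [
    "read_sdf",
    "read_smiles_file",
    "read_pdb_ligand",
    "read_activity_csv",
    "write_windows",
    "read_windows",
]


def _mol_id(mol: Chem.Mol, fallback: str) -> str:
    if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
        return mol.GetProp("_Name").strip()
    return fallback


def read_sdf(path) -> list[Chem.Mol]:
    """Read an SDF; unparsable records raise naming the record index."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    mols = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise MoleculeParseError(f"{Path(path).name}#{i}")
        mol.SetProp("_Name", _mol_id(mol, f"{Path(path).stem}_{i}"))
        mols.append(mol)
    return mols


def read_smiles_file(path) -> list[Chem.Mol]:
    """One record per line: SMILES then optional id after whitespace."""
    mols = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        rec_id = parts[1].strip() if len(parts) > 1 else f"{Path(path).stem}_{i}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeParseError(rec_id)
        mol.SetProp("_Name", rec_id)
        mols.append(mol)
    return mols


def read_pdb_ligand(
    path, res_name: str, template_smiles: Optional[str] = None
) -> Chem.Mol:
    """Extract a ligand (HETATM records with the given 3-letter code).

    PDB files carry no bond orders; if ``template_smiles`` is given the
    orders are transferred from the template so substructure searches
    (e.g. the urea SMARTS) work on the result.
    """
    res_name = res_name.strip().upper()
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("HETATM", "ATOM")) and line[17:20].strip().upper() == res_name:
            lines.append(line)
    if not lines:
        raise MoleculeParseError(res_name, f"not found in {Path(path).name}")
    block = "\n".join(lines) + "\nEND\n"
    mol = Chem.MolFromPDBBlock(block, removeHs=True)
    if mol is None:
        raise MoleculeParseError(res_name, "PDB records could not be parsed")
    if template_smiles:
        template = Chem.MolFromSmiles(template_smiles)
        mol = AllChem.AssignBondOrdersFromTemplate(template, mol)
    mol.SetProp("_Name", res_name)
    return mol


def read_activity_csv(path) -> list[ActivityRecord]:
    """Activity table with columns compound_id,smiles,assay_id,doc_id,type
    and either pactivity or standard_value_nm (converted to -log10 M)."""
    df = pd.read_csv(path, dtype={"compound_id": str, "assay_id": str, "doc_id": str})
    required = {"compound_id", "smiles", "assay_id", "doc_id", "type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    if "pactivity" in df.columns:
        pact = df["pactivity"].astype(float)
    elif "standard_value_nm" in df.columns:
        logger.info("converting standard_value_nm to pActivity = 9 - log10(nM)")
        pact = 9.0 - np.log10(df["standard_value_nm"].astype(float))
    else:
        raise ValueError("activity CSV needs a pactivity or standard_value_nm column")
    bad = pact[~np.isfinite(pact)]
    if len(bad):
        raise ValueError(f"non-finite pActivity at rows {list(bad.index)}")
    return [
        ActivityRecord(
            compound_id=row.compound_id,
            smiles=row.smiles,
            assay_id=row.assay_id,
            doc_id=row.doc_id,
            activity_type=row.type,
            pactivity=float(p),
        )
        for row, p in zip(df.itertuples(), pact)
    ]


def write_windows(windows: Sequence[UmbrellaWindow], outdir) -> None:
    """Per-window trajectory CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"windows": []}
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.csv"
        s = w.samples
        pd.DataFrame(
            {"snapshot_index": np.arange(s.angles.size), "angle_deg": s.angles}
        ).to_csv(outdir / fname, index=False)
        manifest["windows"].append(
            {
                "file": fname,
                "center_deg": w.center,
                "k_kcal_mol_deg2": w.k,
                "temperature_K": s.temperature,
                "seed": s.seed,
                "stride": s.stride,
                "dt_ps": s.dt,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_windows(indir) -> list[UmbrellaWindow]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    windows = []
    for entry in manifest["windows"]:
        df = pd.read_csv(indir / entry["file"])
        windows.append(
            UmbrellaWindow(
                center=entry["center_deg"],
                k=entry["k_kcal_mol_deg2"],
                samples=TrajectorySample(
                    angles=df["angle_deg"].to_numpy(),
                    dt=entry["dt_ps"],
                    temperature=entry["temperature_K"],
                    seed=entry["seed"],
                    stride=entry["stride"],
                ),
            )
        )
    return windows
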