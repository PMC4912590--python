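"""Urea substructure mining and conformer-state classification.

The central motif is the urea core N-C(=O)-N.  For each nitrogen the
orientation of its substituent relative to the carbonyl oxygen is measured
as the dihedral over (substituent first atom, N, C, O); 0 deg corresponds
to the substituent syn to the oxygen, i.e. the planar *trans* amide
arrangement that dominates crystal structures, while +-180 deg is the
planar *cis* arrangement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .geometry import dihedral, wrap_angle

__all__ = [
    "MoleculeParseError",
    "UreaMatch",
    "SubstitutionClass",
    "TorsionClass",
    "ConformerState",
    "TorsionRecord",
    "find_urea",
    "classify_substitution",
    "urea_dihedrals",
    "classify_torsion",
    "classify_state",
    "torsion_histogram",
]

_UREA_SMARTS = Chem.MolFromSmarts("[NX3][CX3](=[OX1])[NX3]")


class MoleculeParseError(ValueError):
    """Raised when a structure record cannot be interpreted."""

    def __init__(self, record_id: str, reason: str = "could not be parsed"):
        self.record_id = record_id
        super().__init__(f"molecule record {record_id!r} {reason}")


class SubstitutionClass(str, enum.Enum):
    """Substitution pattern of the two urea nitrogens (heavy atoms only)."""

    PARENT = "parent"      # (0, 0) urea itself
    MONO = "mono"          # (1, 0)
    GEM_DI = "gem_di"      # (2, 0)  N,N-di
    VIC_DI = "vic_di"      # (1, 1)  N,N'-di
    TRI = "tri"            # (2, 1)
    TETRA = "tetra"        # (2, 2)


class TorsionClass(str, enum.Enum):
    TRANS = "trans"
    INTERMEDIATE = "intermediate"
    CIS = "cis"
    OTHER = "other"


class ConformerState(str, enum.Enum):
    TRANS_TRANS = "trans_trans"
    CIS_TRANS = "cis_trans"
    CIS_CIS = "cis_cis"
    NONPLANAR = "nonplanar"


@dataclass(frozen=True)
class UreaMatch:
    """Mapped atom indices of one urea core within a molecule.

    Nitrogens are ordered deterministically (lower canonical atom rank
    first); ``subst1``/``subst2`` hold heavy-atom neighbours of n1/n2
    excluding the carbonyl carbon, sorted by canonical rank.
    """

    o_idx: int
    c_idx: int
    n1_idx: int
    n2_idx: int
    subst1: tuple = field(default_factory=tuple)
    subst2: tuple = field(default_factory=tuple)
    acyclic: bool = True


@dataclass(frozen=True)
class TorsionRecord:
    molecule_id: str
    side: int  # 1 or 2
    angle: float  # degrees in [-180, 180)
    torsion_class: TorsionClass


def _canonical_ranks(mol: Chem.Mol) -> list[int]:
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def find_urea(mol: Chem.Mol, mol_id: Optional[str] = None) -> list[UreaMatch]:
    """Find all urea cores N-C(=O)-N in ``mol``.

    One match is returned per distinct core; the two equivalent SMARTS
    hits with swapped nitrogens are collapsed, keeping the nitrogen of
    lower canonical rank as n1 (ties broken by atom index).  A match is
    flagged acyclic iff none of the three core atoms (C, N, N) is in a
    ring; cyclic ureas (e.g. the biotin imidazolidinone) are kept in the
    list but flagged so downstream mining can exclude them.
    """
    if mol is None:
        raise MoleculeParseError(str(mol_id))
    ranks = _canonical_ranks(mol)
    matches = []
    seen_cores = set()
    for n1, c, o, n2 in mol.GetSubstructMatches(_UREA_SMARTS):
        core = frozenset((n1, c, n2))
        if core in seen_cores:
            continue
        seen_cores.add(core)
        if (ranks[n2], n2) < (ranks[n1], n1):
            n1, n2 = n2, n1
        subst = []
        for n in (n1, n2):
            atom = mol.GetAtomWithIdx(n)
            nbrs = [
                nb.GetIdx()
                for nb in atom.GetNeighbors()
                if nb.GetIdx() != c and nb.GetAtomicNum() > 1
            ]
            nbrs.sort(key=lambda i: (ranks[i], i))
            subst.append(tuple(nbrs))
        acyclic = not any(
            mol.GetAtomWithIdx(i).IsInRing() for i in (c, n1, n2)
        )
        matches.append(
            UreaMatch(
                o_idx=o,
                c_idx=c,
                n1_idx=n1,
                n2_idx=n2,
                subst1=subst[0],
                subst2=subst[1],
                acyclic=acyclic,
            )
        )
    return matches


_SUBST_CLASS_BY_COUNTS = {
    (0, 0): SubstitutionClass.PARENT,
    (1, 0): SubstitutionClass.MONO,
    (2, 0): SubstitutionClass.GEM_DI,
    (1, 1): SubstitutionClass.VIC_DI,
    (2, 1): SubstitutionClass.TRI,
    (2, 2): SubstitutionClass.TETRA,
}


def classify_substitution(mol: Chem.Mol, match: UreaMatch) -> SubstitutionClass:
    """Classify the urea substitution pattern from heavy-substituent counts."""
    counts = tuple(sorted((len(match.subst1), len(match.subst2)), reverse=True))
    try:
        return _SUBST_CLASS_BY_COUNTS[counts]
    except KeyError:  # pragma: no cover - >2 heavy neighbours is not a urea N
        raise ValueError(f"unexpected substituent counts {counts}")


def urea_dihedrals(
    mol: Chem.Mol, match: UreaMatch, conf_id: int = -1
) -> tuple[Optional[float], Optional[float]]:
    """Measure the two urea torsions from the 3D conformer.

    For each side the dihedral is taken over (substituent first atom, N,
    carbonyl C, O) and wrapped to [-180, 180).  When a nitrogen carries
    more than one heavy substituent the one of lowest canonical rank is
    used, making the measurement deterministic.  A side with no heavy
    substituent is reported as None.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    out = []
    for subst, n_idx in ((match.subst1, match.n1_idx), (match.subst2, match.n2_idx)):
        if not subst:
            out.append(None)
            continue
        s = subst[0]  # lowest canonical rank (sorted in find_urea)
        out.append(dihedral(pos[s], pos[n_idx], pos[match.c_idx], pos[match.o_idx]))
    return out[0], out[1]


def classify_torsion(
    angle: float,
    tol_trans: float = 20.0,
    tol_cis: float = 20.0,
    intermediate_band: tuple[float, float] = (20.0, 30.0),
) -> TorsionClass:
    """Assign one torsion angle to trans / intermediate / cis / other.

    Boundaries are inclusive toward the named class: |angle| == tol_trans
    is trans and |angle| == 180 - tol_cis is cis, so no angle can straddle
    two classes.  The classification is invariant under full turns.
    """
    a = abs(float(wrap_angle(angle)))
    if a <= tol_trans:
        return TorsionClass.TRANS
    if a >= 180.0 - tol_cis:
        return TorsionClass.CIS
    if a <= intermediate_band[1]:
        return TorsionClass.INTERMEDIATE
    return TorsionClass.OTHER


def classify_state(
    angle1: float, angle2: float, tol_state: float = 30.0
) -> ConformerState:
    """Joint two-torsion state; order-independent.

    A torsion counts as trans-like when |angle| <= tol_state and cis-like
    when |angle| >= 180 - tol_state; anything else makes the molecule
    nonplanar.
    """
    labels = []
    for angle in (angle1, angle2):
        a = abs(float(wrap_angle(angle)))
        if a <= tol_state:
            labels.append("t")
        elif a >= 180.0 - tol_state:
            labels.append("c")
        else:
            return ConformerState.NONPLANAR
    key = "".join(sorted(labels))
    return {
        "tt": ConformerState.TRANS_TRANS,
        "ct": ConformerState.CIS_TRANS,
        "cc": ConformerState.CIS_CIS,
    }[key]


def torsion_histogram(
    angles: Sequence[float], bin_width: float = 10.0
) -> pd.DataFrame:
    """Histogram of wrapped torsion angles over [-180, 180).

    Returns a frame with columns bin_left_deg, bin_right_deg, count; the
    counts sum to the number of input angles.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    angles = wrap_angle(np.asarray(list(angles), dtype=float))
    n_bins = int(np.ceil(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return pd.DataFrame(
        {
            "bin_left_deg": edges[:-1],
            "bin_right_deg": edges[1:],
            "count": counts,
        }
    )
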