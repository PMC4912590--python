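"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with its true
parameters known, so classifier fractions, matched-pair deltas, cycle
non-additivities and PMF features can be checked against what was put in:

* torsion-angle datasets emulating the crystal-structure statistics
  (sharp wrapped-normal modes at 0 and +-180 deg, a small uniform
  intermediate band, defaults 88 / 11 / 1 percent);
* minimal urea molecules realizing each substitution class;
* full-factorial SAR tables with additive site effects plus injectable
  pairwise interaction terms;
* idealized 3D conformers of N,N'-dimethyl-urea in any two-torsion state;
* coordinate frames with exactly scheduled hydrogen-bond counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .chem import ConformerState, SubstitutionClass
from .geometry import place_atom, wrap_angle
from .hbond import Acceptor, Donor, Frame
from .mmp import ActivityRecord

__all__ = [
    "TorsionGeneratorSpec",
    "SarGeneratorSpec",
    "gen_torsion_dataset",
    "gen_molecule_set",
    "gen_sar_table",
    "gen_conformer_fixture",
    "HBondGroupSpec",
    "gen_hbond_frames",
]


@dataclass(frozen=True)
class TorsionGeneratorSpec:
    """Mixture model for crystal-structure-like urea torsion angles."""

    n: int = 814
    p_trans: float = 0.88
    p_cis: float = 0.11
    p_intermediate: float = 0.01
    sigma: float = 8.0  # wrapped-normal spread, degrees
    seed: int = 0

    def __post_init__(self):
        total = self.p_trans + self.p_cis + self.p_intermediate
        if not np.isclose(total, 1.0):
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gen_torsion_dataset(spec: TorsionGeneratorSpec) -> np.ndarray:
    """Draw wrapped torsion angles from the three-component mixture.

    trans: wrapped normal at 0 deg; cis: wrapped normal at 180 deg;
    intermediate: uniform magnitude on (20, 30) deg with random sign.
    """
    rng = np.random.default_rng(spec.seed)
    comp = rng.choice(
        3, size=spec.n, p=[spec.p_trans, spec.p_cis, spec.p_intermediate]
    )
    angles = np.empty(spec.n)
    n_trans = int(np.sum(comp == 0))
    n_cis = int(np.sum(comp == 1))
    n_mid = spec.n - n_trans - n_cis
    # normal modes truncated to their class window (|a| <= 20 about the
    # mode): outside the modes and the 20-30 deg shoulder the empirical
    # torsion distribution is unpopulated, so each draw stays classifiable
    # as its component
    angles[comp == 0] = _truncated_normal(rng, 0.0, spec.sigma, 20.0, n_trans)
    angles[comp == 1] = 180.0 + _truncated_normal(rng, 0.0, spec.sigma, 20.0, n_cis)
    mid = rng.uniform(20.0, 30.0, n_mid) * rng.choice([-1.0, 1.0], n_mid)
    angles[comp == 2] = mid
    return wrap_angle(angles)


def _truncated_normal(rng, loc, sigma, half_width, n):
    out = rng.normal(loc, sigma, n)
    bad = np.abs(out - loc) > half_width
    while np.any(bad):
        out[bad] = rng.normal(loc, sigma, int(bad.sum()))
        bad = np.abs(out - loc) > half_width
    return out


# simple acyclic substituents used to build distinct molecules per class
_ALKYLS = ["C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCO", "CCCO", "CCN", "CCCC(C)C"]

_TEMPLATES = {
    SubstitutionClass.PARENT: ("NC(N)=O", 0),
    SubstitutionClass.MONO: ("{0}NC(N)=O", 1),
    SubstitutionClass.GEM_DI: ("{0}N({1})C(N)=O", 2),
    SubstitutionClass.VIC_DI: ("{0}NC(=O)N{1}", 2),
    SubstitutionClass.TRI: ("{0}N({1})C(=O)N{2}", 3),
    SubstitutionClass.TETRA: ("{0}N({1})C(=O)N({2}){3}", 4),
}


def gen_molecule_set(
    counts: dict, seed: int = 0, substituents: Optional[Sequence[str]] = None
) -> list[tuple[str, SubstitutionClass]]:
    """Generate SMILES realizing each requested substitution class.

    Returns ``[(smiles, requested_class), ...]``; every molecule is
    guaranteed (by round-trip through RDKit canonicalization and
    substituent enumeration) to classify back to its requested class.
    The enumeration is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    pool = list(substituents or _ALKYLS)
    out = []
    for cls, want in counts.items():
        cls = SubstitutionClass(cls)
        if want < 0:
            raise ValueError("counts must be non-negative")
        template, n_sites = _TEMPLATES[cls]
        seen = set()
        produced = 0
        if n_sites == 0:
            for _ in range(want):
                out.append((template, cls))
            continue
        for combo in itertools.product(pool, repeat=n_sites):
            if produced >= want:
                break
            smi = template.format(*combo)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            can = Chem.MolToSmiles(mol)
            if can in seen:
                continue
            seen.add(can)
            out.append((can, cls))
            produced += 1
        if produced < want:
            raise ValueError(
                f"substituent pool too small for {want} distinct {cls.value} molecules"
            )
    return out


@dataclass(frozen=True)
class SarGeneratorSpec:
    """Two-site full-factorial SAR table with additive + interaction model.

    pActivity(i, j) = base + effect1[i] + effect2[j] + gamma[i, j] + noise.
    """

    scaffold: str = "O=C(N{0})N{1}"  # two formatting sites on the urea
    substituents1: tuple = ("C", "CC")
    substituents2: tuple = ("CCC", "CCCC")
    effects1: tuple = (0.0, 1.0)
    effects2: tuple = (0.0, 1.0)
    base: float = 6.0
    gamma: tuple = ()  # ((i, j, value), ...) sparse interaction terms
    noise_sigma: float = 0.0
    assay_id: str = "ASSAY-1"
    doc_id: str = "DOC-1"
    activity_type: str = "Ki"
    seed: int = 0

    def __post_init__(self):
        if self.scaffold.count("{0}") != 1 or self.scaffold.count("{1}") != 1:
            raise ValueError("scaffold must contain exactly two sites {0} and {1}")
        if len(self.effects1) != len(self.substituents1):
            raise ValueError("effects1 length mismatch")
        if len(self.effects2) != len(self.substituents2):
            raise ValueError("effects2 length mismatch")

    def gamma_value(self, i: int, j: int) -> float:
        for gi, gj, v in self.gamma:
            if (gi, gj) == (i, j):
                return v
        return 0.0


def gen_sar_table(spec: SarGeneratorSpec) -> list[ActivityRecord]:
    """Full factorial of the two substitution sites with known pActivities."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i, s1 in enumerate(spec.substituents1):
        for j, s2 in enumerate(spec.substituents2):
            smi = spec.scaffold.format(s1, s2)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"scaffold/substituent combination unparsable: {smi}")
            p = spec.base + spec.effects1[i] + spec.effects2[j] + spec.gamma_value(i, j)
            if spec.noise_sigma > 0:
                p += rng.normal(0.0, spec.noise_sigma)
            records.append(
                ActivityRecord(
                    compound_id=f"CPD_{i}_{j}",
                    smiles=Chem.MolToSmiles(mol),
                    assay_id=spec.assay_id,
                    doc_id=spec.doc_id,
                    activity_type=spec.activity_type,
                    pactivity=float(p),
                )
            )
    return records


# idealized internal coordinates (angstrom / degrees) for the urea core
_CO = 1.23
_CN = 1.36
_NC_METHYL = 1.45
_SP2 = 120.0
_OCN = 121.5

_STATE_ANGLES = {
    ConformerState.TRANS_TRANS: (0.0, 0.0),
    ConformerState.CIS_TRANS: (-180.0, 0.0),
    ConformerState.CIS_CIS: (-180.0, -180.0),
}


def gen_conformer_fixture(
    state: ConformerState,
    deviation: float = 0.0,
    side: int = 1,
    mol_id: Optional[str] = None,
) -> Chem.Mol:
    """Idealized 3D N,N'-dimethyl-urea in a prescribed two-torsion state.

    Coordinates are built from idealized internal coordinates (C=O 1.23 A,
    C-N 1.36 A, N-CH3 1.45 A, sp2 angles); the two (C_methyl, N, C, O)
    dihedrals are set to the state's canonical angles, with ``deviation``
    added on the requested side.  For the nonplanar state the deviation IS
    the side's torsion angle (the other side stays at 0).
    """
    state = ConformerState(state)
    if state is ConformerState.NONPLANAR:
        if deviation == 0.0:
            raise ValueError("nonplanar state requires a nonzero deviation")
        phi = [0.0, 0.0]
        phi[side - 1] = deviation
    else:
        phi = list(_STATE_ANGLES[state])
        phi[side - 1] = phi[side - 1] + deviation
    phi1, phi2 = (float(wrap_angle(p)) for p in phi)

    c = np.zeros(3)
    o = np.array([_CO, 0.0, 0.0])
    ang = np.radians(_OCN)
    n1 = np.array([_CN * np.cos(ang), _CN * np.sin(ang), 0.0])
    n2 = place_atom(n1, o, c, _CN, _OCN, 180.0)  # planar core
    m1 = place_atom(o, c, n1, _NC_METHYL, _SP2, _measured_to_nerf(n1, c, o, phi1))
    m2 = place_atom(o, c, n2, _NC_METHYL, _SP2, _measured_to_nerf(n2, c, o, phi2))

    mol = Chem.MolFromSmiles("CNC(=O)NC")  # atoms: C0 N1 C2 O3 N4 C5
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, pos in enumerate([m1, n1, c, o, n2, m2]):
        conf.SetAtomPosition(idx, Point3D(*pos))
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", mol_id or f"dimethylurea_{state.value}")
    return mol


def _measured_to_nerf(n, c, o, target: float) -> float:
    """Torsion argument for place_atom so that dihedral(M, N, C, O) == target.

    place_atom positions M with dihedral(O, C, N, M) == argument; that
    dihedral equals dihedral(M, N, C, O) by chain reversal symmetry, so
    the mapping is the identity.  Kept explicit for readability.
    """
    return target


@dataclass(frozen=True)
class HBondGroupSpec:
    name: str
    kind: str  # "donor" (solute donates) or "acceptor" (solute accepts)
    mean: float  # target mean contacts per frame

    def __post_init__(self):
        if self.kind not in ("donor", "acceptor"):
            raise ValueError("kind must be 'donor' or 'acceptor'")
        if self.mean < 0:
            raise ValueError("mean must be non-negative")


def gen_hbond_frames(
    groups: Sequence[HBondGroupSpec], n_frames: int, seed: int = 0
) -> list[Frame]:
    """Frames whose per-group mean contact counts equal the targets exactly.

    For each group, mean * n_frames must be an integer; the contacts are
    distributed over frames (a random subset of frames carries one extra
    contact) and built at ideal geometry (2.8 A, linear).  Each frame also
    carries decoy contacts violating either the 3.0 A distance or the 135
    degree angle cut-off, so counting exactness exercises both criteria.
    """
    rng = np.random.default_rng(seed)
    schedules = {}
    for grp in groups:
        total = grp.mean * n_frames
        if abs(total - round(total)) > 1e-9:
            raise ValueError(
                f"mean {grp.mean} not achievable with {n_frames} frames"
            )
        total = int(round(total))
        base, extra = divmod(total, n_frames)
        counts = np.full(n_frames, base)
        counts[rng.permutation(n_frames)[:extra]] += 1
        schedules[grp.name] = counts

    frames = []
    for fi in range(n_frames):
        frame = Frame()
        # well-separated origins per group so contacts never cross groups
        for gi, grp in enumerate(groups):
            origin = np.array([100.0 * gi, 0.0, 0.0])
            k = schedules[grp.name][fi]
            if grp.kind == "acceptor":
                # one solute acceptor site with k water donors around it
                frame.acceptors.append(Acceptor(pos=origin, group=grp.name))
                for _ in range(k):
                    direction = _unit(rng)
                    heavy = origin + 2.8 * direction
                    frame.donors.append(
                        Donor(heavy=heavy, hydrogen=heavy - 1.0 * direction, group=None)
                    )
                # decoy: in range but hydrogen pointing away (angle ~0 deg)
                direction = _unit(rng)
                heavy = origin + 2.8 * direction
                frame.donors.append(
                    Donor(heavy=heavy, hydrogen=heavy + 1.0 * direction, group=None)
                )
            else:
                for ci in range(k):
                    # one solute donor per contact, H aimed at its own water
                    direction = _unit(rng)
                    heavy = origin + np.array([0.0, 10.0 * (ci + 1), 0.0])
                    frame.donors.append(
                        Donor(heavy=heavy, hydrogen=heavy + 1.0 * direction, group=grp.name)
                    )
                    frame.acceptors.append(
                        Acceptor(pos=heavy + 2.8 * direction, group=None)
                    )
                # decoy: labelled donor whose water sits beyond the cut-off
                direction = _unit(rng)
                heavy = origin + np.array([0.0, -10.0, 0.0])
                frame.donors.append(
                    Donor(heavy=heavy, hydrogen=heavy + 1.0 * direction, group=grp.name)
                )
                frame.acceptors.append(
                    Acceptor(pos=heavy + 3.5 * direction, group=None)
                )
        frames.append(frame)
    return frames


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
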