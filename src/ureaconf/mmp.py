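"""Matched molecular pairs and double-transformation-cycle non-additivity.

Single-cut fragment-and-index pairing: every acyclic single bond between
heavy atoms is cut once, yielding a (context, fragment) decomposition with
one attachment point each; two compounds measured in the same assay that
share a context but differ in the fragment form a matched pair.  Four
compounds connected by two fragment replacements applied in both orders
form a double transformation cycle; the discrepancy between the same
replacement's effect in the two contexts is the cycle's non-additivity in
log units of activity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import find_urea

__all__ = [
    "ActivityRecord",
    "Fragmentation",
    "MatchedPair",
    "TransformationCycle",
    "fragment_single_cut",
    "find_matched_pairs",
    "delta_distribution",
    "find_cycles",
    "nonadditivity",
]


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    smiles: str
    assay_id: str
    doc_id: str
    activity_type: str  # "Ki" or "IC50"
    pactivity: float


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition: context (larger piece) + fragment."""

    context: str  # canonical SMILES of the larger piece, one [*]
    fragment: str  # canonical SMILES of the removed piece, one [*]
    cut_bond: tuple  # (atom_i, atom_j)
    urea_adjacent: bool
    fragment_heavy_atoms: int = 0


@dataclass(frozen=True)
class MatchedPair:
    compound_a: str
    compound_b: str
    context: str
    fragment_a: str
    fragment_b: str
    assay_id: str
    doc_id: str
    activity_type: str
    pactivity_a: float
    pactivity_b: float

    @property
    def delta(self) -> float:
        """pActivity(B) - pActivity(A)."""
        return self.pactivity_b - self.pactivity_a


@dataclass(frozen=True)
class TransformationCycle:
    """Double transformation cycle a-b-d-c with parallel replacements.

    T1 maps a->c and b->d (same fragment replacement); T2 maps a->b and
    c->d.  ``nonadditivity`` is delta(a->c) - delta(b->d), which equals
    pAct(c) - pAct(a) - pAct(d) + pAct(b) exactly.
    """

    a: str
    b: str
    c: str
    d: str
    t1: tuple  # fragment replacement along a->c and b->d
    t2: tuple  # fragment replacement along a->b and c->d
    delta_ac: float
    delta_bd: float
    assay_id: str
    doc_id: str
    activity_type: str

    @property
    def nonadditivity(self) -> float:
        return self.delta_ac - self.delta_bd


def _heavy_atoms(smiles_with_dummy: str) -> int:
    mol = Chem.MolFromSmiles(smiles_with_dummy)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_single_cut(mol: Chem.Mol) -> list[Fragmentation]:
    """Enumerate all single-cut fragmentations of a molecule.

    One Fragmentation per acyclic single bond between heavy atoms.  The
    larger piece (by heavy-atom count, ties broken lexicographically on
    canonical SMILES) is the context.  ``urea_adjacent`` is true when the
    cut bond touches a urea core atom or a substituent first atom of any
    urea match in the molecule.
    """
    urea_atoms: set[int] = set()
    for m in find_urea(mol):
        urea_atoms.update((m.o_idx, m.c_idx, m.n1_idx, m.n2_idx))
        urea_atoms.update(m.subst1)
        urea_atoms.update(m.subst2)
    out = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if mol.GetAtomWithIdx(i).GetAtomicNum() <= 1:
            continue
        if mol.GetAtomWithIdx(j).GetAtomicNum() <= 1:
            continue
        cut = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True,
                                   dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:  # pragma: no cover - acyclic bond always splits
            continue
        smi = [Chem.MolToSmiles(p) for p in pieces]
        heavy = [_heavy_atoms(s) for s in smi]
        if (heavy[0], smi[0]) >= (heavy[1], smi[1]):
            context, fragment = smi[0], smi[1]
            frag_heavy = heavy[1]
        else:
            context, fragment = smi[1], smi[0]
            frag_heavy = heavy[0]
        out.append(
            Fragmentation(
                context=context,
                fragment=fragment,
                cut_bond=(i, j),
                urea_adjacent=bool({i, j} & urea_atoms),
                fragment_heavy_atoms=frag_heavy,
            )
        )
    return out


def _resolve_duplicates(
    records: Iterable[ActivityRecord], policy: str
) -> list[ActivityRecord]:
    grouped: dict[tuple, list[ActivityRecord]] = {}
    for rec in records:
        key = (rec.compound_id, rec.assay_id, rec.doc_id, rec.activity_type)
        grouped.setdefault(key, []).append(rec)
    out = []
    conflicts = []
    for key, recs in grouped.items():
        values = {r.pactivity for r in recs}
        if len(values) == 1:
            out.append(recs[0])
        elif policy == "median":
            out.append(replace(recs[0], pactivity=float(np.median([r.pactivity for r in recs]))))
        else:
            conflicts.append(key)
    if conflicts:
        raise ValueError(
            "conflicting duplicate measurements for (compound, assay, doc, type): "
            + ", ".join(map(str, sorted(conflicts)))
        )
    return out


def find_matched_pairs(
    records: Sequence[ActivityRecord],
    urea_only: bool = True,
    max_fragment_heavy_atoms: int = 12,
    max_fragment_fraction: float = 0.5,
    duplicate_policy: str = "reject",
) -> list[MatchedPair]:
    """Index single-cut fragmentations and emit matched pairs.

    Pairs require identical (context, assay, publication, activity type)
    and different fragments; each pair is reported once with the lower
    compound id as A.  Fragments larger than ``max_fragment_heavy_atoms``
    heavy atoms or more than ``max_fragment_fraction`` of the parent's
    heavy atoms are discarded before indexing.
    """
    records = _resolve_duplicates(records, duplicate_policy)
    frag_cache: dict[str, tuple] = {}
    index: dict[tuple, dict] = {}
    for rec in records:
        if rec.smiles not in frag_cache:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:
                raise ValueError(f"unparsable SMILES for compound {rec.compound_id}")
            parent_heavy = mol.GetNumHeavyAtoms()
            frags = fragment_single_cut(mol)
            frag_cache[rec.smiles] = (parent_heavy, frags)
        parent_heavy, frags = frag_cache[rec.smiles]
        for fr in frags:
            if urea_only and not fr.urea_adjacent:
                continue
            if fr.fragment_heavy_atoms > max_fragment_heavy_atoms:
                continue
            if fr.fragment_heavy_atoms > max_fragment_fraction * parent_heavy:
                continue
            key = (fr.context, rec.assay_id, rec.doc_id, rec.activity_type)
            index.setdefault(key, {})[(rec.compound_id, fr.fragment)] = rec
    pairs: dict[tuple, MatchedPair] = {}
    for (context, assay, doc, atype), bucket in index.items():
        for (id1, f1), (id2, f2) in itertools.combinations(sorted(bucket), 2):
            if id1 == id2 or f1 == f2:
                continue
            r1, r2 = bucket[(id1, f1)], bucket[(id2, f2)]
            if id2 < id1:
                (id1, f1, r1), (id2, f2, r2) = (id2, f2, r2), (id1, f1, r1)
            pair_key = (id1, id2, context, f1, f2, assay, doc, atype)
            pairs[pair_key] = MatchedPair(
                compound_a=id1,
                compound_b=id2,
                context=context,
                fragment_a=f1,
                fragment_b=f2,
                assay_id=assay,
                doc_id=doc,
                activity_type=atype,
                pactivity_a=r1.pactivity,
                pactivity_b=r2.pactivity,
            )
    return sorted(pairs.values(), key=lambda p: (p.compound_a, p.compound_b, p.context, p.fragment_a, p.fragment_b))


def delta_distribution(
    pairs: Sequence[MatchedPair], bin_width: float = 1.0
) -> dict:
    """Summarize matched-pair activity differences.

    Returns a dict with an |delta| histogram (fixed-width bins from 0), a
    per-transformation aggregate table (direction-normalized so fragment_a
    < fragment_b), and the maximum absolute spread.
    """
    if not pairs:
        raise ValueError("no pairs to summarize")
    deltas = np.array([p.delta for p in pairs])
    abs_d = np.abs(deltas)
    n_bins = int(np.floor(abs_d.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(abs_d, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    rows = []
    for p in pairs:
        fa, fb, d = p.fragment_a, p.fragment_b, p.delta
        if fb < fa:
            fa, fb, d = fb, fa, -d
        rows.append({"fragment_from": fa, "fragment_to": fb, "delta": d})
    per_t = (
        pd.DataFrame(rows)
        .groupby(["fragment_from", "fragment_to"])["delta"]
        .agg(["count", "mean", "min", "max"])
        .reset_index()
    )
    return {
        "histogram": hist,
        "per_transformation": per_t,
        "max_abs_delta": float(abs_d.max()),
    }


def _cycle_symmetries(a, b, c, d):
    # relabelings preserving {T1: a->c, b->d} / {T2: a->b, c->d} structure
    return [
        (a, b, c, d),
        (b, a, d, c),
        (c, d, a, b),
        (d, c, b, a),
        (a, c, b, d),
        (c, a, d, b),
        (b, d, a, c),
        (d, b, c, a),
    ]


def find_cycles(pairs: Sequence[MatchedPair]) -> list[TransformationCycle]:
    """Enumerate double transformation cycles among matched pairs.

    All pairs must come from a single (assay, publication, activity-type)
    group.  Each 4-cycle is reported once, in the orientation with the
    lexicographically smallest (a, b, c, d) tuple among the valid
    relabelings.
    """
    if not pairs:
        return []
    groups = {(p.assay_id, p.doc_id, p.activity_type) for p in pairs}
    if len(groups) > 1:
        raise ValueError("pairs span multiple assay/publication/type groups")
    assay, doc, atype = groups.pop()

    # directed edge lookup: (A, B) -> list of (frag_A, frag_B, delta)
    edges: dict[tuple, list] = {}
    pact: dict[str, float] = {}
    for p in pairs:
        edges.setdefault((p.compound_a, p.compound_b), []).append(
            (p.fragment_a, p.fragment_b)
        )
        edges.setdefault((p.compound_b, p.compound_a), []).append(
            (p.fragment_b, p.fragment_a)
        )
        pact[p.compound_a] = p.pactivity_a
        pact[p.compound_b] = p.pactivity_b

    # transformations: normalized fragment replacement -> directed edges
    by_trans: dict[tuple, list] = {}
    for (u, v), frs in edges.items():
        for f_u, f_v in frs:
            if f_u < f_v:
                by_trans.setdefault((f_u, f_v), []).append((u, v, f_u, f_v))

    found: dict[frozenset, tuple] = {}
    for t1, directed in by_trans.items():
        for (a, c, f_a, f_c), (b, d, f_b, f_d) in itertools.combinations(directed, 2):
            if len({a, b, c, d}) != 4:
                continue
            # need parallel edges a-b and c-d with one common replacement
            for f2a, f2b in edges.get((a, b), []):
                for f2c, f2d in edges.get((c, d), []):
                    if (f2a, f2b) != (f2c, f2d):
                        continue
                    key = frozenset(
                        (frozenset((a, c)), frozenset((b, d)),
                         frozenset((a, b)), frozenset((c, d)))
                    )
                    labeling = min(
                        lab for lab in _cycle_symmetries(a, b, c, d)
                    )
                    prev = found.get(key)
                    if prev is None or labeling < prev[0]:
                        found[key] = (labeling, (a, b, c, d), t1, (f2a, f2b))
                    break
                else:
                    continue
                break

    cycles = []
    for key, (labeling, orig, t1, t2) in sorted(found.items(), key=lambda kv: kv[1][0]):
        a, b, c, d = labeling
        # recover fragment replacements for the canonical labeling
        cycles.append(
            TransformationCycle(
                a=a, b=b, c=c, d=d,
                t1=_edge_fragments(edges, a, c, b, d),
                t2=_edge_fragments(edges, a, b, c, d),
                delta_ac=pact[c] - pact[a],
                delta_bd=pact[d] - pact[b],
                assay_id=assay, doc_id=doc, activity_type=atype,
            )
        )
    return cycles


def _edge_fragments(edges: dict, u, v, x, y) -> tuple:
    """Common fragment replacement along parallel edges u->v and x->y."""
    for f1 in edges.get((u, v), []):
        for f2 in edges.get((x, y), []):
            if f1 == f2:
                return f1
    raise ValueError("parallel edges carry no common replacement")


def nonadditivity(cycle: TransformationCycle) -> float:
    """Signed non-additivity of a double transformation cycle, log units."""
    return cycle.nonadditivity
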