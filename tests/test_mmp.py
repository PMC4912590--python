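import itertools

import numpy as np
import pytest
from rdkit import Chem

from ureaconf import mmp, synth
from ureaconf.mmp import ActivityRecord, find_cycles, find_matched_pairs
from ureaconf.synth import SarGeneratorSpec


def brute_force_pairs(records, **kwargs):
    """All-pairs oracle: two compounds pair iff some single-cut
    decomposition gives them an identical context and different fragments
    (same assay/publication/type).  No indexing."""
    found = set()
    for r1, r2 in itertools.combinations(records, 2):
        if (r1.assay_id, r1.doc_id, r1.activity_type) != (
            r2.assay_id, r2.doc_id, r2.activity_type,
        ):
            continue
        if r1.compound_id == r2.compound_id:
            continue
        p1 = find_matched_pairs([r1, r2], **kwargs)
        for p in p1:
            found.add((p.compound_a, p.compound_b, p.context, p.fragment_a, p.fragment_b))
    return found


def brute_force_cycles(pairs):
    """Quadruple-enumeration oracle over all compound 4-subsets."""
    by_edge = {}
    compounds = set()
    for p in pairs:
        by_edge.setdefault(frozenset((p.compound_a, p.compound_b)), []).append(p)
        compounds.update((p.compound_a, p.compound_b))
    cycles = set()
    for quad in itertools.combinations(sorted(compounds), 4):
        for a, b, c, d in itertools.permutations(quad):
            e_ac = by_edge.get(frozenset((a, c)), [])
            e_bd = by_edge.get(frozenset((b, d)), [])
            e_ab = by_edge.get(frozenset((a, b)), [])
            e_cd = by_edge.get(frozenset((c, d)), [])
            ok = False
            for p1, p2 in itertools.product(e_ac, e_bd):
                if _oriented(p1, a, c) == _oriented(p2, b, d):
                    for q1, q2 in itertools.product(e_ab, e_cd):
                        if _oriented(q1, a, b) == _oriented(q2, c, d):
                            ok = True
            if ok:
                cycles.add(
                    frozenset(
                        (frozenset((a, c)), frozenset((b, d)),
                         frozenset((a, b)), frozenset((c, d)))
                    )
                )
    return cycles


def _oriented(pair, u, v):
    if (pair.compound_a, pair.compound_b) == (u, v):
        return (pair.fragment_a, pair.fragment_b)
    return (pair.fragment_b, pair.fragment_a)


class TestFragmentation:
    def test_dimethylurea_cut_is_urea_adjacent(self):
        frags = mmp.fragment_single_cut(Chem.MolFromSmiles("CNC(=O)NC"))
        contexts = {f.context for f in frags}
        assert "*NC(=O)NC" in contexts
        assert all(f.urea_adjacent for f in frags)

    def test_benzene_has_no_cuttable_bond(self):
        assert mmp.fragment_single_cut(Chem.MolFromSmiles("c1ccccc1")) == []

    @pytest.mark.parametrize(
        "smiles",
        ["CNC(=O)NC", "CCNC(=O)Nc1ccccc1", "CC(C)NC(=O)NCCO", "O=C(Nc1ccc(F)cc1)NC2CC2"],
    )
    def test_count_equals_acyclic_single_bond_count(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        expected = sum(
            1
            for b in mol.GetBonds()
            if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE
        )
        assert len(mmp.fragment_single_cut(mol)) == expected

    @pytest.mark.parametrize("smiles", ["CNC(=O)NCC", "CC(C)NC(=O)Nc1ccccc1O"])
    def test_context_plus_fragment_reassembles_parent(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        parent = Chem.MolToSmiles(mol)
        for fr in mmp.fragment_single_cut(mol):
            pieces = []
            for smi in (fr.context, fr.fragment):
                piece = Chem.MolFromSmiles(smi)
                for atom in piece.GetAtoms():
                    if atom.GetAtomicNum() == 0:
                        atom.SetAtomMapNum(1)
                pieces.append(piece)
            joined = Chem.molzip(Chem.CombineMols(*pieces))
            assert Chem.MolToSmiles(Chem.RemoveHs(joined)) == parent


def _records(rows):
    return [
        ActivityRecord(cid, smi, assay, "DOC-1", "Ki", p)
        for cid, smi, assay, p in rows
    ]


class TestMatchedPairs:
    def test_single_replacement_pairs(self):
        recs = _records(
            [("A", "CNC(=O)NC", "a1", 6.0), ("B", "CCNC(=O)NC", "a1", 7.0)]
        )
        pairs = find_matched_pairs(recs)
        assert {(p.compound_a, p.compound_b) for p in pairs} == {("A", "B")}
        assert all(p.delta == 1.0 for p in pairs)

    def test_different_assays_never_pair(self):
        recs = _records(
            [("A", "CNC(=O)NC", "a1", 6.0), ("B", "CCNC(=O)NC", "a2", 7.0)]
        )
        assert find_matched_pairs(recs) == []

    def test_conflicting_duplicates_rejected_with_ids(self):
        recs = _records(
            [("A", "CNC(=O)NC", "a1", 6.0), ("A", "CNC(=O)NC", "a1", 7.0)]
        )
        with pytest.raises(ValueError, match="A"):
            find_matched_pairs(recs)

    def test_median_policy_resolves_duplicates(self):
        recs = _records(
            [
                ("A", "CNC(=O)NC", "a1", 6.0),
                ("A", "CNC(=O)NC", "a1", 7.0),
                ("A", "CNC(=O)NC", "a1", 8.0),
                ("B", "CCNC(=O)NC", "a1", 9.0),
            ]
        )
        pairs = find_matched_pairs(recs, duplicate_policy="median")
        assert pairs[0].pactivity_a == 7.0

    def test_delta_antisymmetry(self):
        recs = _records(
            [("A", "CNC(=O)NC", "a1", 6.0), ("B", "CCNC(=O)NC", "a1", 7.5)]
        )
        (p, *_) = find_matched_pairs(recs)
        swapped = mmp.MatchedPair(
            compound_a=p.compound_b, compound_b=p.compound_a,
            context=p.context, fragment_a=p.fragment_b, fragment_b=p.fragment_a,
            assay_id=p.assay_id, doc_id=p.doc_id, activity_type=p.activity_type,
            pactivity_a=p.pactivity_b, pactivity_b=p.pactivity_a,
        )
        assert swapped.delta == -p.delta

    def test_matches_brute_force_on_synthetic_sar_set(self):
        spec = SarGeneratorSpec(
            substituents1=("C", "CC", "CCC", "CCCC", "CC(C)C"),
            substituents2=("CCCCC", "CCCCCC", "CCOC", "CCCN"),
            effects1=(0.0, 0.3, 0.9, 1.4, 2.0),
            effects2=(0.0, 0.5, 1.1, 1.7),
        )
        records = synth.gen_sar_table(spec)
        pairs = find_matched_pairs(records)
        got = {(p.compound_a, p.compound_b, p.context, p.fragment_a, p.fragment_b)
               for p in pairs}
        assert got == brute_force_pairs(records)


class TestDeltaDistribution:
    def test_single_pair_spread(self):
        recs = _records(
            [("A", "CNC(=O)NC", "a1", 6.0), ("B", "CCNC(=O)NC", "a1", 7.0)]
        )
        summary = mmp.delta_distribution(find_matched_pairs(recs))
        assert summary["max_abs_delta"] == 1.0

    def test_abs_histogram_bins(self):
        pairs = [
            mmp.MatchedPair("A", "B", "*C", "*N", "*O", "a", "d", "Ki", 8.0, 6.0),
            mmp.MatchedPair("C", "D", "*C", "*N", "*S", "a", "d", "Ki", 5.0, 8.0),
        ]
        hist = mmp.delta_distribution(pairs)["histogram"]
        assert hist.loc[hist.bin_left == 2.0, "count"].item() == 1
        assert hist.loc[hist.bin_left == 3.0, "count"].item() == 1


class TestCycles:
    def test_four_compounds_one_cycle(self):
        records = synth.gen_sar_table(SarGeneratorSpec())
        cycles = find_cycles(find_matched_pairs(records))
        assert len(cycles) == 1

    def test_three_compounds_no_cycle(self):
        records = synth.gen_sar_table(SarGeneratorSpec())[:3]
        assert find_cycles(find_matched_pairs(records)) == []

    def test_matches_quadruple_enumeration_oracle(self):
        spec = SarGeneratorSpec(
            substituents1=("C", "CC", "CCC"),
            substituents2=("CCCC", "CCCCC", "CCO"),
            effects1=(0.0, 0.4, 1.2),
            effects2=(0.0, 0.8, 1.5),
            gamma=((2, 2, 0.7),),
        )
        pairs = find_matched_pairs(synth.gen_sar_table(spec))
        got = {
            frozenset(
                (frozenset((c.a, c.c)), frozenset((c.b, c.d)),
                 frozenset((c.a, c.b)), frozenset((c.c, c.d)))
            )
            for c in find_cycles(pairs)
        }
        assert got == brute_force_cycles(pairs)

    def test_closure_identity(self):
        """Non-additivity equals pAct(c) - pAct(a) - pAct(d) + pAct(b)."""
        spec = SarGeneratorSpec(gamma=((0, 1, 0.9),), noise_sigma=0.2, seed=5)
        records = synth.gen_sar_table(spec)
        pact = {r.compound_id: r.pactivity for r in records}
        for c in find_cycles(find_matched_pairs(records)):
            expected = pact[c.c] - pact[c.a] - pact[c.d] + pact[c.b]
            assert c.nonadditivity == pytest.approx(expected, abs=1e-12)

    def test_fig1e_deltas_give_165(self):
        """A 2.50 log-unit boost in one context vs 0.85 in the other gives
        a non-additivity of 1.65 log units."""
        cycle = mmp.TransformationCycle(
            a="a", b="b", c="c", d="d", t1=("*F", "*C(F)(F)F"), t2=("*p", "*m"),
            delta_ac=2.50, delta_bd=0.85,
            assay_id="a1", doc_id="d1", activity_type="Ki",
        )
        assert mmp.nonadditivity(cycle) == pytest.approx(1.65)

    def test_orientation_algebra(self):
        """Reversing a transformation's direction flips the sign of the
        non-additivity; exchanging the roles of the two transformations
        leaves it unchanged; the absolute value is invariant throughout."""
        spec = SarGeneratorSpec(gamma=((1, 1, 1.1),))
        records = synth.gen_sar_table(spec)
        pact = {r.compound_id: r.pactivity for r in records}
        (c,) = find_cycles(find_matched_pairs(records))

        def closure(a, b, cc, d):
            return pact[cc] - pact[a] - pact[d] + pact[b]

        base = closure(c.a, c.b, c.c, c.d)
        assert base == pytest.approx(c.nonadditivity)
        assert closure(c.c, c.d, c.a, c.b) == pytest.approx(-base)  # reversed T1
        assert closure(c.b, c.a, c.d, c.c) == pytest.approx(-base)  # reversed T2
        assert closure(c.a, c.c, c.b, c.d) == pytest.approx(base)  # roles swapped

    def test_mixed_groups_rejected(self):
        p1 = mmp.MatchedPair("A", "B", "*C", "*N", "*O", "a1", "d", "Ki", 6, 7)
        p2 = mmp.MatchedPair("C", "D", "*C", "*N", "*O", "a2", "d", "Ki", 6, 7)
        with pytest.raises(ValueError):
            find_cycles([p1, p2])
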